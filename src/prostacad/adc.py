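"""Voxel-wise apparent diffusion coefficient maps and CDF functional features.

For a b = 0 baseline signal ``s0`` and a higher-b signal ``s_n`` the ADC at a
voxel is ``ln(s0 / s_n) / (b_n - b0)`` (mm^2/s).  Malignant tissue restricts
water diffusion, so its ADC distribution sits left of the benign one; rather
than feeding variable-size voxel sets to a classifier, each case's in-gland
ADC distribution per b-value is summarized by its empirical CDF evaluated on
a fixed grid spanning a cohort-wide ADC range (100 steps by default).  The
default functional feature vector has 122 entries: 8 b-values x 15
subsampled CDF grid points, plus the case-level in-mask ADC minimum and
maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .features import FeatureVector
from .phantom import ProstateCase

__all__ = [
    "ADCMap",
    "ADCRange",
    "FunctionalLayout",
    "compute_adc_map",
    "estimate_global_range",
    "adc_cdf",
    "functional_feature_vector",
]

#: symmetric widening applied to a degenerate (zero-width) global range, mm^2/s
RANGE_EPSILON = 1e-6


@dataclass
class ADCMap:
    """ADC volume for one (b0, b_n) pair with its valid-voxel mask.

    ``valid_mask`` marks in-mask voxels where both signals were strictly
    positive, i.e. where the log-ratio is defined.
    """

    b_value: float
    b0: float
    values: np.ndarray
    valid_mask: np.ndarray

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass(frozen=True)
class ADCRange:
    """Cohort-wide [adc_min, adc_max] split into ``n_steps`` grid values."""

    adc_min: float
    adc_max: float
    n_steps: int = 100

    def __post_init__(self) -> None:
        if not self.adc_min < self.adc_max:
            raise ValueError("adc_min must be strictly below adc_max")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.adc_min, self.adc_max, self.n_steps)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "adc_min": self.adc_min,
                    "adc_max": self.adc_max,
                    "n_steps": self.n_steps,
                }
            )
        )
        return path

    @staticmethod
    def from_json(path: str | Path) -> "ADCRange":
        d = json.loads(Path(path).read_text())
        return ADCRange(d["adc_min"], d["adc_max"], d["n_steps"])


def compute_adc_map(
    s0_volume: np.ndarray,
    sn_volume: np.ndarray,
    b_n: float,
    mask: np.ndarray,
    b0: float = 0.0,
) -> ADCMap:
    """Voxel-wise ``ln(s0/s_n)/(b_n - b0)`` over the mask.

    Voxels where either signal is non-positive are dropped from the valid
    mask instead of clipped — the log-ratio is undefined there and silent
    clipping would bias the CDF.
    """
    if b_n == b0:
        raise ValueError("b_n must differ from the baseline b0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    s0 = np.asarray(s0_volume, dtype=float)
    sn = np.asarray(sn_volume, dtype=float)
    if s0.shape != mask.shape or sn.shape != mask.shape:
        raise ValueError("volumes and mask must share one grid shape")
    valid = mask & (s0 > 0) & (sn > 0)
    values = np.zeros(mask.shape)
    values[valid] = np.log(s0[valid] / sn[valid]) / (b_n - b0)
    return ADCMap(b_value=float(b_n), b0=float(b0), values=values, valid_mask=valid)


def case_adc_maps(
    case: ProstateCase, b_values: Sequence[float] | None = None
) -> dict[float, ADCMap]:
    """One ADC map per nonzero b-value, over the whole-prostate mask."""
    if b_values is None:
        b_values = case.nonzero_b_values
    s0 = case.dw_volumes[0.0]
    maps = {}
    for b in b_values:
        if b not in case.dw_volumes:
            raise ValueError(f"{case.case_id}: missing b-value {b}")
        maps[b] = compute_adc_map(s0, case.dw_volumes[b], b, case.prostate_mask)
    return maps


def estimate_global_range(
    cohort: Iterable[ProstateCase],
    b_values: Sequence[float] | None = None,
    n_steps: int = 100,
) -> ADCRange:
    """Min/max ADC over all cases, b-values and valid voxels.

    The returned range is what makes CDF features comparable across cases;
    persist it (``to_json``) and reuse it when featurizing new cases.
    """
    lo, hi = np.inf, -np.inf
    any_case = False
    for case in cohort:
        any_case = True
        for adc_map in case_adc_maps(case, b_values).values():
            vals = adc_map.valid_values
            if vals.size:
                lo = min(lo, float(vals.min()))
                hi = max(hi, float(vals.max()))
    if not any_case:
        raise ValueError("cohort is empty")
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("no valid ADC voxels in the cohort")
    if hi - lo < RANGE_EPSILON:  # degenerate: widen symmetrically around the midpoint
        mid = 0.5 * (lo + hi)
        lo, hi = mid - RANGE_EPSILON, mid + RANGE_EPSILON
    return ADCRange(lo, hi, n_steps)


def adc_cdf(adc_map: ADCMap, adc_range: ADCRange) -> np.ndarray:
    """Empirical CDF of valid-voxel ADCs on the range's fixed grid.

    Entry k is the fraction of valid voxels with ADC <= grid[k]; values above
    ``adc_max`` are clamped into the top step, so the last entry is always 1.
    """
    vals = adc_map.valid_values
    if vals.size == 0:
        raise ValueError("ADC map has no valid voxels")
    clamped = np.minimum(np.sort(vals), adc_range.adc_max)
    counts = np.searchsorted(clamped, adc_range.grid, side="right")
    return counts / vals.size


@dataclass(frozen=True)
class FunctionalLayout:
    """Composition of the functional feature vector.

    The default — 15 equally spaced CDF grid samples per b-value plus the
    case ADC extrema — yields 8 x 15 + 2 = 122 features.
    """

    n_cdf_samples: int = 15
    include_extrema: bool = True

    def sample_indices(self, n_steps: int) -> np.ndarray:
        return np.round(np.linspace(0, n_steps - 1, self.n_cdf_samples)).astype(int)

    def width(self, n_b_values: int) -> int:
        return n_b_values * self.n_cdf_samples + (2 if self.include_extrema else 0)


DEFAULT_LAYOUT = FunctionalLayout()


def functional_feature_vector(
    case: ProstateCase,
    adc_range: ADCRange,
    layout: FunctionalLayout = DEFAULT_LAYOUT,
    b_values: Sequence[float] | None = None,
) -> FeatureVector:
    """FS-style functional features for one case (length 122 by default)."""
    if b_values is None:
        b_values = case.nonzero_b_values
    maps = case_adc_maps(case, b_values)
    idx = layout.sample_indices(adc_range.n_steps)
    names: list[str] = []
    values: list[float] = []
    all_min, all_max = np.inf, -np.inf
    for b in b_values:
        cdf = adc_cdf(maps[b], adc_range)
        names.extend(f"adc_cdf_b{int(b)}_g{k:02d}" for k in idx)
        values.extend(cdf[idx])
        vals = maps[b].valid_values
        if vals.size:
            all_min = min(all_min, float(vals.min()))
            all_max = max(all_max, float(vals.max()))
    if layout.include_extrema:
        names += ["adc_case_min", "adc_case_max"]
        values += [all_min, all_max]
    return FeatureVector(names, np.asarray(values))
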