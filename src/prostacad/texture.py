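"""Whole-gland 3D T2W texture features: 36 first-order + 6 GLCM + 16 GLRLM.

In-mask intensities are min-max normalized to integer gray levels 0..255.
The co-occurrence matrix is a single 256 x 256 count matrix accumulated over
all 26 unit-cube neighbor offsets (8 in-plane at angles 0, pi/4, pi/2, 3pi/4
and their opposites, plus all 9 upper-layer and 9 lower-layer offsets) with
both voxels required in-mask, then normalized to unit sum.  The run-length
matrix accumulates maximal equal-level runs along in-plane X lines and
through-plane Z columns; mask gaps terminate runs.  Malignant glands are
more heterogeneous, which these statistics are designed to pick up.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import FeatureVector
from .phantom import ProstateCase

__all__ = [
    "NormalizedVolume",
    "GLCMatrix",
    "GLRLMatrix",
    "normalize_gray_levels",
    "first_order_features",
    "build_glcm",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "texture_feature_vector",
    "NEIGHBOR_OFFSETS_26",
]

N_LEVELS = 256

#: all 26 offsets of the unit neighborhood cube (both directions included)
NEIGHBOR_OFFSETS_26 = tuple(
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off != (0, 0, 0)
)


@dataclass
class NormalizedVolume:
    """Integer gray levels 0..255 inside the mask; outside values are ignored."""

    levels: np.ndarray
    mask: np.ndarray

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


@dataclass
class GLCMatrix:
    matrix: np.ndarray  # 256 x 256
    offsets: tuple[tuple[int, int, int], ...]
    normalized: bool


@dataclass
class GLRLMatrix:
    matrix: np.ndarray  # 256 x L_max, counts
    orientations: tuple[str, ...] = ("xy-horizontal", "z-vertical")

    @property
    def max_run_length(self) -> int:
        return self.matrix.shape[1]


def normalize_gray_levels(volume: np.ndarray, mask: np.ndarray) -> NormalizedVolume:
    """Affine min-max map of in-mask intensities to integers 0..255.

    The in-mask maximum maps to 255 (floor after scaling); a constant volume
    maps to all zeros.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vol = np.asarray(volume, dtype=float)
    vals = vol[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.shape, dtype=np.int16)
    if hi > lo:
        scaled = np.floor((vol - lo) * (N_LEVELS - 1) / (hi - lo))
        levels = np.clip(scaled, 0, N_LEVELS - 1).astype(np.int16)
    levels[~mask] = 0
    return NormalizedVolume(levels=levels, mask=mask)


# ---------------------------------------------------------------------------
# first-order (36)


def _nan_to_zero(x: float) -> float:
    return 0.0 if not np.isfinite(x) else float(x)


def first_order_features(normvol: NormalizedVolume) -> FeatureVector:
    """The fixed 36-item first-order roster on in-mask gray levels.

    Moments and entropy (7), empirical CDF at 10 equally spaced levels,
    percentiles 10..100 step 10, histogram metadata (n_obs, n_bins,
    bin_width, lower_limit), counts in 4 equal-width bins over 0..255, and
    the duplicated descriptive mean.
    """
    x = normvol.in_mask_levels.astype(float)
    if x.size == 0:
        raise ValueError("mask is empty")
    names: list[str] = []
    values: list[float] = []

    hist256 = np.bincount(x.astype(int), minlength=N_LEVELS) / x.size
    nz = hist256[hist256 > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    with np.errstate(all="ignore"):
        moments = {
            "fo_mean": float(x.mean()),
            "fo_median": float(np.median(x)),
            "fo_variance": float(x.var()),
            "fo_std": float(x.std()),
            "fo_kurtosis": _nan_to_zero(stats.kurtosis(x)),
            "fo_skewness": _nan_to_zero(stats.skew(x)),
            "fo_entropy": entropy,
        }
    names += list(moments)
    values += list(moments.values())

    cdf_levels = np.linspace(0, N_LEVELS - 1, 10)
    for t in cdf_levels:
        names.append(f"fo_cdf_{int(round(t)):03d}")
        values.append(float((x <= t).mean()))

    for q in range(10, 101, 10):
        names.append(f"fo_p{q:03d}")
        values.append(float(np.percentile(x, q)))

    n_bins = 4
    counts, edges = np.histogram(x, bins=n_bins, range=(0, N_LEVELS - 1))
    names += ["fo_n_obs", "fo_n_bins", "fo_bin_width", "fo_lower_limit"]
    values += [float(x.size), float(n_bins), float(edges[1] - edges[0]), float(edges[0])]
    for k in range(n_bins):
        names.append(f"fo_hist_bin{k + 1}")
        values.append(float(counts[k]))

    names.append("fo_descriptive_mean")
    values.append(moments["fo_mean"])
    return FeatureVector(names, np.asarray(values))


# ---------------------------------------------------------------------------
# GLCM (6)


def build_glcm(normvol: NormalizedVolume, normalize: bool = True) -> GLCMatrix:
    """Accumulate co-occurrence counts over all 26 neighbor offsets.

    Only pairs with both voxels in-mask contribute.  With ``normalize`` the
    matrix is scaled to unit sum (required by :func:`glcm_features`).
    """
    levels = normvol.levels
    mask = normvol.mask
    shape = levels.shape
    counts = np.zeros(N_LEVELS * N_LEVELS, dtype=np.int64)
    for off in NEIGHBOR_OFFSETS_26:
        src = tuple(
            slice(max(0, -o), s - max(0, o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), s - max(0, -o)) for o, s in zip(off, shape)
        )
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = levels[src][valid].astype(np.int64)
        b = levels[dst][valid].astype(np.int64)
        counts += np.bincount(a * N_LEVELS + b, minlength=N_LEVELS * N_LEVELS)
    total = counts.sum()
    if total < 1:
        raise ValueError("no valid in-mask voxel pairs")
    matrix = counts.reshape(N_LEVELS, N_LEVELS).astype(float)
    if normalize:
        matrix /= total
    return GLCMatrix(matrix=matrix, offsets=NEIGHBOR_OFFSETS_26, normalized=normalize)


def glcm_features(glcm: GLCMatrix) -> FeatureVector:
    """Contrast, correlation, ASM, dissimilarity, homogeneity, energy.

    Correlation at zero marginal variance (single occupied gray level) is
    reported as 1 by convention — a constant texture is perfectly
    predictable — instead of propagating a 0/0.
    """
    if not glcm.normalized:
        raise ValueError("glcm_features requires a normalized matrix")
    p = glcm.matrix
    i, j = np.nonzero(p)
    w = p[i, j]
    diff = (i - j).astype(float)
    contrast = float(w @ diff**2)
    dissimilarity = float(w @ np.abs(diff))
    homogeneity = float(w @ (1.0 / (1.0 + diff**2)))
    asm = float(w @ w)
    energy = float(np.sqrt(asm))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    lev = np.arange(N_LEVELS, dtype=float)
    mu_i, mu_j = float(lev @ pi), float(lev @ pj)
    var_i = float(((lev - mu_i) ** 2) @ pi)
    var_j = float(((lev - mu_j) ** 2) @ pj)
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0
    else:
        cov = float(w @ ((i - mu_i) * (j - mu_j)))
        correlation = cov / np.sqrt(var_i * var_j)
    return FeatureVector(
        [
            "glcm_contrast",
            "glcm_correlation",
            "glcm_asm",
            "glcm_dissimilarity",
            "glcm_homogeneity",
            "glcm_energy",
        ],
        np.array([contrast, correlation, asm, dissimilarity, homogeneity, energy]),
    )


# ---------------------------------------------------------------------------
# GLRLM (16)


def _accumulate_runs(lines: np.ndarray, runs: dict[tuple[int, int], int]) -> None:
    """RLE of each row of ``lines`` (out-of-mask = -1 sentinel breaks runs)."""
    n_lines, length = lines.shape
    # append a sentinel column so runs never cross line boundaries
    flat = np.hstack([lines, np.full((n_lines, 1), -1, dtype=lines.dtype)]).ravel()
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change, flat.size - 1]
    levels = flat[starts]
    lengths = ends - starts + 1
    keep = levels >= 0
    for lev, ln in zip(levels[keep], lengths[keep]):
        runs[(int(lev), int(ln))] = runs.get((int(lev), int(ln)), 0) + 1


def build_glrlm(normvol: NormalizedVolume) -> GLRLMatrix:
    """Maximal equal-level runs along X within each (y, z) line and along Z
    within each (x, y) column, pooled into one 256 x L_max count matrix."""
    if not normvol.mask.any():
        raise ValueError("mask is empty")
    arr = np.where(normvol.mask, normvol.levels, -1).astype(np.int16)
    runs: dict[tuple[int, int], int] = {}
    # X runs: axis 0 as the run axis -> lines indexed by (y, z)
    _accumulate_runs(np.moveaxis(arr, 0, -1).reshape(-1, arr.shape[0]), runs)
    # Z runs: axis 2 as the run axis -> columns indexed by (x, y)
    _accumulate_runs(arr.reshape(-1, arr.shape[2]), runs)
    if not runs:
        raise ValueError("no in-mask runs found")
    l_max = max(ln for _, ln in runs)
    matrix = np.zeros((N_LEVELS, l_max), dtype=np.int64)
    for (lev, ln), c in runs.items():
        matrix[lev, ln - 1] = c
    return GLRLMatrix(matrix=matrix)


GLRLM_FEATURE_NAMES = [
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_glnn",
    "glrlm_rln",
    "glrlm_rlnn",
    "glrlm_rp",
    "glrlm_glv",
    "glrlm_rv",
    "glrlm_re",
    "glrlm_lglre",
    "glrlm_hglre",
    "glrlm_srlgle",
    "glrlm_srhgle",
    "glrlm_lrlgle",
    "glrlm_lrhgle",
]


def glrlm_features(glrlm: GLRLMatrix, n_voxels: int) -> FeatureVector:
    """The 16 standard run-length statistics.

    Gray-level weights use 1-based levels (level i weighs i + 1) so the
    low-gray-level emphases stay defined at level 0.  Run percentage is the
    run count over ``n_voxels`` times the number of orientation families.
    """
    p = glrlm.matrix.astype(float)
    nr = p.sum()
    if nr < 1:
        raise ValueError("run-length matrix holds no runs")
    n_levels, l_max = p.shape
    i = (np.arange(n_levels, dtype=float) + 1.0)[:, None]  # 1-based gray level
    j = (np.arange(l_max, dtype=float) + 1.0)[None, :]  # run length
    pg = p.sum(axis=1)  # per gray level
    pr = p.sum(axis=0)  # per run length

    sre = float((p / j**2).sum() / nr)
    lre = float((p * j**2).sum() / nr)
    gln = float((pg**2).sum() / nr)
    glnn = gln / nr
    rln = float((pr**2).sum() / nr)
    rlnn = rln / nr
    rp = float(nr / (n_voxels * len(glrlm.orientations)))
    mu_g = float((i[:, 0] * pg).sum() / nr)
    glv = float((pg * (i[:, 0] - mu_g) ** 2).sum() / nr)
    mu_r = float((j[0] * pr).sum() / nr)
    rv = float((pr * (j[0] - mu_r) ** 2).sum() / nr)
    q = p[p > 0] / nr
    re = float(-(q * np.log2(q)).sum())
    lglre = float((p / i**2).sum() / nr)
    hglre = float((p * i**2).sum() / nr)
    srlgle = float((p / (i**2 * j**2)).sum() / nr)
    srhgle = float((p * i**2 / j**2).sum() / nr)
    lrlgle = float((p * j**2 / i**2).sum() / nr)
    lrhgle = float((p * i**2 * j**2).sum() / nr)
    return FeatureVector(
        GLRLM_FEATURE_NAMES,
        np.array(
            [sre, lre, gln, glnn, rln, rlnn, rp, glv, rv, re,
             lglre, hglre, srlgle, srhgle, lrlgle, lrhgle]
        ),
    )


def texture_feature_vector(case: ProstateCase) -> FeatureVector:
    """First-order (36) + GLCM (6) + GLRLM (16) on the whole-gland T2W = 58."""
    normvol = normalize_gray_levels(case.t2w_volume, case.prostate_mask)
    fo = first_order_features(normvol)
    glcm = glcm_features(build_glcm(normvol))
    glrlm = glrlm_features(build_glrlm(normvol), int(normvol.mask.sum()))
    return FeatureVector.concat([fo, glcm, glrlm])
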