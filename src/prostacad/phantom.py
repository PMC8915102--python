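"""Synthetic multi-parametric prostate MR phantom cohorts.

Every downstream stage of the pipeline (ADC-CDF functional features, 3D
texture, spherical-harmonics shape markers, PSA fusion, classification) is
exercised against cohorts produced here, since clinical DW/T2W prostate data
with expert segmentations cannot be redistributed.  Each synthetic case
carries the class-conditional structure the diagnostic method relies on:

* **Diffusion**: the DW signal follows a mono-exponential decay
  ``s_n = s0 * exp(-b_n * D)`` with the voxel-wise diffusion coefficient D
  drawn from a class distribution — malignant tissue restricts water motion,
  so its mean apparent diffusion coefficient is lower than the benign mean.
* **Texture**: the T2W volume is a smoothed Gaussian random field whose
  correlation length is shorter for malignant cases, i.e. malignant glands
  look more heterogeneous at the voxel scale.
* **Shape**: the lesion is a star-shaped solid whose surface radius is a
  smooth base plus a band-limited angular perturbation; the perturbation
  amplitude is larger for malignant lesions (more complex surfaces).
* **PSA**: log-normal per class, truncated below at 4 ng/mL (the screening
  inclusion threshold), with a higher malignant mean.

All randomness flows from a single seed through ``numpy`` seed sequences, so
cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .spharm import real_sh_degree_block

__all__ = [
    "DEFAULT_B_VALUES",
    "PhantomConfig",
    "ProstateCase",
    "PhantomError",
    "generate_cohort",
    "generate_case",
    "ellipsoid_mask",
    "star_shaped_mask",
]

#: The nine diffusion-sensitization strengths (s/mm^2) of the acquisition
#: protocol the pipeline expects: a b = 0 baseline plus eight higher values.
DEFAULT_B_VALUES = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 1400.0)


class PhantomError(ValueError):
    """Invalid phantom configuration or infeasible geometry."""


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the synthetic cohort generator.

    Defaults follow the study conditions the pipeline targets: 80 cases with
    a 43 benign / 37 malignant split, the nine-b-value DW protocol, and a
    malignant mean ADC (0.9e-3 mm^2/s) half the benign one (1.8e-3 mm^2/s).
    """

    n_cases: int = 80
    class_balance: float = 37.0 / 80.0  # fraction malignant
    grid_shape: tuple[int, int, int] = (36, 36, 28)
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    adc_benign_mean: float = 1.8e-3  # mm^2/s
    adc_malignant_mean: float = 0.9e-3  # mm^2/s
    adc_sd: float = 2.0e-4  # mm^2/s, voxel-level spread
    noise_sd: float = 5.0  # signal units, additive Gaussian on DW volumes
    texture_corr_len_benign: float = 3.0  # voxels
    texture_corr_len_malignant: float = 1.2  # voxels
    lesion_spike_amp_benign: float = 0.06  # relative radial perturbation
    lesion_spike_amp_malignant: float = 0.25
    psa_benign_mean: float = 8.0  # ng/mL
    psa_malignant_mean: float = 18.0  # ng/mL
    seed: int = 0
    # secondary knobs
    s0_intensity: float = 1000.0  # baseline DW signal inside the gland
    signal_floor: float = 1.0  # clip floor keeping log(s0/sn) defined
    lesion_radius: float = 4.5  # voxels, base radius r0
    psa_log_sd: float = 0.4  # sd of log(PSA) within a class

    def validate(self) -> None:
        if self.n_cases < 0:
            raise PhantomError("n_cases must be non-negative")
        if not 0.0 <= self.class_balance <= 1.0:
            raise PhantomError("class_balance must lie in [0, 1]")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise PhantomError("grid_shape must be three positive integers")
        if len(self.b_values) < 2 or self.b_values[0] != 0.0:
            raise PhantomError("b_values must start at the b = 0 baseline")
        if any(b < 0 for b in self.b_values):
            raise PhantomError("b_values must be non-negative")
        if not self.adc_malignant_mean < self.adc_benign_mean:
            raise PhantomError(
                "malignant mean ADC must be below the benign mean "
                "(tumors restrict water motion)"
            )
        if min(self.psa_benign_mean, self.psa_malignant_mean) <= 4.0:
            raise PhantomError("class PSA means must exceed the 4 ng/mL threshold")
        if self.lesion_radius <= 0:
            raise PhantomError("lesion_radius must be positive")


@dataclass
class ProstateCase:
    """One subject: DW series, T2W volume, masks, PSA and diagnosis."""

    case_id: str
    dw_volumes: dict[float, np.ndarray]  # b-value -> 3D volume
    t2w_volume: np.ndarray
    prostate_mask: np.ndarray
    lesion_mask: np.ndarray
    psa: float
    label: Literal["benign", "malignant"]

    def validate(self) -> None:
        if 0.0 not in self.dw_volumes:
            raise ValueError("dw_volumes must contain the b = 0 baseline")
        shape = self.t2w_volume.shape
        for b, vol in self.dw_volumes.items():
            if vol.shape != shape:
                raise ValueError(f"DW volume at b={b} has shape {vol.shape} != {shape}")
        if self.prostate_mask.shape != shape or self.lesion_mask.shape != shape:
            raise ValueError("masks must share the volume grid")
        if np.any(self.lesion_mask & ~self.prostate_mask):
            raise ValueError("every lesion voxel must be a prostate voxel")
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.t2w_volume.shape

    @property
    def nonzero_b_values(self) -> list[float]:
        return sorted(b for b in self.dw_volumes if b > 0)


# ---------------------------------------------------------------------------
# geometry helpers


def ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    semi_axes: tuple[float, float, float],
    center: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Binary ellipsoid, the default whole-gland region."""
    if center is None:
        center = tuple((s - 1) / 2.0 for s in grid_shape)
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _angular_field_coeffs(
    rng: np.random.Generator, degrees: tuple[int, ...]
) -> dict[int, np.ndarray]:
    """Random coefficients of a band-limited angular field, unit RMS on the sphere.

    The field P(theta, phi) = sum_tau sum_beta g_{tau,beta} Y_{tau,beta} has
    E[P^2] = sum g^2 / (4*pi) for the orthonormal basis; coefficients are
    scaled so the RMS over the sphere is exactly 1.
    """
    coeffs = {tau: rng.standard_normal(2 * tau + 1) / (1.0 + tau) for tau in degrees}
    total = sum(float(c @ c) for c in coeffs.values())
    scale = np.sqrt(4.0 * np.pi / total)
    return {tau: c * scale for tau, c in coeffs.items()}


def _evaluate_angular_field(
    coeffs: dict[int, np.ndarray], theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    out = np.zeros(np.shape(theta)[0] if np.ndim(theta) else 1)
    for tau, c in coeffs.items():
        out = out + real_sh_degree_block(tau, theta, phi) @ c
    return out


def star_shaped_mask(
    grid_shape: tuple[int, int, int],
    center: tuple[float, float, float],
    r0: float,
    amplitude: float,
    degrees: tuple[int, ...] = (2, 3, 4, 5, 6),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Solid with surface radius ``r(theta, phi) = r0 * (1 + amplitude * P)``.

    P is a fixed band-limited random angular field with unit RMS, so
    ``amplitude`` directly controls relative surface roughness.  The radius
    is floored at ``0.2 * r0`` so the solid stays star-shaped about its
    center.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    coeffs = _angular_field_coeffs(rng, degrees)
    rmax = r0 * (1.0 + 3.0 * abs(amplitude)) + 1.0
    lo = [max(0, int(np.floor(c - rmax))) for c in center]
    hi = [min(s, int(np.ceil(c + rmax)) + 1) for s, c in zip(grid_shape, center)]
    xs, ys, zs = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    dx = xs - center[0]
    dy = ys - center[1]
    dz = zs - center[2]
    rho = np.sqrt(dx * dx + dy * dy + dz * dz)
    theta = np.arccos(np.clip(dz / np.maximum(rho, 1e-12), -1, 1))
    phi = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    p = _evaluate_angular_field(coeffs, theta.ravel(), phi.ravel()).reshape(rho.shape)
    radius = np.maximum(r0 * (1.0 + amplitude * p), 0.2 * r0)
    box = (rho <= radius) | (rho == 0)
    mask = np.zeros(grid_shape, dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = box
    # keep the component containing the center (spiky fields can shed slivers)
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:
        mask = labels == labels[int(round(center[0])), int(round(center[1])), int(round(center[2]))]
    return mask


# ---------------------------------------------------------------------------
# per-case synthesis


def _truncated_lognormal(
    rng: np.random.Generator, mean: float, log_sd: float, lower: float = 4.0
) -> float:
    """Log-normal with the given arithmetic mean, resampled until > lower."""
    mu = np.log(mean) - 0.5 * log_sd**2
    for _ in range(1000):
        x = float(np.exp(rng.normal(mu, log_sd)))
        if x > lower:
            return x
    return lower + 1e-6


def generate_case(
    config: PhantomConfig,
    case_id: str,
    label: Literal["benign", "malignant"],
    rng: np.random.Generator,
) -> ProstateCase:
    """Synthesize one labeled case on the configured grid."""
    shape = config.grid_shape
    malignant = label == "malignant"

    semi_axes = tuple(0.40 * s for s in shape)
    prostate = ellipsoid_mask(shape, semi_axes)

    # lesion: offset star-shaped solid inside the gland
    center = tuple((s - 1) / 2.0 for s in shape)
    offset = rng.uniform(-1.0, 1.0, size=3) * 0.15 * min(semi_axes)
    lesion_center = tuple(c + o for c, o in zip(center, offset))
    amp = (
        config.lesion_spike_amp_malignant
        if malignant
        else config.lesion_spike_amp_benign
    )
    lesion = star_shaped_mask(shape, lesion_center, config.lesion_radius, amp, rng=rng)
    if np.any(lesion & ~prostate):
        raise PhantomError(
            f"{case_id}: lesion does not fit inside the prostate mask; "
            "reduce lesion_radius or enlarge grid_shape"
        )

    # voxel-wise diffusion coefficient field
    adc_mean = config.adc_malignant_mean if malignant else config.adc_benign_mean
    d_field = np.full(shape, 2.5e-3)  # free-water-like background
    d_in = rng.normal(adc_mean, config.adc_sd, size=shape)
    d_field[prostate] = np.maximum(d_in[prostate], 1e-5)

    dw_volumes: dict[float, np.ndarray] = {}
    s0_vol = np.full(shape, config.s0_intensity)
    s0_vol[~prostate] = 0.25 * config.s0_intensity
    for b in config.b_values:
        signal = s0_vol * np.exp(-b * d_field)
        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, config.noise_sd, size=shape)
        dw_volumes[float(b)] = np.maximum(signal, config.signal_floor)

    # T2W: smoothed Gaussian random field, class-dependent correlation length
    corr = (
        config.texture_corr_len_malignant
        if malignant
        else config.texture_corr_len_benign
    )
    white = rng.standard_normal(shape)
    fieldv = ndimage.gaussian_filter(white, sigma=corr)
    sd = fieldv[prostate].std()
    if sd > 0:
        fieldv = fieldv / sd
    t2w = 500.0 + 80.0 * fieldv
    t2w[~prostate] = 150.0 + 20.0 * fieldv[~prostate]
    t2w[lesion] -= 60.0  # carcinoma and hyperplasia read hypointense on T2W

    psa_mean = config.psa_malignant_mean if malignant else config.psa_benign_mean
    psa = _truncated_lognormal(rng, psa_mean, config.psa_log_sd)

    case = ProstateCase(
        case_id=case_id,
        dw_volumes=dw_volumes,
        t2w_volume=t2w,
        prostate_mask=prostate,
        lesion_mask=lesion,
        psa=psa,
        label=label,
    )
    case.validate()
    return case


def generate_cohort(config: PhantomConfig) -> list[ProstateCase]:
    """Generate the full labeled cohort, deterministically for a fixed seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_cases + 1)
    n_mal = int(round(config.n_cases * config.class_balance))
    labels = ["malignant"] * n_mal + ["benign"] * (config.n_cases - n_mal)
    np.random.default_rng(children[0]).shuffle(labels)
    return [
        generate_case(
            config,
            f"case_{i:03d}",
            labels[i],
            np.random.default_rng(children[i + 1]),
        )
        for i in range(config.n_cases)
    ]
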