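"""Shared fixtures: phantom cohorts and the fused feature table.

The 80-case cohort and its 266-feature table are expensive (minutes), so
they are built once per session and shared by the texture/selection/
evaluation tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import prostacad as pc
from prostacad.phantom import generate_case


@pytest.fixture(scope="session")
def cohort80() -> list[pc.ProstateCase]:
    """Default study-scale cohort: 80 cases, 43 benign / 37 malignant."""
    return pc.generate_cohort(pc.PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def fs5_table(cohort80) -> pc.FeatureTable:
    """Fused functional | texture | shape | PSA table (80 x 266)."""
    return pc.extract_feature_table(cohort80)


@pytest.fixture(scope="session")
def small_cohort() -> list[pc.ProstateCase]:
    """Four quick cases on a small grid for unit-level checks."""
    cfg = pc.PhantomConfig(
        n_cases=4, grid_shape=(24, 24, 20), lesion_radius=3.0, seed=5
    )
    return pc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_pair() -> tuple[pc.ProstateCase, pc.ProstateCase]:
    """One benign and one malignant case with constant ADC and zero noise."""
    cfg = pc.PhantomConfig(
        n_cases=2,
        grid_shape=(24, 24, 20),
        lesion_radius=3.0,
        adc_sd=0.0,
        noise_sd=0.0,
        seed=13,
    )
    rng = np.random.default_rng(13)
    benign = generate_case(cfg, "benign_0", "benign", rng)
    malignant = generate_case(cfg, "malignant_0", "malignant", rng)
    return benign, malignant
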