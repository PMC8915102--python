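"""End-to-end feature extraction: cohort in, 266-wide feature table out.

Convenience layer tying the stages together: ADC-CDF functional features
(122) on the whole gland, T2W texture (58), spherical-harmonics lesion shape
markers (85), and the PSA biomarker (1).  The cohort-wide ADC range is
estimated here (and can be persisted/reused for new cases); everything else
is per-case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adc import (
    ADCRange,
    DEFAULT_LAYOUT,
    FunctionalLayout,
    estimate_global_range,
    functional_feature_vector,
)
from .features import FeatureTable, FeatureVector
from .phantom import ProstateCase
from .selection import integrate_features
from .shape import ARConfig, shape_features_from_mask
from .texture import texture_feature_vector

__all__ = ["PipelineConfig", "extract_feature_table", "extract_stage_table"]


@dataclass(frozen=True)
class PipelineConfig:
    """Extraction settings for the fused pipeline.

    ``shape_max_vertices`` caps the lesion mesh (the all-pairs repulsion is
    O(I^2) per cycle); 800 vertices resolves desk-scale lesions while
    keeping a cohort extraction in minutes.
    """

    layout: FunctionalLayout = DEFAULT_LAYOUT
    adc_steps: int = 100
    shape_max_vertices: int = 800
    sh_max_order: int = 85
    ar_config: ARConfig | None = None
    normalize_shape_markers: bool = True


def _labels(cases: list[ProstateCase]) -> np.ndarray:
    return np.array([1 if c.label == "malignant" else 0 for c in cases])


def _stack(cases: list[ProstateCase], vectors: list[FeatureVector]) -> FeatureTable:
    return FeatureTable(
        case_ids=[c.case_id for c in cases],
        feature_names=list(vectors[0].names),
        matrix=np.vstack([v.values for v in vectors]),
        labels=_labels(cases),
    )


def extract_stage_table(
    cases: list[ProstateCase],
    stage: str,
    adc_range: ADCRange | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> FeatureTable:
    """Feature table for a single stage: 'functional', 'texture' or 'shape'."""
    if not cases:
        raise ValueError("empty cohort")
    if stage == "functional":
        if adc_range is None:
            adc_range = estimate_global_range(cases, n_steps=config.adc_steps)
        vecs = [functional_feature_vector(c, adc_range, config.layout) for c in cases]
    elif stage == "texture":
        vecs = [texture_feature_vector(c) for c in cases]
    elif stage == "shape":
        vecs = [
            shape_features_from_mask(
                c.lesion_mask,
                max_vertices=config.shape_max_vertices,
                ar_config=config.ar_config,
                max_order=config.sh_max_order,
                normalize=config.normalize_shape_markers,
            )
            for c in cases
        ]
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return _stack(cases, vecs)


def extract_feature_table(
    cases: list[ProstateCase],
    adc_range: ADCRange | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> FeatureTable:
    """The fused table: functional | texture | shape | PSA (266 by default)."""
    if adc_range is None:
        adc_range = estimate_global_range(cases, n_steps=config.adc_steps)
    functional = extract_stage_table(cases, "functional", adc_range, config)
    texture = extract_stage_table(cases, "texture", config=config)
    shape = extract_stage_table(cases, "shape", config=config)
    psa = {c.case_id: c.psa for c in cases}
    return integrate_features(functional, texture, shape, psa)
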