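"""ADC maps and CDF functional features on a benign/malignant pair.

The voxel-wise apparent diffusion coefficient is ln(s0/sn)/(bn - b0); its
whole-gland distribution is summarized by an empirical CDF on a fixed
cohort-wide grid.  Malignant tissue diffuses less, so its CDF climbs to 1 at
lower ADC — the malignant curve dominates the benign one pointwise.
"""

import numpy as np

import prostacad as pc

cohort = pc.generate_cohort(pc.PhantomConfig(n_cases=10, seed=7))
adc_range = pc.estimate_global_range(cohort)
print(
    f"cohort ADC range: [{adc_range.adc_min:.2e}, {adc_range.adc_max:.2e}] mm^2/s, "
    f"{adc_range.n_steps} grid steps"
)

benign = next(c for c in cohort if c.label == "benign")
malignant = next(c for c in cohort if c.label == "malignant")
for case in (benign, malignant):
    amap = pc.compute_adc_map(
        case.dw_volumes[0.0], case.dw_volumes[1400.0], 1400.0, case.prostate_mask
    )
    cdf = pc.adc_cdf(amap, adc_range)
    median = np.median(amap.valid_values)
    half = adc_range.grid[np.searchsorted(cdf, 0.5)]
    print(
        f"{case.label:<10} median ADC {median:.2e} mm^2/s; "
        f"CDF reaches 0.5 at {half:.2e}"
    )

vec = pc.functional_feature_vector(benign, adc_range)
print(f"\nfunctional feature vector: {len(vec)} entries "
      f"(8 b-values x 15 CDF samples + ADC min/max)")
# the malignant gland's CDF crosses 0.5 at a visibly lower ADC than the
# benign one, which is exactly what the classifier picks up from FS1.
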