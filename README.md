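# prostacad

Multi-parametric MRI radiomics for prostate lesion diagnosis: a reusable,
tested implementation of a computer-aided diagnosis (CAD) pipeline that
fuses diffusion-weighted (DW) functional features, T2-weighted (T2W) 3D
texture, spherical-harmonics lesion shape markers and the PSA blood
biomarker, reduces the combined set by bi-directional stepwise selection,
and classifies benign vs malignant under cross-validation.

It is written for researchers working on quantitative prostate MRI who want
the individual feature families, the fusion/selection/evaluation harness, or
a fully synthetic test bed (no clinical data are required or shipped).

## The method

Per case the pipeline consumes a DW series at nine b-values
(b ∈ {0, 100, …, 700, 1400} s/mm²), one T2W volume, whole-gland and lesion
masks, and a scalar PSA (ng/mL). Four feature blocks are extracted:

1. **Functional (122).** Voxel-wise apparent diffusion coefficient maps
   ADC(x, y, z) = ln(s₀/sₙ)/(bₙ − b₀) for the eight nonzero b-values.
   Malignant tissue restricts water motion (lower ADC), so the whole-gland
   ADC distribution is discriminative; each map is summarized by its
   empirical CDF on a fixed 100-step grid spanning a cohort-wide ADC range,
   subsampled at 15 grid points per b-value plus the case ADC extrema
   (8 × 15 + 2 = 122).
2. **Texture (58).** In-mask T2W intensities are min–max normalized to gray
   levels 0..255. 36 first-order statistics; 6 features (contrast,
   correlation, ASM, dissimilarity, homogeneity, energy) of a single
   256 × 256 gray-level co-occurrence matrix accumulated over all 26
   unit-cube neighbor offsets; 16 standard statistics of a gray-level
   run-length matrix built from in-plane X runs and through-plane Z runs.
3. **Shape (85).** The lesion surface is meshed, mapped one-to-one onto the
   unit sphere by attraction–repulsion relaxation (attraction centers each
   node among its mesh neighbors, repulsion with factor C_R/(2I) prevents
   collapse, projection restores unit norm), and the radius function
   r(θ, φ) is expanded in real spherical harmonics. Marker k (k = 1..85) is
   the RMS radial reconstruction error of the series truncated at order k,
   normalized by mean radius: smooth (benign-like) lesions converge at low
   order, spiky (malignant-like) lesions do not.
4. **PSA (1).** The scalar biomarker.

The fused table (122 + 58 + 85 + 1 = 266 features) is reduced by
bi-directional stepwise selection against a logistic model
(likelihood-ratio entry/removal tests at significance 0.05 or 0.1) and
classified by SVM, random forest, decision tree or LDA with nested
grid search under stratified 5-fold, 10-fold or leave-one-out
cross-validation, reporting accuracy, sensitivity, specificity and AUC as
mean ± sd over 10 repeats.

A phantom module generates labeled synthetic cohorts with the
class-conditional structure above (mono-exponential DW decay with
class-dependent ADC, class-dependent T2W heterogeneity, star-shaped lesions
with class-dependent surface perturbation, truncated log-normal PSA), so
every stage is testable end to end.

## Worked example

`examples/05_full_pipeline.py` generates a 24-case cohort, extracts all 266
features, runs stepwise selection at ST = 0.1 and evaluates an SVM under
repeated 5-fold CV:

```
feature table: 24 cases x 266 features
stepwise (ST=0.1) kept 1 features:
  step 1: add adc_cdf_b100_g14 (p=8.73e-09)
[all 266] svm/5fold: acc 100.00±0.00%  sens 100.00±0.00%  spec 100.00±0.00%  auc 1.0000±0.0000
[selected] svm/5fold: acc 100.00±0.00%  sens 100.00±0.00%  spec 100.00±0.00%  auc 1.0000±0.0000
```

On this cleanly separated synthetic cohort a single ADC-CDF feature carries
the diagnosis, so the one-feature model matches the full table; the ± terms
are standard deviations over the 10 fold-rerandomized repeats. The other
examples show each stage in isolation — e.g. `04_shape_markers.py` prints
the reconstruction-error curves of a smooth ellipsoid vs a spiky star
(tolerance 0.02 reached at order 8 vs 15), and `03_texture_features.py`
shows malignant glands with ~3.5× higher GLCM contrast.

A thin CLI mirrors the stages:

```bash
prostacad simulate --out cohort/ --n 12 --seed 1
prostacad extract --cohort cohort/manifest.csv --out features.csv
prostacad select --features features.csv --threshold 0.1 --out subset.json
prostacad evaluate --features features.csv --classifier svm --schema 5fold
```

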