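# Methods

This note records the models, conventions and design choices behind
`prostacad`, at the level a maintainer or reviewer needs to interpret the
outputs. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Functional features (ADC–CDF)

The diffusion model is mono-exponential: for baseline signal s₀ (b = 0) and
sₙ at b-value bₙ, ADC = ln(s₀/sₙ)/(bₙ − b₀) in mm²/s, computed voxel-wise
over the whole-gland mask. Voxels with a non-positive signal in either
volume are **dropped from the valid mask**, not clipped: the log-ratio is
undefined there and silent clipping would bias the distribution tails.

Variable gland sizes are handled by summarizing each map's valid-voxel ADC
distribution as an empirical CDF on a fixed grid: the cohort-wide
[ADC_min, ADC_max] split into 100 equal steps. The range is estimated once
on the training cohort and persisted (JSON) so new cases are featurized on
the same grid; a degenerate range (constant ADC) is widened symmetrically
by ε = 1e−6 mm²/s to keep the grid defined. Values above ADC_max clamp into
the top step, so every CDF ends at exactly 1 and is non-decreasing.

The printed functional width of 122 cannot be the full 8 × 100 CDF grid, so
the composition is a configurable layout object; the default subsamples
each CDF at 15 equally spaced grid indices and appends the case-level ADC
minimum and maximum (8 × 15 + 2 = 122). Alternative layouts are a one-line
change.

## Texture features

In-mask T2W intensities are min–max normalized to integer levels 0..255
per case (floor after affine scaling; a constant volume maps to level 0).
The 36-item first-order roster is fixed and named: mean, median, population
variance, sd, Fisher kurtosis, skewness, Shannon entropy (base 2, 256-level
histogram); the empirical CDF at 10 equally spaced levels; percentiles
10..100 step 10; histogram metadata (n_obs, n_bins = 4, bin width, lower
limit); counts in the 4 equal-width bins; and a duplicated "descriptive
mean" that pads the roster to 36. Moments of a constant volume that are
formally 0/0 (kurtosis, skewness) are reported as 0.

The co-occurrence matrix is one 256 × 256 count matrix accumulated over all
26 neighbor offsets of the unit cube (the four in-plane angles 0, π/4, π/2,
3π/4 and their opposites, plus the 9 + 9 inter-slice offsets), counting only
pairs with both voxels in-mask, then normalized to unit sum. Because every
offset appears with its opposite, the matrix is exactly symmetric. The six
summary features use the standard definitions; correlation of a zero-variance
(single-level) matrix is reported as 1 — a constant texture is perfectly
predictable — to avoid NaN poisoning downstream selection.

Run-length counts pool maximal equal-level runs along in-plane X lines and
through-plane Z columns; out-of-mask voxels terminate runs. The 16 run-length
statistics use the standard radiomics formulas with run percentage computed
against (in-mask voxels × 2 orientation families). Gray-level-weighted
features use 1-based levels (level i weighs i + 1) so the low-gray-level
emphases are defined at level 0.

## Shape markers

The lesion mask (required: one 6-connected component, genus 0 after filling
internal cavities — lesions are solids) is isosurfaced at level 0.5 with
marching cubes after a light Gaussian pre-smoothing of the binary volume
(σ = 0.8 voxels, with a raw-volume fallback for lesions too small to survive
smoothing). Smoothing makes the mesh track the underlying surface rather
than the voxel staircase; without it, surface area is inflated ~8% and the
error markers inherit grid-orientation noise. Meshes above the vertex cap
(2000 by default; 800 in the fused pipeline) are re-extracted on coarser
marching-cubes grids, which bounds the O(I²) repulsion cost.

The origin is the lesion-mask voxel centroid, verified strictly inside the
surface by a solid-angle (winding-number) test; for non-star-shaped regions
whose centroid falls outside, the interior voxel maximizing the Euclidean
distance transform is used instead.

Attraction–repulsion relaxation: nodes start as unit-norm radial projections
of the mesh vertices. Each cycle applies, per node i with neighbor set Jᵢ,
an attraction step Δᵢ = C_A1 Σ_{j∈Jᵢ} (d_ji‖d_ji‖² + C_A2 d_ji/‖d_ji‖), a
repulsion step −C_R/(2I) Σ_{j≠i} d_ji/‖d_ji‖² over all node pairs (the sign
pushes node i *away* from the others — a sum toward them would contract the
mesh, the opposite of repulsion's role of keeping the spherical mesh from
deteriorating), and re-projection to unit norm. Iteration stops when the
mean per-vertex displacement falls below 1e−4 (max 500 cycles) *and* no
spherical triangle is inverted: fold checking is part of the stopping rule
because the relaxation itself is what heals the handful of folds the
voxelized radial projection starts with. Defaults C_A1 = C_A2 = 0.1,
C_R = 0.5: larger attraction strengths (≈0.3) empirically shear the mesh
and accumulate folds, while these converge fold-free in ≈200 cycles.
Residual single-sliver folds at the fixed point are removed by a local
untangling pass (vertices of folded triangles move to their neighbor
centroid and are reprojected); if folds survive all of this the mapping is
rejected with an error, since the one-to-one correspondence is a
precondition of the expansion.

The radius function r(θ, φ) (θ polar from +z, φ azimuth from +x) is fitted
in the real orthonormal spherical-harmonic basis degree by degree with an
incrementally orthogonalized design, so the per-order residuals come from
properly nested least squares and the error curve is non-increasing by
construction. Once the residual reaches the numerical floor or the design
saturates the vertex count, higher degrees are carried flat (their basis
adds nothing). Reported coefficients come from a minimum-norm solve, with a
tiny ridge (1e−8, recorded) if the design is rank-deficient; degrees beyond
saturation carry zeros.

Marker k (k = 1..85) is the RMS radial reconstruction error at truncation
order k, divided by the mean radius. The normalization makes the markers
scale-invariant descriptors of surface complexity (raw errors scale with
the lesion); the error-curve reading — rather than raw coefficients — is
also pose-robust, since rotations only redistribute energy within a degree.
With meshes of I vertices the expansion is rank-limited above degree
≈ √I − 1, so high-order markers of small lesions sit at the numerical
floor; comparisons between shapes are meaningful on the resolved part of
the curve.

## Fusion and stepwise selection

The blocks concatenate in the fixed order functional ‖ texture ‖ shape ‖
PSA = 266 columns, with rows canonically sorted by case id and a
per-feature provenance tag retained. Selection is classic bi-directional
stepwise against a binary-diagnosis logistic regression on z-scored
columns: forward step adds the candidate with the smallest likelihood-ratio
entry p-value when ≤ ST; backward steps then drop, one at a time, the
included feature with the largest removal p-value while it exceeds ST;
alternation stops when a full pass changes nothing (hard cap 2 × p actions
guarantees termination). Ties break toward the lowest column index, making
the procedure a deterministic function of the table. Perfect separation or
a singular Newton step falls back to a ridge-penalized likelihood
(λ = 1e−6), flagged in the per-step trace. The two conventional thresholds,
0.05 and 0.1, give the strict and permissive subsets; under the null the
entry test is approximately calibrated, selecting ≈ ST × p noise features
(verified by simulation in the acceptance suite).

By default selection runs once on the full table, mirroring a fixed feature
set reused across CV schemas; `cross_validate(..., stepwise_threshold=...)`
is the leakage-safe strict mode that re-runs selection inside every training
fold.

## Classification and evaluation

Four families with small, declared hyperparameter lattices: SVM (linear /
gaussian / degree-2 polynomial; C ∈ {0.1, 1, 10}, γ ∈ {scale, 0.1, 1});
random forest with 30 learning cycles; Gini decision tree with a split
budget ∈ {1, 4, 10} (implemented as max_leaf_nodes = splits + 1); LDA in
linear and diagonal-linear variants (the latter a pooled
diagonal-covariance discriminant implemented in-package). Per-feature-set
reference configurations (e.g. linear kernel for the functional set,
gaussian for texture) are available as narrowed lattices, but the full grid
is always searchable.

Evaluation is nested: per outer training split, an inner 5-fold grid search
maximizes accuracy (ties to the first lattice point in declaration order),
the winner is refit on the whole training split, and held-out predictions
are pooled per repeat into one confusion matrix and one score vector —
pooling makes single-class folds benign. Standardization lives inside the
estimator pipeline, so its statistics come from training folds only.
Metrics are accuracy, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)
(malignant positive) in percent, and trapezoidal AUC from a full threshold
sweep; mean ± sd over 10 repeats with folds re-randomized per repeat. The
leave-one-out partition is fixed, so deterministic learners (SVM, DT, LDA)
are evaluated once and their repeat sd is exactly 0; only the stochastic
forest is re-run.

## Synthetic cohorts: what they emulate and what they do not

The generator reproduces the statistical structure the method needs, not MR
physics. Defaults are the study conditions: 80 cases, 43 benign /
37 malignant, the nine-b-value protocol, benign/malignant mean ADC
1.8e−3 / 0.9e−3 mm²/s (sd 2e−4, drawn per voxel inside the gland), additive
Gaussian signal noise (sd 5 at s₀ = 1000) clipped at floor 1 so the
log-ratio stays defined, T2W smoothed-Gaussian random fields with texture
correlation lengths 3.0 (benign) vs 1.2 voxels (malignant), star-shaped
lesions r(θ, φ) = r₀(1 + a·P(θ, φ)) with a band-limited unit-RMS angular
field P (degrees 2–6) and amplitude a = 0.06 vs 0.25, and truncated
log-normal PSA with means 8 vs 18 ng/mL (both > 4, the screening inclusion
threshold). The grid is 36 × 36 × 28 with an ellipsoidal gland and
r₀ = 4.5 voxels — sizes chosen once so a full cohort extraction runs in
minutes on one core while every stage still operates in its intended
regime.

Not emulated: Rician noise, coil bias and distortion, DICOM semantics,
inter-scanner variation, anatomically realistic gland/lesion morphology, or
overlapping class distributions. Consequently, passing tests demonstrate
correctness of the computations and the promised class-separation
*mechanics* (a cleanly separated cohort is classified perfectly; equalized
generators yield chance performance), not clinical-grade accuracy on real
data.

## Numerical conventions collected

- Spherical convention: θ ∈ [0, π] from +z, φ ∈ [0, 2π) from +x;
  (sin θ cos φ, sin θ sin φ, cos θ).
- C_R is read as lying in [0.3, 0.7]; default 0.5.
- Gray normalization maps the in-mask max to exactly 255; constant → 0.
- CDF vectors clamp above-range values into the top step (terminal value 1).
- GLCM correlation at zero marginal variance → 1.
- Degenerate ADC range widened by ±1e−6 mm²/s.
- Stepwise ties → lowest column index; grid-search ties → first lattice
  point.
- All randomness flows through numpy seed sequences from a single seed;
  cohorts are bit-reproducible.
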