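# Methods

This note documents the models, conventions and design choices behind
`usradiomics`, in the spirit of the methods documentation of statsmodels
or scanpy: what is computed, under which assumptions, and where the open
choices were resolved.

## Imaging and ROI construction

Images are 2-D non-negative rasters with an isotropic pixel spacing in mm
(anisotropic inputs are rejected rather than silently resampled). Masks
are pixel-aligned, row-major, 0-based; no sub-pixel contours. The
peritumoral ROI is the exact Euclidean dilation of the tumor mask by a
disk of radius `round(margin_mm / spacing)` pixels, implemented with a
distance transform (identical to structuring-element dilation with an
exact disk, but O(N)); the margin defaults to 7.5 mm, the midpoint of the
0.5–1 cm peritumoral band, and values outside [5, 10] mm are rejected.
Skin/pectoral exclusion masks are subtracted after dilation, so the
analysed ring never contains excluded tissue.

The denoising step reported for the original analysis used an unversioned
commercial tool; the package substitutes a documented median filter
(radius 1 px) that is **off by default**, preferring reproducibility over
fidelity to an unobtainable black box.

## Intensity normalisation and quantisation

Texture features are computed on quantised gray levels. The default
`mu3sigma` scheme clamps in-mask intensities to [μ−3σ, μ+3σ] (statistics
over the ROI being analysed — normalisation is per-ROI, not global) and
bins linearly into Ng = 64 levels, the classical co-occurrence convention.
Because the clamp bounds are affine-equivariant, every downstream feature
is exactly invariant under positive affine transforms of the input
intensities; the test suite asserts bit-level equality of all 278 features
for `I` and `2I + 16`. A constant ROI (σ = 0) maps to level 0 everywhere
and raises a warning flag; its histogram percentiles are therefore 0 (the
degenerate level), its skewness/kurtosis are reported as undefined (NaN),
and matrix features take their degenerate closed-form values.

Undefined values are always explicit NaN markers — a feature is never
silently zero.

## Feature families (registry of 278)

* **Histogram (9).** Mean, variance, skewness, kurtosis and the 1/10/50/
  90/99 percentiles of the quantised levels, percentiles by the
  nearest-rank rule (the ⌈p·n⌉-th order statistic).
* **Co-occurrence (220).** Offsets (0,d), (d,0), (d,d), (d,−d) for
  d = 1..5; pairs accumulated symmetrically and normalised; 11 Haralick
  statistics with levels indexed 1..Ng and natural-log entropies
  (0·log 0 := 0). Sum variance is computed about the sum average. The
  correlation of a zero-variance (single-entry) matrix is reported as 0.
* **Run length (20).** Maximal constant-level runs along mask-interior
  scanlines at 0°/45°/90°/135° (runs break at mask boundaries);
  ShrtREmp, LngREmph, GLevNonU, RLNonUni and Fraction
  (= runs / traversed pixels).
* **Autoregressive (5).** Least-squares fit of the causal four-neighbour
  recursion s(x,y) ≈ θ₁s_W + θ₂s_NW + θ₃s_N + θ₄s_NE on mean-centred
  levels, requiring ≥ 32 pixels with all four neighbours in-mask; Sigma is
  the RMS residual. Quantisation to 64 levels attenuates the estimates by
  well under 1% at these settings; recovery of (0.4, 0, 0.3, 0) on a
  128×128 field is within ±0.05.
* **Wavelets (24).** Orthonormal Haar energies at scales 1–6, computed as
  non-overlapping 2×2 block transforms of the bounding-box patch
  (out-of-mask pixels filled with the in-mask mean), iterating on LL.
  HL carries horizontal frequency (vertical edges), LH vertical. Energies
  average squared coefficients over positions whose dyadic support
  intersects the mask; scales exceeding the bounding box are undefined.
  Scale 1 satisfies Parseval exactly on even-sized patches.

Export-mangled names from spreadsheet round-trips (`X.S.0.1.Contrast`,
`ZWavEnLL_s6`, `WavEnHL_s.3`, `X135dr_GLevNonU`) are mapped to the
canonical `S(0,1)Contrast`, `WavEnLL_s6`, `WavEnHL_s3`, `135dr_GLevNonU`
by `texture.canonical_name`.

Gradient and geometric/shape families are deliberately absent: no member
of those families appears in the signatures this package targets.

## Selection cascade

* **Mann–Whitney.** U uses midranks. When the number of group assignments
  C(n+m, min(n,m)) ≤ 20,000 the two-sided p comes from full enumeration of
  the permutation distribution (exact under ties); tie-free samples with
  min(n,m) ≤ 8 use the exact distribution; otherwise the normal
  approximation with tie and continuity correction. The exact-enumeration
  cutoff is bounded by assignment count rather than group size alone
  because enumeration over C(88, 8) ≈ 4×10¹⁰ assignments is intractable.
* **BH adjustment** is the standard step-up
  p̃₍ᵢ₎ = min₍ⱼ≥ᵢ₎ min(1, m·p₍ⱼ₎/j); it is inflationary, monotone and
  bounded, but *not* idempotent (p = {0, 1, 0.5} is a counterexample), so
  idempotence is not asserted. Features with NaN values are dropped before
  testing, with an explicit audit reason.
* **Spearman pruning** is greedy and deterministic: repeatedly take the
  pair with the largest |ρ| (registry order breaks ties) and drop the
  member with the larger mean absolute correlation against the currently
  retained set, keeping the earlier-registry feature on ties; constant
  features are dropped first. The postcondition max |ρ| ≤ 0.9 is audited.
* **LASSO.** Features are standardized with *global* statistics (the
  per-fold alternative is a known leakage-reduction variant; global
  matches the replicated analysis). The λ grid is 100 log-spaced points
  from λ_max = max|Xᵀ(y−ȳ)|/n down to 10⁻³λ_max; per-λ binomial deviance
  is averaged over 10 stratified, seeded CV folds; λ is the deviance
  minimiser by default with a 1-SE option. Fits use the liblinear
  coordinate solver with C = 1/(nλ); coefficients below 1e-8 are treated
  as exact zeros.
* **Scope.** The cascade runs on the full cohort by default — replicating
  the analysis convention it mirrors, which is optimistic because the
  held-out quarter influences selection. This caveat is deliberate and
  documented; leakage-free workflows should run the steps on the training
  subset only.

## Rad-Score and evaluation

The Rad-Score has no intercept: it is the pure linear combination of the
selected features and their coefficients; classifiers absorb any offset.
Ki67 enters as the binary ≥20% / <20% category. Classifier defaults
(500 trees; 100 gradient-boosting rounds on depth-1 stumps; k = 5; RBF
kernel) are the package's own choices — the replicated analysis does not
state hyperparameters — and are all configurable and seeded. Confusion
counts use a 0.5 posterior threshold; AUC is trapezoidal over all unique
thresholds and equals U/(n₊n₋) exactly; the accuracy CI is Clopper–Pearson
exact binomial. "1 − AUC" predictor importance — undefined in the source
material — is implemented as permutation importance: 1 minus the mean
held-out AUC after permuting the predictor (100 seeded permutations), so a
non-influential predictor scores exactly 1 − AUC_full.

Cohort statistics use Pearson χ² **without** continuity correction for
categorical group comparisons — the convention verified to reproduce all
six published categorical p-values from their count tables (a
Yates-corrected test does not, e.g. the Ki67 table would give ≈ 0.010) —
and Mann–Whitney for age, consistent with the nonparametric choice used
for features. Batch effects are screened per feature by Welch t-tests
between the two machines, flagging "no batch effect" when every defined p
exceeds 0.050.

## Synthetic data: what it does and does not emulate

The lesion generator produces hypoechoic, irregularly-margined
perturbed-ellipse masses on a brighter background: the echogenicity map is
piecewise constant, multiplied by a mean-one Rayleigh speckle perturbation
(I = E·(1 + (R − E[R])), R ~ Rayleigh(scale)) and Gaussian-smoothed at the
texture correlation length — a single texture knob. The mean-one form is
used so that speckle_scale → 0 gives the exact noise-free limit (a raw
Rayleigh multiplier has a scale-free coefficient of variation and no such
limit). Margin irregularity is a smooth random harmonic perturbation of
the elliptical radius, bounded so the lesion stays in-frame; an optional
posterior shadow halves intensity below the lesion; a top band of rows
acts as the skin exclusion.

Cohort defaults mirror the replicated study conditions: 50 positive / 38
negative lesions, Ki67-high rates 46/50 and 26/38, an even two-machine
split independent of class. The class effect enters **only** through the
texture correlation length (2.4 ± 0.25 px positive vs 1.3 ± 0.25 px
negative) and echogenicity contrast (0.45 vs 0.55) — never through mask
geometry — so feature-recovery tests are unambiguous. These effect sizes
are free parameters (no quantitative image-texture difference is published)
chosen once as a deliberately strong, clearly separated effect; the null
configuration equalises the texture distributions *and* the Ki67 rates,
because class-dependent Ki67 alone would carry signal and invalidate the
null calibration band.

What the generator does **not** emulate: B-mode physics (no
point-spread-function convolution, attenuation or depth-dependent gain),
operator variability, heterogeneous intratumoral echotexture, and real
inter-machine differences (machines are labels only). Passing end-to-end
tests therefore demonstrates that the pipeline recovers planted texture
signal and stays calibrated under the null — not that any particular AUC
is attainable on clinical images.

## Problem sizes and numerical choices

Synthetic cohorts use 128×128 images at 0.2 mm/px with lesion semi-axes
of 14–22 px, keeping a full 88-lesion cohort extraction under ~5 s and the
40-cohort end-to-end check within a few minutes; these sizes are the
package's default study conditions, with everything configurable upward.
Ties, degenerate ROIs and empty survivor sets are all defined behaviours
(documented above) rather than errors; the cascade halts with an
informative empty result when a step eliminates everything.

## Known limitations

* Full-cohort selection scope reproduces a leakage-prone convention by
  design; metrics from it are optimistic.
* The published headline AUCs (≈0.93) and cohort-specific survivor counts
  (248→10→7, 88→15→5) depend on the original patient images and are not
  reproduction targets; only their arithmetic self-consistency and the
  pipeline's behaviour on synthetic data are claimed.
* The feature registry totals 278 named features; published exports of
  the same tool report 306 or 310 variables depending on sub-version.
  The registry count is recorded in the extraction manifest rather than
  forced to either printed number.
* Exact Mann–Whitney enumeration is capped at 20,000 assignments; beyond
  that the corrected normal approximation is used.
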