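# Methods

## Designs and coding

Both supported designs live on coded factor levels obtained from the
affine map coded = (natural − mid)/half-range, so −1/0/+1 are the
low/mid/high levels and the face-centered axial distance is 1. The
three-level full factorial enumerates {−1, 0, +1}³ (27 points); the
face-centered CCD uses the 8 vertices, 6 face centers and the center
point (15 points). Replicates, when requested, are appended at the
vertices and center and share a `replicate_group` label with the original
run. Aborted conditions are removed by a drop-list of coded points;
`max_variance_inflation` reports the largest VIF of the coded linear
columns so users can verify that a drop left the design close to
orthogonal (exactly 1 for the intact factorial). Natural values outside a
factor's studied range raise a warning, not an error: predicting slightly
outside the domain is legitimate, but should be a conscious act.

The factor-to-X assignment is fixed by the order of the `FactorSpec`
list; all defaults use (T, t, Q).

## Quadratic surface and pooled-variance inference

The model matrix contains the intercept, linear, two-way interaction and
quadratic columns of the coded levels. The OLS solve uses a QR
decomposition; the per-term variances Cᵢᵢ are taken from the explicit
inverse cross-product (M′M)⁻¹ because the coefficient test needs them
individually. A rank-deficient matrix raises an error naming the
collinear terms rather than silently pseudo-inverting.

Coefficient significance uses Sc = √(S²_pooled · Cᵢᵢ), where S²_pooled
pools the within-group sums of squares of all replicated conditions and
carries Σ(n_g − 1) degrees of freedom. Testing against replicate-based
pure error (rather than the residual mean square) keeps the test valid
while the model itself is still in doubt during reduction; because the
within-group contrasts are orthogonal to the model space, the statistic
is exactly t-distributed under normal errors. The residual-based test
remains available via `variance="residual"`. A zero pooled variance
(identical replicates) makes every test undefined and raises an error
instead of returning p = 0.

Model reduction follows the hierarchy convention: the intercept and the
linear terms are never removed; non-significant quadratic terms are
candidates; an interaction XᵢXⱼ becomes a candidate only once both Xᵢ²
and Xⱼ² are out. One term — the least significant candidate — is removed
per pass, the model refitted and retested, until no candidate remains.
Note the asymmetry this creates on purpose: a non-significant interaction
survives as long as either parent quadratic is retained.

The ANOVA table computes the regression sum of squares about the response
mean (regression DF = number of terms − 1), splits the residual into
pure error (from replicate groups) and lack of fit, and reports
upper-tail F tests: MS_reg/MS_res and MS_lof/MS_pe. The same assembly
routine accepts published SS/DF pairs directly, which is how the
factorial worked example is reproduced. Significance stars follow the
0.05/0.01/0.001 convention.

Optimization evaluates the fitted polynomial on a coded grid (default
step 0.05, i.e. 2.5% of each factor's half-range — effectively
instantaneous and finer than any practical setting of the equipment) and
returns the maximizing point in natural units; factors can be pinned for
contour-style slices. A grid is used instead of a stationary-point
formula because the optimum of a saddle-shaped or monotone surface lies
on the domain boundary.

## PC1 multiresponse scoring

The peak-area table is autoscaled (column mean 0, sd 1 with the n−1
denominator; a constant column is an error naming the column) and
decomposed by SVD. Component signs are fixed by making the
largest-magnitude loading of each component positive, which makes results
reproducible across linear-algebra backends. The DOE response is the PC1
score vector, re-oriented so that the majority of PC1 loadings are
positive (scores and loadings flip together); a 50/50 sign split is
broken by the sign of the largest-magnitude loading. When all responses
rise and fall together, a high score then always reads as "more of most
compounds". Raw scores are used, never biplot-scaled ones, since biplot
scaling is a display transformation.

## SNV and ASCA

SNV standardizes each spectrum across wavelengths (n−1 sd), removing
multiplicative gain and additive baseline exactly; a flat spectrum is an
error naming the run. The default analysis window is 220–400 nm,
configurable.

The ASCA decomposition removes the grand mean and assigns to each run,
per main effect, the deviation of its level-mean spectrum from the grand
mean; optional two-way interaction matrices hold cell-mean deviations net
of main effects; the residual is the remainder, so the reconstruction
grand mean + Σ effects + residual = X holds exactly by construction.
Level means are computed as unweighted means of cell means (a
Type-III-like choice): under mild unbalance — a couple of aborted runs —
each cell keeps equal weight and the effect matrices keep their intended
interpretation. For a balanced design this reduces to plain level means,
the effect matrices are mutually orthogonal, and the effect sums of
squares are additive; under unbalance additivity is approximate, which is
why the variance percentages are reported per term rather than forced to
sum to 100.

Per-effect PCA is an (uncentered) SVD of the effect matrix — the rows are
already deviations. Score plots need the per-sample scatter as well, so
the residual-augmented rows (effect + residual) are projected onto the
same loadings; by linearity these projections average to the level-mean
scores.

**Permutation test.** The tested factor's level labels are permuted
across runs (other factors untouched) and the factor's effect SS
recomputed; p = (1 + #{SS_perm ≥ SS_obs})/(n_perm + 1). The permutation
statistic uses plain level means rather than unweighted cell means: on
the balanced layout the two coincide, but permuting one factor's labels
unbalances the joint cells, and the cell-mean statistic then loses
exchangeability and becomes conservative (observed null rejection ~1%
instead of 5%). With plain level means the test is calibrated: the null
rejection rate at α = 0.05 measured over 200 synthetic null datasets
falls within [2%, 9%]. Seeds are mandatory.

**Bootstrap loading significance.** Runs are resampled with replacement
within design cells; each cycle recomputes the decomposition and the
effect PCA, aligns the loading vector's sign to the point estimate by dot
product (preventing sign-flip artifacts), and a wavelength is flagged
when the percentile interval at the requested level (default 95%,
1000 cycles) excludes zero. Designs whose cells contain single runs — the
usual case when only vertices and center are replicated — make
within-cell resampling degenerate; the procedure then warns and falls
back to a residual bootstrap: resampled residual rows are added back to
the fitted decomposition. Because fitted effects absorb part of the
noise, raw residuals understate the error variance by (n − p)/n; the
resampled residuals are rescaled by √(n/(n − p)) (p = decomposition
degrees of freedom), without which the false-flag rate on null
wavelengths runs near 12% instead of the nominal ~5–6%.

## DPPH calibration

Inhibition % is 100·(t₀ − t₁)/t₀ with t₁ the replicate-averaged reacted
absorbance; values outside [0, 100] are flagged but not clipped, since
clipping would bias the line. The calibration is a straight OLS line of
mean inhibition on concentration — over the studied dose range the
response stays near-linear, so no sigmoid model is fitted — and
IC50 = (50 − b₀)/b₁ with a first-order (delta-method) standard error from
the coefficient covariance. A non-positive slope warns and leaves IC50
undefined. A replicate-level fit (no pre-averaging) is available. The CCD
response is the raw absorbance drop Y = mean(t₀) − t₁.

## Synthetic data

The generators exist to give every stage a known ground truth:

* **Areas** — a latent "extract quality" quadratic surface evaluated at
  the run's coded levels, multiplied by positive per-response loadings
  (uniform 0.5–1.5) and perturbed by Gaussian noise (sd 0.5 on a surface
  spanning ≈ ±3). The shared latent factor reproduces the all-positive
  PC1 loading structure of correlated peak areas. Default surface signs:
  quality rises with amount, falls with time, with a temperature–time
  interaction that rewards high temperature only at short times.
* **Spectra** — sums of Gaussian bands at the polyphenol classes'
  absorption positions (hydroxybenzoic 250/290 nm, hydroxycinnamic
  320 nm, flavone/flavonol 350 nm wide enough to cover 330–370 nm), whose
  amplitudes depend linearly on coded factor levels (flavone band
  stronger at low temperature and short time), then multiplied by a
  random gain (sd 0.15) and shifted by a random baseline (sd 0.05) — the
  scatter SNV must remove — plus white noise (sd 0.01 AU).
* **DPPH responses** — a concave quadratic surface whose default
  coefficients mirror the fitted antioxidant CCD (strong positive Q,
  negative T² and Q², negative T·t; noise sd 0.013 AU, the pooled pure
  error of the packaged table), clipped to the physical range [0, t₀].

Default layouts reproduce the study: the replicated factorial with the
two aborted conditions removed (34 runs) and the 22-run CCD with its six
duplicated "bis" conditions. Everything is bit-reproducible given a seed,
and the CLI writes a machine-readable ground-truth sidecar next to every
generated dataset.

What the generators do **not** emulate: chromatographic peak shapes or
retention drift, realistic band asymmetry and overlap in the UV spectra,
heteroscedastic instrument noise, and any between-batch botanical
variability. Passing recovery tests therefore demonstrates the
correctness of the statistical machinery under the stated model, not
robustness to every artifact of real instruments.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen to estimate the
relevant rates tightly while keeping the suite quick: 200 seeded
simulations for CI coverage (2000 term-level checks, binomial SE ≈ 0.5%),
200 null datasets × 199 permutations for test calibration, and 5 datasets
× 200 bootstrap cycles for band localization (the operational default
remains 1000 cycles). Tolerances: exact identities (reconstruction,
SNV invariances, SS additivity) are asserted at 1e−8–1e−12; published
values at the precision they were printed.

Tie-breaks and degenerate inputs are handled explicitly rather than left
to backend behavior: PCA sign conventions (above), the PC1 orientation
tie-break, zero-variance columns/spectra as named errors, missing
replicates disabling the lack-of-fit split with a warning, and
out-of-domain predictions as warnings.

## Known limitations

* The ASCA effect percentages under unbalance depend on the unweighted
  cell-mean convention; other weightings give slightly different splits.
* The permutation test covers main effects; interaction significance is
  not implemented (interaction effect matrices are available).
* The percentile bootstrap is first-order accurate; with very few runs
  per level its false-flag rate can drift a few points above nominal.
* The DPPH model is a straight line by design; it will extrapolate poorly
  outside the near-linear dose range and reports that only through R².
* IC50 is expressed per mass of dry plant material, not dry extract, so
  values are not directly comparable across protocols that normalize
  differently.
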