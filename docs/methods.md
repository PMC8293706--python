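# Methods

## Scope and data model

The package analyzes the relationship between lizard body size and climate
at two levels. At the **assemblage level** the observational unit is a grid
cell (1°×1° by default, addressed by row-major integer id; latitude and
longitude always mean cell centers) whose response is the median log₁₀ body
mass (grams) of all species whose range overlaps the cell. At the
**species level** the unit is a species, with climate summarized over its
occupied cells. Body size enters as log₁₀ mass throughout; when only
maximum snout–vent length (SVL, mm) is available it is transformed with a
clade-specific power law log₁₀(mass) = a + b·log₁₀(SVL). The bundled
coefficients are literature-plausible placeholders (family-level intercepts
around −5 and slopes around 3) and are meant to be edited; every analysis
also accepts precomputed log₁₀ mass, so allometry is never load-bearing.

Aggregation conventions that the underlying field literature leaves open,
fixed here and exposed as knobs:

- cells count as occupied under *any* overlap of the range (presence =
  any overlap);
- cell medians use the mean of the two central values at even counts;
- species-level climate is the **unweighted mean over occupied cells** and
  species latitude is the range-centroid latitude (alternatives such as
  type localities or area weighting are not implemented);
- cells below `min_richness` (default 1, i.e. no filtering) are dropped.

## Spatial-error SAR estimator

Model: y = Xβ + u with u = λ_sp·W·u + ε, ε ~ N(0, σ²I). With
A = I − λ_sp W the log-likelihood is

ℓ(β, σ², λ_sp) = −n/2·log(2πσ²) + log|A| − ‖A(y − Xβ)‖²/(2σ²).

For fixed λ_sp, β̂ is OLS on the whitened data (Ay, AX) and σ̂² = RSS/n, so
ℓ is profiled to one dimension. log|A| = Σᵢ log(1 − λ_sp ωᵢ) over the
eigenvalues ωᵢ of W, computed once per weights matrix and cached; W from a
symmetric contiguity structure (row-standardized) is similar to a symmetric
matrix, so the spectrum is real. λ_sp is found by bounded Brent search on
(1/ω_min + 10⁻⁶, 1/ω_max − 10⁻⁶) with tolerance 10⁻⁸; an optimum within
10⁻⁴ of either end sets a `boundary` flag and warns. Weights default to
**queen contiguity among retained cells, row-standardized** (rook by flag);
rows without neighbors keep zero weights and, if the whole matrix is empty,
the fit degenerates to OLS. Coefficient SEs come from σ̂²(X'A'AX)⁻¹ at the
optimum with two-sided asymptotic z tests (λ_sp is treated as known for
coefficient inference, the convention of the standard spatial-regression
implementations). Predictors enter untransformed and unstandardized.

Fit quality is the likelihood-ratio **Nagelkerke pseudo-R²**,
1 − exp(−(2/n)(ℓ_model − ℓ_null)) with ℓ_null from the intercept-only OLS
fit; it is clamped to [0, 1) and is *not* a variance-explained proportion.
The fully normalized variant (divided by 1 − exp((2/n)ℓ_null)) is available
by flag but meaningless when the Gaussian null density exceeds 1.

A latitude-only fit is classified as `bergmann` (significant positive
slope), `inverse_bergmann` (significant negative), or `none`, at α = 0.05
by default.

## Trait-randomization reliability screen

Wide-ranging species recur in many neighboring cells and can manufacture
smooth, strong-looking gradients. The screen permutes log₁₀ mass across
species (occupancy untouched), rebuilds the cell medians and refits the SAR
model n_rand times (default 100; replicate seeds derive from the master
seed by a counter so any replicate is reproducible alone). Because
permuting masses cannot change which cells are occupied, the retained
cells, climate design and spatial weights are computed once and reused.

Two decision rules are reported:

- **t-test rule (default):** one-sample t test of the randomized pseudo-R²
  values against the observed value as a fixed reference, one-sided
  (randoms < observed), verdict `reliable` iff p < α. If the randoms have
  zero variance the t statistic is undefined and the verdict falls back to
  direct comparison (all randoms strictly below the observed value →
  reliable).
- **permutation rule (`method="permutation"`):** exact rank p-value
  (1 + #{randoms ≥ observed}) / (n_rand + 1).

**Calibration warning.** When traits carry no climate signal the observed
gradient is itself one draw from the permutation ensemble, so the t-test
rule — which treats the observed value as a constant — fires whenever one
exchangeable draw exceeds the mean of the others by about
t₀.₉₅/√n_rand ≈ 0.24 standard deviations. Its false-alarm probability is
therefore ≈ P(Z > 0.24) ≈ 0.4 rather than the nominal 0.05, and simulation
confirms ~40% at n_rand = 50. The permutation rule is exact (measured ≤ 7%
at the same settings). The t-test rule is kept as the default because it is
the classical convention this pipeline mirrors; studies needing a
calibrated verdict should pass `method="permutation"`. Both p-values are
always stored in the result. With a strong simulated climate effect both
rules detect the gradient in ≥ 95% of datasets.

## PGLS with Pagel's λ

Residual covariance V = σ²C(λ): C[i,j] is the root-to-MRCA distance of
species pair (i, j) (diagonal = root-to-tip distance; simulated trees have
unit root depth so diag C = 1), and C(λ) multiplies off-diagonals by
λ ∈ [0, 1]. For fixed λ, β̂ and σ̂² have closed GLS forms on
Cholesky-whitened data; λ̂ maximizes the profile likelihood by bounded
search on [0, 1] (tolerance 10⁻⁸, endpoints checked explicitly since the
bounded optimizer never touches them; boundary optima warn but are not
fatal). Estimation is ML, not REML (matching the common comparative-methods
convention; REML is not offered because model comparison across fixed
effects is part of the workflow). Coefficient tests are two-sided t on
n − p degrees of freedom with SEs from the unbiased σ² estimate. The
reported R² is 1 − RSS/TSS on the λ̂-whitened data, with TSS around the
GLS-weighted mean — one of several species-level "R²" definitions in use;
it is reported for orientation, not comparability.

Species absent from the tree are dropped from PGLS (they remain in the
mixed models); the pipeline logs the dropped set.

## Nested mixed model

The tree-free species-level analysis is a Gaussian LMM (identity link —
the response is continuous log mass):

y = Xβ + b_family + b_genus:family + ε.

With one record per species a species-level random intercept is not
identifiable and is absorbed into ε. Fitting is REML by default (ML by
flag) via statsmodels MixedLM; predictors are standardized internally for
the optimizer and estimates mapped back exactly (affine equivariance), and
the optimizer falls back lbfgs → powell → nm if a step leaves the feasible
region. Within a single-family group the family intercept is dropped
(genus-only structure); with a single family *and* genus the model is OLS
with zero components. Note that (RE)ML variance estimates approach but do
not exactly hit the 0 boundary on data simulated without group effects, so
fixed effects then agree with OLS statistically (~10⁻²), not bitwise. The
wide-range sensitivity filter removes the ⌈fraction·n⌉ species (default
10%) with the largest ranges; ties at the cutoff retain the
lexicographically smallest species ids, deterministically.

## Synthetic data generator

The generator emulates the study design, not any particular region:

- **Climate surfaces**: value = intercept + slope·(lat − lat_min) + noise,
  with white Gaussian noise smoothed by a moving average over a
  (2r+1)² window (edge-truncated and renormalized). The radius is the
  single spatial-autocorrelation knob; smoothing shrinks the marginal
  noise SD below the nominal `noise_sd` (quoted SD is pre-smoothing).
  Default trends mimic a subtropical-to-temperate gradient (e.g. MAT
  25 °C at the southern edge falling 0.5 °C per degree latitude).
- **Ranges**: spreading-dye growth — uniform random seed cell, repeated
  uniform (or climate-similarity-weighted) accretion of an unoccupied rook
  neighbor until the target size (uniform between configured bounds).
  Ranges are 4-connected by construction; candidate cells are sorted
  before sampling so output is a pure function of (parameters, seed).
- **Phylogeny**: Yule process with Exponential(k) waiting times plus one
  Exponential(n) tail after the last birth (so terminal branches are
  positive and C is positive definite), rescaled to unit root depth.
  Families/genera for the mixed models are carved from the tree by
  splitting clades larger than n/n_families and merging the smallest
  results — roughly balanced, occasionally paraphyletic, nested strictly.
- **Traits**: log₁₀ mass = Xβ + u + ε with u ~ MVN(0, σ²_phylo·C(λ_true))
  — the λ transform applied at simulation time exactly as the PGLS
  estimator applies it — and ε i.i.d. β may be a single vector or a
  per-family map (opposite-sign group effects).

What the generator does **not** emulate: real range-shape constraints
(coasts, mountains), altitude, equal-area cell correction, sampling error
in SVL, polygon-to-grid digitization artifacts. Passing tests therefore
demonstrate estimator correctness under the stated model, not robustness
to those features of real data.

## Validation studies and problem sizes

The self-validation studies (`sizeclines.validation`, rerun by
`scripts/acceptance.py`) use conditions chosen for estimator
identifiability: per-variable climate noise SDs doubled relative to the
surface defaults and smoothing radius 1, so the five predictors are not
near-collinear functions of latitude at the study sizes.

- SAR recovery: 100 datasets on a 20×20 grid (400 cells), truth
  λ_sp = 0.8, σ = 0.1, β = (1.0, 0.02, 0.001, 2·10⁻⁴, −0.01, 4·10⁻⁴).
- PGLS recovery: 100 datasets of 200 tips, truth λ = 0.9, β_MAT = 0.02,
  σ_phylo = 0.2, σ_resid = 0 (the estimator's own generative model).
- LMM recovery: 100 balanced designs of 20 families × 5 genera × 4
  species, components (0.3, 0.2, 0.1).
- Null-model calibration/power: 100 datasets on a 12×12 grid, 60 species,
  n_rand = 50; pure-noise traits vs. masses tracking MAT at 0.08/°C.
- Sign recovery: 100 orchestrated runs, 18×12 grid, 70 species in two
  families with β_MAT = ±0.1, σ_phylo = 0.08, σ_resid = 0.02. Recovery is
  scored on the species-level PGLS MAT coefficients; the assemblage-level
  SAR signs are reported alongside and are noisier, since cell medians mix
  species wherever group ranges overlap.

## Numerical conventions and edge cases

- A perfect fit (RSS = 0) reports log-likelihood +∞ (the likelihood
  supremum) rather than failing.
- Rank-deficient designs raise an error naming the collinear columns
  (pivoted QR); constant climate across cells is caught this way.
- The λ_sp search interval is empty only if W has no negative eigenvalues;
  the implementation then brackets with conventional (−1, 1) style bounds.
- Pseudo-R² is clamped to 0 (with a warning) if the model likelihood falls
  below the null, which can only happen through numerical noise.
- All randomness flows from explicit integer seeds; derived seeds are
  produced with seed-sequence hashing and stay below 2³¹.

## Known limitations

- Coefficient inference in the SAR conditions on λ̂_sp (no joint observed
  information); for the study sizes used here the difference is below the
  reported precision.
- The spatial-lag (y-lag) SAR variant, GMM estimation, Moran-eigenvector
  filtering, OU/kappa/delta phylogenetic transforms and measurement-error
  models are out of scope.
- The permutation screen permutes masses globally; spatially restricted or
  richness-preserving randomizations are not implemented.
- Grid cells are treated as equal-area; at continental latitude spans this
  overweights high-latitude cells.
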