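# Methods

This note documents the models, parameter choices and numerical conventions
behind `methclock`, and what its synthetic benchmark does and does not show
about real methylation data.

## Data model and preprocessing

A study is a probes × samples β-value matrix (values in [0, 1], missing
allowed) with a sample sheet (dataset/GSE label, age in years, sex, a
dot-separated MeSH-style tissue code, health status, optional family id)
and a probe annotation (chromosome, gene symbols, probe class cg/rs/ch,
reliability flag). Tables are TSV; the sample sheet's order is
authoritative and matrices are reordered to it on read.

Sample filters keep controls with 20 < age ≤ 85 — the half-open window
deliberately removes age exactly 20 and keeps exactly 85, since the
methylation–age relation is nonlinear outside this range — and keep one
random sample per family (twins/repeats), with the draw seeded and recorded.
Probe filtering acts on a training/validation pair jointly: the probe-set
intersection, minus probes still missing after imputation, blacklisted or
flagged-unreliable probes, rs (SNP control) probes, and everything on X or
Y. Missing β-values are imputed by the probe's mean within the same dataset
beforehand; a probe entirely missing within one dataset stays missing and
is caught by the filter. This ordering (impute → filter-by-missingness)
means only probes that cannot be rescued within some dataset are dropped.
Imputation is deliberately simple — a per-dataset mean; fancier matrix
completion methods exist for real arrays and can replace it, as can a real
between-array normalization via the identity normalization hook. The
logit2 transform `M = log2(β/(1−β))` uses an ε = 1e-6 clamp so degenerate
β ∈ {0, 1} (possible in synthetic or truncated data) stay finite.

## The clock solver

Clocks minimize the elastic-net objective (see README) by cyclic coordinate
descent with warm starts down a decreasing λ grid of
`λ_max = max_j |⟨x_j, y − ȳ⟩| / (n·α)` (α̃ = 0.001 substituted for ridge)
to `λ_max · r` with `r = 0.01` if n < p else `1e-4`, 50 log-spaced points.
Predictors are standardized internally (population SD); coefficients are
reported on the original scale and, for the selection analysis, on the
standardized scale. λ_max is inflated by 1e-10 relatively so that the first
path point has exactly zero coefficients regardless of rounding.

Two conventions follow the reference coordinate-descent solver used
throughout the clock literature, and were verified against it (R `glmnet`)
on matched fixtures:

* **Convergence** is declared when the largest single-coefficient update Δ
  of a full sweep satisfies Δ² < tol · var(y), tol = 1e-7 by default. An
  absolute coefficient tolerance is available by shrinking `tol`; the
  oracle tests run at tol = 1e-14…1e-16, where solutions satisfy the KKT
  conditions to better than 1e-7 and match an independent numerical
  minimizer to 1e-4 and the ridge closed form to 1e-8.
* **Early path termination**: an internally computed path stops once the
  training deviance ratio exceeds 0.999 or improves by less than a 1e-5
  fraction per step. Cross-validation computes the grid on the full data
  and lets each fold's path terminate on its own, carrying its last model
  forward — the behavior of the reference implementation's CV. An
  explicitly supplied grid is always solved in full.

λ is selected at the minimum of the pooled held-out squared error (the
minimum-MSE rule, not the 1-SE rule), ties resolving to the strongest
penalty. Folds are a seeded uniform permutation split into 10 near-equal
parts (n ≥ 10) or leave-one-out (n < 10). Age is regressed untransformed:
within (20, 85] the linear form is adequate and the usual log-age transform
for minors is out of scope.

## Evaluation scores

Both scores derive from the calibration regression of predicted methylage
on chronological age. RMSE is the root mean squared residual **about that
fitted line** — a deliberate, documented divergence from the common
"error versus the identity line" clock metric: a constant or even linear
miscalibration is absorbed by θ₁, θ₂ and does not count as error. The
adjusted R² uses K = 2 (the two calibration parameters) regardless of how
many CpGs the clock contains. Consequences of the about-the-line
convention matter for interpretation; see "Limitations" below.

## The experimental harness

Within each tissue (samples aggregated by dot-boundary MeSH-code prefix,
with an alias map folding cell-subset suffixes like `.CD4` into the
parent), every dataset is held out in turn; clocks are trained on the rest,
pooled, for every cell of penalty × sex configuration × ladder size, and a
cell is attempted only when both sides keep ≥ 3 samples. The ladder is the
fixed sequence 25…2750 (points above the pool are dropped) plus the full
pool. Subsampling is stratified by decade age bins — the coarsest binning
that preserves the age distribution over (20, 85] — with
largest-remainder quotas and seeded uniform draws within strata; excluded
samples form the test split. Joint-trained clocks are validated jointly and
per sex; sex-specific clocks on their own sex. Each cell derives its seed
by hashing (tissue, held-out GSE, penalty, sex, size) with the master seed,
so adding cells never perturbs existing ones. The transfer experiment
trains one clock per penalty on **all** blood samples and scores it on each
other tissue's datasets (`tissue_specific = 0` rows).

## Mixed-model comparisons

Score tables are compared with `Score ~ log n [+ dummy] + (1|GSE)`: a
random intercept on the validation dataset of origin, natural log of the
training-set size (the partial correlation is base-invariant after
standardization), and the contrast dummy of interest (penalty pair,
sex-specific vs joint, tissue pair, or tissue-trained vs blood-trained).
Response, log n and the dummy are all z-scored (n−1 denominator) so the
fixed-effect slope of the dummy is a partial correlation; note that with
correlated covariates such standardized partial slopes can exceed 1 in
magnitude.

REML estimation profiles the criterion over the variance ratio
θ = τ²/σ²: with a single random intercept, V = I + θZZ′ is block diagonal
and analytically invertible per group, so the profiled criterion
`log|V| + log|X′V⁻¹X| + (n−p)·log(r′V⁻¹r)` costs O(n·p²) per evaluation
and is minimized over log₁₀θ ∈ [−8, 8] (bounded scalar minimization,
xatol 1e-10), with the θ = 0 boundary checked explicitly. Wald t-tests use
the deliberately conservative df = n_obs − n_fixed − n_groups
(Satterthwaite-style corrections are out of scope); on simulated null
tables the resulting rejection rate at α = 0.05 is measured at ≈ 0.04–0.06.
P-values are adjusted with the Benjamini–Yekutieli step-up rule within a
reporting family — the set of contrasts shown together: the two responses
for the size analysis, the tissues for the penalty and sex analyses, and
tissues × responses for the transfer analysis.

## CpG-selection analysis

Per tissue, the coefficient matrix of the (leave-one-dataset-out) clocks is
thresholded — |c| ≤ 0.1 set to 0, a closed-interval reading so a
coefficient exactly at the printed bound is zeroed — on the
standardized-predictor scale by default, where a single cut is comparable
across CpGs (the original scale is available). CpGs with non-zero
coefficients in fewer than 10% of a tissue's clocks are dropped (exactly
10% is kept). Consensus sets are the intersection ("all clocks") and union
("any clock") of the per-clock selections; genes are the union of annotated
symbols; overlaps of three labeled sets are reported as the seven exclusive
Venn regions; and gene lists can be matched case-insensitively against
user-supplied reference-clock gene lists (two-column TSV).

## The synthetic generator

The generator emulates the statistical structure the comparison pipeline
assumes — not real 450K data. For clock CpG j, sample i in dataset g:

    M_ij = b_j + (s_j + δ_j·1[sex_i = F]) · age_i + u_{j,g} + ε_ij

with dataset-level intercepts u ~ N(0, batch_sd²) per CpG, residuals
ε ~ N(0, noise_sd²), ages uniform on (20, 85], fair-coin sexes, β = 2^M /
(1 + 2^M), uniform missingness, and appended X/Y and rs probes with no age
signal. Background CpGs have s_j = 0; tissue-specific CpGs drift only in
their own tissue; shared CpGs drift identically everywhere. Slope
magnitudes are uniform on `slope_range` (default 0.01–0.05 M-units/year)
with random sign. Baselines are uniform on `baseline_range` but clamped so
β stays within (0.01, 0.99) across the age range at ±3 total SD, avoiding
logit saturation. Sex modulation acts on the **slope** (δ_j magnitudes
drawn like slopes): a sex-constant level offset would be absorbed by the
calibration regression and could never give sex-specific training an
advantage, whereas sex-dependent drift can. Each dataset draws from its own
RNG stream keyed by (seed, tissue, dataset), so enlarging a design never
perturbs existing datasets.

Default study conditions — the conditions the packaged benchmark runs
under — are three tissues (blood plus two others) × 4 datasets × 120
samples, 150 background + 20 shared + 10 tissue-specific CpGs per tissue,
batch_sd 0.2, noise_sd 0.5, 1% missingness. These were chosen once as a
realistic-but-tractable desk-scale analogue of a multi-cohort 450K
compilation; the CpG count is far below a real array's (a deliberate
problem-size choice documented here, since fitting cost scales with it),
which mainly affects absolute runtimes, not the contrasts.

A second generator produces score tables directly
(`Score = effect · z(log n) + a_g + e`) for mixed-model parameter-recovery
and calibration tests, with all labels assigned at random so every label
contrast is null by construction.

## What the synthetic benchmark shows — and does not

On the standard conditions the pipeline reproduces: a positive,
BY-significant partial correlation between validation adjusted R² and
log sample size; a null sex-specific contrast without planted sex effects
and a positive one with them; and a strongly positive tissue-trained vs
blood-trained contrast on adjusted R². Two outcomes deserve flags:

* **Penalty contrast.** Lasso clocks score measurably below elastic-net
  clocks at small n here (and directionally in the reference solver too).
  All planted clock CpGs are collinear through age, and the elastic net's
  grouping behavior genuinely helps when n ≈ 25–100; with the pipeline's
  exact CV-argmin the per-tissue contrast survives BY adjustment. Real
  compilations, with far noisier and more heterogeneous scores, showed no
  significant penalty difference; the synthetic design is cleaner than
  reality in precisely the way that makes this small real effect
  detectable. Treat the penalty analysis as a power demonstration, not as
  contradicting the equivalence conclusion on real data.
* **Transfer RMSE.** The blood-vs-tissue contrast is decisive for adjusted
  R² but flat for RMSE. Because RMSE is measured about the calibration
  line, it equals the clock's projected CpG-noise ‖w‖·σ, and CV-optimal
  shrinkage equalizes that between a 20-CpG blood clock and a 30-CpG
  tissue clock (measured 2.79 vs 2.78 years) even while relative noise —
  hence adjusted R² (0.94 vs 0.977) — differs sharply. Under a purely
  linear generator the calibration-RMSE contrast carries no information;
  real cross-tissue RMSE differences come from miscalibration and
  nonlinearity that this generator intentionally omits.

Other known limitations: no cell-composition heterogeneity, no realistic
probe manifest or probe-wise noise heteroscedasticity, no nonlinear
(pediatric) age effects, and imputation/normalization stand-ins simpler
than the published tools used on real arrays. Passing tests here validate
the machinery — solvers, metrics, inference, bookkeeping — not biological
conclusions.
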