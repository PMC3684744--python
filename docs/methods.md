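# Methods

`dispersalkit` infers species-level dispersal ability of butterflies from
life-history traits.  This note documents the models and procedures it
implements, the choices made where the design was genuinely open, and what
the synthetic-data studies do and do not demonstrate.

## The four dispersal measurements

Dispersal is not one quantity; the package treats four elements of the
process, each with a normalizing transform on which all models operate:

| element | construction | raw scale | transform |
|---|---|---|---|
| mean dispersal distance | negative-exponential kernel P(D) = e^(−αD) fitted to MRR movement distances; mean = 1/α | km | ln x |
| long-distance dispersal (LDD) frequency | inverse-power kernel P(D) = aD^(−b); probability of movements beyond 5 km | probability | log₁₀ x |
| dispersal propensity | 1 − (resident fraction among recaptures), averaged over patches with equal weight | fraction | −√x |
| gene flow | F_ST among local populations (inversely related to gene flow) | F_ST | 1 − √F_ST |

Kernel fits use closed-form maximum likelihood: α̂ = 1/mean for the
exponential (so the fitted mean distance *is* the sample mean, which is
unbiased), and b̂ = 1 + n/Σln(Dᵢ/d_min) for the Pareto form with reference
distance d_min, a = (b̂−1)d_min^(b̂−1) by normalization.  No numerical
optimizer is involved.  A weighted-least-squares path on log binned
densities (`fit_binned`) serves data published only as binned kernels; the
raw-distance MLE is preferred for its statistical properties.

Two conventions are worth making explicit because the source material for
this kind of analysis leaves them open:

* **Tail probability.**  P(D > 5 km) is the integrated tail mass of the
  fitted density — exp(−αt), or (t/d_min)^−(b−1) — not a point evaluation
  of the density at 5 km.  A frequency of movements beyond a distance is a
  tail mass.
* **Gene-flow transform.**  The stored raw value is always F_ST; the
  analysis value is 1 − √F_ST, which increases with gene flow.  Both
  directions of `transform`/`inverse_transform` are exact on their
  domains (round-trip error < 1e−12).

## Trait coding

Eighteen candidate predictors: 17 life-history traits (demography,
ecological specialization, behaviour) plus wing length.  Ordinal scores
(9-category fecundity, 8-level female maturation, …) are coded as their
integer score and treated as numeric, which is what makes second-degree
polynomials over them meaningful.  Binary traits are 0/1.  Wing length is
stored in mm and enters models as log(wing length) — allometries are power
shaped — as an ordinary candidate, not a forced covariate.  Missing cells
are kept as an explicit mask; model selection uses complete cases over the
response plus the full candidate set, so that AICc compares every model on
one fixed dataset (per-model case deletion would make the criterion values
incomparable).

## Syndrome detection: two-stage exhaustive AICc selection

1. **Curvature pre-screen.**  For each non-binary candidate, fit
   y ~ t + t² (centered powers) and enter the trait as a quadratic pair
   whenever the quadratic coefficient has p < 0.1 — pooling significant and
   marginally significant curvature — else as a linear term.  Numerically
   perfect fits are screened on the coefficient itself (no sampling noise
   exists to test against).
2. **Stage 1.**  Exhaustive search over all subsets of the main-effect
   terms with at most `max_coef` = 8 slope coefficients (a quadratic pair
   counts 2), ranked by AICc.  The cap guards against saturation at the
   small species counts (25–29) typical of dispersal compilations, and is
   configurable.
3. **Stage 2.**  Variables appearing in any stage-1 model within ΔAICc ≤ 2
   of the best are pooled; all pairwise interactions among them join the
   candidate set; the exhaustive search repeats under the same cap.
   Marginality is enforced: an interaction is admissible only with both
   main effects present (this also makes centering irrelevant to fitted
   values).
4. **Final choice.**  The model with the highest R² within the stage-2
   ΔAICc ≤ 2 set — prediction is the goal, and that model captures the most
   deviance.  Term stability is reported as each term's inclusion
   frequency across the top set.

Numerical conventions: AICc = −2ℓ + 2p + 2p(p+1)/(n−p−1) with p counting
intercept, slopes and residual variance, ℓ the Gaussian log-likelihood at
the MLE variance RSS/n.  Models whose RSS falls below 1e−12 of the total
sum of squares are treated as numerically perfect: their likelihood is
unbounded, AICc is −∞, and R² is set to exactly 1 so that ties resolve by
parsimony (fewer coefficients, then lexicographic term order) rather than
floating-point residue.  AICc ties generally break by higher adjusted R²,
then fewer coefficients, then term order — deterministic by construction.
The exhaustive search solves each subset from one precomputed Gram matrix
(Cholesky on X'X); the chosen model is refit through statsmodels OLS for
its public coefficient table, and tests assert the two routes agree to
1e−8.

**Recovery semantics.**  The pre-screen is univariate, so when screening
one true trait the other acts as residual noise, and a true linear trait is
flagged quadratic with probability ≈ the screen's α even at zero noise; the
flagged trait then enters as a quadratic pair whose quadratic coefficient
fits exactly 0.  Simulation studies therefore score recovery at the effect
level: a generating linear effect is recovered when the trait is present as
a linear term *or* a quadratic pair (which contains the linear slope);
quadratic and interaction effects must match in kind; "exact recovery"
additionally requires that no extra variable enters.

## Quality assessment by cross-validation

Random 75–25 partitions (training size = round half-up of 0.75n, so 29
species split 22/7); the model's coefficients are re-estimated on each
training partition and applied to the held-out species; 100 partitions give
per-species mean predictions and SEs (species never held out — possible at
small n — are listed and get no SE; rank-deficient training draws are
redrawn and counted).  Two measures compare observations with mean
predictions, both on the transformed scale where the models live:

* **rightness** — OLS slope of observed on predicted, with intercept
  (ideal 1);
* **imprecision** — mean |observed − predicted|, divided by the observed
  value for the two scale-dependent measures (mean distance, LDD
  frequency).

Twenty independent repeats, each with fresh partitions (the repeats nest
the partitions), give means ± SEs.  The reference model is a GLM with
log wing length as the only regressor, refit per partition under the
identical protocol.  Gains are reported as a rightness difference and an
imprecision ratio (reference/trait, > 1 favouring the trait model), with
significance from an OLS regression of the per-repeat performance values on
a model-type indicator.

## Variance partitioning (LMG)

The chosen model's R² is split among regressor units by averaging each
unit's sequential R² increment over all orderings.  Contributions are
non-negative and sum to the full R² (telescoping identity; asserted to
1e−10).  Up to 10 units the exact subset-weighted form is used (weight
|S|!(p−|S|−1)!/p! for the increment after subset S; 2^p distinct
submodels); above that, seeded random orderings are averaged.  By default a
quadratic pair or interaction is one unit (one contribution per listed
term); a per-coefficient mode decomposes per design column instead, since
either grouping is defensible when polynomials are present.

## Phylogenetic check (PGLS, Pagel's λ)

Before trusting plain GLMs, the selected model can be refit by GLS with
residual covariance λ-scaled from the tree's Brownian structure
(cov(i,j) = shared root-path length; λ multiplies off-diagonals only).  λ
is estimated by ML on [0, 1] via a 16-point grid pre-scan plus bounded
refinement; on ultrametric trees each λ evaluation is O(n) after one
eigendecomposition (the eigenvectors of C diagonalize V(λ) for every λ),
with a Cholesky path otherwise and a 1e−10 relative ridge guarding
numerically duplicate tips.

The λ = 0 test is the subtle part.  The asymptotic null for the LR
statistic at a boundary is the mixture ½χ²₀ + ½χ²₁, but with ML (not REML)
the mean is estimated, and projecting it out gives the profile score for λ
a negative expectation at 0; empirically λ̂ hits the boundary ~80% of the
time on 64–256-tip pure-birth trees and the mixture test rejects at ~1.5%
instead of 5%.  `PGLSResult.lr_pvalue` reports the mixture p-value with
this caveat; `PGLSModel.lr_test_mc` simulates the null on the same tree —
the LR statistic is invariant to the coefficients and the residual scale,
so the Monte-Carlo test has exact size — and is what the calibration study
uses.

## Prediction for unmeasured species

The chosen model is applied to the full trait table; transformed
predictions are back-transformed with truncation into each element's valid
domain (LDD frequency to (0, 1]; propensity and gene flow to [0, 1]; mean
distance needs none).  Because a trait's effect is only known over the
range spanned by the training species, species with any retained trait
outside the training [min, max] (closed interval) are flagged and their
natural-scale predictions suppressed unless `extrapolate` is requested.
Distribution summaries use type-7 quantiles (linear interpolation of order
statistics) — "90% of species" statements depend on the convention — and
attach Gaussian KDEs for plotting.

## The synthetic-data generator

No machine-readable species data accompany the trait and dispersal
compilations this package targets, so every stage is exercised on synthetic
data emulating their documented structure: traits uniform within each
trait's admissible range (wing length 11–37.5 mm), responses generated on
the transformed scale as intercept + Σ coef·(standardized trait terms) +
Gaussian noise, back-transformed and clipped into the valid raw domain
(clipping recorded per species); movement distances from exponential or
Pareto kernels; per-patch residency counts binomial around a common leave
probability; F_ST uniform in [0, 0.18] (weak structuring, as observed in
butterflies); pure-birth trees with Brownian traits at tunable λ.  Traits
are independent by default — a Gaussian copula accepts a correlation
matrix when co-variation matters — because independence keeps recovery
studies interpretable.

Default study conditions for the recovery and cross-validation studies:
n = 29 species (the mean-distance sample size), two true linear effects of
1.0–1.2 response-SD per trait-SD among 10 candidates, noise SD 0.25 on the
transformed scale, wing length carrying no signal.  Simulation scales:
200 kernel samples of n = 500; 100 selection replicates per noise level;
50 cross-validation comparison replicates at 20 repeats × 100 partitions;
400 null and 100 Brownian PGLS simulations on 64-tip trees with 199
simulated-null draws per test.

**What passing does and does not show.**  The studies demonstrate that the
machinery is correct and well calibrated under its own assumptions —
independent uniform traits, Gaussian noise on the transformed scale,
correctly specified linear syndromes.  Real trait tables are correlated,
ordinal scores are coarse, dispersal measurements carry heterogeneous
observation error, and true syndromes need not be linear; none of these are
claimed.  In particular the published headline numbers for the empirical
butterfly dataset (coefficients, rightness/imprecision values, distribution
summaries) are not reproducible without the original species data, which
were never deposited; the package reproduces the *procedure*, not those
numbers.

## Known limitations

* Propensity averaging over patches is unweighted; no detectability or
  effort correction for MRR designs.
* Only the two kernel families above; no mixtures or heavy-tail
  alternatives.
* PGLS supports a single λ for the residual covariance; no OU models or
  Blomberg's K.
* The stage-2 interaction pool grows quadratically in the stage-1 variable
  pool; with noise-free responses (every superset of the true model is
  "perfect") the search can visit several hundred thousand models per
  dataset, which is exhaustive by design but not fast.
* Complete-case handling drops species missing any candidate trait for a
  response, which can discard information when missingness is heavy.
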