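# dispersalkit

Trait-based inference of butterfly dispersal.

Measuring dispersal is hard: mark-release-recapture (MRR) campaigns and
population-genetic surveys exist for only a fraction of species, while
life-history traits are catalogued for nearly all of them.  Because
dispersal co-evolves with other traits into *dispersal syndromes*, a
species' life history can stand in for the missing measurements — and does
so far better than the classic proxy, wing size.  `dispersalkit` implements
that programme end to end for the four standard elements of butterfly
dispersal:

* **mean dispersal distance** — 1/α of a negative-exponential kernel
  P(D) = e^(−αD) fitted to MRR movement distances (analysed as ln x);
* **frequency of long-distance dispersal** — P(D > 5 km) from an
  inverse-power kernel P(D) = aD^(−b) (log₁₀ x);
* **dispersal propensity** — 1 − resident fraction among recaptures,
  averaged over patches (−√x);
* **gene flow** — from F_ST among local populations (1 − √F_ST).

For each element the pipeline is: a quadratic pre-screen of every
non-binary trait (p < 0.1 curvature enters as a second-degree polynomial);
**stage 1**, an exhaustive all-subsets Gaussian-GLM search over 18
candidate predictors (17 life-history traits + log wing length) capped at 8
slope coefficients and ranked by AICc; **stage 2**, the same search over
the variables of the stage-1 ΔAICc ≤ 2 set plus all their pairwise
interactions; the final model is the highest-R² member of the stage-2 top
set.  Quality is quantified by cross-validation (75–25 partitions × 100,
20 repeats): *rightness* (slope of observed on predicted, ideal 1) and
*imprecision* (mean absolute error, relative for the scale-dependent
measures), with gains reported against a wing-size-only reference GLM.
Explained variance is partitioned among traits by the LMG (all-orderings)
decomposition, phylogenetic signal is checked by PGLS with ML Pagel's λ,
and the selected model predicts dispersal for every species whose traits
fall inside the training ranges, with domain-respecting back-transforms.

A synthetic-data module generates trait tables, syndrome-structured
responses, kernel distance samples, residency counts, F_ST values, and
pure-birth trees with Brownian traits, so the whole pipeline is testable
without the (undeposited) empirical species data.  See
[docs/methods.md](docs/methods.md) for the full model description and
design choices.

## Worked example

```python
import dispersalkit as dk

# synthesize a study: 29 species, a two-trait syndrome for mean distance
traits = dk.simulate_trait_table(dk.SimulationConfig(n_species=29, seed=42))
true = dk.TrueModel(
    "mean_distance",
    (dk.TrueTerm("larval_growth_rate", "linear", -1.2),
     dk.TrueTerm("ovigeny_index", "linear", 1.0)),
    intercept=-1.5, noise_sd=0.25,
)
sim = dk.simulate_responses(traits, true, seed=7)

model = dk.DispersalTraitModel.from_tables(
    sim.dataset, traits, "mean_distance",
    candidates=["larval_growth_rate", "ovigeny_index", "fecundity", "voltinism",
                "flight_period", "myrmecophily", "mate_location", "thermal_tolerance",
                "adult_lifetime", "log_wing_length"],
)
res = model.fit()
print(res.summary())
```

```
Two-stage exhaustive AICc selection
============================================================
response: mean_distance (n = 29 complete cases)
stage 1: 835 models searched, 3 within delta AICc <= 2
stage 2: 267 models searched, 5 within delta AICc <= 2

Model: mean_distance ~ poly(adult_lifetime, 2) + flight_period + larval_growth_rate
       + poly(ovigeny_index, 2) + adult_lifetime:larval_growth_rate
       + adult_lifetime:ovigeny_index
n = 29, slopes k = 8, AICc = -8.753
R^2 = 0.9948, adj. R^2 = 0.9927, residual SD = 0.1194
...
```

Both generating traits (larval growth rate, ovigeny index) are retained
with dominant coefficients; the extra terms are the small-sample freight
the highest-R² rule tolerates.  Cross-validated quality against the
wing-size-only reference (wing length carries no signal here):

```python
gain = res.compare_with_reference(seed=1)
print(gain.summary())
```

```
gain in rightness: +6.9141 (p = 1.06e-32)
gain in precision: x 9.615 (p = 1.85e-70)
```

The trait model cross-validates at rightness 0.9906 ± 0.0005 where the
reference manages −5.92 ± 0.17, and its predictions are 9.6× more precise.
Variance partition and prediction for 142 unmeasured species:

```python
print(res.importance())
big = dk.simulate_trait_table(dk.SimulationConfig(n_species=142, seed=99))
preds = res.predict(big)
print(dk.summarize_distribution(preds, observed=sim.dataset).round(4))
```

```
ImportanceDecomposition(R^2 = 0.9948; poly(adult_lifetime, 2): 0.0722,
  flight_period: 0.0201, larval_growth_rate: 0.4254,
  poly(ovigeny_index, 2): 0.4415, adult_lifetime:larval_growth_rate: 0.0255,
  adult_lifetime:ovigeny_index: 0.0101)

               n    mean     min     max     q10     q50     q90
predicted  107.0  0.5757  0.0072  5.2029  0.0321  0.2335  1.4237
observed    29.0  0.4964  0.0088  1.8982  0.0181  0.3837  1.0674
```

The two dominant contributions are the generating traits (together 0.87 of
R² = 0.99).  Of 142 species, 107 fall inside the training trait ranges and
receive natural-scale predictions (km); the predicted and observed
distributions of mean dispersal distance agree closely (medians 0.23 vs
0.38 km at n = 107 vs 29).

A thin CLI mirrors the library: `dispersalkit simulate | select | validate
| importance | pgls | predict | kernels` (see `dispersalkit --help`).

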