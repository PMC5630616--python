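# prefnet

Predicting weighted bipartite interaction networks — which consumer species
interacts with which resource species, and how often — at new field sites,
including sites in habitats modified by human land use.

`prefnet` is written for community ecologists working with weighted
host–parasitoid (or plant–pollinator) networks: count matrices `B_ijk`
recording interaction events between resource species *i* and consumer
species *j* at field site *k*, with networks grouped by habitat type.

## The model

The core idea is to decompose weighted network structure into two
interpretable parts:

```
B_ijk ∝ γ_ij · x̂_i · x̂_j
```

* `x̂_i`, `x̂_j` — **effective abundances**, estimated from the interaction
  counts themselves by solving the over-determined log-linear system
  `α·ln x_i + β·ln x_j = ln B_ijk` (one equation per positive count, minimum
  norm least squares) over a grid of scaling exponents `0 < α, β ≤ 2` in
  steps of 0.05, selecting the pair with the largest multinomial
  log-likelihood. They are *functional* quantities consistent with mass
  action, not census abundances.
* `γ_ij` — **interaction preferences**, the multiplicative deviation of each
  link from the random-encounter (mass action) expectation: γ = 1 is
  consistent with mass action, γ > 1 preferred, γ < 1 less preferred, γ = 0
  forbidden.

Seven models of increasing complexity turn this decomposition into
predictions `p_ijk` on the positive-count support of a test group: a uniform
**null** model; an **aggregate counts** model (no decomposition); **random
encounter** (abundances only); **alternative preferences** (carry the
calibration habitat's γ over unchanged); **correlated preferences** (reorder
each consumer's γ column to the preference rank order of the new habitat and
fit an exponent δ); **specified preferences** (hardcode a few influential
links to their test-derived values); and **complete characterisation**
(every γ from the test habitat).

Predictions are scored with the multinomial log-likelihood of the observed
counts, rescaled per site against the null model
(`F_{M,k} = (L_null − L_M)/L_null`) and per group between the
random-encounter and complete-characterisation anchors
(`R_M = (L_re − L_M)/(L_re − L_complete)`), plus AIC/BIC.

Because the field data sets this method was developed on are available only
on request, the package ships a first-class synthetic-data module
(`prefnet.synthetic`) that simulates ground-truth groups and habitat
modifications (column-rank permutations of γ, hardcoded link changes,
switches), so every stage is testable end to end.

## Worked example

The aggregation pitfall: five sites share two hosts and one parasitoid; the
first host has counts {3, 3, 3, 3, 3} across sites, the second {10, 0, 0, 0, 0}.

```python
from prefnet import make_paper_toy, fit_effective_abundances, aggregate_abundance_proxy

toy = make_paper_toy()
print(aggregate_abundance_proxy(toy))
ab = fit_effective_abundances(toy)
print(f"alpha_hat={ab.alpha_hat}  x(h1)={ab.host_abundance['h1']:.2f}  "
      f"x(h2)={ab.host_abundance['h2']:.2f}")
```

```
{'h1': 15, 'p1': 25, 'h2': 10}
alpha_hat=1.0  x(h1)=2.64  x(h2)=8.82
```

Summing counts across sites ranks host 1 above host 2 (15 vs 10), but the
effective-abundance fit, which respects site-level structure, ranks host 2
well above host 1 — aggregation underestimates spatially less-common species.

Predicting between two groups sampled from the same habitat:

```python
import numpy as np
from prefnet import RunConfig, ScenarioSpec, run_pipeline, simulate_group
from prefnet.synthetic import sample_group

spec = ScenarioSpec(preference_model="negative_neighbor_structure", seed=1)
_, truth = simulate_group(spec)
cal = sample_group(truth, spec, np.random.default_rng(11), "meadow_a")
test = sample_group(truth, spec, np.random.default_rng(12), "meadow_b")
result = run_pipeline(RunConfig(cal, test, models=["aggregate", "re", "alt", "complete"]))
for label, report in sorted(result.reports.items()):
    r = "   NA" if report.r_m is None else f"{report.r_m:5.2f}"
    print(f"{label:26s} loglik={report.group_loglik:9.2f}  R={r}")
```

```
aggregate_counts           loglik=  -624.94  R= 0.90
alternative_preferences    loglik=  -600.69  R= 0.94
complete_characterisation  loglik=  -566.69  R= 1.00
random_encounter           loglik= -1155.56  R=-0.00
```

`R` reads as "fraction of the attainable likelihood gain over mass action":
carrying the calibration preference matrix over (alternative preferences,
R = 0.94) captures nearly everything the complete characterisation captures,
because the two groups share one habitat's behaviour.

A command-line interface mirrors the library
(`prefnet simulate | fit-abundance | fit-preferences | predict | evaluate |
compare-preferences | run`); see `prefnet --help`.

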