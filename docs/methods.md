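# Methods

## Model and assumptions

`prefnet` treats a weighted bipartite network as counts `B_ijk` of
interaction events between resource (host) species *i* and consumer
(parasitoid) species *j* at field site *k*, and decomposes expected counts as

    B_ijk ∝ γ_ij · x̂_i · x̂_j

with effective abundances `x̂` shared by all sites of a group (one habitat
type) and a single preference matrix `γ` per group. Both are inferential
conveniences, not biological claims: there are rarely enough data to estimate
site-level abundances, and a shared γ is what makes the matrix transferable
to new sites. Counts at each evaluation unit are modelled as one multinomial
draw over the unit's positive-count cells; all likelihoods are multinomial
log-pmfs computed with log-gamma factorials.

Key consequences of these assumptions:

* Only the *positive-count support* enters likelihoods (`a_ijk = 1` iff
  `B_ijk > 0`). Explicit zero-count markers denote forbidden or
  known-but-unobserved links and never enter the support.
* Abundances carry a gauge freedom (a constant can move between guilds);
  every probability and likelihood reported is invariant to it. Reported
  abundances are pinned by the minimum-Euclidean-norm least-squares solution
  in log space.
* The estimator is conservative by construction: it attributes as much
  structure as possible to mass action, so genuinely strong preferences are
  systematically shrunk toward 1. In small networks (2×2) a single strong
  link can be absorbed almost entirely into the two species' abundances;
  identifiability of γ improves with network size and link density.

## Effective-abundance estimation

For each exponent pair (α, β) the over-determined system
`α·u_i + β·v_j = ln B_ijk` (one equation per positive count, `u = ln x`)
is solved by `numpy.linalg.lstsq` (rcond=None), giving the minimum-norm
least-squares solution. Each pair is scored by the multinomial log-likelihood
of the group's counts with cell weights `x_i·x_j` (first power — the
exponents only shape within-guild spread), and the best pair (α̂, β̂) wins.

* Grid: `0 < α, β ≤ 2` in steps of 0.05 (1600 points). Configurable through
  `ScalingGrid`.
* Ties: broken by the lexicographically smallest (α, β) via strict-greater
  comparison in ascending loop order. Exact float ties essentially occur only
  in gauge-degenerate systems (e.g. a single consumer species), where any
  winner yields identical probabilities.
* Species with no positive counts have no equation; they are dropped with a
  warning and receive no abundance.
* If the bipartite link graph is disconnected, relative scales between
  components are arbitrary; the fit flags `connected=False` (networkx
  connectivity check) and proceeds, since within-support probabilities
  remain well defined per component.

## Preference derivation

`γ_ij = B̄_ij / (κ·x̂_i·x̂_j)` where `B̄_ij` is the mean count over the sites
at which the link is positive and `κ = Σ B̄ / Σ x̂ x̂` (sums over positive
links). κ makes the mass-action anchor exact: counts exactly proportional to
abundance products give γ ≡ 1, and `Σ γ x̂ x̂ = Σ x̂ x̂` holds by
construction. The absolute normalisation cancels in every model probability.

Averaging over *occupied* sites only (rather than all sites) keeps rare
links' preferences from being diluted by absences, at the cost of an upward
zero-truncation bias for links whose expected per-site count is O(1). This
bias vanishes as counts grow and is quantified in the anchor scenario below.

Uncertainty: per-link 2.5/97.5 percentile intervals from a multinomial
bootstrap (default 1000 replicates) that resamples each site's counts with
its empirical proportions and refits abundances with (α, β) frozen at
(α̂, β̂) for speed. Cross-group comparison classifies links as incumbents
(positive in both groups; significant change = disjoint intervals) or
switches (positive in one; significant = interval excluding 1).

The neighbour-preference diagnostic correlates each link's γ with the mean γ
of the other links sharing its host or parasitoid (Spearman), with a
two-sided permutation test (default 999 shuffles, seeded). Zero variance in
either vector is reported as *undefined*, never coerced to 0.

## The seven models

All models emit strictly positive probabilities summing to 1 (checked to
1e-12) over the evaluation support. Per-link weights are site-independent;
normalisation runs over all (i, j, k) cells of the evaluation unit — the
whole group for `R`, a single site (renormalised) for `F`. Specifics:

* **Switches** (test links absent from calibration): γ = 1 under the
  `mass_action` rule (the default; it performed better in the original field
  comparisons) or `1 − 2^(−1/(x̂^cal_i x̂^cal_j))` under `less_preferred`.
  A species absent from calibration has no x̂^cal, and the switch falls back
  to mass action.
* **Aggregate counts**: test links never seen in calibration receive a
  pseudo-mass of 1e-3 × the smallest positive calibration link sum, keeping
  the model evaluable (zero mass would send the whole log-likelihood to −∞)
  while preserving its intended poor ranking. Factor configurable.
* **Correlated preferences**: per consumer column, the multiset of
  calibration γ values (switches filled first) is reassigned to hosts in the
  descending preference rank order of the rank source (the test-derived
  matrix). Rank ties break by host identifier; value assignment is a stable
  descending sort. The exponent δ is fitted on a grid (0, 3] step 0.05 by
  maximum likelihood of the evaluation counts, ties to the smallest δ; the
  grid mirrors the (α, β) convention since nothing pins a natural range.
  δ is fitted on whatever evaluation unit is passed in (the whole test group
  in the pipeline).
* **Influential interactions**: each link is scored by the log-likelihood of
  the test counts with all preferences at 1 except the focal link's
  test-derived γ′; links are sorted by this contribution and the selection
  takes everything above the single largest gap in the sorted sequence —
  a deterministic stand-in for judging an "obvious discontinuity" by eye —
  capped at 50% of links to prevent degenerate full selection. A `top_n`
  override and an abundance-product rule of thumb (`abundant_pairs_rule`)
  are provided.
* **Specified preferences**: selected links hardcoded to their test values on
  top of either the calibration matrix (`base="cal"`) or the rank-reordered
  matrix raised to δ (`base="corr"`, the combined model).

AIC/BIC parameter counts are a stated convention (reported with every
result): abundance-based models carry `S_h + S_p − 2` free parameters,
correlated adds 1 (δ), specified adds one per hardcoded link, complete one
per link, null and aggregate none.

## Performance measures

`F_{M,k} = (L_null,k − L_{M,k})/L_null,k` per site, with per-site
renormalised probabilities; a single-cell site has `L_null = 0` and F is
flagged undefined (`None`), not 0. The alternative convention (group-
normalised p restricted to the site) was considered and rejected because a
probability vector must sum to 1 over the multinomial support being scored.
`R_M = (L_re − L_M)/(L_re − L_complete)` at the group level, treating all
sites' support cells as one multinomial; degenerate scales
(`L_re = L_complete`) are flagged undefined. −∞ log-likelihoods (positive
count on a zero-probability cell) propagate as explicit `-inf` with a
warning, never silently.

## Synthetic data: what it emulates and what it does not

`ScenarioSpec` defaults mimic the field studies the method targets: 8 sites
per group (studies used 6–13), 10 hosts × 8 parasitoids, 200 recorded events
per site, lognormal(0, 1) abundances per guild, 30% of species pairs
forbidden. Counts are a single multinomial draw per site with a fixed total
— exactly the distribution the likelihood scores — with abundances drawn
once per group. Habitat modification is emulated by editing the planted γ
table: per-column rank permutations (systematic selectivity change),
hardcoded per-link overwrites (new foraging strategies), switch
additions/removals, and a global exponent. The
`negative_neighbor_structure` option gives each host one strongly preferred
link (γ = √strength) and weaker ones elsewhere (γ = 1/√strength), the
pattern reported for open habitats.

Not emulated: overdispersion relative to the multinomial (real sampling is
clumped), temporal turnover, observation error in species identity, and any
spatial structure among sites. Passing tests therefore demonstrate
correctness of the estimators and the internal consistency of the model
chain, not robustness to field-data messiness.

## Test and acceptance scenario sizes

Chosen so the whole chain is exercised at meaningful statistical resolution:

* Parameter recovery: 6+6 species, 5 sites, 10³ counts/site, 20 seeds;
  within-guild Spearman between planted and recovered abundances averages
  ≥ 0.9 (measured ≈ 0.99).
* Mass-action anchor: same sizes at 10⁴ counts/site with abundance σ = 0.5,
  so every link's expected count is large enough (≥ ~50 per site) that
  max|γ−1| < 0.1 probes estimator correctness rather than rare-link
  sampling noise; under the heavier-tailed σ = 1 default, links with ~1
  expected count per site keep max|γ−1| of order 0.5 at 10⁴ counts purely
  from zero-truncation and small-count noise. The deviation is also checked
  to shrink from 10³ to 10⁴ counts.
* Habitat-modification discrimination: structured truths (per-column γ
  spanning 4 to 0.25, lognormal abundances), 20 seeds; random per-column
  rank permutation for the correlated-vs-alternative comparison, plus three
  heavy links hardcoded to γ = 6 for the specified-vs-correlated comparison;
  replicate pairs from one truth for the similar-habitat check (R > 0 in
  ≥ 90% of seeds).
* `scripts/acceptance.py` runs the same scenarios (20 seeds, all seeded from
  the `--seed` argument via named substreams) in under a couple of minutes.

## Known limitations

* Effective abundances are not census abundances; how they relate to survey
  data is an open empirical question, and the estimator deliberately
  under-attributes structure to behaviour.
* Preferences are only defined for co-occurring, observed pairs; systems
  with heavy species turnover leave the calibration matrix sparse and push
  every model toward its switch rule.
* The AIC/BIC parameter counts are a convention, not derived degrees of
  freedom; use them comparatively, not absolutely.
* The bootstrap freezes (α̂, β̂), slightly understating interval width.
* Per-site F is noisy at sites with few counts — there is little room for
  non-random weighted structure in tiny samples.
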