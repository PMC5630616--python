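"""Ground-truth simulators for testing every stage of the pipeline.

The sampling model is exactly the model the likelihood scores: per-guild
abundances are drawn once per group (they are assumed to hold across all of a
group's field sites), cell weights on the non-forbidden links are
``γ_ij·x_i·x_j``, and each site's counts are one multinomial draw with a
fixed per-site total.  Habitat modification is emulated by editing the
ground-truth preference table: per-column rank permutations (systematic
changes in consumer selectivity), hardcoded per-link overwrites (new foraging
strategies), and link additions/removals (switches).

Defaults mimic the field studies the method was designed for: groups of eight
sites, roughly ten species per guild, a few hundred recorded parasitism
events per site, and around 30% of species pairs forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .network_core import (
    Link,
    NetworkGroup,
    SpeciesRegistry,
    ValidationError,
    WeightedNetwork,
)

__all__ = [
    "ScenarioSpec",
    "Modification",
    "GroundTruth",
    "simulate_group",
    "apply_modification",
    "make_paper_toy",
]


@dataclass
class Modification:
    """A habitat-modification recipe applied to a ground truth."""

    #: per-parasitoid permutation of that column's γ values: a mapping
    #: parasitoid → explicit host order, or "random" / "reverse" for all columns
    rank_permutation: Union[None, str, dict[str, list[str]]] = None
    hardcoded_changes: dict[Link, float] = field(default_factory=dict)
    switch_additions: list[Link] = field(default_factory=list)
    switch_removals: list[Link] = field(default_factory=list)
    delta_true: float = 1.0


@dataclass
class ScenarioSpec:
    """Parameters of one simulated group of site networks."""

    n_hosts: int = 10
    n_parasitoids: int = 8
    n_sites: int = 8
    counts_per_site: Union[int, list[int]] = 200
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    preference_model: str = "mass_action"  # | "planted" | "negative_neighbor_structure"
    planted_gamma: dict[Link, float] = field(default_factory=dict)
    neighbor_strength: float = 9.0
    forbidden_fraction: float = 0.3
    modification: Optional[Modification] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hosts, self.n_parasitoids, self.n_sites) < 1:
            raise ValidationError("dimensions must be >= 1")
        totals = self.site_totals()
        if any(t < 1 for t in totals):
            raise ValidationError("counts_per_site must be >= 1")
        if not 0 <= self.forbidden_fraction < 1:
            raise ValidationError("forbidden_fraction must be in [0, 1)")
        if any(g < 0 for g in self.planted_gamma.values()):
            raise ValidationError("planted preferences must be >= 0")

    def site_totals(self) -> list[int]:
        if isinstance(self.counts_per_site, int):
            return [self.counts_per_site] * self.n_sites
        return list(self.counts_per_site)


@dataclass
class GroundTruth:
    """Planted quantities behind a simulated group."""

    host_abundance: dict[str, float]
    parasitoid_abundance: dict[str, float]
    gamma: dict[Link, float]  # non-forbidden links only
    forbidden: set[Link]

    def allowed_links(self) -> list[Link]:
        return sorted(self.gamma)


def _host_ids(n: int) -> list[str]:
    return [f"h{i + 1:02d}" for i in range(n)]


def _par_ids(n: int) -> list[str]:
    return [f"p{j + 1:02d}" for j in range(n)]


def _draw_truth(spec: ScenarioSpec, rng: np.random.Generator) -> GroundTruth:
    hosts, pars = _host_ids(spec.n_hosts), _par_ids(spec.n_parasitoids)
    x_h = {
        h: float(v)
        for h, v in zip(
            hosts, rng.lognormal(spec.abundance_mu, spec.abundance_sigma, len(hosts))
        )
    }
    x_p = {
        p: float(v)
        for p, v in zip(
            pars, rng.lognormal(spec.abundance_mu, spec.abundance_sigma, len(pars))
        )
    }
    all_links = [(h, p) for h in hosts for p in pars]
    n_forbidden = int(round(spec.forbidden_fraction * len(all_links)))
    forbidden: set[Link] = set()
    if n_forbidden:
        # keep every species attached to at least one allowed link
        order = [all_links[i] for i in rng.permutation(len(all_links))]
        deg_h = {h: len(pars) for h in hosts}
        deg_p = {p: len(hosts) for p in pars}
        for link in order:
            if len(forbidden) == n_forbidden:
                break
            h, p = link
            if deg_h[h] > 1 and deg_p[p] > 1:
                forbidden.add(link)
                deg_h[h] -= 1
                deg_p[p] -= 1
    allowed = [l for l in all_links if l not in forbidden]
    if not allowed:
        raise ValidationError("all links forbidden")
    if spec.preference_model == "mass_action":
        gamma = {l: 1.0 for l in allowed}
    elif spec.preference_model == "planted":
        gamma = {l: float(spec.planted_gamma.get(l, 1.0)) for l in allowed}
    elif spec.preference_model == "negative_neighbor_structure":
        # per host one strongly preferred link, the rest much less preferred
        hi = float(np.sqrt(spec.neighbor_strength))
        lo = 1.0 / hi
        gamma = {l: lo for l in allowed}
        for h in hosts:
            row = [l for l in allowed if l[0] == h]
            if row:
                gamma[row[rng.integers(len(row))]] = hi
    else:
        raise ValidationError(f"unknown preference model {spec.preference_model!r}")
    return GroundTruth(x_h, x_p, gamma, forbidden)


def apply_modification(
    truth: GroundTruth,
    modification: Modification,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """A new ground truth with the requested preference edits applied.

    Rank permutations conserve each column's multiset of γ values; hardcoded
    changes overwrite single links; switch additions enter at mass action
    (γ = 1) unless also hardcoded, and removals become forbidden.
    """
    gamma = dict(truth.gamma)
    forbidden = set(truth.forbidden)
    hosts = sorted(truth.host_abundance)
    pars = sorted(truth.parasitoid_abundance)
    mod = modification
    if mod.rank_permutation is not None:
        if rng is None and mod.rank_permutation == "random":
            raise ValueError("random rank permutation needs an rng")
        for p in pars:
            col = sorted(h for h in hosts if (h, p) in gamma)
            if len(col) < 2:
                continue
            if mod.rank_permutation == "random":
                new_order = [col[i] for i in rng.permutation(len(col))]
            elif mod.rank_permutation == "reverse":
                new_order = list(reversed(col))
            elif isinstance(mod.rank_permutation, dict):
                new_order = mod.rank_permutation.get(p, col)
                if sorted(new_order) != col:
                    raise ValidationError(
                        f"permutation for column {p!r} does not match its hosts"
                    )
            else:
                raise ValidationError(
                    f"unknown rank permutation {mod.rank_permutation!r}"
                )
            values = [gamma[(h, p)] for h in col]
            for h, v in zip(new_order, values):
                gamma[(h, p)] = v
    for link in mod.switch_removals:
        if link not in gamma:
            raise ValidationError(f"cannot remove unknown link {link}")
        del gamma[link]
        forbidden.add(link)
    for link in mod.switch_additions:
        h, p = link
        if h not in truth.host_abundance or p not in truth.parasitoid_abundance:
            raise ValidationError(f"switch addition references unknown species {link}")
        gamma[link] = 1.0
        forbidden.discard(link)
    for link, g in mod.hardcoded_changes.items():
        if link not in gamma:
            raise ValidationError(f"hardcoded change references unknown link {link}")
        gamma[link] = float(g)
    if mod.delta_true != 1.0:
        gamma = {l: g ** mod.delta_true for l, g in gamma.items()}
    return GroundTruth(
        dict(truth.host_abundance), dict(truth.parasitoid_abundance), gamma, forbidden
    )


def sample_group(
    truth: GroundTruth,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    group_id: str = "sim",
) -> NetworkGroup:
    """Multinomial site networks from a ground truth (fixed per-site totals)."""
    links = truth.allowed_links()
    w = np.array(
        [
            truth.gamma[l]
            * truth.host_abundance[l[0]]
            * truth.parasitoid_abundance[l[1]]
            for l in links
        ]
    )
    if w.sum() <= 0:
        raise ValidationError("all link weights are zero")
    p = w / w.sum()
    networks = []
    for k, total in enumerate(spec.site_totals()):
        draw = rng.multinomial(total, p)
        counts = {l: int(c) for l, c in zip(links, draw) if c > 0}
        networks.append(WeightedNetwork(f"s{k + 1:02d}", counts))
    registry = SpeciesRegistry.from_lists(
        sorted(truth.host_abundance), sorted(truth.parasitoid_abundance)
    )
    return NetworkGroup(group_id=group_id, registry=registry, networks=networks)


def simulate_group(spec: ScenarioSpec) -> tuple[NetworkGroup, GroundTruth]:
    """Draw a ground truth and a group of site networks from it.

    Reproducible given ``spec.seed``; any ``spec.modification`` is applied to
    the truth before sampling.  Returns the group together with the planted
    abundances and preferences.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _draw_truth(spec, rng)
    if spec.modification is not None:
        truth = apply_modification(truth, spec.modification, rng)
    group = sample_group(truth, spec, rng)
    return group, truth


def make_paper_toy() -> NetworkGroup:
    """The two-host, one-parasitoid aggregation example.

    Five single-parasitoid site networks where the first host has counts
    {3, 3, 3, 3, 3} and the second {10, 0, 0, 0, 0}: aggregation ranks host 1
    above host 2 (15 vs 10 counts), yet host 2 is the more abundant one at
    the level of individual field sites.
    """
    registry = SpeciesRegistry.from_lists(["h1", "h2"], ["p1"])
    counts_h2 = [10, 0, 0, 0, 0]
    networks = []
    for k in range(5):
        counts: dict[Link, int] = {("h1", "p1"): 3}
        if counts_h2[k] > 0:
            counts[("h2", "p1")] = counts_h2[k]
        networks.append(WeightedNetwork(f"s{k + 1}", counts))
    return NetworkGroup(group_id="toy", registry=registry, networks=networks)
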