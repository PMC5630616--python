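"""Interaction preferences: deviations of counts from mass action.

A weighted network decomposes as ``B_ijk ∝ γ_ij · x̂_i · x̂_j``: the preference
γ_ij is the multiplicative deviation of link (i, j) from the random-encounter
expectation given the effective abundances.  γ = 1 is consistent with mass
action, γ > 1 a preferred interaction, γ < 1 a less-preferred one, and γ = 0 a
forbidden interaction (e.g. host immunity).  One preference matrix is assumed
valid across all field sites of a group.

For multi-site data the per-link count level is summarised by B̄_ij, the mean
count over the sites where the link is present, and normalised by
κ = Σ B̄_ij / Σ x̂_i x̂_j (sums over positive links) so that data exactly
proportional to abundance products give γ ≡ 1.

This module also provides a multinomial bootstrap for per-link confidence
intervals, a comparison of preference matrices between two groups (incumbent
links vs switches, significance by interval overlap), and a neighbour-
preference correlation diagnostic: in structurally simple (open) habitats a
link with high preference tends to sit among low-preference neighbours,
showing up as a negative correlation between a link's γ and the mean γ of the
links sharing its host or parasitoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import spearmanr

from .abundance import EffectiveAbundances, _solve, _system
from .network_core import (
    Link,
    NetworkGroup,
    ValidationError,
    aggregate_counts,
    support_mask,
)

__all__ = [
    "PreferenceMatrix",
    "derive_preferences",
    "BootstrapIntervals",
    "bootstrap_preferences",
    "PreferenceChangeReport",
    "compare_preferences",
    "NeighborCorrelation",
    "neighbor_preference_correlation",
]


@dataclass
class PreferenceMatrix:
    """Preferences γ_ij on a group's link set.

    ``entries`` holds γ for every recorded link; γ = 0 exactly for links
    recorded only as explicit forbidden markers.  ``normalisation_kappa`` is
    the constant relating mean counts to abundance products.
    """

    entries: dict[Link, float]
    normalisation_kappa: float
    source_group: str
    abundances_used: EffectiveAbundances

    def __post_init__(self) -> None:
        for link, g in self.entries.items():
            if g < 0:
                raise ValidationError(f"negative preference {g} for link {link}")
        if self.normalisation_kappa <= 0:
            raise ValidationError("normalisation constant must be positive")

    def positive_links(self) -> set[Link]:
        return {l for l, g in self.entries.items() if g > 0}

    def get(self, link: Link) -> Optional[float]:
        return self.entries.get(link)


def _mean_positive_counts(group: NetworkGroup) -> dict[Link, float]:
    """B̄_ij: mean count over the sites where link (i, j) is positive."""
    totals: dict[Link, int] = {}
    n_sites: dict[Link, int] = {}
    for net in group.networks:
        for link, c in net.counts.items():
            if c > 0:
                totals[link] = totals.get(link, 0) + c
                n_sites[link] = n_sites.get(link, 0) + 1
    return {l: totals[l] / n_sites[l] for l in totals}


def derive_preferences(
    group: NetworkGroup, abund: EffectiveAbundances
) -> PreferenceMatrix:
    """γ_ij = B̄_ij / (κ · x̂_i · x̂_j) on the group's links.

    Links recorded only as zero markers are kept as forbidden (γ = 0).  By
    construction Σ γ_ij x̂_i x̂_j = Σ x̂_i x̂_j over positive links, and data
    exactly proportional to the abundance products yield γ ≡ 1.
    """
    bbar = _mean_positive_counts(group)
    if not bbar:
        raise ValidationError("group has no positive counts")
    for (h, p) in bbar:
        if h not in abund.host_abundance:
            raise ValidationError(f"no abundance for host {h!r}")
        if p not in abund.parasitoid_abundance:
            raise ValidationError(f"no abundance for parasitoid {p!r}")
    products = {l: abund.product(*l) for l in bbar}
    kappa = sum(bbar.values()) / sum(products.values())
    entries = {l: bbar[l] / (kappa * products[l]) for l in sorted(bbar)}
    for link, s in aggregate_counts(group).items():
        if s == 0:
            entries[link] = 0.0  # explicit forbidden marker
    return PreferenceMatrix(
        entries=entries,
        normalisation_kappa=kappa,
        source_group=group.group_id,
        abundances_used=abund,
    )


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

@dataclass
class BootstrapIntervals:
    """2.5/97.5 percentile intervals for each link's γ."""

    intervals: dict[Link, tuple[float, float]]
    n_boot: int
    seed: int

    def get(self, link: Link) -> Optional[tuple[float, float]]:
        return self.intervals.get(link)


def _resample_group(group: NetworkGroup, rng: np.random.Generator) -> NetworkGroup:
    from .network_core import WeightedNetwork

    networks = []
    for net in group.networks:
        links = sorted(net.positive_links())
        total = sum(net.counts[l] for l in links)
        if total == 0:
            continue  # empty site contributes nothing to the resample
        props = np.array([net.counts[l] for l in links], dtype=float) / total
        draw = rng.multinomial(total, props)
        counts = {l: int(c) for l, c in zip(links, draw) if c > 0}
        if counts:
            networks.append(WeightedNetwork(net.site_id, counts))
    return NetworkGroup(
        group_id=group.group_id,
        registry=group.registry,
        networks=networks,
        habitat_complexity=group.habitat_complexity,
        consumer_resource_label=group.consumer_resource_label,
        totals_for_ratio=group.totals_for_ratio,
    )


def bootstrap_preferences(
    group: NetworkGroup,
    abund: EffectiveAbundances,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapIntervals:
    """Percentile intervals for γ by per-site multinomial resampling.

    Each replicate resamples every site's counts from a multinomial with the
    site's total and empirical cell proportions, refits abundances with the
    exponents fixed at (α̂, β̂), and rederives preferences.  Links absent from
    a replicate contribute no sample to their interval.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    samples: dict[Link, list[float]] = {l: [] for l in sorted(support_mask(group).links)}
    for _ in range(n_boot):
        g = _resample_group(group, rng)
        if not g.networks:
            continue
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # dropped-species warnings per replicate
            a, b, hosts, pars, *_ = _system(g)
            sol, _resid = _solve(a, b, abund.alpha_hat, abund.beta_hat, len(hosts))
            ab = EffectiveAbundances(
                host_abundance={h: float(np.exp(sol[i])) for i, h in enumerate(hosts)},
                parasitoid_abundance={
                    p: float(np.exp(sol[len(hosts) + i])) for i, p in enumerate(pars)
                },
                alpha_hat=abund.alpha_hat,
                beta_hat=abund.beta_hat,
                loglik=0.0,
                residual_norm=0.0,
                connected=True,
            )
            pm = derive_preferences(g, ab)
        for link, gamma in pm.entries.items():
            if gamma > 0 and link in samples:
                samples[link].append(gamma)
    intervals = {
        l: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for l, v in samples.items()
        if v
    }
    return BootstrapIntervals(intervals=intervals, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# cross-group comparison
# ---------------------------------------------------------------------------

@dataclass
class LinkChange:
    link: Link
    gamma_a: Optional[float]
    gamma_b: Optional[float]
    ci_a: Optional[tuple[float, float]]
    ci_b: Optional[tuple[float, float]]
    status: str  # "incumbent" | "switch"
    significant: bool
    direction: str  # "increase" | "decrease" | "none"


@dataclass
class PreferenceChangeReport:
    records: list[LinkChange]
    fraction_significant_incumbent: Optional[float]
    fraction_significant_switch: Optional[float]
    n_incumbent: int
    n_switch: int
    n_increase: int
    n_decrease: int


def _disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def compare_preferences(
    pm_a: PreferenceMatrix,
    pm_b: PreferenceMatrix,
    ci_a: BootstrapIntervals,
    ci_b: BootstrapIntervals,
) -> PreferenceChangeReport:
    """Classify links as incumbents or switches and flag significant changes.

    Incumbents (positive in both groups) change significantly when their
    bootstrap intervals are disjoint; a switch (positive in exactly one
    group) is significant when its interval excludes the mass-action value 1.
    Direction compares point estimates (incumbents) or γ against 1 (switches).
    """
    links_a, links_b = pm_a.positive_links(), pm_b.positive_links()
    shared_species = (
        {h for h, _ in pm_a.entries} & {h for h, _ in pm_b.entries}
        | {p for _, p in pm_a.entries} & {p for _, p in pm_b.entries}
    )
    if not shared_species:
        raise ValidationError("preference matrices share no species")
    records: list[LinkChange] = []
    n_sig_inc = n_sig_sw = n_up = n_down = 0
    for link in sorted(links_a | links_b):
        ga, gb = pm_a.get(link), pm_b.get(link)
        ia, ib = ci_a.get(link), ci_b.get(link)
        if link in links_a and link in links_b:
            status = "incumbent"
            significant = ia is not None and ib is not None and _disjoint(ia, ib)
            if significant:
                n_sig_inc += 1
                direction = "increase" if gb > ga else "decrease"
                if direction == "increase":
                    n_up += 1
                else:
                    n_down += 1
            else:
                direction = "none"
        else:
            status = "switch"
            ci = ib if link in links_b else ia
            g = gb if link in links_b else ga
            significant = ci is not None and (ci[1] < 1.0 or ci[0] > 1.0)
            if significant:
                n_sig_sw += 1
                direction = "increase" if g > 1.0 else "decrease"
            else:
                direction = "none"
        records.append(
            LinkChange(link, ga, gb, ia, ib, status, significant, direction)
        )
    n_inc = sum(1 for r in records if r.status == "incumbent")
    n_sw = len(records) - n_inc
    return PreferenceChangeReport(
        records=records,
        fraction_significant_incumbent=(n_sig_inc / n_inc) if n_inc else None,
        fraction_significant_switch=(n_sig_sw / n_sw) if n_sw else None,
        n_incumbent=n_inc,
        n_switch=n_sw,
        n_increase=n_up,
        n_decrease=n_down,
    )


# ---------------------------------------------------------------------------
# neighbour-preference diagnostic
# ---------------------------------------------------------------------------

@dataclass
class NeighborCorrelation:
    rho: Optional[float]
    p_value: Optional[float]
    undefined: bool
    n_links: int


def neighbor_preference_correlation(
    pm: PreferenceMatrix, n_perm: int = 999, seed: int = 0
) -> NeighborCorrelation:
    """Spearman correlation between each link's γ and its neighbours' mean γ.

    The neighbours of link (i, j) are the other positive links sharing host i
    or parasitoid j.  Significance is a two-sided permutation test shuffling
    γ values across links.  With no variance in either vector the statistic
    is undefined and flagged as such (never coerced to zero).
    """
    links = sorted(pm.positive_links())
    neighbor_sets = []
    kept_links = []
    for l in links:
        nb = [m for m in links if m != l and (m[0] == l[0] or m[1] == l[1])]
        if nb:
            kept_links.append(l)
            neighbor_sets.append(nb)
    if len(kept_links) < 3:
        raise ValidationError("need at least 3 links with at least 1 neighbour")
    gamma = {l: pm.entries[l] for l in links}

    def _stat(values: Mapping[Link, float]) -> float:
        x = np.array([values[l] for l in kept_links])
        y = np.array(
            [np.mean([values[m] for m in nb]) for nb in neighbor_sets]
        )
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return np.nan
        return spearmanr(x, y).statistic

    rho = _stat(gamma)
    if np.isnan(rho):
        return NeighborCorrelation(None, None, True, len(kept_links))
    rng = np.random.default_rng(seed)
    vals = np.array([gamma[l] for l in links])
    n_extreme = 0
    n_valid = 0
    for _ in range(n_perm):
        perm = {l: v for l, v in zip(links, rng.permutation(vals))}
        r = _stat(perm)
        if np.isnan(r):
            continue
        n_valid += 1
        if abs(r) >= abs(rho) - 1e-12:
            n_extreme += 1
    p = (1 + n_extreme) / (1 + n_valid) if n_valid else 1.0
    return NeighborCorrelation(float(rho), float(p), False, len(kept_links))
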