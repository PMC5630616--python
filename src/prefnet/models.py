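"""Seven models predicting weighted network structure at new field sites.

Every model produces a probability vector ``p_ijk`` over an evaluation
support (the positive-count cells of the test group), ordered here from least
to most data-hungry:

1. **null** — all supported interactions equally likely.
2. **aggregate counts** — p proportional to calibration-group link sums,
   with no abundance/preference separation.
3. **random encounter** — p ∝ x̂′_i·x̂′_j from test-group effective
   abundances (pure mass action).
4. **alternative preferences** — p ∝ γ^cal_ij·x̂′_i·x̂′_j: the calibration
   preference matrix carried over unchanged (for similar habitat types).
5. **correlated preferences** — per-parasitoid columns of γ^cal reordered to
   the preference rank order observed in the test habitat, raised to a fitted
   exponent δ (systematic, community-wide preference change).
6. **specified preferences** — a small set of influential links hardcoded to
   their test-derived preferences on top of the calibration (or correlated)
   matrix.
7. **complete characterisation** — every preference taken from the test
   group; the best attainable fit within the decomposition and the R = 1
   anchor of group-level performance.

Links present in the test support but absent from the calibration matrix are
*switches*; they either follow mass action (γ = 1) or are treated as
inherently less preferred, γ = 1 − 2^(−1/(x̂^cal_i·x̂^cal_j)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .evaluate import multinomial_loglik
from .network_core import Cell, Link, NetworkGroup, SupportMask, ValidationError
from .abundance import EffectiveAbundances
from .preference import PreferenceMatrix

__all__ = [
    "MODEL_LABELS",
    "SWITCH_RULES",
    "PredictedProbabilities",
    "null_model",
    "aggregate_counts_model",
    "random_encounter_model",
    "switch_preference",
    "alternative_preferences_model",
    "correlated_preferences_model",
    "InfluentialSelection",
    "influential_interactions",
    "abundant_pairs_rule",
    "specified_preferences_model",
    "complete_characterisation_model",
    "predicted_counts",
]

MODEL_LABELS = (
    "null",
    "aggregate_counts",
    "random_encounter",
    "alternative_preferences",
    "correlated_preferences",
    "specified_preferences",
    "complete_characterisation",
)

SWITCH_RULES = ("mass_action", "less_preferred")

#: pseudo-mass factor for test links unseen in calibration (aggregate model)
AGGREGATE_PSEUDO_MASS_FACTOR = 1e-3

#: δ grid for the correlated preferences model: (0, 3] in steps of 0.05
DELTA_GRID = tuple(round(0.05 * i, 10) for i in range(1, 61))


@dataclass
class PredictedProbabilities:
    """A model's probability vector on a stated support; sums to 1."""

    model_label: str
    support: SupportMask
    probs: dict[Cell, float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.probs) != self.support.cells:
            raise ValidationError("probabilities do not cover the support")
        if any(p <= 0 for p in self.probs.values()):
            raise ValidationError("all probabilities must be strictly positive")
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"probabilities sum to {total!r}, not 1")


def _from_weights(
    label: str, support: SupportMask, weights: Mapping[Cell, float], params: dict
) -> PredictedProbabilities:
    total = sum(weights[c] for c in support.cells)
    if total <= 0:
        raise ValidationError("model weights sum to zero")
    probs = {c: weights[c] / total for c in support.sorted_cells()}
    # renormalise once more to absorb float round-off below the 1e-12 gate
    s = sum(probs.values())
    probs = {c: p / s for c, p in probs.items()}
    return PredictedProbabilities(label, support, probs, params)


# ---------------------------------------------------------------------------
# reference models
# ---------------------------------------------------------------------------

def null_model(support: SupportMask) -> PredictedProbabilities:
    """Uniform probabilities: p_ijk = 1 / Σ a_ijk."""
    w = {c: 1.0 for c in support.cells}
    return _from_weights("null", support, w, {})


def aggregate_counts_model(
    cal_group: NetworkGroup, support: SupportMask
) -> PredictedProbabilities:
    """p proportional to the calibration link sums Σ_k B^cal_ijk.

    Test links never seen in calibration receive a small pseudo-mass (1e-3 ×
    the smallest positive calibration link sum) so the model stays evaluable;
    with zero mass a single unseen link would force the whole likelihood to
    −∞.
    """
    from .network_core import aggregate_counts

    sums = {l: s for l, s in aggregate_counts(cal_group).items() if s > 0}
    if not sums:
        raise ValidationError("calibration group has no positive counts")
    if not (support.links & set(sums)):
        raise ValidationError("no test link appears in the calibration group")
    pseudo = min(sums.values()) * AGGREGATE_PSEUDO_MASS_FACTOR
    w = {c: float(sums.get((c[0], c[1]), pseudo)) for c in support.cells}
    return _from_weights(
        "aggregate_counts", support, w, {"pseudo_mass": pseudo}
    )


def random_encounter_model(
    abund_test: EffectiveAbundances, support: SupportMask
) -> PredictedProbabilities:
    """Mass action: p ∝ x̂′_i·x̂′_j (no k-dependence of cell weights)."""
    w = {}
    for c in support.cells:
        h, p, _k = c
        if not abund_test.has_link(h, p):
            raise ValidationError(f"missing test abundance for link ({h}, {p})")
        w[c] = abund_test.product(h, p)
    return _from_weights("random_encounter", support, w, {})


# ---------------------------------------------------------------------------
# preference-based models
# ---------------------------------------------------------------------------

def switch_preference(
    x_cal_i: Optional[float], x_cal_j: Optional[float], rule: str
) -> float:
    """Preference assigned to a switch (a link unseen in calibration).

    ``mass_action`` → 1; ``less_preferred`` → 1 − 2^(−1/(x̂^cal_i·x̂^cal_j)),
    which falls towards 0 for abundant calibration species (had the link been
    viable it would likely have been seen).  A species absent from the
    calibration group has no calibration abundance and falls back to mass
    action.
    """
    if rule not in SWITCH_RULES:
        raise ValueError(f"unknown switch rule {rule!r}")
    if rule == "mass_action":
        return 1.0
    if x_cal_i is None or x_cal_j is None:
        return 1.0
    if x_cal_i <= 0 or x_cal_j <= 0:
        raise ValidationError("calibration abundances must be positive")
    return 1.0 - 2.0 ** (-1.0 / (x_cal_i * x_cal_j))


def _gamma_with_switches(
    pm_cal: PreferenceMatrix, links: set[Link], rule: str
) -> dict[Link, float]:
    """γ^cal extended over ``links``: calibration values where positive,
    switch values elsewhere."""
    cal_ab = pm_cal.abundances_used
    out: dict[Link, float] = {}
    for link in sorted(links):
        g = pm_cal.get(link)
        if g is not None and g > 0:
            out[link] = g
        else:
            h, p = link
            xi = cal_ab.host_abundance.get(h)
            xj = cal_ab.parasitoid_abundance.get(p)
            out[link] = switch_preference(xi, xj, rule)
    return out


def _preference_weights(
    gamma: Mapping[Link, float],
    abund: EffectiveAbundances,
    support: SupportMask,
) -> dict[Cell, float]:
    w = {}
    for c in support.cells:
        h, p, _k = c
        if not abund.has_link(h, p):
            raise ValidationError(f"missing test abundance for link ({h}, {p})")
        w[c] = gamma[(h, p)] * abund.product(h, p)
    return w


def alternative_preferences_model(
    pm_cal: PreferenceMatrix,
    abund_test: EffectiveAbundances,
    rule: str,
    support: SupportMask,
) -> PredictedProbabilities:
    """p ∝ γ^cal_ij·x̂′_i·x̂′_j, with switches handled by ``rule``."""
    gamma = _gamma_with_switches(pm_cal, support.links, rule)
    w = _preference_weights(gamma, abund_test, support)
    return _from_weights(
        "alternative_preferences", support, w, {"switch_rule": rule, "gamma": gamma}
    )


def _reorder_columns(
    gamma_alt: Mapping[Link, float],
    rank_source: PreferenceMatrix,
    support: SupportMask,
) -> dict[Link, float]:
    """Reorder each parasitoid column of γ^alt to the rank order of the
    rank-source preferences (highest value to highest-ranked host)."""
    out: dict[Link, float] = {}
    for par in support.parasitoids:
        hosts = support.hosts_of_column(par)
        for h in hosts:
            if rank_source.get((h, par)) is None:
                raise ValidationError(
                    f"rank source has no entry for link ({h}, {par})"
                )
        # hosts by descending rank-source preference, ties by identifier
        ranked_hosts = sorted(
            hosts, key=lambda h: (-rank_source.entries[(h, par)], h)
        )
        values = sorted((gamma_alt[(h, par)] for h in hosts), reverse=True)
        for h, v in zip(ranked_hosts, values):
            out[(h, par)] = v
    return out


def _fit_delta(
    gamma: Mapping[Link, float],
    abund: EffectiveAbundances,
    support: SupportMask,
    eval_counts: Mapping[Cell, int],
    grid: Sequence[float] = DELTA_GRID,
) -> float:
    best_delta, best_ll = None, None
    for delta in grid:
        w = {
            c: gamma[(c[0], c[1])] ** delta * abund.product(c[0], c[1])
            for c in support.cells
        }
        total = sum(w.values())
        p = {c: v / total for c, v in w.items()}
        ll = multinomial_loglik(eval_counts, p)
        if best_ll is None or ll > best_ll:
            best_delta, best_ll = delta, ll
    return best_delta


def correlated_preferences_model(
    pm_cal: PreferenceMatrix,
    rank_source: PreferenceMatrix,
    abund_test: EffectiveAbundances,
    delta: Union[float, str],
    support: SupportMask,
    eval_counts: Optional[Mapping[Cell, int]] = None,
    rule: str = "mass_action",
) -> PredictedProbabilities:
    """Column-rank reordering of γ^cal with an exponent δ.

    Within each parasitoid column the calibration preferences (switches
    filled first) keep their multiset of values but are re-assigned to hosts
    in the descending preference rank order of ``rank_source`` — the
    systematic pattern identified with the novel habitat.  p ∝
    (γ^corr)^δ·x̂′_i·x̂′_j; ``delta="fit"`` selects δ̂ on a (0, 3] grid by
    maximum likelihood of ``eval_counts`` (ties to the smallest δ).
    """
    gamma_alt = _gamma_with_switches(pm_cal, support.links, rule)
    gamma_corr = _reorder_columns(gamma_alt, rank_source, support)
    if delta == "fit":
        if eval_counts is None:
            raise ValueError("delta='fit' requires eval_counts")
        delta_val = _fit_delta(gamma_corr, abund_test, support, eval_counts)
    else:
        delta_val = float(delta)
    w = {
        c: gamma_corr[(c[0], c[1])] ** delta_val * abund_test.product(c[0], c[1])
        for c in support.cells
    }
    return _from_weights(
        "correlated_preferences",
        support,
        w,
        {"delta": delta_val, "switch_rule": rule, "gamma_corr": gamma_corr},
    )


# ---------------------------------------------------------------------------
# influential-interaction selection and hardcoding
# ---------------------------------------------------------------------------

@dataclass
class InfluentialSelection:
    ranked: list[tuple[Link, float]]  # (link, loglik contribution), descending
    selected: list[Link]
    gap_index: Optional[int]


def influential_interactions(
    test_group: NetworkGroup,
    pm_test: PreferenceMatrix,
    abund_test: EffectiveAbundances,
    cap_fraction: float = 0.5,
    top_n: Optional[int] = None,
) -> InfluentialSelection:
    """Rank links by their solo contribution to the test log-likelihood.

    For each link the likelihood of the test counts is computed with all
    preferences set to 1 except the focal link, which keeps its test-derived
    γ′.  Links are sorted by this contribution and the selection is every
    link above the single largest gap in the sorted sequence, capped at
    ``cap_fraction`` of the links (an "obvious discontinuity" made
    deterministic).  ``top_n`` overrides the gap rule.
    """
    from .network_core import support_mask as _support_mask

    support = _support_mask(test_group)
    links = sorted(support.links)
    if len(links) < 2:
        raise ValidationError("need at least 2 links to rank contributions")
    counts = test_group.counts_on(support.sorted_cells())
    scores: list[tuple[Link, float]] = []
    for focal in links:
        g = pm_test.get(focal)
        if g is None:
            raise ValidationError(f"test preference matrix lacks link {focal}")
        gamma = {l: 1.0 for l in links}
        gamma[focal] = g
        w = {
            c: gamma[(c[0], c[1])] * abund_test.product(c[0], c[1])
            for c in support.cells
        }
        total = sum(w.values())
        p = {c: v / total for c, v in w.items()}
        scores.append((focal, multinomial_loglik(counts, p)))
    # descending by contribution, ties by link identifier
    ranked = sorted(scores, key=lambda t: (-t[1], t[0]))
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        return InfluentialSelection(ranked, [l for l, _ in ranked[:top_n]], None)
    values = [v for _, v in ranked]
    gaps = [values[i] - values[i + 1] for i in range(len(values) - 1)]
    max_gap = max(gaps)
    if max_gap <= 0:
        return InfluentialSelection(ranked, [], None)
    gap_index = gaps.index(max_gap)  # first occurrence of the largest gap
    n_sel = min(gap_index + 1, int(cap_fraction * len(links)))
    return InfluentialSelection(ranked, [l for l, _ in ranked[:n_sel]], gap_index)


def abundant_pairs_rule(
    abund_test: EffectiveAbundances, support: SupportMask, n: int
) -> list[Link]:
    """Top-n support links by abundance product x̂′_i·x̂′_j.

    The rule of thumb when influential interactions are unknown in advance:
    target interactions between the more abundant species.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    links = sorted(support.links)
    if n > len(links):
        warnings.warn(
            f"n={n} exceeds the {len(links)} support links; selecting all",
            stacklevel=2,
        )
        n = len(links)
    ranked = sorted(links, key=lambda l: (-abund_test.product(*l), l))
    return ranked[:n]


def specified_preferences_model(
    pm_cal: PreferenceMatrix,
    pm_test: PreferenceMatrix,
    abund_test: EffectiveAbundances,
    selected_links: Sequence[Link],
    rule: str,
    support: SupportMask,
    base: str = "cal",
    rank_source: Optional[PreferenceMatrix] = None,
    delta: Union[float, str] = 1.0,
    eval_counts: Optional[Mapping[Cell, int]] = None,
) -> PredictedProbabilities:
    """Hardcode test-derived preferences for the selected influential links.

    The base matrix is γ^cal with switches (``base="cal"``) or the
    rank-reordered (γ^corr)^δ (``base="corr"``, combining with the correlated
    model); selected entries are then overwritten with their γ′ values from
    the test habitat.
    """
    missing = [l for l in selected_links if pm_test.get(l) is None]
    if missing:
        raise ValidationError(f"selected links missing from test preferences: {missing}")
    if not set(selected_links) <= support.links:
        raise ValidationError("selected links must be support links")
    gamma_alt = _gamma_with_switches(pm_cal, support.links, rule)
    if base == "cal":
        gamma = dict(gamma_alt)
        delta_val = None
    elif base == "corr":
        rank_source = rank_source or pm_test
        gamma_corr = _reorder_columns(gamma_alt, rank_source, support)
        if delta == "fit":
            if eval_counts is None:
                raise ValueError("delta='fit' requires eval_counts")
            delta_val = _fit_delta(gamma_corr, abund_test, support, eval_counts)
        else:
            delta_val = float(delta)
        gamma = {l: g ** delta_val for l, g in gamma_corr.items()}
    else:
        raise ValueError(f"unknown base {base!r}")
    for link in selected_links:
        gamma[link] = pm_test.entries[link]
    w = _preference_weights(gamma, abund_test, support)
    return _from_weights(
        "specified_preferences",
        support,
        w,
        {
            "switch_rule": rule,
            "base": base,
            "delta": delta_val,
            "hardcoded_links": sorted(selected_links),
            "gamma": gamma,
        },
    )


def complete_characterisation_model(
    pm_test: PreferenceMatrix,
    abund_test: EffectiveAbundances,
    support: SupportMask,
) -> PredictedProbabilities:
    """p ∝ γ′_ij·x̂′_i·x̂′_j: every preference from the test habitat.

    The best fit attainable within the decomposition; defines the R = 1
    anchor of group-level performance (not a perfect fit — one preference
    matrix still summarises several sites).
    """
    gamma: dict[Link, float] = {}
    for link in sorted(support.links):
        g = pm_test.get(link)
        if g is None:
            raise ValidationError(f"test preference matrix lacks link {link}")
        gamma[link] = g
    w = _preference_weights(gamma, abund_test, support)
    return _from_weights("complete_characterisation", support, w, {"gamma": gamma})


def predicted_counts(
    prediction: PredictedProbabilities, total_counts: int
) -> dict[Cell, float]:
    """Expected counts B*_ijk = p_ijk × total recorded events."""
    return {c: p * total_counts for c, p in prediction.probs.items()}
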