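"""Multinomial likelihood and model-performance measures.

Recorded counts on a support are modelled as one draw from a multinomial
distribution with the model's cell probabilities, so the log-likelihood of a
model is the multinomial log-pmf of the observed counts.  Two rescalings make
likelihoods comparable across sites and groups:

* site-level ``F_{M,k} = (L_null,k − L_{M,k}) / L_null,k`` — 1 if the model
  explains the site's count distribution completely, 0 if it does no better
  than the uniform null model, negative if worse;
* group-level ``R_M = (L_re − L_M) / (L_re − L_complete)`` — 1 if the model
  matches the complete-characterisation model, 0 if it matches the
  random-encounter model, negative if worse.

AIC/BIC are provided for formal model comparison, with a configurable
parameter-count table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.special import gammaln

from .network_core import Cell, NetworkGroup, support_mask

__all__ = [
    "multinomial_loglik",
    "site_performance",
    "group_performance",
    "information_criteria",
    "default_n_params",
    "SiteScore",
    "EvaluationReport",
    "evaluate_prediction",
]


def multinomial_loglik(
    counts: Mapping[Cell, int] | Mapping[tuple, int],
    probs: Mapping[Cell, float] | Mapping[tuple, float],
) -> float:
    """Log of the multinomial pmf of ``counts`` under cell probabilities ``probs``.

    Factorial terms are computed with ``gammaln``.  A cell with probability 0
    but a positive count makes the outcome impossible; ``-inf`` is returned
    with a warning.  Both mappings must be defined on exactly the same support.
    """
    if set(counts) != set(probs):
        raise ValueError("counts and probs are defined on different supports")
    keys = sorted(counts)
    b = np.array([counts[k] for k in keys], dtype=float)
    p = np.array([probs[k] for k in keys], dtype=float)
    if np.any(b < 0) or np.any(b != np.floor(b)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
    impossible = (p == 0) & (b > 0)
    if np.any(impossible):
        warnings.warn(
            "positive count on zero-probability cell; log-likelihood is -inf",
            stacklevel=2,
        )
        return float("-inf")
    n = b.sum()
    ll = gammaln(n + 1.0) - gammaln(b + 1.0).sum()
    pos = b > 0
    ll += float(np.dot(b[pos], np.log(p[pos])))
    return float(ll)


def site_performance(loglik_null: float, loglik_model: float) -> Optional[float]:
    """Site-level performance ``F = (L_null − L_M)/L_null``.

    Returns ``None`` (flagged undefined) when ``L_null = 0``, which happens
    exactly when the site has a single support cell and any model is trivially
    perfect there.
    """
    if loglik_null == 0.0:
        return None
    if loglik_null > 0:
        raise ValueError("null log-likelihood must be <= 0")
    return (loglik_null - loglik_model) / loglik_null


def group_performance(
    loglik_re: float, loglik_complete: float, loglik_model: float
) -> Optional[float]:
    """Group-level performance ``R = (L_re − L_M)/(L_re − L_complete)``.

    Returns ``None`` when the random-encounter and complete-characterisation
    likelihoods coincide (preferences add nothing; the scale is degenerate).
    """
    denom = loglik_re - loglik_complete
    if denom == 0.0:
        return None
    return (loglik_re - loglik_model) / denom


def information_criteria(
    loglik: float, n_params: int, n_obs: int
) -> tuple[float, float]:
    """(AIC, BIC) for a model log-likelihood.

    ``n_obs`` is the total number of recorded interaction events in the
    evaluation unit (the multinomial total).
    """
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    aic = 2.0 * n_params - 2.0 * loglik
    bic = n_params * math.log(n_obs) - 2.0 * loglik
    return aic, bic


def default_n_params(
    model_label: str,
    n_hosts: int,
    n_parasitoids: int,
    n_links: int = 0,
    n_hardcoded: int = 0,
) -> int:
    """Default parameter counts for the seven models.

    Abundance-based models carry ``S_h + S_p − 2`` free relative-abundance
    parameters (one gauge constant per guild is not identifiable); the
    correlated model adds the exponent δ, the specified model one parameter
    per hardcoded link, the complete model one per link.
    """
    base = n_hosts + n_parasitoids - 2
    table = {
        "null": 0,
        "aggregate_counts": 0,
        "random_encounter": base,
        "alternative_preferences": base,
        "correlated_preferences": base + 1,
        "specified_preferences": base + n_hardcoded,
        "complete_characterisation": base + n_links,
    }
    try:
        return table[model_label]
    except KeyError:
        raise ValueError(f"unknown model label {model_label!r}") from None


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class SiteScore:
    loglik: float
    f: Optional[float]  # None when the site's null likelihood is 0
    n_cells: int


@dataclass
class EvaluationReport:
    model_label: str
    per_site: dict[str, SiteScore]
    group_loglik: float
    r_m: Optional[float]
    aic: Optional[float] = None
    bic: Optional[float] = None
    n_params: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "model": self.model_label,
            "group_loglik": self.group_loglik,
            "R": self.r_m,
            "aic": self.aic,
            "bic": self.bic,
            "n_params": self.n_params,
            "per_site": {
                k: {"loglik": s.loglik, "F": s.f, "n_cells": s.n_cells}
                for k, s in self.per_site.items()
            },
        }


def _renormalise(probs: Mapping[Cell, float], cells: list[Cell]) -> dict[Cell, float]:
    total = sum(probs[c] for c in cells)
    return {c: probs[c] / total for c in cells}


def group_loglik(prediction, group: NetworkGroup) -> float:
    """Multinomial log-likelihood of the whole group's counts under a prediction.

    All support cells across sites form one multinomial (multiple k-indices).
    """
    cells = prediction.support.sorted_cells()
    counts = group.counts_on(cells)
    return multinomial_loglik(counts, {c: prediction.probs[c] for c in cells})


def site_logliks(prediction, group: NetworkGroup) -> dict[str, float]:
    """Per-site log-likelihoods with probabilities renormalised per site."""
    out: dict[str, float] = {}
    for site in sorted(prediction.support.sites):
        cells = prediction.support.cells_at_site(site)
        p = _renormalise(prediction.probs, cells)
        counts = group.counts_on(cells)
        out[site] = multinomial_loglik(counts, p)
    return out


def evaluate_prediction(
    prediction,
    group: NetworkGroup,
    loglik_re: Optional[float] = None,
    loglik_complete: Optional[float] = None,
    n_params: Optional[int] = None,
) -> EvaluationReport:
    """Score one model prediction against a test group.

    Per-site F values use the uniform null model on each site's support;
    the group-level R requires the random-encounter and complete model
    log-likelihoods to be supplied.
    """
    l_group = group_loglik(prediction, group)
    per_site: dict[str, SiteScore] = {}
    for site, l_m in site_logliks(prediction, group).items():
        cells = prediction.support.cells_at_site(site)
        p_null = {c: 1.0 / len(cells) for c in cells}
        l_null = multinomial_loglik(group.counts_on(cells), p_null)
        per_site[site] = SiteScore(
            loglik=l_m, f=site_performance(l_null, l_m), n_cells=len(cells)
        )
    r_m = None
    if loglik_re is not None and loglik_complete is not None:
        r_m = group_performance(loglik_re, loglik_complete, l_group)
    aic = bic = None
    if n_params is not None:
        total = sum(
            group.counts_on(prediction.support.sorted_cells()).values()
        )
        aic, bic = information_criteria(l_group, n_params, int(total))
    return EvaluationReport(
        model_label=prediction.model_label,
        per_site=per_site,
        group_loglik=l_group,
        r_m=r_m,
        aic=aic,
        bic=bic,
        n_params=n_params,
    )
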