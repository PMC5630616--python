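"""Effective species abundances from interaction counts.

Under mass action (random encounter) the expected count between host *i* and
parasitoid *j* is proportional to the product of their abundances; a general
form allows guild-specific scaling exponents, ``B_ijk ∝ x_i^α x_j^β``.
Taking logarithms gives one linear equation per positive recorded count,

    α·ln(x_i) + β·ln(x_j) = ln(B_ijk),

an over-determined system whose minimum-Euclidean-norm least-squares solution
defines relative log-abundances for a fixed (α, β).  Each (α, β) pair on a
0.05-step grid over (0, 2]² is scored by the multinomial log-likelihood of the
group's counts with cell probabilities proportional to ``x_i·x_j`` (first
power: the exponents only shape how estimated abundance is distributed within
a guild).  The highest-likelihood pair gives the *effective abundances*
``x̂_i, x̂_j`` — functional quantities consistent with mass action, not census
abundances.

The abundances carry a gauge freedom (a constant can be moved between the two
guilds); the likelihood and all downstream probabilities are invariant to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

from .network_core import (
    Link,
    NetworkGroup,
    ValidationError,
    aggregate_counts,
    support_mask,
)

__all__ = [
    "ScalingGrid",
    "EffectiveAbundances",
    "solve_log_linear",
    "fit_effective_abundances",
    "aggregate_abundance_proxy",
]


def _grid_values(max_value: float, step: float) -> tuple[float, ...]:
    n = int(round(max_value / step))
    return tuple(round(i * step, 10) for i in range(1, n + 1))


@dataclass(frozen=True)
class ScalingGrid:
    """Candidate scaling exponents; defaults cover (0, 2] in steps of 0.05."""

    alpha_values: tuple[float, ...] = _grid_values(2.0, 0.05)
    beta_values: tuple[float, ...] = _grid_values(2.0, 0.05)

    def __post_init__(self) -> None:
        for name, vals in (("alpha", self.alpha_values), ("beta", self.beta_values)):
            if not vals:
                raise ValueError(f"{name}_values is empty")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name}_values must be positive")
            if list(vals) != sorted(vals):
                raise ValueError(f"{name}_values must be sorted ascending")


@dataclass
class EffectiveAbundances:
    """Per-guild effective abundances with the selected exponents.

    Abundances are defined only for species with at least one positive count
    in the fitted group.  ``connected`` is False when the bipartite link graph
    splits into components, in which case relative scales *between* components
    are arbitrary (probabilities within a single connected support remain
    well defined per component).
    """

    host_abundance: dict[str, float]
    parasitoid_abundance: dict[str, float]
    alpha_hat: float
    beta_hat: float
    loglik: float
    residual_norm: float
    connected: bool

    def product(self, host_id: str, parasitoid_id: str) -> float:
        return self.host_abundance[host_id] * self.parasitoid_abundance[parasitoid_id]

    def has_link(self, host_id: str, parasitoid_id: str) -> bool:
        return (
            host_id in self.host_abundance
            and parasitoid_id in self.parasitoid_abundance
        )


# ---------------------------------------------------------------------------
# the log-linear system
# ---------------------------------------------------------------------------

def _system(group: NetworkGroup):
    """Design matrix (unit coefficients), rhs, species orders, and cell index.

    One row per positive count B_ijk; columns are host then parasitoid
    log-abundances.  Scaling the host columns by α and the parasitoid columns
    by β yields the system for a given exponent pair.
    """
    cells = support_mask(group).sorted_cells()
    hosts = sorted({h for (h, _p, _k) in cells})
    pars = sorted({p for (_h, p, _k) in cells})
    dropped_h = [h for h in group.registry.hosts if h not in set(hosts)]
    dropped_p = [p for p in group.registry.parasitoids if p not in set(pars)]
    if dropped_h or dropped_p:
        warnings.warn(
            "species with no positive counts excluded from abundance fit: "
            f"{dropped_h + dropped_p}",
            stacklevel=3,
        )
    h_idx = {h: i for i, h in enumerate(hosts)}
    p_idx = {p: i for i, p in enumerate(pars)}
    counts = group.counts_on(cells)
    n_eq, n_unk = len(cells), len(hosts) + len(pars)
    a = np.zeros((n_eq, n_unk))
    b = np.empty(n_eq)
    row_h = np.empty(n_eq, dtype=int)
    row_p = np.empty(n_eq, dtype=int)
    for r, cell in enumerate(cells):
        h, p, _k = cell
        a[r, h_idx[h]] = 1.0
        a[r, len(hosts) + p_idx[p]] = 1.0
        b[r] = np.log(counts[cell])
        row_h[r] = h_idx[h]
        row_p[r] = p_idx[p]
    count_vec = np.array([counts[c] for c in cells], dtype=float)
    return a, b, hosts, pars, row_h, row_p, count_vec


def _solve(a: np.ndarray, b: np.ndarray, alpha: float, beta: float, n_hosts: int):
    scale = np.concatenate(
        [np.full(n_hosts, alpha), np.full(a.shape[1] - n_hosts, beta)]
    )
    sol, _res, _rank, _sv = np.linalg.lstsq(a * scale, b, rcond=None)
    resid = float(np.linalg.norm((a * scale) @ sol - b))
    return sol, resid


def solve_log_linear(
    group: NetworkGroup, alpha: float, beta: float
) -> tuple[dict[str, float], dict[str, float], float]:
    """Minimum-norm least-squares log-abundances for fixed exponents.

    Returns ``(host log-abundances u_i, parasitoid log-abundances v_j,
    residual norm)`` with ``u_i = ln(x_i)``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    a, b, hosts, pars, *_ = _system(group)
    sol, resid = _solve(a, b, alpha, beta, len(hosts))
    u = {h: float(sol[i]) for i, h in enumerate(hosts)}
    v = {p: float(sol[len(hosts) + i]) for i, p in enumerate(pars)}
    return u, v, resid


def _mass_action_loglik(
    logw: np.ndarray, count_vec: np.ndarray, loglik_const: float
) -> float:
    logp = logw - logsumexp(logw)
    return float(loglik_const + np.dot(count_vec, logp))


def _is_connected(group: NetworkGroup) -> bool:
    g = nx.Graph()
    for (h, p), s in aggregate_counts(group).items():
        if s > 0:
            g.add_edge(("H", h), ("P", p))
    return nx.is_connected(g) if g.number_of_nodes() > 0 else True


def fit_effective_abundances(
    group: NetworkGroup, grid: Optional[ScalingGrid] = None
) -> EffectiveAbundances:
    """Grid search over (α, β); the maximum-likelihood pair wins.

    Ties are broken by the lexicographically smallest (α, β).  The reported
    log-likelihood uses probabilities ∝ x̂_i·x̂_j over the group's own support.
    """
    grid = grid or ScalingGrid()
    a, b, hosts, pars, row_h, row_p, count_vec = _system(group)
    if len(count_vec) < 2:
        raise ValidationError("need at least 2 positive counts to fit abundances")
    n = count_vec.sum()
    loglik_const = float(gammaln(n + 1.0) - gammaln(count_vec + 1.0).sum())
    nh = len(hosts)
    best = None  # (loglik, alpha, beta, sol, resid)
    for alpha in grid.alpha_values:
        for beta in grid.beta_values:
            sol, resid = _solve(a, b, alpha, beta, nh)
            logw = sol[row_h] + sol[nh + row_p]
            ll = _mass_action_loglik(logw, count_vec, loglik_const)
            if best is None or ll > best[0]:
                best = (ll, alpha, beta, sol, resid)
    ll, alpha_hat, beta_hat, sol, resid = best
    return EffectiveAbundances(
        host_abundance={h: float(np.exp(sol[i])) for i, h in enumerate(hosts)},
        parasitoid_abundance={
            p: float(np.exp(sol[nh + i])) for i, p in enumerate(pars)
        },
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        loglik=ll,
        residual_norm=resid,
        connected=_is_connected(group),
    )


def aggregate_abundance_proxy(group: NetworkGroup) -> dict[str, float]:
    """Naive abundance proxy: per-species marginal count sums across sites.

    This is the estimator that aggregation across sites makes misleading —
    it underestimates spatially less-common species — and is provided for
    comparison and diagnostics only.  Keys are species identifiers from both
    guilds; an identifier used in both guilds accumulates both margins.
    """
    sums: dict[str, float] = {}
    for (h, p), s in aggregate_counts(group).items():
        sums[h] = sums.get(h, 0) + s
        sums[p] = sums.get(p, 0) + s
    return sums
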