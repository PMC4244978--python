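"""Path entropy and maximum-entropy steady states.

The path entropy of a traversal Γ of Z reactions from a state S is::

    S_g[Γ(S)] = - Σ_{i=1..Z} Pr(S_{i-1} + δS_i) log Pr(S_{i-1} + δS_i)

with Pr the normalized multinomial-Boltzmann probability of the state
produced by each reaction.  A steady state is thermodynamically optimal when
every reaction (in either direction) is equally likely from the steady
state; the optimizer therefore maximizes the entropy of the *normalized*
per-reaction likelihood distribution, which attains its maximum log Z
exactly on the equal-likelihood manifold.  Clamped boundary conditions
generally prevent the maximum from being reached exactly; the residual
reports how far the returned state is from equal likelihood.

The optimizer works on the continuous relaxation of the objective: log n! is
extended to log Γ(n+1), which is smooth in the species amounts, exact at
integers, and free of the Stirling error at small counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .network import NetworkError, ReactionNetwork
from .thermo import StateError, SystemState


class InfeasiblePathError(ValueError):
    """A traversal prefix would drive some count negative."""

    def __init__(self, position: int, species_id: str):
        self.position = position
        self.species_id = species_id
        super().__init__(
            f"traversal infeasible at position {position}: "
            f"count of {species_id!r} would become negative"
        )


@dataclass(frozen=True)
class PathwayOrder:
    """Ordered traversal of (reaction_id, direction) pairs."""

    steps: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for rid, d in self.steps:
            if d not in (1, -1):
                raise NetworkError(f"direction of {rid!r} must be +1 or -1")

    def __len__(self) -> int:
        return len(self.steps)


def cycle_order(net: ReactionNetwork, direction: int = 1) -> PathwayOrder:
    """All reactions once, in network order, in the given direction."""
    return PathwayOrder(tuple((rid, direction) for rid in net.reaction_ids))


def bidirectional_order(net: ReactionNetwork) -> PathwayOrder:
    """Each reaction in both directions — the equal-likelihood criterion set."""
    steps = []
    for rid in net.reaction_ids:
        steps.append((rid, 1))
        steps.append((rid, -1))
    return PathwayOrder(tuple(steps))


@dataclass(frozen=True)
class MaxEntResult:
    """Optimal continuous composition under the pool constraint."""

    optimal_counts: dict[str, float]
    path_entropy: float
    residual: float
    converged: bool
    n_starts: int


def _continuous_log_pr(
    m: np.ndarray,
    mu_dyn: np.ndarray,
    log_q: float,
    clamped_shift: float,
) -> float:
    """Log normalized multinomial-Boltzmann probability at real-valued counts.

    ``clamped_shift`` adds the boundary (clamped-species) potential change of
    the generating move, so that chemostat driving enters the likelihood.
    """
    n = float(m.sum())
    config = float(gammaln(n + 1) - gammaln(m + 1).sum())
    return config - float(m @ mu_dyn) - n * log_q - clamped_shift


def _term_log_probs_discrete(
    state: SystemState,
    order: PathwayOrder,
    net: ReactionNetwork,
    shared_base: bool,
) -> list[float]:
    """Per-step log Pr along a traversal from an integer state (chained by
    default; clamped counts are re-clamped between steps)."""
    state._check(net)
    mu_dyn = net.mu_hat[net.dynamic_mask]
    log_q = float(logsumexp(-mu_dyn))
    dyn_idx = np.flatnonzero(net.dynamic_mask)
    cl_idx = np.flatnonzero(~net.dynamic_mask)
    mu_cl = net.mu_hat[cl_idx]
    current = state.counts.astype(np.int64).copy()
    out = []
    for pos, (rid, d) in enumerate(order.steps, start=1):
        col = net.stoich[:, net.reaction_index(rid)]
        target = current + d * col
        if np.any(target < 0):
            bad = int(np.argmax(target < 0))
            raise InfeasiblePathError(pos, net.species_ids[bad])
        clamped_shift = float((d * col[cl_idx]) @ mu_cl)
        lp = _continuous_log_pr(
            target[dyn_idx].astype(float), mu_dyn, log_q, clamped_shift
        )
        out.append(lp)
        if not shared_base:
            current = target.copy()
            current[cl_idx] = net.clamp_counts[cl_idx]  # re-clamp
    return out


def path_entropy(
    state0: SystemState,
    order: PathwayOrder,
    net: ReactionNetwork,
    shared_base: bool = False,
) -> float:
    """−Σ p log p over the states generated by a traversal.

    By default successive terms chain through the updated (re-clamped)
    states; ``shared_base=True`` evaluates every reaction from ``state0``.
    """
    if len(order) == 0:
        return 0.0
    lps = _term_log_probs_discrete(state0, order, net, shared_base)
    return float(sum(-math.exp(lp) * lp for lp in lps))


def maxent_steady_state(
    net: ReactionNetwork,
    order: PathwayOrder | None = None,
    total_pool: float = 0.0,
    clamped: dict[str, int] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    tol: float = 1e-6,
) -> MaxEntResult:
    """Maximize the steady-state path entropy over dynamic-species amounts.

    The candidate steady state is a continuous composition ``n`` of the
    dynamic species summing to ``total_pool``; every reaction of ``order``
    (default: all reactions, both directions) is applied to the shared
    candidate state, yielding a likelihood per reaction.  The objective is
    the entropy of the normalized per-reaction likelihoods — maximal when
    each respective reaction is equally likely.  The optimum is diagnosed
    by the equal-likelihood residual (max deviation of the per-reaction log
    likelihoods from their mean); ``path_entropy`` reports the raw
    −Σ P log P of the optimal neighborhood.

    A deterministic multi-start local ascent (SLSQP, seeded Dirichlet
    starts) is used; the best start is reported, and non-convergence is
    reported through ``converged``, never silently.
    """
    if total_pool <= 0:
        raise StateError("total_pool must be positive")
    if order is None:
        order = bidirectional_order(net)
    dyn_idx = np.flatnonzero(net.dynamic_mask)
    m_dyn = len(dyn_idx)
    if m_dyn == 0:
        raise StateError("network has no dynamic species")
    cl_idx = np.flatnonzero(~net.dynamic_mask)
    mu_dyn = net.mu_hat[dyn_idx]
    mu_cl = net.mu_hat[cl_idx]
    log_q = float(logsumexp(-mu_dyn))
    clamp_override = dict(clamped or {})  # retained for interface symmetry

    deltas = []
    shifts = []
    for rid, d in order.steps:
        col = net.stoich[:, net.reaction_index(rid)]
        deltas.append(d * col[dyn_idx].astype(float))
        shifts.append(float((d * col[cl_idx]) @ mu_cl))
    deltas = np.array(deltas)
    shifts = np.array(shifts)

    def term_log_probs(n: np.ndarray) -> np.ndarray | None:
        m = n[None, :] + deltas
        if np.any(m < 0):
            return None
        tot = m.sum(axis=1)
        config = gammaln(tot + 1) - gammaln(m + 1).sum(axis=1)
        return config - m @ mu_dyn - tot * log_q - shifts

    def objective(n: np.ndarray) -> float:
        # Entropy of the normalized per-reaction likelihoods: maximal
        # (= log Z) exactly when every reaction is equally likely, which is
        # the optimality criterion the residual reports.
        lps = term_log_probs(n)
        if lps is None:
            worst = float(np.minimum(n[None, :] + deltas, 0.0).sum())
            return 1e6 * (1.0 - worst)
        lq = lps - logsumexp(lps)
        q = np.exp(lq)
        return float((q * lq).sum())  # minimize Σ q log q == maximize H

    # lower bounds keep every move applicable (counts stay non-negative)
    need = np.maximum(0.0, -deltas).max(axis=0)
    lb = np.minimum(need, total_pool / (2 * m_dyn))
    bounds = [(float(l), float(total_pool)) for l in lb]
    constraint = {"type": "eq", "fun": lambda n: n.sum() - total_pool}

    rng = np.random.default_rng(seed)
    starts = [np.full(m_dyn, total_pool / m_dyn)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.dirichlet(np.ones(m_dyn)) * total_pool)

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb, None)
        x0 *= total_pool / x0.sum()
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=[constraint],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    n_opt = np.clip(best.x, 0.0, None)
    n_opt *= total_pool / n_opt.sum()
    lps = term_log_probs(n_opt)
    if lps is None:
        residual = math.inf
        entropy = math.nan
    else:
        residual = float(np.max(np.abs(lps - lps.mean())))
        # raw path entropy -Σ P log P of the neighborhood at the optimum
        entropy = float(-(np.exp(lps) * lps).sum())
    converged = bool(residual <= tol or best.success)
    return MaxEntResult(
        optimal_counts={
            net.species_ids[i]: float(v) for i, v in zip(dyn_idx, n_opt)
        },
        path_entropy=entropy,
        residual=residual,
        converged=converged,
        n_starts=len(starts),
    )


def write_maxent_tsv(result: MaxEntResult, path) -> None:
    lines = ["species_id\toptimal_amount"]
    for sid, v in result.optimal_counts.items():
        lines.append(f"{sid}\t{v!r}")
    lines.append(
        f"# summary\tpath_entropy={result.path_entropy!r}"
        f"\tresidual={result.residual!r}\tconverged={int(result.converged)}"
    )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
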