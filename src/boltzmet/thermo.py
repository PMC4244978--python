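"""Multinomial-Boltzmann state weights, entropies and likelihood ratios.

The microscopic state of a reaction network is the vector of particle counts
``n_j``.  Its unnormalized log mass density (dimensionless, in units of
``k_B T``) is::

    -A/k_BT = log N! - Σ_j log n_j! + Σ_j n_j log q_j,   log q_j = -mu_hat_j

where the combinatorial (multinomial) part runs over the *dynamic* species and
``N`` is their total count.  Clamped species are chemostatted reservoirs: they
contribute chemical-potential terms only, which cancel between any two states
with equal clamped counts and surface as the boundary driving force when a
reaction is evaluated before re-clamping.

The decomposition ``-A/k_BT = S_config - E/k_BT`` (configurational entropy
minus reduced energy) is exact by construction and is the energy–entropy
compensation seen along pathway profiles.

Transition weights between states K and J are likelihood ratios::

    Pr(J)/Pr(K) = e^{-ΔS_g},  ΔS_g = -(log w(J) - log w(K))

which is the quantity the Markov simulator turns into move probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.special import gammaln, logsumexp

from .network import CLAMPED, NetworkError, ReactionNetwork, Species

NORMALIZED = "normalized"
ODDS = "odds"


class StateError(ValueError):
    """Raised for states inconsistent with the network they are used with."""


@dataclass
class SystemState:
    """Non-negative integer counts per species, aligned with a network.

    ``counts`` follows the species order of the network the state was built
    from.  Clamped species hold their ``clamp_count``.
    """

    species_ids: tuple[str, ...]
    counts: np.ndarray

    @classmethod
    def from_counts(
        cls, net: ReactionNetwork, counts: dict[str, int] | None = None
    ) -> "SystemState":
        """Build a state from a (possibly partial) species→count map.

        Unspecified dynamic species default to 0; clamped species always take
        their clamp_count (an explicit conflicting value is rejected).
        """
        counts = dict(counts or {})
        vec = np.zeros(len(net.species), dtype=np.int64)
        for i, sp in enumerate(net.species):
            if sp.role == CLAMPED:
                given = counts.pop(sp.id, sp.clamp_count)
                if given != sp.clamp_count:
                    raise StateError(
                        f"clamped species {sp.id!r}: count {given} != "
                        f"clamp_count {sp.clamp_count}"
                    )
                vec[i] = sp.clamp_count
            else:
                vec[i] = int(counts.pop(sp.id, 0))
        if counts:
            raise StateError(f"counts for unknown species: {sorted(counts)}")
        if np.any(vec < 0):
            raise StateError("negative count")
        return cls(species_ids=net.species_ids, counts=vec)

    def as_dict(self) -> dict[str, int]:
        return {sid: int(c) for sid, c in zip(self.species_ids, self.counts)}

    def n_total(self, net: ReactionNetwork) -> int:
        """Total count over dynamic species."""
        self._check(net)
        return int(self.counts[net.dynamic_mask].sum())

    def _check(self, net: ReactionNetwork) -> None:
        if self.species_ids != net.species_ids:
            raise StateError("state species do not match network species")
        if np.any(self.counts < 0):
            raise StateError("negative count")

    def copy(self) -> "SystemState":
        return SystemState(self.species_ids, self.counts.copy())


@dataclass(frozen=True)
class SpeciesDistribution:
    """Boltzmann probabilities θ_i over a species set and the log normalizer."""

    theta: dict[str, float]
    log_q_total: float


@dataclass(frozen=True)
class StateThermo:
    """Energy–entropy decomposition of one state's log mass density.

    ``neg_A_over_kBT = config_entropy - energy_term`` holds exactly.
    ``log_likelihood`` (the normalized log probability, = -S_g) is populated
    in normalized mode only.
    """

    neg_A_over_kBT: float
    energy_term: float
    config_entropy: float
    log_likelihood: float | None = None


@dataclass(frozen=True)
class EnsembleEntropy:
    """Gibbs entropy of the enumerated closed-system ensemble."""

    S_G: float
    mean_energy_B: float
    n_states: int


@dataclass(frozen=True)
class TransitionWeight:
    """Log-likelihood change ΔS_g for a state change K→J and its odds e^{-ΔS_g}."""

    delta_Sg: float
    odds: float


def boltzmann_theta(species: list[Species]) -> SpeciesDistribution:
    """Boltzmann probabilities θ_i = e^{-mu_hat_i} / Σ_j e^{-mu_hat_j}.

    Computed through log-sum-exp, so reduced potentials up to |mu_hat| ≈ 700
    do not overflow.
    """
    if not species:
        raise StateError("boltzmann_theta requires at least one species")
    mu = np.array([s.mu_hat for s in species])
    log_q = float(logsumexp(-mu))
    theta = np.exp(-mu - log_q)
    return SpeciesDistribution(
        theta={s.id: float(t) for s, t in zip(species, theta)}, log_q_total=log_q
    )


def _log_weight_parts(
    counts: np.ndarray, net: ReactionNetwork
) -> tuple[float, float]:
    """(config_entropy, energy_term) of a count vector.

    The multinomial coefficient runs over dynamic species; the energy term
    runs over all species (clamped reservoirs contribute n·mu_hat).
    """
    if np.any(counts < 0):
        raise StateError("negative count")
    dyn = counts[net.dynamic_mask]
    n_total = dyn.sum()
    config = float(gammaln(n_total + 1) - gammaln(dyn + 1).sum())
    energy = float(counts @ net.mu_hat)
    return config, energy


def log_state_weight(
    state: SystemState, net: ReactionNetwork, mode: str = ODDS
) -> StateThermo:
    """Log mass density of a state, decomposed into entropy and energy terms.

    In ``odds`` mode (the open-system default) the returned
    ``neg_A_over_kBT`` is the unnormalized log weight.  In ``normalized``
    mode ``log_likelihood`` additionally holds the log of the multinomial-
    Boltzmann probability of the dynamic sub-system (weights sum to one over
    all compositions of ``N_total``).
    """
    state._check(net)
    config, energy = _log_weight_parts(state.counts, net)
    neg_a = config - energy
    log_like: float | None = None
    if mode == NORMALIZED:
        mu_dyn = net.mu_hat[net.dynamic_mask]
        log_q = float(logsumexp(-mu_dyn))
        dyn = state.counts[net.dynamic_mask]
        energy_dyn = float(dyn @ mu_dyn)
        log_like = config - energy_dyn - float(dyn.sum()) * log_q
    elif mode != ODDS:
        raise StateError(f"unknown mode {mode!r}")
    return StateThermo(
        neg_A_over_kBT=neg_a,
        energy_term=energy,
        config_entropy=config,
        log_likelihood=log_like,
    )


def delta_Sg(
    stateK: SystemState,
    stateJ: SystemState,
    net: ReactionNetwork,
    mode: str = ODDS,
) -> TransitionWeight:
    """Likelihood ratio of a state change K→J: Pr(J)/Pr(K) = e^{-ΔS_g}.

    Normalized and odds modes agree whenever the move conserves the dynamic
    total (the normalizer cancels).
    """
    tK = log_state_weight(stateK, net, mode)
    tJ = log_state_weight(stateJ, net, mode)
    if mode == NORMALIZED:
        dlw = tJ.log_likelihood - tK.log_likelihood  # type: ignore[operator]
    else:
        dlw = tJ.neg_A_over_kBT - tK.neg_A_over_kBT
    return TransitionWeight(delta_Sg=-dlw, odds=math.exp(dlw))


# ---------------------------------------------------------------------------
# Closed-system enumeration
# ---------------------------------------------------------------------------

def n_compositions(n_total: int, m: int) -> int:
    """Number of ways to place n_total identical particles into m species."""
    return math.comb(n_total + m - 1, m - 1)


def _compositions(n_total: int, m: int) -> Iterator[tuple[int, ...]]:
    if m == 1:
        yield (n_total,)
        return
    for first in range(n_total + 1):
        for rest in _compositions(n_total - first, m - 1):
            yield (first, *rest)


def enumerate_states(
    net: ReactionNetwork, n_total: int, cap: int = 2_000_000
) -> list[SystemState]:
    """All states placing ``n_total`` particles among the dynamic species.

    Clamped species sit at their clamp counts.  Raises if the state space
    exceeds ``cap``.
    """
    dyn_idx = np.flatnonzero(net.dynamic_mask)
    m = len(dyn_idx)
    if m == 0:
        raise StateError("network has no dynamic species")
    size = n_compositions(n_total, m)
    if size > cap:
        raise StateError(f"state space has {size} states, exceeding cap {cap}")
    base = net.clamp_counts.copy()
    states = []
    for comp in _compositions(n_total, m):
        vec = base.copy()
        vec[dyn_idx] = comp
        states.append(SystemState(net.species_ids, vec))
    return states


def _enumerated_log_probs(
    states: list[SystemState], net: ReactionNetwork
) -> np.ndarray:
    logw = np.array(
        [log_state_weight(s, net).neg_A_over_kBT for s in states]
    )
    return logw - logsumexp(logw)


def gibbs_entropy(
    net: ReactionNetwork, n_total: int, cap: int = 2_000_000
) -> EnsembleEntropy:
    """Gibbs entropy S_G = -Σ_J Pr(J) log Pr(J) over the enumerated ensemble.

    ``mean_energy_B`` is the ensemble average of the dynamic-species reduced
    energy Σ n_j mu_hat_j.
    """
    states = enumerate_states(net, n_total, cap=cap)
    logp = _enumerated_log_probs(states, net)
    p = np.exp(logp)
    s_g = float(-(p * logp).sum())
    mu_dyn = net.mu_hat[net.dynamic_mask]
    energies = np.array(
        [float(s.counts[net.dynamic_mask] @ mu_dyn) for s in states]
    )
    return EnsembleEntropy(
        S_G=s_g, mean_energy_B=float(p @ energies), n_states=len(states)
    )


@dataclass(frozen=True)
class EquilibriumReport:
    """Exact enumeration averages of the equilibrium return identity."""

    mean_exp_negDeltaSg: float
    mean_deltaSg: float
    n_states: int


def equilibrium_identity_check(
    net: ReactionNetwork, n_total: int, cap: int = 200_000
) -> EquilibriumReport:
    """Verify, by exact enumeration, the equilibrium fluctuation identity.

    With a symmetric proposal kernel (uniform over the 2R directed reactions,
    infeasible proposals counting as identity transitions with ΔS_g = 0):

    * ``mean_exp_negDeltaSg`` — the equilibrium average of e^{-ΔS_g} over
      proposed transitions; equals 1 exactly.
    * ``mean_deltaSg`` — the average of ΔS_g over the *realized* transitions
      of the detailed-balanced Metropolis chain; equals 0 exactly, because
      the stationary pair measure Pr(K)P(J|K) is swap-symmetric.
    """
    states = enumerate_states(net, n_total, cap=cap)
    logp = _enumerated_log_probs(states, net)
    p = np.exp(logp)
    index = {tuple(s.counts[net.dynamic_mask]): i for i, s in enumerate(states)}
    dyn_idx = np.flatnonzero(net.dynamic_mask)
    n_rxn = len(net.reactions)
    n_prop = 2 * n_rxn

    mean_exp = 0.0
    mean_dsg = 0.0
    for k, state in enumerate(states):
        dyn = state.counts[dyn_idx]
        for j_rxn in range(n_rxn):
            for direction in (1, -1):
                delta = direction * net.stoich[dyn_idx, j_rxn]
                target = dyn + delta
                feasible = (
                    np.all(target >= 0)
                    and np.all(state.counts + direction * net.stoich[:, j_rxn] >= 0)
                )
                if not feasible or tuple(target) not in index:
                    # identity transition: ΔS_g = 0 contributes e^0 = 1
                    mean_exp += p[k] / n_prop
                    continue
                j = index[tuple(target)]
                dsg = -(logp[j] - logp[k])
                mean_exp += p[k] / n_prop * math.exp(-dsg)
                accept = min(1.0, math.exp(-dsg))
                mean_dsg += p[k] * accept / n_prop * dsg
    return EquilibriumReport(
        mean_exp_negDeltaSg=float(mean_exp),
        mean_deltaSg=float(mean_dsg),
        n_states=len(states),
    )


def write_state_thermo_tsv(
    rows: list[tuple[SystemState, StateThermo]],
    net: ReactionNetwork,
    path,
) -> None:
    """One row per (state, decomposition); kBT recorded in the header."""
    lines = [
        f"# kBT_kJ_per_mol: {net.context.kBT_kJ_per_mol!r}",
        "counts\tneg_A_over_kBT\tenergy_term\tconfig_entropy\tlog_likelihood",
    ]
    for state, th in rows:
        counts = ",".join(str(int(c)) for c in state.counts)
        ll = "" if th.log_likelihood is None else repr(th.log_likelihood)
        lines.append(
            f"{counts}\t{th.neg_A_over_kBT!r}\t{th.energy_term!r}"
            f"\t{th.config_entropy!r}\t{ll}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
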