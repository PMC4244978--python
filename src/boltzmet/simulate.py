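"""Seeded Markov-chain simulation of reaction-network states.

Chain time is the event count; there is no physical-time calibration, because
absolute rates would require the rate constants the method deliberately
avoids.  Two sampling modes are provided:

``metropolis``
    Propose uniformly among the 2R directed reactions, accept with
    min(1, e^{-ΔS_g}); infeasible proposals count as rejected
    self-transitions.  In a closed system this kernel satisfies detailed
    balance with respect to the multinomial-Boltzmann mass and is the mode
    used for equilibrium checks.

``odds``
    Select among the currently feasible directed reactions with probability
    proportional to their odds e^{-ΔS_g} (rates proportional to the
    thermodynamic driving force under a local-equilibrium assumption); the
    chain moves at every step.  This is the mode used for driven,
    non-equilibrium steady-state flux profiles.

After each accepted move the likelihood ratio has already been evaluated on
the raw post-move state; clamped species are then reset to their clamp
counts, which is what turns cofactor potential differences into a sustained
driving force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import CLAMPED, ReactionNetwork
from .thermo import ODDS, StateError, SystemState, TransitionWeight

METROPOLIS = "metropolis"

_RNG_ALGORITHM = "PCG64"


class DeadlockError(RuntimeError):
    """No feasible reaction event exists at the current state."""

    def __init__(self, step_index: int):
        self.step_index = step_index
        super().__init__(
            f"simulation deadlocked at step {step_index}: no feasible reaction event"
        )


@dataclass(frozen=True)
class DirectedEvent:
    """One proposed reaction firing (reaction, direction) at a chain step."""

    reaction_id: str
    direction: int
    step_index: int
    accepted: bool


@dataclass
class Trajectory:
    """Seeded event stream with per-reaction forward/reverse flux tallies.

    Events are stored compactly as parallel arrays; :meth:`event` builds a
    :class:`DirectedEvent` view.  ``dynamic_totals[i]`` is the total dynamic
    count after step i.
    """

    seed: int
    mode: str
    reaction_ids: tuple[str, ...]
    reaction_idx: np.ndarray
    direction: np.ndarray
    accepted: np.ndarray
    flux_plus: dict[str, int]
    flux_minus: dict[str, int]
    snapshots: dict[int, np.ndarray]
    snapshot_stride: int | None
    initial_counts: np.ndarray
    final_counts: np.ndarray
    dynamic_totals: np.ndarray = field(repr=False, default=None)

    @property
    def n_steps(self) -> int:
        return len(self.reaction_idx)

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    def event(self, i: int) -> DirectedEvent:
        return DirectedEvent(
            reaction_id=self.reaction_ids[int(self.reaction_idx[i])],
            direction=int(self.direction[i]),
            step_index=i,
            accepted=bool(self.accepted[i]),
        )

    def events(self):
        for i in range(self.n_steps):
            yield self.event(i)


class _Kernel:
    """Precomputed move set: per directed event, sparse deltas and weights."""

    def __init__(self, net: ReactionNetwork):
        self.net = net
        self.n_rxn = len(net.reactions)
        self.mu_hat = net.mu_hat
        self.dynamic = net.dynamic_mask
        # directed event e -> (reaction j, direction d)
        self.moves = []  # list of (j, d, entries, dN, requirements)
        for j in range(self.n_rxn):
            col = net.stoich[:, j]
            nz = np.flatnonzero(col)
            for d in (1, -1):
                entries = [(int(i), int(d * col[i]), bool(self.dynamic[i])) for i in nz]
                d_n = int(d * col[self.dynamic].sum())
                d_energy = float(d * (col @ self.mu_hat))
                requires = [(i, -dn) for i, dn, _ in entries if dn < 0]
                self.moves.append((j, d, entries, d_n, d_energy, requires))

    def feasible(self, counts: list[int], move_index: int) -> bool:
        for i, need in self.moves[move_index][5]:
            if counts[i] < need:
                return False
        return True

    def delta_logw(self, counts: list[int], n_dyn: int, move_index: int) -> float:
        """Δ log weight of applying a directed move (pre-re-clamp state)."""
        _, _, entries, d_n, d_energy, _ = self.moves[move_index]
        lg = math.lgamma
        d_config = 0.0
        if d_n:
            d_config += lg(n_dyn + d_n + 1) - lg(n_dyn + 1)
        for i, dn, is_dyn in entries:
            if is_dyn:
                d_config -= lg(counts[i] + dn + 1) - lg(counts[i] + 1)
        return d_config - d_energy


def feasible_events(
    state: SystemState, net: ReactionNetwork
) -> list[tuple[DirectedEvent, TransitionWeight]]:
    """Candidate directed reactions applicable at ``state``.

    One candidate per reaction per direction whose application leaves all
    counts non-negative (clamped consumption is checked against the clamp
    count), paired with the transition weight against the post-move,
    pre-re-clamp state.
    """
    state._check(net)
    kern = _Kernel(net)
    counts = [int(c) for c in state.counts]
    n_dyn = state.n_total(net)
    out = []
    for e, (j, d, *_rest) in enumerate(kern.moves):
        if not kern.feasible(counts, e):
            continue
        dlw = kern.delta_logw(counts, n_dyn, e)
        out.append(
            (
                DirectedEvent(
                    reaction_id=net.reactions[j].id,
                    direction=d,
                    step_index=0,
                    accepted=False,
                ),
                TransitionWeight(delta_Sg=-dlw, odds=math.exp(dlw)),
            )
        )
    return out


def step(
    state: SystemState,
    net: ReactionNetwork,
    rng: np.random.Generator,
    mode: str = METROPOLIS,
) -> tuple[SystemState, DirectedEvent]:
    """Advance one chain step; returns the successor state and the event."""
    traj = _run(net, state, 1, mode, rng=rng, snapshot_stride=None)
    new = SystemState(net.species_ids, traj.final_counts.copy())
    return new, traj.event(0)


def simulate(
    net: ReactionNetwork,
    state0: SystemState,
    steps: int,
    mode: str = ODDS,
    seed: int = 0,
    snapshot_stride: int | None = None,
) -> Trajectory:
    """Run a seeded Markov chain of ``steps`` single-reaction events.

    Snapshots (full count vectors) are recorded at step 0, every
    ``snapshot_stride`` steps, and at the final step.  Identical inputs and
    seed reproduce the trajectory exactly.
    """
    if steps < 0:
        raise StateError("steps must be >= 0")
    rng = np.random.default_rng(seed)
    return _run(net, state0, steps, mode, rng=rng, snapshot_stride=snapshot_stride, seed=seed)


def _run(
    net: ReactionNetwork,
    state0: SystemState,
    steps: int,
    mode: str,
    rng: np.random.Generator,
    snapshot_stride: int | None,
    seed: int = -1,
) -> Trajectory:
    if mode not in (METROPOLIS, ODDS):
        raise StateError(f"unknown simulation mode {mode!r}")
    state0._check(net)
    kern = _Kernel(net)
    counts = [int(c) for c in state0.counts]
    n_dyn = state0.n_total(net)
    n_moves = 2 * kern.n_rxn

    reaction_idx = np.empty(steps, dtype=np.int32)
    direction = np.empty(steps, dtype=np.int8)
    accepted = np.empty(steps, dtype=bool)
    dynamic_totals = np.empty(steps, dtype=np.int64)
    jp = [0] * kern.n_rxn
    jm = [0] * kern.n_rxn
    snapshots: dict[int, np.ndarray] = {0: np.array(counts, dtype=np.int64)}

    # clamped indices whose counts must be restored after a move
    exp, feasible, delta_logw = math.exp, kern.feasible, kern.delta_logw
    moves = kern.moves

    if mode == METROPOLIS:
        proposals = rng.integers(0, n_moves, size=steps)
        uniforms = rng.random(steps)
    else:
        uniforms = rng.random(steps)

    for t in range(steps):
        if mode == METROPOLIS:
            e = int(proposals[t])
            ok = feasible(counts, e)
            if not ok and not any(feasible(counts, k) for k in range(n_moves)):
                raise DeadlockError(t)
            acc = False
            if ok:
                dlw = delta_logw(counts, n_dyn, e)
                if dlw >= 0.0 or uniforms[t] < exp(dlw):
                    acc = True
        else:  # odds mode
            weights = []
            candidates = []
            total = 0.0
            for k in range(n_moves):
                if feasible(counts, k):
                    w = exp(delta_logw(counts, n_dyn, k))
                    candidates.append(k)
                    weights.append(w)
                    total += w
            if not candidates:
                raise DeadlockError(t)
            u = uniforms[t] * total
            acc_w = 0.0
            e = candidates[-1]
            for k, w in zip(candidates, weights):
                acc_w += w
                if u < acc_w:
                    e = k
                    break
            acc = True

        j, d, entries, d_n, _, _ = moves[e]
        reaction_idx[t] = j
        direction[t] = d
        accepted[t] = acc
        if acc:
            # apply dynamic deltas; clamped counts never actually change
            # (move-then-re-clamp is a no-op on the stored counts)
            for i, dn, is_dyn in entries:
                if is_dyn:
                    counts[i] += dn
            n_dyn += d_n
            if d > 0:
                jp[j] += 1
            else:
                jm[j] += 1
        dynamic_totals[t] = n_dyn
        if snapshot_stride and (t + 1) % snapshot_stride == 0:
            snapshots[t + 1] = np.array(counts, dtype=np.int64)

    final = np.array(counts, dtype=np.int64)
    if steps > 0:
        snapshots[steps] = final.copy()
    rids = net.reaction_ids
    return Trajectory(
        seed=seed,
        mode=mode,
        reaction_ids=rids,
        reaction_idx=reaction_idx,
        direction=direction,
        accepted=accepted,
        flux_plus={rids[j]: jp[j] for j in range(kern.n_rxn)},
        flux_minus={rids[j]: jm[j] for j in range(kern.n_rxn)},
        snapshots=snapshots,
        snapshot_stride=snapshot_stride,
        initial_counts=state0.counts.copy(),
        final_counts=final,
        dynamic_totals=dynamic_totals,
    )


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def _network_hash(net: ReactionNetwork) -> str:
    import hashlib

    h = hashlib.sha256()
    for s in net.species:
        h.update(f"{s.id}|{s.mu0!r}|{s.role}|{s.clamp_count}".encode())
    for r in net.reactions:
        h.update(f"{r.id}|{r.equation()}".encode())
    return h.hexdigest()[:16]


def write_trajectory_tsv(traj: Trajectory, net: ReactionNetwork, path) -> None:
    lines = [
        f"# seed: {traj.seed}",
        f"# mode: {traj.mode}",
        f"# steps: {traj.n_steps}",
        f"# rng: {_RNG_ALGORITHM}",
        f"# network_hash: {_network_hash(net)}",
        "step\treaction_id\tdirection\taccepted",
    ]
    for i in range(traj.n_steps):
        lines.append(
            f"{i}\t{traj.reaction_ids[int(traj.reaction_idx[i])]}"
            f"\t{int(traj.direction[i]):+d}\t{int(traj.accepted[i])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_snapshots_tsv(traj: Trajectory, net: ReactionNetwork, path) -> None:
    lines = [f"# seed: {traj.seed}", "step\tspecies_id\tcount"]
    for t in sorted(traj.snapshots):
        for sid, c in zip(net.species_ids, traj.snapshots[t]):
            lines.append(f"{t}\t{sid}\t{int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_flux_tsv(traj: Trajectory, path) -> None:
    lines = ["reaction_id\tJ_plus\tJ_minus\tJ_net"]
    for rid in traj.reaction_ids:
        jp, jm = traj.flux_plus[rid], traj.flux_minus[rid]
        lines.append(f"{rid}\t{jp}\t{jm}\t{jp - jm}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_tsv(path, net: ReactionNetwork) -> Trajectory:
    """Re-load a trajectory event file written by :func:`write_trajectory_tsv`."""
    meta: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            k, _, v = line.lstrip("#").partition(":")
            meta[k.strip()] = v.strip()
            continue
        if line.startswith("step\t") or not line.strip():
            continue
        rows.append(line.split("\t"))
    ridx = {rid: j for j, rid in enumerate(net.reaction_ids)}
    n = len(rows)
    reaction_idx = np.array([ridx[r[1]] for r in rows], dtype=np.int32)
    direction = np.array([int(r[2]) for r in rows], dtype=np.int8)
    accepted = np.array([bool(int(r[3])) for r in rows])
    jp = {rid: 0 for rid in net.reaction_ids}
    jm = {rid: 0 for rid in net.reaction_ids}
    for r, d, a in zip(reaction_idx, direction, accepted):
        if a:
            if d > 0:
                jp[net.reaction_ids[int(r)]] += 1
            else:
                jm[net.reaction_ids[int(r)]] += 1
    return Trajectory(
        seed=int(meta.get("seed", -1)),
        mode=meta.get("mode", "unknown"),
        reaction_ids=net.reaction_ids,
        reaction_idx=reaction_idx,
        direction=direction,
        accepted=accepted,
        flux_plus=jp,
        flux_minus=jm,
        snapshots={},
        snapshot_stride=None,
        initial_counts=np.zeros(len(net.species), dtype=np.int64),
        final_counts=np.zeros(len(net.species), dtype=np.int64),
        dynamic_totals=np.zeros(n, dtype=np.int64),
    )
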