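"""Pathway profiles, entropy-production statistics, and diagnostics.

A pathway profile accumulates, along an ordered traversal of reactions, the
change in the log mass density Δ𝒜/k_BT together with its exact decomposition
into a reduced-energy change ΔE/k_BT and a configurational-entropy change ΔS
(``Δ𝒜 = ΔE − ΔS`` elementwise).  Around a full cycle with re-clamped
cofactors, the cumulative Δ𝒜 telescopes to the net clamped-species potential
change — the boundary driving force of the cycle.

Flux statistics reduce a trajectory to per-reaction forward/reverse event
counts J+ and J−; their ratio is the odds of entropy production at that
reaction, and J·ΔS_g gives microscopic and net entropy-production terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ReactionNetwork
from .simulate import Trajectory, simulate
from .steady import InfeasiblePathError, PathwayOrder, cycle_order
from .thermo import StateError, SystemState


@dataclass
class PathwayProfile:
    """Cumulative (Δ𝒜, ΔE, ΔS)/k_BT sequences along a traversal."""

    order: PathwayOrder
    cum_dA: np.ndarray
    cum_dE: np.ndarray
    cum_dS: np.ndarray

    def step_dA(self) -> np.ndarray:
        return np.diff(self.cum_dA, prepend=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_index": np.arange(1, len(self.order) + 1),
                "reaction_id": [rid for rid, _ in self.order.steps],
                "direction": [d for _, d in self.order.steps],
                "cum_dA": self.cum_dA,
                "cum_dE": self.cum_dE,
                "cum_dS": self.cum_dS,
            }
        )


def pathway_profile(
    state: SystemState, order: PathwayOrder, net: ReactionNetwork
) -> PathwayProfile:
    """Thermodynamic profile of a traversal chained from ``state``.

    Each step evaluates the move on the raw post-move state (before
    re-clamping), so clamped cofactor potentials contribute their boundary
    driving terms; the state is then re-clamped and chained forward.
    """
    state._check(net)
    dyn = net.dynamic_mask
    cl_idx = np.flatnonzero(~dyn)
    lg = math.lgamma
    current = state.counts.astype(np.int64).copy()
    n_dyn = int(current[dyn].sum())
    dA, dE, dS = [], [], []
    a = e = s = 0.0
    for pos, (rid, d) in enumerate(order.steps, start=1):
        col = net.stoich[:, net.reaction_index(rid)]
        target = current + d * col
        if np.any(target < 0):
            bad = int(np.argmax(target < 0))
            raise InfeasiblePathError(pos, net.species_ids[bad])
        d_energy = float((d * col) @ net.mu_hat)
        d_n = int((d * col[dyn]).sum())
        d_config = 0.0
        if d_n:
            d_config += lg(n_dyn + d_n + 1) - lg(n_dyn + 1)
        for i in np.flatnonzero(col):
            if dyn[i]:
                d_config -= lg(target[i] + 1) - lg(current[i] + 1)
        # Δ𝒜 = -(Δ log w) = ΔE - ΔS
        a += d_energy - d_config
        e += d_energy
        s += d_config
        dA.append(a)
        dE.append(e)
        dS.append(s)
        current = target
        current[cl_idx] = net.clamp_counts[cl_idx]
        n_dyn += d_n
    return PathwayProfile(
        order=order,
        cum_dA=np.array(dA),
        cum_dE=np.array(dE),
        cum_dS=np.array(dS),
    )


def dilute_cycle_profile(
    state_counts: dict[str, float],
    order: PathwayOrder,
    net: ReactionNetwork,
    eps: float = 1e-9,
) -> PathwayProfile:
    """Cumulative free-energy profile at a (possibly fractional) composition.

    Uses the dilute large-N limit of the discrete log-weight change:
    ΔG_r/RT = Σ_j δ_j μ̂_j + Σ_{dynamic j} δ_j log x_j with mole fractions
    x_j floored at ``eps``.  All reactions are evaluated from the shared
    composition (no chaining), as appropriate for a stationary mean state.
    """
    dyn_idx = np.flatnonzero(net.dynamic_mask)
    n = np.array([float(state_counts.get(sid, 0.0)) for sid in net.species_ids])
    total = max(n[dyn_idx].sum(), eps)
    x = np.maximum(n[dyn_idx] / total, eps)
    log_x = np.log(x)
    dA, dE, dS = [], [], []
    a = e = s = 0.0
    for rid, d in order.steps:
        col = net.stoich[:, net.reaction_index(rid)]
        d_energy = float((d * col) @ net.mu_hat)
        d_mix = float((d * col[dyn_idx]) @ log_x)
        a += d_energy + d_mix
        e += d_energy
        s += -d_mix
        dA.append(a)
        dE.append(e)
        dS.append(s)
    return PathwayProfile(
        order=order, cum_dA=np.array(dA), cum_dE=np.array(dE), cum_dS=np.array(dS)
    )


@dataclass
class FluxStatistics:
    """Per-reaction flux tallies, odds, and entropy-production terms."""

    table: pd.DataFrame
    total_J_plus: int
    total_J_minus: int
    total_net_EP: float
    ref_state: dict[str, int]

    def row(self, reaction_id: str) -> pd.Series:
        return self.table.set_index("reaction_id").loc[reaction_id]


def mean_state(traj: Trajectory, net: ReactionNetwork) -> SystemState:
    """Rounded mean of the recorded snapshots, re-clamped."""
    if not traj.snapshots:
        raise StateError("trajectory has no snapshots")
    stack = np.stack([traj.snapshots[t] for t in sorted(traj.snapshots)])
    mean = np.round(stack.mean(axis=0)).astype(np.int64)
    mean[~net.dynamic_mask] = net.clamp_counts[~net.dynamic_mask]
    return SystemState(net.species_ids, np.maximum(mean, 0))


def flux_statistics(
    traj: Trajectory,
    net: ReactionNetwork,
    ref_state: SystemState | None = None,
) -> FluxStatistics:
    """Tally J± per reaction and evaluate entropy-production terms.

    ΔS_g per reaction is evaluated for the forward direction at a single
    reference state (default: rounded trajectory mean), recorded in the
    output.  Rows with J− = 0 carry NaN odds rather than infinities.
    """
    if traj.n_steps == 0:
        raise StateError("trajectory is empty")
    for rid in traj.reaction_ids:
        if rid not in net.reaction_ids:
            raise StateError(f"reaction {rid!r} absent from network")
    if ref_state is None:
        ref_state = mean_state(traj, net)
    ref_state._check(net)
    from .simulate import _Kernel

    kern = _Kernel(net)
    counts = [int(c) for c in ref_state.counts]
    n_dyn = ref_state.n_total(net)
    rows = []
    total_net_ep = 0.0
    for j, rid in enumerate(net.reaction_ids):
        jp = traj.flux_plus.get(rid, 0)
        jm = traj.flux_minus.get(rid, 0)
        move_fwd = 2 * j  # forward directed move index
        if kern.feasible(counts, move_fwd):
            dsg = -kern.delta_logw(counts, n_dyn, move_fwd)
        else:
            dsg = math.nan
        odds = jp / jm if jm > 0 else math.nan
        micro_ep = jp * dsg
        net_ep = (jp - jm) * dsg
        if not math.isnan(net_ep):
            total_net_ep += net_ep
        rows.append(
            {
                "reaction_id": rid,
                "J_plus": jp,
                "J_minus": jm,
                "odds": odds,
                "delta_Sg_at_state": dsg,
                "micro_EP_plus": micro_ep,
                "net_EP": net_ep,
            }
        )
    table = pd.DataFrame(rows)
    return FluxStatistics(
        table=table,
        total_J_plus=int(table["J_plus"].sum()),
        total_J_minus=int(table["J_minus"].sum()),
        total_net_EP=total_net_ep,
        ref_state=ref_state.as_dict(),
    )


def flux_free_energy_diagnostic(
    stats: FluxStatistics, profile: PathwayProfile
) -> pd.DataFrame:
    """Compare per-reaction Δ𝒜/k_BT with −log(J+/J−), reaction by reaction.

    The flux–free-energy relation ΔG = −RT log(J+/J−) is an assumption, not
    an identity; this diagnostic reports both columns and their difference
    and makes no claim of equality.  Rows with J− = 0 are flagged.
    """
    step_da = dict(
        zip((rid for rid, _ in profile.order.steps), profile.step_dA())
    )
    rows = []
    for _, r in stats.table.iterrows():
        rid = r["reaction_id"]
        if rid not in step_da:
            continue
        da = float(step_da[rid])
        if r["J_minus"] > 0 and r["J_plus"] > 0:
            mlo = -math.log(r["J_plus"] / r["J_minus"])
            rows.append(
                {
                    "reaction_id": rid,
                    "delta_A": da,
                    "minus_log_odds": mlo,
                    "discrepancy": da - mlo,
                    "flagged": False,
                }
            )
        else:
            rows.append(
                {
                    "reaction_id": rid,
                    "delta_A": da,
                    "minus_log_odds": math.nan,
                    "discrepancy": math.nan,
                    "flagged": True,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReversalDiagnostic:
    """Empirical forward/reverse passage odds for one state pair."""

    forward_count: int
    reverse_count: int
    log_odds: float
    dissipation_proxy: float
    supported: bool


def reversal_odds(
    traj: Trajectory,
    pairK: SystemState,
    pairJ: SystemState,
    window: int = 1,
    net: ReactionNetwork | None = None,
) -> ReversalDiagnostic:
    """Empirical trajectory-reversal odds for the passage K→J vs J→K.

    Counts, over the recorded snapshots, occurrences of state K followed by
    state J within ``window`` snapshot intervals (and vice versa).  The log
    odds uses +1 Laplace smoothing (raw counts are reported alongside); its
    magnitude is an empirical dissipation proxy, positive when the K→J
    passage aligns with the net driving.
    """
    steps = sorted(traj.snapshots)
    if len(steps) < 2:
        raise StateError("trajectory snapshots too sparse for reversal analysis")
    seq = [tuple(traj.snapshots[t]) for t in steps]
    key_k = tuple(pairK.counts)
    key_j = tuple(pairJ.counts)
    fwd = rev = 0
    n = len(seq)
    for t, s in enumerate(seq):
        if s == key_k:
            if any(seq[u] == key_j for u in range(t + 1, min(n, t + 1 + window))):
                fwd += 1
        if s == key_j:
            if any(seq[u] == key_k for u in range(t + 1, min(n, t + 1 + window))):
                rev += 1
    # computed as a difference of logs so that swapping the pair negates
    # the value bit-exactly
    log_odds = math.log(fwd + 1) - math.log(rev + 1)
    return ReversalDiagnostic(
        forward_count=fwd,
        reverse_count=rev,
        log_odds=log_odds,
        dissipation_proxy=log_odds,
        supported=(fwd + rev) > 0,
    )


# ---------------------------------------------------------------------------
# Total-pool (concentration) scan
# ---------------------------------------------------------------------------

def scan_child_seed(seed: int, fold_index: int) -> int:
    """Deterministic per-fold seed; the first fold reuses the parent seed."""
    return (seed + 1000003 * fold_index) % (2**31)


@dataclass
class ScanEntry:
    fold: float
    pool: int
    flagged: bool
    profile: PathwayProfile | None
    mean_counts: dict[str, float] | None
    seed: int


def _rescale_pool(
    base_dyn: np.ndarray, target_total: int
) -> np.ndarray:
    """Distribute target_total proportionally to base counts (largest remainder)."""
    if base_dyn.sum() == 0:
        out = np.zeros_like(base_dyn)
        out[0] = target_total
        return out
    raw = base_dyn / base_dyn.sum() * target_total
    floors = np.floor(raw).astype(np.int64)
    rem = int(target_total - floors.sum())
    frac_order = np.argsort(-(raw - floors), kind="stable")
    for i in range(rem):
        floors[frac_order[i % len(floors)]] += 1
    return floors


def concentration_scan(
    net: ReactionNetwork,
    folds: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001),
    steps: int = 50_000,
    seed: int = 0,
    base_state: SystemState | None = None,
    order: PathwayOrder | None = None,
    burn_in: float = 0.2,
    snapshot_stride: int | None = None,
) -> dict[float, ScanEntry]:
    """Scale the dynamic pool by each fold, simulate, and profile each state.

    For each fold the total dynamic pool of ``base_state`` is rescaled, the
    driven chain (odds mode) is run for ``steps`` events, and the stationary
    mean composition (after a fixed 20 % burn-in) is summarized by a
    dilute-limit cumulative profile.  A fold whose pool rounds to zero
    dynamic particles is flagged instead of simulated.
    """
    if base_state is None:
        raise StateError("concentration_scan requires a base_state")
    if any(f <= 0 for f in folds):
        raise StateError("folds must be positive")
    base_state._check(net)
    dyn_idx = np.flatnonzero(net.dynamic_mask)
    base_dyn = base_state.counts[dyn_idx].astype(float)
    n0 = base_dyn.sum()
    stride = snapshot_stride or max(1, steps // 1000)
    the_order = order or cycle_order(net)
    out: dict[float, ScanEntry] = {}
    for i, fold in enumerate(folds):
        child = scan_child_seed(seed, i)
        target = int(round(fold * n0))
        if target == 0:
            out[fold] = ScanEntry(
                fold=fold, pool=0, flagged=True, profile=None,
                mean_counts=None, seed=child,
            )
            continue
        vec = base_state.counts.copy()
        vec[dyn_idx] = _rescale_pool(base_dyn, target)
        state = SystemState(net.species_ids, vec)
        traj = simulate(
            net, state, steps, mode="odds", seed=child, snapshot_stride=stride
        )
        snaps = sorted(traj.snapshots)
        keep = [t for t in snaps if t >= burn_in * steps]
        stack = np.stack([traj.snapshots[t] for t in keep]).astype(float)
        mean = stack.mean(axis=0)
        mean_counts = {
            sid: float(mean[k]) for k, sid in enumerate(net.species_ids)
        }
        profile = dilute_cycle_profile(mean_counts, the_order, net)
        out[fold] = ScanEntry(
            fold=fold, pool=target, flagged=False, profile=profile,
            mean_counts=mean_counts, seed=child,
        )
    return out


def write_profile_tsv(profile: PathwayProfile, path) -> None:
    from pathlib import Path

    df = profile.to_frame()
    lines = ["step_index\treaction_id\tcum_dA\tcum_dE\tcum_dS"]
    for _, r in df.iterrows():
        lines.append(
            f"{int(r['step_index'])}\t{r['reaction_id']}"
            f"\t{r['cum_dA']!r}\t{r['cum_dE']!r}\t{r['cum_dS']!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
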