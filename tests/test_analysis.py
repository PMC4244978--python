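"""Pathway profiles, flux statistics, diagnostics, and the pool scan."""

import math

import numpy as np
import pytest

import boltzmet as bm
from boltzmet.analysis import ScanEntry, mean_state
from boltzmet.steady import InfeasiblePathError


class TestPathwayProfile:
    def test_empty_order(self, abc_equal):
        net, state = abc_equal
        prof = bm.pathway_profile(state, bm.PathwayOrder(()), net)
        assert len(prof.cum_dA) == len(prof.cum_dE) == len(prof.cum_dS) == 0

    def test_single_step_decomposition(self):
        net, state = bm.make_abc_fixture((0.0, 0.0, 0.0), 12)  # (4,4,4)
        prof = bm.pathway_profile(state, bm.PathwayOrder((("AB", 1),)), net)
        assert prof.cum_dA[0] == pytest.approx(-math.log(4 / 5), abs=1e-12)
        assert prof.cum_dE[0] == pytest.approx(0.0, abs=1e-12)
        assert prof.cum_dS[0] == pytest.approx(math.log(4 / 5), abs=1e-12)

    @pytest.mark.parametrize("variant", ["ecoli", "cyano", "chlorobium"])
    def test_energy_entropy_compensation_identity(self, variant):
        """cum_dA = cum_dE - cum_dS elementwise on every profile step."""
        net, state = bm.make_tca_fixture(variant)
        prof = bm.pathway_profile(state, bm.cycle_order(net), net)
        assert np.abs(prof.cum_dA - (prof.cum_dE - prof.cum_dS)).max() < 1e-10

    @pytest.mark.parametrize("variant", ["ecoli", "cyano", "chlorobium"])
    def test_cycle_closure_equals_boundary_driving_force(self, variant):
        """Around one full re-clamped cycle, Σ Δ𝒜 equals the net clamped-
        species potential change of the overall reaction."""
        net, state = bm.make_tca_fixture(variant)
        prof = bm.pathway_profile(state, bm.cycle_order(net), net)
        overall = bm.net_stoichiometry(net, {rid: 1 for rid in net.reaction_ids})
        mu = {s.id: s.mu_hat for s in net.species}
        drive = sum(v * mu[sid] for sid, v in overall.items())
        assert prof.cum_dA[-1] == pytest.approx(drive, abs=1e-8)

    def test_chlorobium_reverses_profile_sign(self, tca_ecoli, tca_chlorobium):
        net_e, st_e = tca_ecoli
        net_c, st_c = tca_chlorobium
        da_e = bm.pathway_profile(st_e, bm.cycle_order(net_e), net_e).cum_dA[-1]
        da_c = bm.pathway_profile(st_c, bm.cycle_order(net_c), net_c).cum_dA[-1]
        assert da_e < 0 < da_c

    def test_infeasible_prefix(self, abc_equal):
        net, _ = abc_equal
        state = bm.SystemState.from_counts(net, {"C": 6})
        with pytest.raises(InfeasiblePathError):
            bm.pathway_profile(state, bm.PathwayOrder((("AB", 1),)), net)


def _fake_trajectory(net, tallies):
    """Trajectory with prescribed (J+, J-) tallies per reaction."""
    events = []
    for rid, (jp, jm) in tallies.items():
        j = net.reaction_index(rid)
        events += [(j, 1)] * jp + [(j, -1)] * jm
    reaction_idx = np.array([e[0] for e in events], dtype=np.int32)
    direction = np.array([e[1] for e in events], dtype=np.int8)
    return bm.Trajectory(
        seed=0,
        mode="odds",
        reaction_ids=net.reaction_ids,
        reaction_idx=reaction_idx,
        direction=direction,
        accepted=np.ones(len(events), dtype=bool),
        flux_plus={rid: t[0] for rid, t in tallies.items()},
        flux_minus={rid: t[1] for rid, t in tallies.items()},
        snapshots={},
        snapshot_stride=None,
        initial_counts=np.zeros(len(net.species), dtype=np.int64),
        final_counts=np.zeros(len(net.species), dtype=np.int64),
        dynamic_totals=np.zeros(len(events), dtype=np.int64),
    )


class TestFluxStatistics:
    def test_balanced_and_skewed_odds(self, abc_equal):
        net, state = abc_equal
        traj = _fake_trajectory(net, {"AB": (50, 50), "BC": (75, 25)})
        stats = bm.flux_statistics(traj, net, ref_state=state)
        ab = stats.row("AB")
        bc = stats.row("BC")
        assert ab["odds"] == pytest.approx(1.0)
        assert ab["net_EP"] == pytest.approx(0.0)
        assert bc["odds"] == pytest.approx(3.0)
        assert stats.total_J_plus + stats.total_J_minus == traj.n_accepted

    def test_equilibrium_run_odds_near_unity(self, abc_tilted):
        net, state = abc_tilted
        traj = bm.simulate(
            net, state, 1_000_000, mode="metropolis", seed=21, snapshot_stride=10_000
        )
        stats = bm.flux_statistics(traj, net)
        for _, row in stats.table.iterrows():
            assert 0.9 <= row["odds"] <= 1.1

    def test_empty_trajectory_rejected(self, abc_equal):
        net, state = abc_equal
        traj = bm.simulate(net, state, 0, seed=0)
        with pytest.raises(bm.StateError):
            bm.flux_statistics(traj, net, ref_state=state)


class TestFluxFreeEnergyDiagnostic:
    def test_zero_reverse_flux_flagged(self, abc_equal):
        net, state = abc_equal
        traj = _fake_trajectory(net, {"AB": (10, 0), "BC": (5, 5)})
        stats = bm.flux_statistics(traj, net, ref_state=state)
        prof = bm.pathway_profile(state, bm.cycle_order(net), net)
        table = bm.flux_free_energy_diagnostic(stats, prof).set_index("reaction_id")
        assert bool(table.loc["AB", "flagged"])
        assert not bool(table.loc["BC", "flagged"])
        assert math.isnan(table.loc["AB", "minus_log_odds"])

    def test_equilibrium_columns_vanish(self, abc_tilted):
        net, state = abc_tilted
        traj = bm.simulate(net, state, 400_000, mode="metropolis", seed=8)
        ref = bm.SystemState.from_counts(net, {"A": 3, "B": 1, "C": 2})
        stats = bm.flux_statistics(traj, net, ref_state=ref)
        prof = bm.pathway_profile(ref, bm.cycle_order(net), net)
        table = bm.flux_free_energy_diagnostic(stats, prof)
        assert np.abs(table["minus_log_odds"]).max() < 0.15

    def test_near_equilibrium_reactions_more_concordant(self, tca_ecoli):
        """In a driven cycle, reactions closer to equilibrium show a smaller
        flux/free-energy discrepancy than reactions far from it."""
        net, state = tca_ecoli
        steps, burn = 100_000, 20_000
        traj = bm.simulate(net, state, steps, mode="odds", seed=6,
                           snapshot_stride=1000)
        keep = [t for t in sorted(traj.snapshots) if t >= burn]
        mean = np.stack([traj.snapshots[t] for t in keep]).mean(axis=0)
        prof = bm.dilute_cycle_profile(
            dict(zip(net.species_ids, mean)), bm.cycle_order(net), net
        )
        step_da = prof.step_dA()
        stationary = np.arange(traj.n_steps) >= burn
        disc = {}
        for j, rid in enumerate(net.reaction_ids):
            m = stationary & (traj.reaction_idx == j) & traj.accepted
            jp = int(((traj.direction == 1) & m).sum())
            jm = int(((traj.direction == -1) & m).sum())
            assert jp > 0 and jm > 0
            disc[rid] = abs(step_da[j] + math.log(jp / jm))
        order = np.argsort(np.abs(step_da))
        rids = list(net.reaction_ids)
        near = [disc[rids[j]] for j in order[:4]]
        far = [disc[rids[j]] for j in order[4:]]
        assert np.mean(near) < np.mean(far)


class TestReversalOdds:
    def test_antisymmetry_exact(self, abc_tilted):
        net, state = abc_tilted
        traj = bm.simulate(net, state, 5000, mode="metropolis", seed=11,
                           snapshot_stride=1)
        k = bm.SystemState.from_counts(net, {"A": 2, "B": 2, "C": 2})
        j = bm.SystemState.from_counts(net, {"A": 1, "B": 3, "C": 2})
        fwd = bm.reversal_odds(traj, k, j, window=1)
        rev = bm.reversal_odds(traj, j, k, window=1)
        assert fwd.log_odds == -rev.log_odds
        assert fwd.forward_count == rev.reverse_count

    def test_equilibrium_log_odds_near_zero(self, abc_equal):
        net, state = abc_equal
        traj = bm.simulate(net, state, 200_000, mode="metropolis", seed=15,
                           snapshot_stride=1)
        k = bm.SystemState.from_counts(net, {"A": 2, "B": 2, "C": 2})
        j = bm.SystemState.from_counts(net, {"A": 1, "B": 3, "C": 2})
        diag = bm.reversal_odds(traj, k, j, window=1)
        assert diag.supported
        assert abs(diag.log_odds) < 0.1

    def test_driven_passage_aligned_with_driving(self):
        """In a chemostat-driven linear chain, a passage along the driving
        direction has positive empirical log odds."""
        from boltzmet.network import (
            Reaction, ReactionNetwork, Species, ThermoContext,
        )

        ctx = ThermoContext()
        kbt = ctx.kBT_kJ_per_mol
        net = ReactionNetwork(
            ctx,
            [
                Species("Xc", 0.0, 0.0, role="clamped", clamp_count=50),
                Species("A", 3.0 * kbt, 3.0),
                Species("B", 3.0 * kbt, 3.0),
                Species("Yc", -3.0 * kbt, -3.0, role="clamped", clamp_count=50),
            ],
            [
                Reaction("in", {"Xc": 1}, {"A": 1}),
                Reaction("ab", {"A": 1}, {"B": 1}),
                Reaction("out", {"B": 1}, {"Yc": 1}),
            ],
        )
        state = bm.SystemState.from_counts(net, {"A": 10, "B": 10})
        traj = bm.simulate(net, state, 100_000, mode="odds", seed=17,
                           snapshot_stride=1)
        k = bm.SystemState.from_counts(net, {"A": 1, "B": 0})
        j = bm.SystemState.from_counts(net, {"A": 0, "B": 1})
        diag = bm.reversal_odds(traj, k, j, window=1)
        assert diag.supported
        assert diag.log_odds > 0


class TestConcentrationScan:
    def test_single_fold_consistency(self, tca_ecoli):
        net, state = tca_ecoli
        res = bm.concentration_scan(
            net, folds=(1.0,), steps=5000, seed=19, base_state=state
        )
        entry = res[1.0]
        traj = bm.simulate(
            net, state, 5000, mode="odds", seed=bm.scan_child_seed(19, 0),
            snapshot_stride=5,
        )
        keep = [t for t in sorted(traj.snapshots) if t >= 0.2 * 5000]
        mean = np.stack([traj.snapshots[t] for t in keep]).mean(axis=0)
        direct = bm.dilute_cycle_profile(
            dict(zip(net.species_ids, mean)), bm.cycle_order(net), net
        )
        assert np.array_equal(entry.profile.cum_dA, direct.cum_dA)

    def test_pooling_and_spread(self):
        """Shrinking the pool concentrates mass on the lowest-potential
        intermediates and widens the per-reaction Δ𝒜 spread."""
        net, state = bm.make_tca_fixture("ecoli", pool_scale=10)
        res = bm.concentration_scan(
            net, folds=(1.0, 0.001), steps=20_000, seed=23, base_state=state
        )
        spread = {}
        for fold, entry in res.items():
            assert not entry.flagged
            sd = entry.profile.step_dA()
            spread[fold] = float(sd.max() - sd.min())
        assert spread[1.0] < spread[0.001]
        small = res[0.001]
        dyn = {sid: small.mean_counts[sid] for sid in net.dynamic_ids}
        top = max(dyn, key=dyn.get)
        mu = {s.id: s.mu_hat for s in net.species if s.role == "dynamic"}
        lowest = sorted(mu, key=mu.get)[:2]
        assert top in lowest  # citrate or succinyl-CoA pools

    def test_zero_pool_flagged(self, abc_equal):
        net, state = abc_equal
        res = bm.concentration_scan(
            net, folds=(0.01,), steps=100, seed=1, base_state=state
        )
        entry = res[0.01]
        assert entry.flagged and entry.profile is None

    def test_requires_base_state(self, abc_equal):
        net, _ = abc_equal
        with pytest.raises(bm.StateError):
            bm.concentration_scan(net, folds=(1.0,), steps=10, seed=0)
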