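"""Molecular mass-action system: hand-computed derivatives, conservation,
solver-independence and qualitative treatment contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteosim.network import (ALGEBRAIC, DYNAMIC, Edge, INPUT,
                              SignalingNetwork)
from osteosim.signaling import (HOURS_PER_DAY, KineticParams, SpeciesState,
                                TreatmentSchedule, SignalingError, rhs,
                                simulate_signaling, tf_readout)
from osteosim.signaling import _Compiled
from conftest import rk4


def toy_pair_network():
    """Single conservation pair M with one activator input A and one
    inhibitor input I."""
    species = {"M": DYNAMIC, "M_u": ALGEBRAIC, "A": INPUT, "I": INPUT}
    edges = [Edge("A", "M"), Edge("I", "M", sign="inhibit")]
    return SignalingNetwork(species, edges, [("M", "M_u", "C_M")], [],
                            {"C_M": 1.0})


def toy_chain_network():
    """Three-species chain driven by the BMP2 ligand input."""
    species = {"BMP2": INPUT}
    for s in ("X1", "X2", "X3"):
        species[s] = DYNAMIC
        species[f"{s}_u"] = ALGEBRAIC
    edges = [Edge("BMP2", "X1"), Edge("X1", "X2"), Edge("X2", "X3")]
    pairs = [(s, f"{s}_u", f"C_{s}") for s in ("X1", "X2", "X3")]
    return SignalingNetwork(species, edges, pairs, [],
                            {f"C_{s}": 1.0 for s in ("X1", "X2", "X3")})


class TestRhs:
    def test_hand_computed_single_pair(self):
        # a*[A]*(C - pM) - d*[I]*pM = 0.1*1*0.5 - 0.05*1*0.5 = 0.025
        net = toy_pair_network()
        params = KineticParams({"a_M": 0.1, "d_M": 0.05})
        state = SpeciesState(0.0, {"M": 0.5, "A": 1.0, "I": 1.0})
        d = rhs(state, params, net)
        assert d["M"] == pytest.approx(0.025, abs=1e-12)

    def test_saturated_species_has_no_activation(self):
        net = toy_pair_network()
        params = KineticParams({"a_M": 5.0, "d_M": 0.05})
        state = SpeciesState(0.0, {"M": 1.0, "A": 3.0, "I": 0.0})
        assert rhs(state, params, net)["M"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_pool_cannot_decay(self):
        net = toy_pair_network()
        params = KineticParams({"a_M": 0.0001, "d_M": 50.0})
        state = SpeciesState(0.0, {"M": 0.0, "A": 0.5, "I": 4.0})
        assert rhs(state, params, net)["M"] >= 0.0

    def test_missing_parameter_is_named(self):
        net = toy_pair_network()
        params = KineticParams({"a_M": 0.1})
        with pytest.raises(SignalingError, match="d_M"):
            rhs(SpeciesState(0.0, {"M": 0.5}), params, net)

    def test_negative_concentration_rejected(self):
        net = toy_pair_network()
        params = KineticParams({"a_M": 0.1, "d_M": 0.05})
        with pytest.raises(SignalingError, match="negative"):
            rhs(SpeciesState(0.0, {"M": -0.2}), params, net)


class TestSimulation:
    def test_pure_decay_is_monotone(self, net, kparams):
        # with vanishing activation rates a kicked state decays toward 0
        decay_only = kparams.replace(
            **{k: 1e-12 for k in kparams.values if k.startswith("a_")})
        sched = TreatmentSchedule([], "relax")
        init = SpeciesState(0.0, {s: 0.5 for s in net.dynamic_species()})
        traj = simulate_signaling(net, decay_only, sched,
                                  t_grid=np.linspace(0, 48, 97),
                                  initial=init)
        for s in ("TAK1", "p38", "ERK", "Akt", "Runx2"):
            y = traj[s]
            assert y[-1] < 0.01
            assert np.all(np.diff(y) <= 1e-9)

    def test_conservation_at_all_output_times(self, net, kparams, schedules):
        traj = simulate_signaling(net, kparams, schedules["B1I4"])
        for ph, base, total_id in net.pairs:
            total = traj[ph] + traj[base]
            assert np.allclose(total, net.totals[total_id], rtol=1e-6)

    def test_receptor_total_constant(self, net, kparams, schedules):
        traj = simulate_signaling(net, kparams, schedules["I1B1"])
        free_plus_complex = traj["BMP2_R"] + traj["BMPR_free"]
        assert np.allclose(free_plus_complex, net.totals["C_BMP2_R"],
                           rtol=1e-6)

    def test_nonnegative_trajectories(self, net, kparams, schedules):
        traj = simulate_signaling(net, kparams, schedules["B1I4"])
        assert traj.y.min() >= 0.0

    def test_bad_grid_rejected(self, net, kparams, schedules):
        with pytest.raises(ValueError):
            simulate_signaling(net, kparams, schedules["B1"],
                               t_grid=np.array([2.0, 1.0]))

    def test_adaptive_matches_fixed_step_oracle(self):
        """Adaptive LSODA agrees with brute-force RK4 at dt=1e-3 h."""
        net = toy_chain_network()
        params = KineticParams({"a_X1": 1.0, "d_X1": 0.3, "a_X2": 2.0,
                                "d_X2": 0.6, "a_X3": 0.8, "d_X3": 0.2})
        sched = TreatmentSchedule([("BMP2", 0, 50.0)], "B0")
        t_grid = np.linspace(0.0, 12.0, 25)
        traj = simulate_signaling(net, params, sched, t_grid=t_grid)

        comp = _Compiled(net, params)
        u = {"BMP2": 1.0, "IGF1": 0.0}
        y_oracle = rk4(lambda t, y: comp.rhs(y, u), np.zeros(3), 0.0, 12.0,
                       dt=1e-3)
        np.testing.assert_allclose(traj.y[-1], y_oracle, rtol=1e-4)

    def test_gsk3b_phosphorylation_highest_after_sequential_delivery(
            self, scenario_results):
        """BMP-2 priming before IGF-1 (B1I4) drives stronger GSK3beta
        phosphorylation than IGF-1 alone at matched times past day 4.5."""
        b1i4 = scenario_results["B1I4"].signaling
        i1 = scenario_results["I1"].signaling
        t_cmp = np.arange(4.5 * HOURS_PER_DAY, 6 * HOURS_PER_DAY, 4.0)
        g_b1i4 = np.interp(t_cmp, b1i4.t, b1i4["GSK3b"])
        g_i1 = np.interp(t_cmp, i1.t, i1["GSK3b"])
        assert np.all(g_b1i4 > g_i1)


class TestTfReadout:
    def test_zero_trajectory_gives_zero_readouts(self, net, kparams):
        sched = TreatmentSchedule([], "control")
        traj = simulate_signaling(net, kparams, sched,
                                  t_grid=np.linspace(0, 24, 49))
        readouts = tf_readout(traj, net)
        assert all(v == 0.0 for v in readouts.values())

    def test_saturated_upstream_gives_unit_readout(self, net, kparams):
        from osteosim.signaling import SignalingTrajectory
        names = net.dynamic_species()
        y = np.tile([net.total_of(s) for s in names], (5, 1))
        traj = SignalingTrajectory(net, np.linspace(0, 10, 5), y, names)
        readouts = tf_readout(traj, net)
        assert all(v == pytest.approx(1.0) for v in readouts.values())

    def test_bmp_first_activates_runx2_more_than_igf_alone(
            self, scenario_results):
        assert (scenario_results["B1"].tf["Runx2"]
                > scenario_results["I1"].tf["Runx2"])

    def test_igf_before_bmp_suppresses_runx2(self, scenario_results):
        # ERK activated by early IGF-1 dephosphorylates SMAD1/5
        assert (scenario_results["I1B4"].tf["Runx2"]
                < scenario_results["B1"].tf["Runx2"])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(a=st.floats(0.05, 5.0), d=st.floats(0.05, 5.0),
       dose_day=st.integers(0, 2))
def test_conservation_bounds_hold_for_random_rates(a, d, dose_day):
    """0 <= [pM] <= C_M along the whole trajectory, whatever the rates."""
    net = toy_chain_network()
    params = KineticParams({f"{p}_{s}": r for s in ("X1", "X2", "X3")
                            for p, r in (("a", a), ("d", d))})
    sched = TreatmentSchedule([("BMP2", dose_day, 50.0)], "t")
    traj = simulate_signaling(net, params, sched,
                              t_grid=np.linspace(0, 72, 73))
    assert traj.y.min() >= 0.0
    assert traj.y.max() <= 1.0 + 1e-7
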