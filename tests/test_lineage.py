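"""Cell-lineage compartment model: hand-computed derivatives, mass
bookkeeping, absorbing compartments and solver-independence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteosim.lineage import (COMPARTMENTS, LineageError, LineageParams,
                              LineageState, effective_rates, lineage_rhs,
                              observables, simulate_lineage)
from osteosim.signaling import TreatmentSchedule
from conftest import rk4

ZERO_TF = {"Runx2": 0.0, "Osterix": 0.0, "bCatenin": 0.0, "ProlifTF": 0.0}


def zero_rates():
    return {k: 0.0 for k in ("P_MSC", "P_OBp", "P_OBa", "D_MSC", "D_OBp",
                             "Q_MSC", "Q_OBp")}


class TestEffectiveRates:
    def test_no_cytokine_gives_basal_rates(self, lparams):
        sched = TreatmentSchedule([], "control")
        r = effective_rates(3.0, lparams, sched, {"Runx2": 0.9})
        assert r["D_MSC"] == pytest.approx(lparams.D0_MSC)
        assert r["P_MSC"] == pytest.approx(lparams.P0_MSC)
        assert r["Q_MSC"] == pytest.approx(lparams.Q0_MSC)

    def test_window_closes_after_tp(self, lparams):
        sched = TreatmentSchedule([("BMP2", 1, 50.0)], "B1")
        tf = {"Runx2": 0.8}
        inside = effective_rates(2.0, lparams, sched, tf)
        after = effective_rates(1 + lparams.t_p + 0.5, lparams, sched, tf)
        assert inside["D_MSC"] > lparams.D0_MSC
        assert after["D_MSC"] == pytest.approx(lparams.D0_MSC)

    def test_bmp_window_rate_law(self, lparams):
        # D_MSC = D0_MSC + b_1 * runx2 readout inside the BMP-2 window
        sched = TreatmentSchedule([("BMP2", 1, 50.0)], "B1")
        r = 0.37
        rates = effective_rates(2.0, lparams, sched, {"Runx2": r})
        assert rates["D_MSC"] == pytest.approx(
            lparams.D0_MSC + lparams.b_1 * r)


class TestRhs:
    def test_all_zero_rates_is_fixed_point(self):
        st0 = LineageState(0.0, 1.0, 0.2, 0.3, 0.4)
        d = lineage_rhs(st0, zero_rates())
        assert all(v == 0.0 for v in d.values())

    def test_quiescent_pool_constant_without_quit_flux(self):
        rates = zero_rates()
        rates.update(D_MSC=0.3, D_OBp=0.2)
        d = lineage_rhs(LineageState(0.0, 1.0, 0.5, 0.5, 0.1), rates)
        assert d["MSCq"] == 0.0

    def test_hand_computed_derivatives(self):
        rates = zero_rates()
        rates.update(P_MSC=0.2, D_MSC=0.1, Q_MSC=0.05)
        d = lineage_rhs(LineageState(0.0, 1.0, 0.0, 0.0, 0.0), rates)
        assert d["BMSC"] == pytest.approx(0.05)
        assert d["OBp"] == pytest.approx(0.1)
        assert d["MSCq"] == pytest.approx(0.05)
        assert d["OBa"] == pytest.approx(0.0)

    def test_negative_rate_rejected(self):
        rates = zero_rates()
        rates["D_MSC"] = -0.1
        with pytest.raises(LineageError):
            lineage_rhs(LineageState(0.0, 1.0, 0, 0, 0), rates)


class TestSimulation:
    def test_zero_dynamics_constant_trajectory(self):
        params = LineageParams(P0_MSC=0, P0_OBp=0, P0_OBa=0, D0_MSC=0,
                               D0_OBp=0, Q0_MSC=0, Q0_OBp=0, b_1=0, i_1=0,
                               i_2=0, i_3=0, t_p=1.0)
        traj = simulate_lineage(params, TreatmentSchedule([], "c"), ZERO_TF,
                                horizon_days=10)
        assert np.allclose(traj["BMSC"], 1.0)
        assert np.allclose(traj.total(), 1.0)

    def test_mass_conserved_without_proliferation(self, schedules):
        params = LineageParams(P0_MSC=0, P0_OBp=0, P0_OBa=0, D0_MSC=0.05,
                               D0_OBp=0.04, Q0_MSC=0.02, Q0_OBp=0.03,
                               b_1=0.3, i_1=0, i_2=0.2, i_3=0.1, t_p=4.0)
        tf = {"Runx2": 0.7, "Osterix": 0.6, "bCatenin": 0.5, "ProlifTF": 0.4}
        traj = simulate_lineage(params, schedules["B1I4"], tf,
                                horizon_days=29)
        assert np.allclose(traj.total(), 1.0, atol=1e-8)

    def test_absorbing_compartments_never_lose_mass(self, lparams,
                                                    schedules):
        tf = {"Runx2": 0.7, "Osterix": 0.6, "bCatenin": 0.5, "ProlifTF": 0.4}
        traj = simulate_lineage(lparams, schedules["B1I4"], tf,
                                horizon_days=29)
        assert np.all(np.diff(traj["MSCq"]) >= -1e-10)
        assert np.all(np.diff(traj["OBa"]) >= -1e-10)

    def test_exponential_growth_when_only_proliferating(self):
        params = LineageParams(P0_MSC=0.2, P0_OBp=0.3, P0_OBa=0.1, D0_MSC=0,
                               D0_OBp=0, Q0_MSC=0, Q0_OBp=0, b_1=0, i_1=0,
                               i_2=0, i_3=0, t_p=1.0)
        init = LineageState(0.0, 1.0, 0.0, 0.5, 0.25)
        traj = simulate_lineage(params, TreatmentSchedule([], "c"), ZERO_TF,
                                horizon_days=10, initial=init)
        assert traj.at_day(10).BMSC == pytest.approx(np.exp(0.2 * 10),
                                                     rel=1e-6)
        assert traj.at_day(10).OBp == pytest.approx(0.5 * np.exp(0.3 * 10),
                                                    rel=1e-6)

    def test_oba_monotone_in_b1(self, lparams, schedules, scenario_results):
        tf = scenario_results["B1I4"].tf
        obas = []
        for b1 in (0.1, 0.4, 0.8):
            traj = simulate_lineage(lparams.replace(b_1=b1),
                                    schedules["B1I4"], tf, horizon_days=29)
            obas.append(traj.at_day(29).OBa)
        assert obas[0] < obas[1] < obas[2]

    def test_adaptive_matches_fixed_step_oracle(self, lparams, schedules):
        tf = {"Runx2": 0.7, "Osterix": 0.6, "bCatenin": 0.5, "ProlifTF": 0.4}
        sched = schedules["B1I4"]
        traj = simulate_lineage(lparams, sched, tf, horizon_days=12)

        def f(t, y):
            st0 = LineageState(t, *y)
            d = lineage_rhs(st0, effective_rates(t, lparams, sched, tf))
            return [d[c] for c in COMPARTMENTS]

        y = np.array([1.0, 0.0, 0.0, 0.0])
        # integrate piecewise so the rate discontinuities align
        breaks = [0, 1, 4, 1 + lparams.t_p, 4 + lparams.t_p, 12.0]
        for t0, t1 in zip(breaks[:-1], breaks[1:]):
            fmid = lambda t, yy, m=0.5 * (t0 + t1): [
                lineage_rhs(LineageState(t, *yy),
                            effective_rates(m, lparams, sched, tf))[c]
                for c in COMPARTMENTS]
            y = rk4(fmid, y, t0, t1, dt=1e-3)
        np.testing.assert_allclose(traj.y[-1], y, rtol=1e-5)


class TestObservables:
    def test_constant_trajectory_normalizes_to_one(self):
        params = LineageParams(P0_MSC=0, P0_OBp=0, P0_OBa=0, D0_MSC=0,
                               D0_OBp=0, Q0_MSC=0, Q0_OBp=0, b_1=0, i_1=0,
                               i_2=0, i_3=0, t_p=1.0)
        traj = simulate_lineage(params, TreatmentSchedule([], "c"), ZERO_TF,
                                horizon_days=29)
        obs = observables(traj)
        assert all(v == pytest.approx(1.0) for v in
                   obs["total_mass_norm"].values())

    def test_control_self_normalizes_to_one(self, scenario_results):
        ctrl = scenario_results["control"].lineage
        obs = observables(ctrl, control_oba=ctrl.at_day(29).OBa)
        assert obs["oba"] == pytest.approx(1.0)

    def test_day_beyond_horizon_rejected(self, lparams, schedules):
        traj = simulate_lineage(lparams, schedules["B1"], ZERO_TF,
                                horizon_days=10)
        with pytest.raises(LineageError):
            observables(traj, oba_day=29.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(d_msc=st.floats(0, 0.5), d_obp=st.floats(0, 0.5),
       q_msc=st.floats(0, 0.3), q_obp=st.floats(0, 0.3))
def test_mass_moves_but_never_appears_without_proliferation(
        d_msc, d_obp, q_msc, q_obp):
    """With P=0, differentiation/quit only redistribute mass (to 1e-8)."""
    params = LineageParams(P0_MSC=0, P0_OBp=0, P0_OBa=0, D0_MSC=d_msc,
                           D0_OBp=d_obp, Q0_MSC=q_msc, Q0_OBp=q_obp, b_1=0,
                           i_1=0, i_2=0, i_3=0, t_p=1.0)
    traj = simulate_lineage(params, TreatmentSchedule([], "c"), ZERO_TF,
                            horizon_days=15)
    assert np.allclose(traj.total(), 1.0, atol=1e-8)
    assert traj.y.min() >= 0.0
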