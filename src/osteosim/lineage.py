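"""Compartmental cell-lineage ODE system.

Four compartments: BMSC (bone-marrow stromal stem cells), OBp
(preosteoblasts), OBa (mature osteoblasts) and MSCq (non-osteoblastic cells
that have quit the lineage):

    d[BMSC]/dt = P_MSC(t)[BMSC] - (D_MSC(t) + Q_MSC(t))[BMSC]
    d[MSCq]/dt = Q_MSC(t)[BMSC] + Q_OBp(t)[OBp]
    d[OBp]/dt  = P_OBp(t)[OBp] + D_MSC(t)[BMSC] - (D_OBp(t) + Q_OBp(t))[OBp]
    d[OBa]/dt  = P_OBa(t)[OBa] + D_OBp(t)[OBp]

MSCq and OBa are absorbing.  Every rate is a basal value plus cytokine-driven
promotion terms that are active inside a rectangular delivery window
[delivery day, delivery day + t_p] and scaled by the scalar TF readouts the
molecular model provides:

* ``b_1`` — BMP-2 promotion of BMSC -> OBp differentiation, gated by Runx2;
* ``i_1`` — IGF-1 promotion of proliferation, gated by the proliferative TF;
* ``i_2`` — IGF-1 promotion of OBp -> OBa maturation, gated by the mean of
  the osterix and beta-catenin readouts;
* ``i_3`` — IGF-1 promotion of non-osteoblastic transformation of BMSCs,
  gated by the *absence* of timely Runx2 activation (1 - Runx2 readout).

Time is in days; populations are dsDNA-equivalent arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.integrate import solve_ivp

from .signaling import TreatmentSchedule

COMPARTMENTS = ("BMSC", "MSCq", "OBp", "OBa")


class LineageError(RuntimeError):
    pass


@dataclass
class LineageState:
    t: float           # days
    BMSC: float
    MSCq: float
    OBp: float
    OBa: float

    def total(self) -> float:
        return self.BMSC + self.MSCq + self.OBp + self.OBa


@dataclass
class LineageParams:
    """Basal rates (per day), cytokine effect coefficients and the effective
    cytokine window t_p (days)."""

    P0_MSC: float = 0.10
    P0_OBp: float = 0.10
    P0_OBa: float = 0.12
    D0_MSC: float = 0.01
    D0_OBp: float = 0.01
    Q0_MSC: float = 0.005
    Q0_OBp: float = 0.04
    b_1: float = 0.40
    i_1: float = 0.01
    i_2: float = 0.40
    i_3: float = 0.02
    t_p: float = 4.0

    def __post_init__(self) -> None:
        for k, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0, got {v}")
        if self.t_p <= 0:
            raise ValueError("t_p must be > 0")

    def replace(self, **updates: float) -> "LineageParams":
        vals = asdict(self)
        vals.update(updates)
        return LineageParams(**vals)


def _window(t: float, schedule: TreatmentSchedule, cytokine: str,
            t_p: float) -> float:
    """1 inside [delivery, delivery + t_p] of any matching event, else 0."""
    for cyt, day, _ in schedule.events:
        if cyt == cytokine and day <= t <= day + t_p:
            return 1.0
    return 0.0


def effective_rates(t: float, params: LineageParams,
                    schedule: TreatmentSchedule,
                    tf: dict[str, float]) -> dict[str, float]:
    """Time-dependent rates: basal + coefficient x TF readout x window(t)."""
    w_b = _window(t, schedule, "BMP2", params.t_p)
    w_i = _window(t, schedule, "IGF1", params.t_p)
    r_runx2 = tf.get("Runx2", 0.0)
    r_mat = 0.5 * (tf.get("Osterix", 0.0) + tf.get("bCatenin", 0.0))
    r_prol = tf.get("ProlifTF", 0.0)
    rates = {
        "P_MSC": params.P0_MSC + params.i_1 * r_prol * w_i,
        "P_OBp": params.P0_OBp + params.i_1 * r_prol * w_i,
        "P_OBa": params.P0_OBa + params.i_1 * r_prol * w_i,
        "D_MSC": params.D0_MSC + params.b_1 * r_runx2 * w_b,
        "D_OBp": params.D0_OBp + params.i_2 * r_mat * w_i,
        "Q_MSC": params.Q0_MSC + params.i_3 * (1.0 - r_runx2) * w_i,
        "Q_OBp": params.Q0_OBp,
    }
    return {k: max(v, 0.0) for k, v in rates.items()}


def lineage_rhs(state: LineageState, rates: dict[str, float]) -> dict[str, float]:
    """Compartment derivatives for given instantaneous rates."""
    for k, v in rates.items():
        if v < 0:
            raise LineageError(f"negative rate {k}={v}")
    bmsc, obp, oba = state.BMSC, state.OBp, state.OBa
    return {
        "BMSC": rates["P_MSC"] * bmsc - (rates["D_MSC"] + rates["Q_MSC"]) * bmsc,
        "MSCq": rates["Q_MSC"] * bmsc + rates["Q_OBp"] * obp,
        "OBp": (rates["P_OBp"] * obp + rates["D_MSC"] * bmsc
                - (rates["D_OBp"] + rates["Q_OBp"]) * obp),
        "OBa": rates["P_OBa"] * oba + rates["D_OBp"] * obp,
    }


@dataclass
class LineageTrajectory:
    t: np.ndarray                      # days
    y: np.ndarray                      # (n_times, 4) in COMPARTMENTS order

    def __getitem__(self, compartment: str) -> np.ndarray:
        return self.y[:, COMPARTMENTS.index(compartment)]

    def total(self) -> np.ndarray:
        return self.y.sum(axis=1)

    def at_day(self, day: float) -> LineageState:
        if day < self.t[0] - 1e-9 or day > self.t[-1] + 1e-9:
            raise LineageError(f"day {day} outside simulated horizon "
                               f"[{self.t[0]}, {self.t[-1]}]")
        vals = [float(np.interp(day, self.t, self.y[:, i])) for i in range(4)]
        return LineageState(day, *vals)

    def states(self) -> list[LineageState]:
        return [LineageState(float(tk), *map(float, self.y[k]))
                for k, tk in enumerate(self.t)]


def simulate_lineage(params: LineageParams, schedule: TreatmentSchedule,
                     tf: dict[str, float], horizon_days: float = 29.0,
                     initial: LineageState | None = None,
                     points_per_day: int = 4,
                     rtol: float = 1e-9, atol: float = 1e-12,
                     ) -> LineageTrajectory:
    """Integrate the compartment system from day 0 to ``horizon_days``.

    Rates are piecewise constant between delivery-window boundaries, so the
    integration restarts at each boundary.  Default initial condition: 100%
    BMSC, mass 1, at day 0.
    """
    if horizon_days < 1:
        raise ValueError("horizon must be >= 1 day")
    if initial is None:
        initial = LineageState(0.0, 1.0, 0.0, 0.0, 0.0)
    if initial.BMSC <= 0:
        raise ValueError("initial BMSC must be > 0")

    breaks = {0.0, float(horizon_days)}
    for _, day, _ in schedule.events:
        for b in (day, day + params.t_p):
            if 0.0 < b < horizon_days:
                breaks.add(float(b))
    breaks = sorted(breaks)

    t_grid = np.unique(np.concatenate(
        [np.linspace(0, horizon_days, int(horizon_days * points_per_day) + 1),
         np.array(breaks)]))

    def f(t, y):
        st = LineageState(t, *y)
        rates = effective_rates(t, params, schedule, tf)
        d = lineage_rhs(st, rates)
        return [d[c] for c in COMPARTMENTS]

    ts, ys = [], []
    y = np.array([initial.BMSC, initial.MSCq, initial.OBp, initial.OBa])
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        seg = t_grid[(t_grid >= t0) & (t_grid <= t1)]
        mid = 0.5 * (t0 + t1)

        def f_seg(t, y, _mid=mid):
            # rates constant within the segment; evaluate at midpoint
            st = LineageState(t, *y)
            rates = effective_rates(_mid, params, schedule, tf)
            d = lineage_rhs(st, rates)
            return [d[c] for c in COMPARTMENTS]

        sol = solve_ivp(f_seg, (t0, t1), y, method="LSODA", t_eval=seg,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise LineageError(f"solver failure near day {sol.t[-1]:.3f}: "
                               f"{sol.message}")
        ts.append(sol.t)
        ys.append(sol.y.T)
        y = sol.y[:, -1]

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys)
    t_out, idx = np.unique(t_all, return_index=True)
    y_out = np.clip(y_all[idx], 0.0, None)
    return LineageTrajectory(t_out, y_out)


def observables(traj: LineageTrajectory,
                mass_days: tuple[float, ...] = (1, 4, 8, 11),
                oba_day: float = 29.0,
                control_oba: float | None = None) -> dict:
    """Experiment-matched summaries of a lineage trajectory.

    Returns total mass at ``mass_days`` normalized to the first requested day
    (the dsDNA readout) and OBa at ``oba_day`` (the calcium-deposition
    readout), normalized to ``control_oba`` when provided.
    """
    masses = {}
    for d in mass_days:
        masses[d] = traj.at_day(d).total()
    ref = masses[mass_days[0]]
    mass_norm = {d: m / ref for d, m in masses.items()}
    oba = traj.at_day(oba_day).OBa
    if control_oba is not None:
        if control_oba <= 0:
            raise LineageError("control OBa must be positive for normalization")
        oba = oba / control_oba
    return {"total_mass_norm": mass_norm, "oba": oba, "oba_day": oba_day}
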