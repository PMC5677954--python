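"""Mass-action molecular ODE system.

For every tracked phospho form M the dynamics follow

    d[pM]/dt = sum_j a_j [pA_j] ([M]) - sum_j d_j [I_j] [pM],   [M] = C_M - [pM]

with a_j the phosphorylation/association rate of the target species, [pA_j]
the active concentrations of its upstream activators and [I_j] the
concentrations of its inhibitors; species with no explicit inhibitor
dephosphorylate against an unmodeled unit phosphatase pool.  Ligand-receptor
complexes obey the same form with association/dissociation rates and the
receptor conservation free + complexed = R_total.

Time is in hours (signaling settles within a few hours); concentrations are
in arbitrary units with conserved totals defaulting to 1, because the assay
data the model is fitted to are relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import (ACTIVATE, INHIBIT, SignalingNetwork,
                      kinetic_parameter_ids)

HOURS_PER_DAY = 24.0
#: reference dose (ng/ml) mapped to 1.0 concentration unit
DOSE_SCALE_NG_PER_ML = 50.0
#: trajectory values below this are treated as solver round-off and clipped
NEG_TOL = 1e-9


class SignalingError(RuntimeError):
    pass


@dataclass
class KineticParams:
    """Rate constants, keyed by parameter id (``a_<species>`` / ``d_<species>``
    / ``d_TF``), units 1/(concentration·hour)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if v <= 0:
                raise ValueError(f"rate {k!r} must be positive, got {v}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def require(self, net: SignalingNetwork) -> None:
        missing = [p for p in kinetic_parameter_ids(net) if p not in self.values]
        if missing:
            raise SignalingError(f"missing kinetic parameters: {missing}")

    def replace(self, **updates: float) -> "KineticParams":
        vals = dict(self.values)
        vals.update(updates)
        return KineticParams(vals)


@dataclass
class SpeciesState:
    t: float                              # hours
    concentrations: dict[str, float]


@dataclass
class TreatmentSchedule:
    """Ordered cytokine delivery events: (cytokine, day, dose in ng/ml)."""

    events: list[tuple[str, int, float]]
    scenario_label: str = ""

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e[1])
        for cyt, day, dose in self.events:
            if cyt not in ("BMP2", "IGF1"):
                raise ValueError(f"unknown cytokine {cyt!r}")
            if day < 0 or dose <= 0:
                raise ValueError(f"invalid event ({cyt}, {day}, {dose})")

    @property
    def event_days(self) -> list[int]:
        return [d for _, d, _ in self.events]

    def first_day(self) -> int | None:
        return self.events[0][1] if self.events else None

    def last_day(self) -> int | None:
        return self.events[-1][1] if self.events else None

    def ligand_level(self, cytokine: str, t_hours: float,
                     decay_per_hour: float = 0.0) -> float:
        """Ligand concentration (units of 50 ng/ml) at time ``t_hours``.

        Step input held constant after delivery; optional exponential decay.
        """
        level = 0.0
        for cyt, day, dose in self.events:
            if cyt != cytokine:
                continue
            t0 = day * HOURS_PER_DAY
            if t_hours >= t0:
                amt = dose / DOSE_SCALE_NG_PER_ML
                if decay_per_hour > 0:
                    amt *= np.exp(-decay_per_hour * (t_hours - t0))
                level += amt
        return level


# ---------------------------------------------------------------------------
# compiled model
# ---------------------------------------------------------------------------

class _Compiled:
    """Array form of the network for fast RHS evaluation."""

    def __init__(self, net: SignalingNetwork, params: KineticParams):
        params.require(net)
        self.net = net
        self.names = net.dynamic_species()
        self.index = {s: i for i, s in enumerate(self.names)}
        n = len(self.names)
        self.C = np.array([net.total_of(s) for s in self.names])
        paired = set(net.paired_dynamic())
        self.a = np.array([params[f"a_{s}"] for s in self.names])
        self.d = np.array([params[f"d_{s}"] if s in paired else params["d_TF"]
                           for s in self.names])
        inputs = set(net.input_species())

        act_t, act_s, act_w, act_u = [], [], [], []    # dynamic-source activators
        in_t, in_name, in_w = [], [], []               # input-source activators
        inh_t, inh_s = [], []
        iinh_t, iinh_name, iinh_w = [], [], []         # input-source inhibitors
        for e in net.edges:
            ti = self.index[e.target]
            if e.sign == ACTIVATE:
                if e.source in inputs:
                    in_t.append(ti); in_name.append(e.source); in_w.append(e.weight)
                else:
                    act_t.append(ti); act_s.append(self.index[e.source])
                    act_w.append(e.weight)
                    act_u.append(e.source_form == "unphospho")
            elif e.source in inputs:
                iinh_t.append(ti); iinh_name.append(e.source)
                iinh_w.append(e.weight)
            else:
                inh_t.append(ti); inh_s.append(self.index[e.source])
        self.act_t = np.array(act_t, dtype=int)
        self.act_s = np.array(act_s, dtype=int)
        self.act_w = np.array(act_w)
        self.act_u = np.array(act_u, dtype=bool)
        self.in_t = np.array(in_t, dtype=int)
        self.in_name = in_name
        self.in_w = np.array(in_w)
        self.inh_t = np.array(inh_t, dtype=int)
        self.inh_s = np.array(inh_s, dtype=int)
        self.iinh_t = np.array(iinh_t, dtype=int)
        self.iinh_name = iinh_name
        self.iinh_w = np.array(iinh_w)
        # species with an explicit inhibitor lose the implicit unit phosphatase
        self.has_inh = np.zeros(n, dtype=bool)
        self.has_inh[self.inh_t] = True
        self.has_inh[self.iinh_t] = True

    def rhs(self, y: np.ndarray, u: dict[str, float]) -> np.ndarray:
        yc = np.clip(y, 0.0, self.C)
        src = np.where(self.act_u, self.C[self.act_s] - yc[self.act_s],
                       yc[self.act_s])
        act = np.zeros_like(yc)
        np.add.at(act, self.act_t, self.act_w * src)
        if len(self.in_t):
            uin = np.array([u.get(nm, 0.0) for nm in self.in_name])
            np.add.at(act, self.in_t, self.in_w * uin)
        inh = np.where(self.has_inh, 0.0, 1.0)
        np.add.at(inh, self.inh_t, yc[self.inh_s])
        if len(self.iinh_t):
            uinh = np.array([u.get(nm, 0.0) for nm in self.iinh_name])
            np.add.at(inh, self.iinh_t, self.iinh_w * uinh)
        return self.a * act * (self.C - yc) - self.d * inh * yc


def rhs(state: SpeciesState, params: KineticParams,
        net: SignalingNetwork) -> dict[str, float]:
    """Instantaneous derivatives d[pM]/dt for every dynamic species.

    Activator/inhibitor concentrations are read from ``state``; input species
    (ligands or constant pools) are read from ``state`` as well.
    """
    comp = _Compiled(net, params)
    y = np.empty(len(comp.names))
    for i, s in enumerate(comp.names):
        c = state.concentrations.get(s, 0.0)
        if c < 0:
            raise SignalingError(f"negative concentration for {s!r}: {c}")
        y[i] = c
    u = {s: state.concentrations.get(s, 0.0) for s in net.input_species()}
    dy = comp.rhs(y, u)
    return dict(zip(comp.names, dy))


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclass
class SignalingTrajectory:
    net: SignalingNetwork
    t: np.ndarray                      # hours
    y: np.ndarray                      # (n_times, n_dynamic)
    names: list[str] = field(default_factory=list)

    def __getitem__(self, species: str) -> np.ndarray:
        """Concentration time series; algebraic species via conservation."""
        if species in self.names:
            return self.y[:, self.names.index(species)]
        for ph, base, total_id in self.net.pairs:
            if base == species:
                return self.net.totals[total_id] - self[ph]
        raise KeyError(species)

    def states(self) -> list[SpeciesState]:
        out = []
        for k, tk in enumerate(self.t):
            conc = {s: float(self.y[k, i]) for i, s in enumerate(self.names)}
            for ph, base, total_id in self.net.pairs:
                conc[base] = self.net.totals[total_id] - conc[ph]
            out.append(SpeciesState(float(tk), conc))
        return out

    def to_frame(self, scenario: str = ""):
        import pandas as pd
        rows = []
        for i, s in enumerate(self.names):
            for k, tk in enumerate(self.t):
                rows.append((float(tk), s, float(self.y[k, i]), scenario))
        return pd.DataFrame(rows, columns=["time_h", "species", "value",
                                           "scenario"])


def simulate_signaling(net: SignalingNetwork, params: KineticParams,
                       schedule: TreatmentSchedule,
                       t_grid: np.ndarray | None = None,
                       initial: SpeciesState | None = None,
                       ligand_decay_per_hour: float = 0.0,
                       rtol: float = 1e-6, atol: float = 1e-9,
                       ) -> SignalingTrajectory:
    """Integrate the molecular system over ``t_grid`` (hours).

    Ligand inputs switch on at their scheduled days (``day*24`` hours) and
    persist (optionally with exponential decay).  Integration is restarted at
    each delivery so the step input is resolved exactly.  Default initial
    condition: every phospho form at 0.
    """
    comp = _Compiled(net, params)
    if t_grid is None:
        t_end = ((schedule.last_day() or 0) + 2) * HOURS_PER_DAY
        t_grid = np.arange(0.0, t_end + 1e-9, 0.25)
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")

    if initial is None:
        y0 = np.zeros(len(comp.names))
    else:
        y0 = np.array([initial.concentrations.get(s, 0.0) for s in comp.names])
    if np.any(y0 < 0):
        raise SignalingError("negative initial concentration")

    event_times = sorted({d * HOURS_PER_DAY for d in schedule.event_days
                          if t_grid[0] < d * HOURS_PER_DAY < t_grid[-1]})
    breaks = [t_grid[0]] + event_times + [t_grid[-1]]

    def make_f(ligs: dict[str, float] | None = None):
        def f(t, y):
            u = {lig: schedule.ligand_level(lig, t, ligand_decay_per_hour)
                 for lig in ("BMP2", "IGF1")}
            return comp.rhs(y, u)
        return f

    ts, ys = [], []
    y = y0
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        seg_mask = (t_grid >= t0) & (t_grid <= t1)
        t_eval = np.unique(np.concatenate([[t0], t_grid[seg_mask], [t1]]))
        sol = solve_ivp(make_f(), (t0, t1), y, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise SignalingError(
                f"solver failure near t={sol.t[-1]:.3f} h: {sol.message}")
        keep = np.isin(sol.t, t_grid[seg_mask])
        ts.append(sol.t[keep])
        ys.append(sol.y.T[keep])
        y = sol.y[:, -1]

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys)
    t_out, idx = np.unique(t_all, return_index=True)
    y_out = y_all[idx]

    if np.any(y_out < -NEG_TOL):
        worst = float(y_out.min())
        raise SignalingError(f"negative concentration excursion {worst:.3e}")
    y_out = np.clip(y_out, 0.0, None)
    return SignalingTrajectory(net, t_out, y_out, list(comp.names))


# ---------------------------------------------------------------------------
# TF readout
# ---------------------------------------------------------------------------

def tf_readout(traj: SignalingTrajectory, net: SignalingNetwork,
               window: tuple[float, float] | None = None) -> dict[str, float]:
    """Scalar activation level in [0, 1] for each TF output.

    TF expression changes much more slowly than phosphorylation, so each TF's
    activity is summarized from its *immediate upstream* signaling proteins:
    the time-average over the readout window of the upstream phospho fraction
    [p-upstream]/C, averaged across upstream edges.  For beta-catenin the
    upstream species is GSK3beta, whose *phosphorylated* (kinase-inactive)
    pool is what releases active beta-catenin, so the phospho fraction is the
    correct activating signal there too.
    """
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    t0, t1 = window if window is not None else (traj.t[0], traj.t[-1])
    mask = (traj.t >= t0) & (traj.t <= t1)
    if mask.sum() < 2:
        mask = np.ones_like(traj.t, dtype=bool)
    tm = traj.t[mask]
    span = tm[-1] - tm[0]

    out: dict[str, float] = {}
    for tf in net.tf_species():
        fracs = []
        for e in net.upstream_of(tf):
            if e.source in net.input_species():
                continue
            frac = traj[e.source][mask] / net.total_of(e.source)
            fracs.append(np.trapezoid(frac, tm) / span if span > 0
                         else float(frac.mean()))
        out[tf] = float(np.clip(np.mean(fracs) if fracs else 0.0, 0.0, 1.0))
    return out
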