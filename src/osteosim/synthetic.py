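"""Synthetic assay-data generator.

Emulates the study design's measurement tables for the six treatment
scenarios (control, I1, B1, I1B1, I1B4, B1I4; cytokine initial + delivery
day, 50 ng/ml each):

* RPPA-like phospho time courses of 12 signaling proteins for the four
  scenarios that carry RPPA data (I1, B1, I1B4, B1I4), sampled at offsets
  from the *last* delivery (single-cytokine groups were assayed at day 1,
  dual-cytokine groups at day 4);
* dsDNA total cell mass at days 1/4/8/11, 4 replicates, all six scenarios;
* ARS calcium deposition at day 28 normalized to control, 4 replicates;
* an optional ALP-like preosteoblast index.

Noise is multiplicative lognormal (assays are positive-valued), mean
preserving, with a configurable coefficient of variation.  Identical seeds
yield identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .defaults import default_kinetic_params, default_lineage_params
from .lineage import LineageParams
from .network import SignalingNetwork, build_canonical_network
from .pipeline import simulate_scenario
from .signaling import HOURS_PER_DAY, KineticParams, TreatmentSchedule

SCENARIOS = ("control", "I1", "B1", "I1B1", "I1B4", "B1I4")
RPPA_SCENARIOS = ("I1", "B1", "I1B4", "B1I4")
DEFAULT_DOSE = 50.0  # ng/ml

#: the 12 signaling proteins covered by the RPPA-like table -> network species
RPPA_PROTEINS: dict[str, str] = {
    "p38 MAPK": "p38", "SMAD1/5": "SMAD15", "ERK": "ERK", "GSK3b": "GSK3b",
    "S6": "S6", "Akt": "Akt", "mTOR": "mTOR", "p70S6K": "p70S6K",
    "c-Raf": "cRaf", "MEK": "MEK", "TAK1": "TAK1", "PI3K": "PI3K",
}

DEFAULT_RPPA_OFFSETS_H = (0.0, 0.25, 0.5, 1.0, 2.0, 6.0, 12.0, 24.0, 48.0)
DSDNA_DAYS = (1, 4, 8, 11)
ARS_DAY = 28.0
N_REPLICATES = 4


def scenario_table(dose: float = DEFAULT_DOSE) -> list[TreatmentSchedule]:
    """The six treatment schedules of the experimental design."""
    def ev(cyt, day):
        return (cyt, day, dose)
    return [
        TreatmentSchedule([], "control"),
        TreatmentSchedule([ev("IGF1", 1)], "I1"),
        TreatmentSchedule([ev("BMP2", 1)], "B1"),
        TreatmentSchedule([ev("IGF1", 1), ev("BMP2", 1)], "I1B1"),
        TreatmentSchedule([ev("IGF1", 1), ev("BMP2", 4)], "I1B4"),
        TreatmentSchedule([ev("BMP2", 1), ev("IGF1", 4)], "B1I4"),
    ]


@dataclass
class SyntheticDataset:
    rppa: pd.DataFrame     # scenario, protein, time_h, value
    dsdna: pd.DataFrame    # scenario, day, replicate, mass
    ars: pd.DataFrame      # scenario, replicate, oba_raw, ars_norm
    alp: pd.DataFrame      # scenario, day, obp_fraction
    truth: dict
    seed: int
    tf_readouts: dict[str, dict[str, float]] = field(default_factory=dict)

    def save(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ("rppa", "dsdna", "ars", "alp"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            written.append(p)
        p = outdir / "truth.json"
        p.write_text(json.dumps(
            {"seed": self.seed, "truth": self.truth,
             "tf_readouts": self.tf_readouts}, indent=1, sort_keys=True))
        written.append(p)
        return written


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate(seed: int = 0, noise_cv: float = 0.1,
             kparams: KineticParams | None = None,
             lparams: LineageParams | None = None,
             net: SignalingNetwork | None = None,
             rppa_offsets_h: tuple[float, ...] = DEFAULT_RPPA_OFFSETS_H,
             ) -> SyntheticDataset:
    """Forward-simulate all six scenarios and emit noisy assay tables."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    kparams = kparams or default_kinetic_params()
    lparams = lparams or default_lineage_params()
    net = net or build_canonical_network()

    results = {}
    for sched in scenario_table():
        results[sched.scenario_label] = simulate_scenario(
            sched, kparams, lparams, net=net)

    rppa_rows = []
    for scen in RPPA_SCENARIOS:
        res = results[scen]
        anchor = res.schedule.last_day() * HOURS_PER_DAY
        times = anchor + np.asarray(rppa_offsets_h)
        for protein, species in RPPA_PROTEINS.items():
            mean = np.interp(times, res.signaling.t, res.signaling[species])
            noisy = mean * _lognormal_factors(rng, noise_cv, len(times))
            for t_off, v in zip(rppa_offsets_h, noisy):
                rppa_rows.append((scen, protein, float(t_off), float(v)))
    rppa = pd.DataFrame(rppa_rows,
                        columns=["scenario", "protein", "time_h", "value"])

    dsdna_rows = []
    for scen in SCENARIOS:
        traj = results[scen].lineage
        for day in DSDNA_DAYS:
            mean = traj.at_day(day).total()
            reps = mean * _lognormal_factors(rng, noise_cv, N_REPLICATES)
            for r, v in enumerate(reps, start=1):
                dsdna_rows.append((scen, day, r, float(v)))
    dsdna = pd.DataFrame(dsdna_rows,
                         columns=["scenario", "day", "replicate", "mass"])

    control_oba = results["control"].lineage.at_day(ARS_DAY).OBa
    ars_rows = []
    for scen in SCENARIOS:
        mean = results[scen].lineage.at_day(ARS_DAY).OBa
        reps = mean * _lognormal_factors(rng, noise_cv, N_REPLICATES)
        for r, v in enumerate(reps, start=1):
            ars_rows.append((scen, r, float(v), float(v / control_oba)))
    ars = pd.DataFrame(ars_rows,
                       columns=["scenario", "replicate", "oba_raw", "ars_norm"])

    alp_rows = []
    for scen in SCENARIOS:
        traj = results[scen].lineage
        for day in (6, 11):
            st = traj.at_day(day)
            alp_rows.append((scen, day, float(st.OBp / st.total())))
    alp = pd.DataFrame(alp_rows, columns=["scenario", "day", "obp_fraction"])

    truth = {"kinetic": dict(kparams.values),
             "lineage": {k: float(v) for k, v in vars(lparams).items()}}
    tf_readouts = {scen: results[scen].tf for scen in SCENARIOS}
    return SyntheticDataset(rppa, dsdna, ars, alp, truth, seed, tf_readouts)
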