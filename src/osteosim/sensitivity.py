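"""Global sensitivity analysis: LHS + PRCC and eFAST indices.

Two complementary estimators of how strongly each parameter shapes a scalar
model output when all parameters are perturbed together:

* PRCC — Spearman partial rank correlation coefficient between a parameter
  and the output after rank-transforming everything and regressing out all
  other parameters; monotone-influence measure in [-1, 1], computed on a
  Latin hypercube sample.
* eFAST — extended Fourier Amplitude Sensitivity Test: each parameter in
  turn drives the input space along a periodic search curve at a distinct
  frequency; the output variance concentrated at that frequency (and its
  harmonics) yields the first-order ("main effect") index, and the variance
  in the complementary low-frequency band yields the total-effect index.
  A dummy parameter provides a significance floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata


@dataclass
class SensitivityResult:
    names: list[str]
    prcc: dict[str, float] = field(default_factory=dict)
    main_effect: dict[str, float] = field(default_factory=dict)
    total_effect: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    output_label: str = ""
    n_samples: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nm in self.names:
            rows.append((nm, self.prcc.get(nm, np.nan),
                         self.main_effect.get(nm, np.nan),
                         self.total_effect.get(nm, np.nan),
                         100.0 * self.main_effect.get(nm, np.nan)))
        return pd.DataFrame(rows, columns=["parameter", "prcc", "main_effect",
                                           "total_effect", "share_pct"])


# ---------------------------------------------------------------------------
# Latin hypercube sampling
# ---------------------------------------------------------------------------

def lhs_sample(bounds: dict[str, tuple[float, float]], n: int,
               seed: int | None = None) -> pd.DataFrame:
    """Latin hypercube sample: one point per stratum per parameter marginal."""
    names = list(bounds)
    lows = np.array([bounds[k][0] for k in names], dtype=float)
    highs = np.array([bounds[k][1] for k in names], dtype=float)
    if np.any(~np.isfinite(lows)) or np.any(~np.isfinite(highs)) \
            or np.any(lows >= highs):
        raise ValueError("bounds must be finite with low < high")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    return pd.DataFrame(qmc.scale(unit, lows, highs), columns=names)


# ---------------------------------------------------------------------------
# PRCC
# ---------------------------------------------------------------------------

def _residual(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef

def prcc(samples: pd.DataFrame, outputs: np.ndarray
         ) -> tuple[dict[str, float], dict[str, str]]:
    """Partial rank correlation of each parameter with the output.

    Constant output makes the coefficient undefined; it is reported as 0
    with a flag.  Requires at least 3 more samples than parameters.
    """
    y = np.asarray(outputs, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("outputs must be finite")
    X = samples.to_numpy(dtype=float)
    n, d = X.shape
    if n < d + 3:
        raise ValueError(f"need >= {d + 3} samples for {d} parameters, got {n}")
    flags: dict[str, str] = {}
    if np.ptp(y) == 0:
        return ({nm: 0.0 for nm in samples.columns},
                {nm: "constant_output" for nm in samples.columns})
    Xr = np.apply_along_axis(rankdata, 0, X)
    yr = rankdata(y)
    out: dict[str, float] = {}
    for j, nm in enumerate(samples.columns):
        others = np.delete(Xr, j, axis=1)
        rx = _residual(Xr[:, j], others)
        ry = _residual(yr, others)
        denom = np.sqrt((rx @ rx) * (ry @ ry))
        if denom == 0:
            out[nm] = 0.0
            flags[nm] = "degenerate"
        else:
            out[nm] = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    return out, flags


# ---------------------------------------------------------------------------
# eFAST
# ---------------------------------------------------------------------------

DUMMY = "_dummy"


def _efast_frequencies(d: int, n: int, M: int) -> tuple[int, np.ndarray]:
    """Driving frequency for the parameter of interest and complementary
    frequencies for the other d-1 parameters.

    Complementary frequencies stay at or below omega_max/(2M) so their first
    M harmonics cannot alias onto the driving harmonics; within that band
    they are chosen as distinct odd values (highest first) to decorrelate the
    complementary parameters along a single search curve.
    """
    omega_max = (n - 1) // (2 * M)
    if omega_max < 2 * M:
        raise ValueError(
            f"n={n} too small for M={M}; need n >= {4 * M * M + 1}")
    comp_max = max(omega_max // (2 * M), 1)
    candidates = list(range(comp_max if comp_max % 2 else comp_max - 1, 0, -2))
    candidates += [c for c in range(comp_max, 0, -1) if c not in candidates]
    comp = np.array([candidates[k % len(candidates)] for k in range(d - 1)])
    return omega_max, comp


def efast(model, bounds: dict[str, tuple[float, float]],
          n_per_curve: int = 513, M_harmonics: int = 4,
          n_resample: int = 3, seed: int | None = None,
          include_dummy: bool = True) -> SensitivityResult:
    """eFAST main/total effect indices of ``model`` over ``bounds``.

    ``model`` maps a dict of parameter values to a scalar and must be
    deterministic.  ``n_per_curve`` points are taken along each of
    ``n_resample`` random-phase search curves per parameter; variance at the
    driving frequency's first ``M_harmonics`` harmonics gives the main
    effect, the complementary band gives the total effect.  When
    ``include_dummy`` a non-influential dummy parameter is appended as a
    significance threshold.
    """
    names = list(bounds)
    if include_dummy:
        names = names + [DUMMY]
    d = len(names)
    lows = np.array([bounds.get(k, (0.0, 1.0))[0] for k in names])
    highs = np.array([bounds.get(k, (0.0, 1.0))[1] for k in names])
    rng = np.random.default_rng(seed)
    n = int(n_per_curve)
    if n % 2 == 0:
        n += 1
    omega_i, comp = _efast_frequencies(d, n, M_harmonics)
    s = (2.0 * np.pi / n) * np.arange(n)

    main = np.zeros(d)
    total = np.zeros(d)
    for j in range(d):
        omegas = np.empty(d)
        omegas[j] = omega_i
        omegas[np.arange(d) != j] = comp
        Sm = np.zeros(n_resample)
        St = np.zeros(n_resample)
        for r in range(n_resample):
            phase = rng.uniform(0, 2 * np.pi, size=d)
            x_unit = 0.5 + np.arcsin(np.sin(omegas[None, :] * s[:, None]
                                            + phase[None, :])) / np.pi
            X = lows + x_unit * (highs - lows)
            y = np.array([model({nm: row[k] for k, nm in enumerate(names)
                                 if nm != DUMMY})
                          for row in X], dtype=float)
            coeffs = np.fft.rfft(y - y.mean()) / n
            power = 2.0 * np.abs(coeffs) ** 2          # variance per frequency
            V = power[1:].sum()
            if V <= 0:
                continue
            harmonics = omega_i * np.arange(1, M_harmonics + 1)
            Vi = power[harmonics[harmonics < len(power)]].sum()
            # complementary set lives below omega_i/2: its driving frequencies
            # are <= omega_i/(2M) so their first M harmonics stay in this band
            cutoff = max(omega_i // 2, 1)
            Vc = power[1:cutoff + 1].sum()
            Sm[r] = Vi / V
            St[r] = 1.0 - Vc / V
        main[j] = Sm.mean()
        total[j] = St.mean()

    result = SensitivityResult(
        names=names,
        main_effect={nm: float(np.clip(main[j], 0, 1))
                     for j, nm in enumerate(names)},
        total_effect={nm: float(np.clip(total[j], 0, 1))
                      for j, nm in enumerate(names)},
        n_samples=n * n_resample * d, seed=seed)
    return result


def variance_share_report(result: SensitivityResult,
                          threshold: float = 0.02) -> pd.DataFrame:
    """Parameters whose main-effect variance share reaches ``threshold``
    (default 2%), sorted descending — the pie-chart filter."""
    rows = [(nm, share) for nm, share in result.main_effect.items()
            if nm != DUMMY and share >= threshold]
    rows.sort(key=lambda r: -r[1])
    return pd.DataFrame(rows, columns=["parameter", "share"])


# ---------------------------------------------------------------------------
# pipeline-facing wrappers
# ---------------------------------------------------------------------------

def cellular_output_factory(schedule, tf_readouts, base_params,
                            day: float = 29.0):
    """Scalar output for lineage-parameter GSA: OBa at ``day``."""
    from .lineage import simulate_lineage

    def output(values: dict[str, float]) -> float:
        params = base_params.replace(**values)
        traj = simulate_lineage(params, schedule, tf_readouts,
                                horizon_days=day)
        return traj.at_day(day).OBa
    return output


def molecular_output_factory(net, schedule, base_params, tf: str = "Runx2"):
    """Scalar output for kinetic-parameter GSA: a TF readout."""
    from .pipeline import scenario_tf_readouts

    def output(values: dict[str, float]) -> float:
        params = base_params.replace(**values)
        _, readouts = scenario_tf_readouts(net, params, schedule)
        return readouts[tf]
    return output


def run_prcc(model, bounds: dict[str, tuple[float, float]], n: int = 1000,
             seed: int | None = None, output_label: str = "") -> SensitivityResult:
    """LHS-sample ``bounds``, evaluate ``model`` per row, compute PRCC."""
    samples = lhs_sample(bounds, n, seed=seed)
    outputs = np.array([model(row.to_dict())
                        for _, row in samples.iterrows()])
    coeffs, flags = prcc(samples, outputs)
    return SensitivityResult(names=list(bounds), prcc=coeffs, flags=flags,
                             output_label=output_label, n_samples=n, seed=seed)
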