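import numpy as np
import pytest

from osteosim import (build_canonical_network, default_kinetic_params,
                      default_lineage_params, generate, scenario_table,
                      simulate_scenario)


@pytest.fixture(scope="session")
def net():
    return build_canonical_network()


@pytest.fixture(scope="session")
def kparams():
    return default_kinetic_params()


@pytest.fixture(scope="session")
def lparams():
    return default_lineage_params()


@pytest.fixture(scope="session")
def schedules():
    return {s.scenario_label: s for s in scenario_table()}


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-noise six-scenario dataset under ground-truth parameters."""
    return generate(seed=1, noise_cv=0.0)


@pytest.fixture(scope="session")
def scenario_results(net, kparams, lparams, schedules):
    """Full pipeline results for all six experimental scenarios."""
    return {label: simulate_scenario(s, kparams, lparams, net=net)
            for label, s in schedules.items()}


@pytest.fixture(scope="session")
def default_grid(kparams, lparams):
    from osteosim.screening import run_grid
    return run_grid(kparams, lparams)


def rk4(f, y0, t0, t1, dt):
    """Fixed-step classic Runge-Kutta integration (independent oracle)."""
    n = int(np.ceil((t1 - t0) / dt))
    t, y = t0, np.asarray(y0, dtype=float)
    for _ in range(n):
        h = min(dt, t1 - t)
        if h <= 0:
            break
        k1 = np.asarray(f(t, y))
        k2 = np.asarray(f(t + h / 2, y + h / 2 * k1))
        k3 = np.asarray(f(t + h / 2, y + h / 2 * k2))
        k4 = np.asarray(f(t + h, y + h * k3))
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y
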