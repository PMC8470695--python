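import math

import numpy as np
import pytest

import crckinetics as ck


@pytest.fixture(scope="session")
def benchmark_suite():
    return ck.make_benchmark_suite(seed=0)


@pytest.fixture
def single_step():
    """One recruitment reaction with halftime exactly 1 s."""
    return ck.CRCParameters(rates=(math.log(2.0),), amplitude=1.0)


@pytest.fixture
def two_step():
    return ck.CRCParameters(rates=(0.2, 0.05), amplitude=1.0)


@pytest.fixture
def delayed_removal_params():
    return ck.CRCParameters(rates=(0.5, 0.05), detachment_delay=30.0,
                            amplitude=1.0, has_removal=True)


def noise_free_curve(model, interval=1.0, duration=300.0, seed=0):
    design = ck.SimulationDesign(n_cells=2, sampling_interval=interval, duration=duration,
                                 noise_sd_fraction=0.0, cell_scale_sd=0.0, seed=seed)
    return ck.simulate_curve(model, design)


def rng_models(seed, count, max_chain=4, allow_removal=True):
    """Random well-separated CRC parameterizations for property checks."""
    rng = np.random.default_rng(seed)
    models = []
    while len(models) < count:
        removal = allow_removal and bool(rng.integers(0, 2))
        m = int(rng.integers(1, max_chain + 1))
        n_rates = m + 1 if removal else m
        rates = np.exp(rng.uniform(np.log(1e-3), np.log(2.0), size=n_rates))
        if ck.core.rates_degenerate(rates, 1e-3):
            continue
        tau = float(rng.uniform(0.0, 100.0)) if removal else 0.0
        models.append(ck.CRCParameters(rates=tuple(rates), detachment_delay=tau,
                                       amplitude=float(rng.uniform(0.5, 2000.0)),
                                       has_removal=removal))
    return models
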