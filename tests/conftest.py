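import numpy as np
import pandas as pd
import pytest

from wt1sig import (
    ClinicalTable,
    ExpressionMatrix,
    SimulationConfig,
    simulate_series,
)


def make_expr(values, probes=None, samples=None, **kw):
    values = np.asarray(values, float)
    probes = probes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), **kw)


def make_clin(samples, os_time=None, os_event=None, **extra):
    n = len(samples)
    df = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    df["os_time"] = os_time if os_time is not None else np.arange(1, n + 1, dtype=float)
    df["os_event"] = os_event if os_event is not None else np.ones(n, int)
    for k, v in extra.items():
        df[k] = v
    return ClinicalTable(df)


@pytest.fixture(scope="session")
def planted_cohort():
    """Mid-size cohort with planted latent structure for recovery tests."""
    cfg = SimulationConfig(
        n_samples=200, n_probes=400, n_signal_probes=30, seed=11
    )
    expr, clin, truth = simulate_series(cfg)
    return expr, clin, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no expression-outcome structure (lambda=0, b=0, gamma=0)."""
    cfg = SimulationConfig(
        n_samples=150,
        n_probes=300,
        n_signal_probes=10,
        signal_loading_scale=0.0,
        driver_loading=0.0,
        hazard_coeff=0.0,
        seed=5,
    )
    expr, clin, truth = simulate_series(cfg)
    return expr, clin, truth
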