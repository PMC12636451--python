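import numpy as np
import pandas as pd
import pytest

from flymet import simulate as sim


@pytest.fixture
def toy_survival_table():
    """Two genotypes, small hand-checkable census counts."""
    from flymet.survival import SurvivalTable
    rows = [
        {"genotype": "a", "vial": "v1", "census_day": 3.5, "deaths": 0, "censored": 0},
        {"genotype": "a", "vial": "v1", "census_day": 7.0, "deaths": 2, "censored": 0},
        {"genotype": "a", "vial": "v1", "census_day": 10.5, "deaths": 1, "censored": 1},
        {"genotype": "b", "vial": "v2", "census_day": 7.0, "deaths": 3, "censored": 0},
    ]
    return SurvivalTable(pd.DataFrame(rows))


@pytest.fixture
def null_trace_set():
    """Artifact-free traces: no bleach, no treatment, no pH coupling, no noise."""
    spec = sim.TraceSimSpec(n_rois=3, bleach_rate=0.0, treatment_effect=0.0,
                            ph_coupling=0.0, noise_sd=0.0, seed=0)
    return sim.simulate_traces(spec)


@pytest.fixture
def small_flux_plate():
    return sim.simulate_flux_plate(sim.FluxSimSpec(n_wells=4, n_batches=2,
                                                   measurements_per_phase=3, seed=11))


def brute_holm(p):
    """Step-down Holm from its definition: sort ascending, multiply by
    (n - rank), enforce monotonicity, cap at 1."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min((n - rank) * p[idx], 1.0))
        adj[idx] = running
    return adj


def brute_bh(p):
    """Step-up Benjamini-Hochberg from its definition: sort descending,
    multiply by n/rank, enforce monotonicity from the largest down."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = n - rank_from_top          # ascending rank of this p-value
        running = min(running, min(n / k * p[idx], 1.0))
        adj[idx] = running
    return adj
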