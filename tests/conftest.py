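import numpy as np
import pandas as pd
import pytest

from rnadx.simulate import (
    SimulationConfig,
    simulate_allele_counts,
    simulate_expression_counts,
    simulate_junction_table,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=120,
        n_samples=24,
        n_junction_clusters=30,
        n_variants=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def expr_sim(small_config):
    return simulate_expression_counts(small_config)


@pytest.fixture(scope="session")
def junc_sim(small_config):
    return simulate_junction_table(small_config)


@pytest.fixture(scope="session")
def allele_sim(small_config):
    return simulate_allele_counts(small_config)


# ---------------------------------------------------------------------------
# brute-force oracles shared across test modules
# ---------------------------------------------------------------------------

def hochberg_brute(p):
    """Step-up Hochberg by direct evaluation of the recursion:
    adj_(k) = min(adj_(k+1), (m - k + 1) * p_(k)), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    running = 1.0
    for k in range(m - 1, -1, -1):
        running = min(running, (m - k) * sorted_p[k])
        adj[k] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_brute(p):
    """Step-up Benjamini-Hochberg: adj_(k) = min_{j >= k} (m / j) p_(j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    running = 1.0
    for k in range(m - 1, -1, -1):
        running = min(running, m / (k + 1) * sorted_p[k])
        adj[k] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj
    return out
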