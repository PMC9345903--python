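"""Shared fixtures: small hand-built graphs and session-scoped benchmarks."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from slscreen.synthetic import (
    SimConfig,
    generate_ccl_panel,
    generate_cohort,
    generate_drug_catalog,
    generate_go,
)


@pytest.fixture
def chain_graph() -> nx.DiGraph:
    """Three-term is_a chain G -> C -> R in the MF namespace."""
    g = nx.DiGraph()
    for t in ("R", "C", "G"):
        g.add_node(t, namespace="MF")
    g.add_edge("G", "C", etype="is_a")
    g.add_edge("C", "R", etype="is_a")
    return g


@pytest.fixture(scope="session")
def bench_config() -> SimConfig:
    """The default synthetic benchmark: 15 planted pairs among 1,500 candidates."""
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def bench_cohort(bench_config):
    return generate_cohort(bench_config)


@pytest.fixture(scope="session")
def bench_go(bench_config):
    return generate_go(bench_config)


@pytest.fixture(scope="session")
def bench_drugs(bench_config, bench_cohort):
    _, truth = bench_cohort
    catalog = generate_drug_catalog(truth, bench_config)
    panel = generate_ccl_panel(bench_config, truth, catalog)
    return catalog, panel


@pytest.fixture
def toy_mutation_matrix() -> pd.DataFrame:
    rng = np.random.default_rng(3)
    m = (rng.random((20, 50)) < 0.3).astype(int)
    return pd.DataFrame(
        m, index=[f"g{i}" for i in range(20)], columns=[f"s{j}" for j in range(50)]
    )
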