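"""Shared fixtures: small deterministic graphs and datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ammonet.data_model import FeatureTable, SampleMetadata
from ammonet.graphcore import Graph


@pytest.fixture
def two_triangles_bridge() -> Graph:
    """Two K3s (a,b,c) and (d,e,f) joined by the bridge c-d."""
    g = Graph()
    for u, v in [("a", "b"), ("a", "c"), ("b", "c"),
                 ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]:
        g.add_edge(u, v)
    return g


@pytest.fixture
def small_metadata() -> SampleMetadata:
    rows = []
    for i in range(1, 7):
        rows.append({"sample_id": f"s{i:02d}", "subject_id": f"R{i:02d}",
                     "group": "high" if i <= 3 else "low", "sex": "M"})
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def small_table(small_metadata) -> FeatureTable:
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=0.5, size=(5, 6)),
        index=[f"m{i}" for i in range(5)],
        columns=[f"s{i:02d}" for i in range(1, 7)],
    )
    return FeatureTable(layer="muscle_metabolome", level="metabolite", data=data)


def random_graph(rng: np.random.Generator, n_max: int = 7, p: float | None = None) -> Graph:
    """Erdos-Renyi draw used by oracle-equivalence tests."""
    n = int(rng.integers(1, n_max + 1))
    p = float(rng.uniform(0.1, 0.9)) if p is None else p
    g = Graph(nodes=[f"v{i:02d}" for i in range(n)])
    nodes = g.nodes
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g
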