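"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from mitonet import SyntheticSpec, correlation_matrix
from mitonet.pcit import CorrelationMatrix


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast-to-generate planted dataset used across module tests."""
    return SyntheticSpec(
        n_samples=100,
        modules=((8, 0.9), (8, 0.85)),
        n_background_genes=10,
        isolated_cluster_size=6,
        tf_count=4,
        n_low_expression=3,
        seed=7,
    )


def random_correlation(seed: int, n: int) -> CorrelationMatrix:
    """Random valid correlation matrix (sample correlation of random data)."""
    rng = np.random.default_rng(seed)
    n_samples = n + int(rng.integers(5, 15))
    data = pd.DataFrame(
        rng.standard_normal((n, n_samples)),
        index=[f"g{i:03d}" for i in range(n)],
    )
    return correlation_matrix(data)


def radiality_oracle(net) -> dict[str, float]:
    """Brute-force radiality: hand-written Floyd-Warshall all-pairs distances."""
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    inf = float("inf")
    dist = [[inf] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0.0
    for a, b in net.edges:
        dist[index[a]][index[b]] = 1.0
        dist[index[b]][index[a]] = 1.0
    for k in range(n):
        dk = dist[k]
        for i in range(n):
            dik = dist[i][k]
            if dik == inf:
                continue
            di = dist[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < di[j]:
                    di[j] = alt
    result: dict[str, float] = {}
    for i, v in enumerate(nodes):
        comp = [j for j in range(n) if dist[i][j] < inf]
        if len(comp) == 1:
            result[v] = math.nan
            continue
        diameter = max(dist[a][b] for a in comp for b in comp)
        mean_dist = sum(dist[i][j] for j in comp if j != i) / (len(comp) - 1)
        result[v] = (diameter + 1.0 - mean_dist) / diameter
    return result
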