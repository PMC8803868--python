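import numpy as np
import pytest

import mapgraph as mg
from mapgraph.graphs import MapGraph


@pytest.fixture(scope="session")
def small_cohort():
    """Four-condition mini cohort shared across read-only tests."""
    cfg = mg.CohortConfig(
        counts={
            "control": 3,
            "short_training": 3,
            "early_cuff": 3,
            "adapted_sham": 3,
        },
        seed=1234,
    )
    return mg.generate_cohort(cfg, with_trials=False)


@pytest.fixture(scope="session")
def control_map(small_cohort):
    return small_cohort.maps[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_map_graph(rng, n, density=0.55):
    """Random sparse weighted graph with positions straddling the midline."""
    a = rng.random((n, n))
    a = (a + a.T) / 2
    a[a < 1 - density] = 0.0
    np.fill_diagonal(a, 0.0)
    pos = (np.arange(n) - n / 2 + 0.5) * 20.0
    return MapGraph(weights=np.clip(a, 0, 1), positions_um=pos, positions_norm=pos / 3.2)


# ---------------------------------------------------------------------------
# independent brute-force oracles for the weighted graph metrics


def oracle_modularity(w, labels):
    n = len(w)
    l = sum(w[i][j] for i in range(n) for j in range(n))
    k = [sum(w[i][j] for j in range(n)) for i in range(n)]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i][j] - k[i] * k[j] / l
    return q / l


def oracle_module_degree_zscore(w, labels):
    n = len(w)
    z = [0.0] * n
    for m in set(labels):
        members = [i for i in range(n) if labels[i] == m]
        if len(members) < 2:
            continue
        k_in = [sum(w[i][j] for j in members) for i in members]
        mean = sum(k_in) / len(k_in)
        sd = (sum((v - mean) ** 2 for v in k_in) / len(k_in)) ** 0.5
        if sd > 1e-12:
            for idx, i in enumerate(members):
                z[i] = (k_in[idx] - mean) / sd
    return z


def oracle_participation(w, labels):
    n = len(w)
    y = [0.0] * n
    for i in range(n):
        k_i = sum(w[i][j] for j in range(n))
        if k_i <= 1e-12:
            continue
        s = 0.0
        for m in set(labels):
            k_im = sum(w[i][j] for j in range(n) if labels[j] == m)
            s += (k_im / k_i) ** 2
        y[i] = 1.0 - s
    return y


def oracle_assortativity(w):
    n = len(w)
    k = [sum(w[i][j] for j in range(n)) for i in range(n)]
    links = [(i, j) for i in range(n) for j in range(i + 1, n) if w[i][j] > 0]
    if len(links) < 2:
        return float("nan")
    l = sum(w[i][j] for i, j in links)
    m_prod = sum(w[i][j] * k[i] * k[j] for i, j in links) / l
    m_sum = sum(w[i][j] * (k[i] + k[j]) / 2 for i, j in links) / l
    m_sq = sum(w[i][j] * (k[i] ** 2 + k[j] ** 2) / 2 for i, j in links) / l
    den = m_sq - m_sum**2
    if abs(den) < 1e-12:
        return float("nan")
    return (m_prod - m_sum**2) / den


def all_partitions(n):
    """Every set partition of range(n) as a restricted-growth label list."""

    def rec(prefix, maxv):
        if len(prefix) == n:
            yield list(prefix)
            return
        for v in range(maxv + 2):
            yield from rec(prefix + [v], max(maxv, v))

    yield from rec([], -1)
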