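"""Graph representation and weighted-metric quantification of map structure.

Each connectivity map becomes a weighted undirected graph: nodes are
granule-cell-layer columns, edge weights are the Pearson correlations between
the column amplitude profiles, clipped to [0, 1] (negative correlation means
no similarity).  Patchy maps yield block-structured adjacency matrices whose
community structure is extracted with the Louvain algorithm.  Four weighted
metrics summarise the topology:

* modularity Q^w — how cleanly the graph splits into modules ("patchiness"),
* module-degree z-score z_i^w — within-module degree centrality,
* participation coefficient y_i^w — how much a node's weight reaches foreign
  modules,
* assortativity r^w — whether similar-degree nodes attach to each other.

Absolute values are hard to compare across graphs of different size, so every
metric can be expressed as a percent deviation from degree-preserving
rewired null graphs, Δ% = (actual − median(null)) / median(null) × 100.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import networkx as nx
from networkx.algorithms.community import louvain_communities

from .maps import ConnectivityMap, ZScoreMap

#: division guard for Δ% and degenerate assortativity denominators
EPS = 1e-12

FEATURE_SCHEMES = ("g_global", "g_bilateral", "g_zonewise", "g_weights_zonewise")


@dataclass
class MapGraph:
    """Column-correlation graph of one connectivity map."""

    weights: np.ndarray              # (n, n) symmetric, zero diagonal, in [0, 1]
    positions_um: np.ndarray
    positions_norm: np.ndarray
    zone_labels: np.ndarray | None = None   # per-node structural zone label
    rewired: bool = False            # True for null-model instances
    warning: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(w, w.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-links must be zero")
        if w.min() < 0 or w.max() > 1 + 1e-9:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Weighted node degrees k_i^w."""
        return self.weights.sum(axis=1)

    @property
    def ipsi_mask(self) -> np.ndarray:
        return self.positions_um >= 0

    def subgraph(self, mask: np.ndarray) -> "MapGraph":
        idx = np.flatnonzero(mask)
        return MapGraph(
            weights=self.weights[np.ix_(idx, idx)],
            positions_um=self.positions_um[idx],
            positions_norm=self.positions_norm[idx],
            zone_labels=None if self.zone_labels is None else self.zone_labels[idx],
            rewired=self.rewired,
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        r, c = np.nonzero(np.triu(self.weights, 1))
        g.add_weighted_edges_from(
            (int(i), int(j), float(self.weights[i, j])) for i, j in zip(r, c)
        )
        return g


@dataclass
class ModulePartition:
    """Node→module assignment with the achieved modularity."""

    labels: np.ndarray               # (n,) integer module ids, canonical order
    modularity: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)


def build_correlation_graph(cmap: ConnectivityMap) -> MapGraph:
    """Pairwise Pearson correlation of column profiles, clipped to [0, 1].

    Constant columns have undefined correlation and get zero weight to every
    partner; negative correlations are treated as absence of similarity.
    """
    a = cmap.amplitudes
    if a.shape[1] < 2:
        raise ValueError("need at least 2 columns to build a graph")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 rows per column for a correlation")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(a.T)
    corr = np.nan_to_num(corr, nan=0.0)      # constant columns → no similarity
    np.fill_diagonal(corr, 0.0)
    w = np.clip(corr, 0.0, 1.0)
    w = (w + w.T) / 2.0
    return MapGraph(
        weights=w,
        positions_um=cmap.column_positions.copy(),
        positions_norm=cmap.normalized_positions,
    )


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber module ids in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def _refine_partition(graph: MapGraph, labels: np.ndarray) -> np.ndarray:
    """Greedy single-node-move refinement until no move improves modularity.

    Louvain's aggregation phase can lock individual nodes into communities a
    single reassignment would improve on; this deterministic local pass
    (including moves into a fresh singleton module) removes such residues.
    """
    w = graph.weights
    l = w.sum()
    k = graph.degrees
    labels = labels.copy()
    improved = True
    sweeps = 0
    while improved and sweeps < 100:
        improved = False
        sweeps += 1
        for i in range(graph.n_nodes):
            current = labels[i]
            candidates = list(np.unique(labels))
            fresh = max(candidates) + 1
            candidates.append(fresh)
            # ΔQ of moving i into module m: 2·(w(i,m) − k_i·K_m/l)/l relative
            # to leaving it alone, with i removed from its own module first
            best_m, best_gain = current, 0.0
            k_im = np.array([w[i, labels == m].sum() for m in candidates])
            K_m = np.array([k[labels == m].sum() for m in candidates])
            for idx, m in enumerate(candidates):
                if m == current:
                    continue
                gain_add = k_im[idx] - k[i] * K_m[idx] / l
                cur_idx = candidates.index(current)
                gain_rem = k_im[cur_idx] - k[i] * (K_m[cur_idx] - k[i]) / l
                gain = 2.0 * (gain_add - gain_rem) / l
                if gain > best_gain + 1e-13:
                    best_gain, best_m = gain, m
            if best_m != current:
                labels[i] = best_m
                improved = True
    return _canonical_labels(labels)


def detect_modules(
    graph: MapGraph, seed: int = 0, n_restarts: int = 20, resolution: float = 1.0
) -> ModulePartition:
    """Louvain community detection, best of ``n_restarts`` seeded runs.

    Each run is polished by a greedy single-node-move refinement.  Ties on
    modularity are broken by the lowest module count and then by the
    lexicographically smallest canonical assignment, making the result
    deterministic for a given seed.  A graph with no positive edge collapses
    to a single trivial module.
    """
    n = graph.n_nodes
    if graph.weights.sum() <= 0:
        return ModulePartition(labels=np.zeros(n, dtype=int), modularity=0.0)
    g = graph.to_networkx()
    best: tuple | None = None
    for r in range(n_restarts):
        comms = louvain_communities(g, weight="weight", resolution=resolution, seed=seed + r)
        labels = np.empty(n, dtype=int)
        for m, nodes in enumerate(comms):
            labels[list(nodes)] = m
        if resolution == 1.0:
            labels = _refine_partition(graph, labels)
        labels = _canonical_labels(labels)
        q = modularity(graph, ModulePartition(labels=labels, modularity=np.nan))
        key = (-q, len(np.unique(labels)), tuple(labels))
        if best is None or key < best[0]:
            best = (key, labels, q)
    return ModulePartition(labels=best[1], modularity=best[2])


def modularity(graph: MapGraph, partition: ModulePartition) -> float:
    """Weighted modularity Q^w of a partition.

    Q^w = (1/l^w) Σ_ij [w_ij − k_i^w k_j^w / l^w] δ(m_i, m_j), summed over
    ordered node pairs with l^w = Σ_ij w_ij the total (double-counted)
    weight.
    """
    w = graph.weights
    l = w.sum()
    if l <= 0:
        raise ValueError("graph has no weight")
    k = graph.degrees
    q = 0.0
    for m in np.unique(partition.labels):
        idx = partition.members(m)
        q += w[np.ix_(idx, idx)].sum() - (k[idx].sum() ** 2) / l
    return float(q / l)


def module_degree_zscore(graph: MapGraph, partition: ModulePartition) -> np.ndarray:
    """Within-module degree z-score z_i^w per node.

    Nodes in singleton modules, or in modules with zero degree spread, get
    z = 0 so homogeneous modules contribute neutrally to medians.
    """
    w = graph.weights
    z = np.zeros(graph.n_nodes)
    for m in np.unique(partition.labels):
        idx = partition.members(m)
        if idx.size < 2:
            continue
        k_in = w[np.ix_(idx, idx)].sum(axis=1)
        sd = k_in.std()
        if sd > EPS:
            z[idx] = (k_in - k_in.mean()) / sd
    return z


def participation(graph: MapGraph, partition: ModulePartition) -> np.ndarray:
    """Participation coefficient y_i^w per node; isolated nodes get 0."""
    w = graph.weights
    k = graph.degrees
    y = np.zeros(graph.n_nodes)
    modules = np.unique(partition.labels)
    k_to_module = np.stack([w[:, partition.members(m)].sum(axis=1) for m in modules], axis=1)
    nz = k > EPS
    y[nz] = 1.0 - np.sum((k_to_module[nz] / k[nz, None]) ** 2, axis=1)
    return y


def assortativity(graph: MapGraph, node_mask: np.ndarray | None = None) -> float:
    """Weighted degree assortativity r^w; NaN when algebraically undefined.

    Evaluated over the links of the graph (or the induced subgraph when a
    node mask is given): the weighted correlation between the degrees at the
    two ends of each link.  On regular graphs the variance term vanishes and
    the coefficient is undefined (returned as NaN, not raised).
    """
    g = graph if node_mask is None else graph.subgraph(np.asarray(node_mask, dtype=bool))
    w = g.weights
    iu, ju = np.nonzero(np.triu(w, 1))
    if iu.size < 2:
        return float("nan")
    wl = w[iu, ju]
    k = g.degrees
    ki, kj = k[iu], k[ju]
    l = wl.sum()
    mean_prod = (wl * ki * kj).sum() / l
    mean_sum = (wl * (ki + kj) / 2.0).sum() / l
    mean_sq = (wl * (ki ** 2 + kj ** 2) / 2.0).sum() / l
    denom = mean_sq - mean_sum ** 2
    if abs(denom) < EPS:
        return float("nan")
    return float((mean_prod - mean_sum ** 2) / denom)


def rewire_graph(
    graph: MapGraph, rng: np.random.Generator, n_swaps_per_edge: int = 10
) -> MapGraph:
    """One degree-preserving rewired null instance.

    Pairs of edges (a,b), (c,d) are repeatedly swapped to (a,d), (c,b) when
    the target slots are empty, carrying their weights along.  The binary
    degree sequence is preserved exactly.  Graphs with fewer than two edges
    are returned unchanged with a warning flag.
    """
    w = graph.weights.copy()
    iu, ju = np.nonzero(np.triu(w, 1))
    n_edges = iu.size
    if n_edges < 2:
        return MapGraph(
            weights=w,
            positions_um=graph.positions_um.copy(),
            positions_norm=graph.positions_norm.copy(),
            zone_labels=graph.zone_labels,
            rewired=True,
            warning="too few edges to rewire",
        )
    edges = list(zip(iu.tolist(), ju.tolist()))
    attempts = n_swaps_per_edge * n_edges
    for _ in range(attempts):
        e1, e2 = rng.integers(0, len(edges), size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if w[a, d] != 0 or w[c, b] != 0:
            continue
        w1, w2 = w[a, b], w[c, d]
        w[a, b] = w[b, a] = 0.0
        w[c, d] = w[d, c] = 0.0
        w[a, d] = w[d, a] = w1
        w[c, b] = w[b, c] = w2
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
    return MapGraph(
        weights=w,
        positions_um=graph.positions_um.copy(),
        positions_norm=graph.positions_norm.copy(),
        zone_labels=graph.zone_labels,
        rewired=True,
    )


def null_ensemble(
    graph: MapGraph,
    n_nulls: int = 10,
    n_swaps_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[MapGraph]:
    """Ensemble of degree-preserving rewired null graphs (≥10 by default)."""
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return [rewire_graph(graph, rng, n_swaps_per_edge) for _ in range(n_nulls)]


def relative_metric(actual: float, nulls: Sequence[float]) -> float:
    """Δ% = (actual − median(nulls)) / median(nulls) × 100; NaN if degenerate."""
    vals = np.asarray([v for v in nulls if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no finite null values")
    med = np.median(vals)
    if abs(med) < EPS or not np.isfinite(actual):
        return float("nan")
    return float((actual - med) / med * 100.0)


def graph_metrics(graph: MapGraph, partition: ModulePartition) -> dict:
    """All four weighted metrics for one graph under one partition."""
    return {
        "modularity": modularity(graph, partition),
        "module_degree_zscore": module_degree_zscore(graph, partition),
        "participation": participation(graph, partition),
        "assortativity": assortativity(graph),
    }


def assemble_features(
    graph: MapGraph,
    partition: ModulePartition,
    scheme: str = "g_global",
    zone_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Reduce node metrics to a per-map feature vector.

    ``g_global``: [Q, median z, median y, r] (4-dim).
    ``g_bilateral``: [Q, (median z, median y, r) on the ipsilateral induced
    subgraph, same on the contralateral one] (7-dim).
    ``g_zonewise``: per-zone medians of z and y plus per-zone assortativity
    of the induced subgraph, flattened zone-major.
    Empty node groups yield NaN entries (missing, imputed downstream).
    """
    q = modularity(graph, partition)
    z = module_degree_zscore(graph, partition)
    y = participation(graph, partition)
    if scheme == "g_global":
        return np.array([q, np.median(z), np.median(y), assortativity(graph)])
    if scheme == "g_bilateral":
        out = [q]
        for mask in (graph.ipsi_mask, ~graph.ipsi_mask):
            if mask.sum() == 0:
                out += [np.nan, np.nan, np.nan]
            else:
                out += [
                    float(np.median(z[mask])),
                    float(np.median(y[mask])),
                    assortativity(graph, mask),
                ]
        return np.array(out)
    if scheme == "g_zonewise":
        labels = zone_labels if zone_labels is not None else graph.zone_labels
        if labels is None:
            raise ValueError("zone labels required for the zone-wise scheme")
        labels = np.asarray(labels)
        out = []
        for zone in _zone_order(labels):
            mask = labels == zone
            if mask.sum() == 0:
                out += [np.nan, np.nan, np.nan]
            else:
                out += [
                    float(np.median(z[mask])),
                    float(np.median(y[mask])),
                    assortativity(graph, mask),
                ]
        return np.array(out)
    raise ValueError(f"unknown scheme {scheme!r}")


def _zone_order(labels: np.ndarray) -> list:
    seen: list = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    return seen


def zonewise_weights(
    cmap: ConnectivityMap,
    zmap: ZScoreMap,
    zone_labels: Sequence[str],
    zone_order: Sequence[str],
) -> np.ndarray:
    """Per-zone normalised mean significant synaptic weight (g_weights_zonewise).

    The mean amplitude of significant (z ≥ threshold) sites is computed per
    structural zone and normalised by the map-wide mean significant weight;
    zones without map coverage are NaN, covered zones without significant
    sites are 0.
    """
    zone_labels = np.asarray(list(zone_labels))
    sig = zmap.z >= zmap.threshold
    all_sig = cmap.amplitudes[sig]
    norm = all_sig.mean() if all_sig.size else np.nan
    out = []
    for zone in zone_order:
        cols = zone_labels == zone
        if cols.sum() == 0:
            out.append(np.nan)
            continue
        zone_sig = sig[:, cols]
        if zone_sig.sum() == 0:
            out.append(0.0)
        else:
            out.append(float(cmap.amplitudes[:, cols][zone_sig].mean() / norm))
    return np.array(out)


def relative_features(
    graph: MapGraph,
    partition: ModulePartition,
    nulls: Sequence[MapGraph],
    seed: int = 0,
) -> dict:
    """Δ% of the four global metrics against a null ensemble.

    Each null graph is re-partitioned with its own Louvain run (community
    structure is not portable across rewirings); node metrics are reduced by
    the whole-graph median before the Δ% comparison.
    """
    actual = _global_metric_values(graph, partition)
    null_vals = {k: [] for k in actual}
    for i, ng in enumerate(nulls):
        np_part = detect_modules(ng, seed=seed + 1000 + i)
        vals = _global_metric_values(ng, np_part)
        for k, v in vals.items():
            null_vals[k].append(v)
    return {k: relative_metric(actual[k], null_vals[k]) for k in actual}


def _global_metric_values(graph: MapGraph, partition: ModulePartition) -> dict:
    return {
        "modularity": modularity(graph, partition),
        "module_degree_zscore": float(np.median(module_degree_zscore(graph, partition))),
        "participation": float(np.median(participation(graph, partition))),
        "assortativity": assortativity(graph),
    }
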