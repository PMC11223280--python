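"""Binary network construction and graph-theoretic parameters.

Networks are built from a connectivity matrix by thresholding with the
no-isolated-node rule: the threshold is the *maximum* value at which
every node still keeps at least one edge.  For a single matrix that is
``min over nodes of (max over that node's off-diagonal weights)``; edges
are kept when weight >= threshold.

Five parameters are computed on the binary undirected graph:

- node degree            K_i = sum_j a_ij, mean K
- clustering coefficient C_i = 2 E_i / (K_i (K_i - 1)), mean C
- characteristic path    L = mean shortest-path length over reachable
  length                 ordered pairs (unreachable pairs excluded)
- global efficiency      E_glob = mean of 1 / l_ij with 1/inf = 0
- local efficiency       E(i) = global efficiency of the subgraph
                         induced by i's neighbors, mean E_loc

Shortest paths, triangle counts and efficiencies are delegated to
networkx; the formulas above fix the conventions (degree-<2 nodes have
C_i = E(i) = 0 and count in the means).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from eegfc.connectivity import ConnectivityMatrix
from eegfc.errors import ConfigurationError, DataError
from eegfc.montage import RegionScheme
from eegfc.signal_prep import BandDefinition

THRESHOLD_MODES = ("per_subject_min", "group_mean")


@dataclass
class BinaryNetwork:
    """Thresholded undirected adjacency with its threshold provenance."""

    adjacency: np.ndarray
    threshold: float
    band: BandDefinition
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DataError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise DataError("adjacency must be symmetric")
        if not np.all((a == 0) | (a == 1)):
            raise DataError("adjacency must be 0/1")
        if np.any(np.diag(a) != 0):
            raise DataError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def to_graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        g.add_nodes_from(range(self.n_nodes))
        return g


@dataclass
class GraphMetrics:
    """Whole-network and per-node topological parameters of one network."""

    node_degree: np.ndarray  # K_i
    mean_degree: float  # K
    node_clustering: np.ndarray  # C_i
    mean_clustering: float  # C
    char_path_length: float  # L
    global_efficiency: float  # E_glob
    node_local_efficiency: np.ndarray  # E(i)
    mean_local_efficiency: float  # E_loc
    n_nodes: int


def max_spanning_threshold(m: ConnectivityMatrix) -> float:
    """Largest threshold leaving no isolated node (min over nodes of row max)."""
    w = m.values.copy()
    np.fill_diagonal(w, -np.inf)
    row_max = w.max(axis=1)
    if np.any(row_max <= 0):
        bad = m.channel_labels[int(np.argmin(row_max))]
        raise DataError(
            f"subject {m.subject_id!r}: node {bad} has no positive weight; "
            "no threshold can avoid isolating it"
        )
    return float(row_max.min())


def band_threshold(ms: list[ConnectivityMatrix], mode: str = "per_subject_min") -> float:
    """One band-wide threshold from a set of per-subject matrices.

    ``per_subject_min`` guarantees no isolated node in any subject's
    network; ``group_mean`` thresholds the grand-average matrix.
    """
    if mode not in THRESHOLD_MODES:
        raise ConfigurationError(f"unknown threshold mode {mode!r}; expected {THRESHOLD_MODES}")
    if not ms:
        raise DataError("band_threshold: empty matrix list")
    if mode == "per_subject_min":
        return float(min(max_spanning_threshold(m) for m in ms))
    from eegfc.connectivity import group_average

    return max_spanning_threshold(group_average(ms))


def binarize(m: ConnectivityMatrix, threshold: float, validate: bool = False) -> BinaryNetwork:
    """Binarize with the >= rule: edge kept when weight equals the threshold."""
    if threshold < 0:
        raise ConfigurationError(f"threshold must be >= 0, got {threshold}")
    a = (m.values >= threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    net = BinaryNetwork(
        adjacency=a,
        threshold=float(threshold),
        band=m.band,
        channel_labels=m.channel_labels,
        subject_id=m.subject_id,
        group=m.group,
    )
    if validate and np.any(net.adjacency.sum(axis=1) == 0):
        iso = m.channel_labels[int(np.argmin(net.adjacency.sum(axis=1)))]
        raise DataError(
            f"subject {m.subject_id!r}: node {iso} isolated at threshold {threshold}"
        )
    return net


def degree(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node degree K_i and mean K."""
    k = net.adjacency.sum(axis=1).astype(float)
    return k, float(k.mean())


def clustering(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering C_i = 2 E_i / (K_i (K_i - 1)) and mean C.

    Nodes with fewer than two neighbors have C_i = 0 and count in the mean.
    """
    cdict = nx.clustering(net.to_graph())
    c = np.array([cdict[i] for i in range(net.n_nodes)], dtype=float)
    return c, float(c.mean())


def _shortest_path_lengths(g: nx.Graph) -> dict[int, dict[int, int]]:
    return dict(nx.all_pairs_shortest_path_length(g))


def path_length(net: BinaryNetwork) -> float:
    """Characteristic path length L over reachable ordered pairs.

    Unreachable pairs are excluded from both the sum and the count, so a
    graph of disconnected cliques averages only within-clique distances.
    """
    g = net.to_graph()
    total = 0.0
    count = 0
    for i, dists in _shortest_path_lengths(g).items():
        for j, d in dists.items():
            if i != j:
                total += d
                count += 1
    if count == 0:
        raise DataError("path_length: graph has no edges, no finite path exists")
    return total / count


def global_efficiency(net: BinaryNetwork) -> float:
    """E_glob: mean inverse shortest-path length over all ordered pairs (1/inf = 0)."""
    return float(nx.global_efficiency(net.to_graph()))


def local_efficiency(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node E(i) (global efficiency of the neighbor subgraph) and mean E_loc.

    E(i) = 0 for nodes with fewer than two neighbors.
    """
    g = net.to_graph()
    e = np.zeros(net.n_nodes)
    for i in range(net.n_nodes):
        nbrs = list(g.neighbors(i))
        if len(nbrs) >= 2:
            e[i] = nx.global_efficiency(g.subgraph(nbrs))
    return e, float(e.mean())


def compute_metrics(net: BinaryNetwork) -> GraphMetrics:
    """All five whole-brain parameters plus the nodal values behind them."""
    k, mean_k = degree(net)
    c, mean_c = clustering(net)
    eloc, mean_eloc = local_efficiency(net)
    return GraphMetrics(
        node_degree=k,
        mean_degree=mean_k,
        node_clustering=c,
        mean_clustering=mean_c,
        char_path_length=path_length(net),
        global_efficiency=global_efficiency(net),
        node_local_efficiency=eloc,
        mean_local_efficiency=mean_eloc,
        n_nodes=net.n_nodes,
    )


def regional_means(
    gm: GraphMetrics,
    channel_labels: tuple[str, ...],
    scheme: RegionScheme | None = None,
) -> dict[str, dict[str, float]]:
    """Region-wise means of the nodal K_i, C_i, E(i) values.

    Nodal values are computed on the whole graph first, then averaged
    within each region of the electrode partition.
    """
    scheme = scheme or RegionScheme()
    for ch in channel_labels:
        scheme.region_of(ch)  # raises if any channel is unmapped
    out: dict[str, dict[str, float]] = {}
    for region in scheme.regions:
        idx = scheme.members(region, list(channel_labels))
        if not idx:
            continue
        out[region] = {
            "K": float(gm.node_degree[idx].mean()),
            "C": float(gm.node_clustering[idx].mean()),
            "E_loc": float(gm.node_local_efficiency[idx].mean()),
        }
    return out


def metrics_table(
    rows: list[tuple[BinaryNetwork, GraphMetrics]],
    scheme: RegionScheme | None = None,
    include_regional: bool = True,
) -> pd.DataFrame:
    """Tidy table (subject, group, band, parameter, region, value) for the stats stage."""
    records = []
    for net, gm in rows:
        base = {"subject": net.subject_id, "group": net.group, "band": net.band.name}
        whole = {
            "K": gm.mean_degree,
            "C": gm.mean_clustering,
            "L": gm.char_path_length,
            "E_glob": gm.global_efficiency,
            "E_loc": gm.mean_local_efficiency,
        }
        for param, value in whole.items():
            records.append({**base, "parameter": param, "region": "whole_brain", "value": value})
        if include_regional and net.channel_labels:
            try:
                regional = regional_means(gm, net.channel_labels, scheme)
            except ConfigurationError:
                continue  # non-standard montage without an explicit scheme
            for region, vals in regional.items():
                for param, value in vals.items():
                    records.append({**base, "parameter": param, "region": region, "value": value})
    return pd.DataFrame.from_records(records)
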