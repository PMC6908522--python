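"""Coexpression networks, threshold selection and common connectivity patterns.

Similarity between genes is the absolute Pearson correlation of their
normalized expression profiles. An edge threshold tau is chosen by scanning
a grid and comparing the observed clustering coefficient C(tau) — the mean
local (Watts-Strogatz) coefficient over nodes of degree >= 2 — with the
Erdos-Renyi expectation C_o(tau) = 2E / (N(N-1)) of a random graph with the
same size; the selected tau* is the first local maximum of
D(tau) = C - C_o whose network keeps a minimum number of edges.

The common connectivity pattern (CCP) of two networks is the graph of edges
present in both, its nodes being those edges' endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy
from .errors import ConfigurationError, NetworkError

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.50, 0.9901, 0.01), 2)


@dataclass
class SimilarityMatrix:
    """Symmetric |Pearson r| matrix over gene labels (diagonal 1)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if len(self.labels) != len(set(self.labels)):
            raise NetworkError("duplicate gene labels in similarity matrix")
        if v.shape != (len(self.labels), len(self.labels)):
            raise NetworkError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise NetworkError("similarity matrix is not symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise NetworkError("similarity values must lie in [0, 1]")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class GeneNetwork:
    """Simple undirected graph over gene labels.

    ``edges`` are unordered pairs stored with lexicographically sorted
    endpoints; ``nodes`` are exactly the edge endpoints (isolated genes are
    excluded).
    """

    nodes: set[str]
    edges: set[tuple[str, str]]
    threshold: float | None = None

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise NetworkError(f"self-loop on {a!r}")
            canon.add((a, b) if a < b else (b, a))
        self.edges = canon
        endpoints = {v for e in self.edges for v in e}
        if not endpoints <= self.nodes:
            raise NetworkError("edge endpoint missing from node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def degree(self) -> dict[str, int]:
        deg = {v: 0 for v in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


@dataclass
class ThresholdScan:
    """Per-tau network summaries over the scanning grid."""

    grid: np.ndarray
    n_active_nodes: np.ndarray
    n_edges: np.ndarray
    observed_cc: np.ndarray       # C(tau)
    random_cc: np.ndarray         # C_o(tau)
    selected: float | None = None

    @property
    def excess_cc(self) -> np.ndarray:
        """D(tau) = C - C_o."""
        return self.observed_cc - self.random_cc

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tau": self.grid,
            "n_active_nodes": self.n_active_nodes,
            "n_edges": self.n_edges,
            "C": self.observed_cc,
            "C_random": self.random_cc,
            "D": self.excess_cc,
        })


def similarity_matrix(study: ExpressionStudy,
                      gene_subset: list[str] | None = None) -> SimilarityMatrix:
    """|Pearson| similarity across all samples of a study.

    Genes in ``gene_subset`` missing from the study are reported and
    skipped; zero-variance genes are dropped with a warning.
    """
    if len(study.samples) < 3:
        raise NetworkError("similarity requires >= 3 samples")
    if gene_subset is None:
        genes = study.features
    else:
        missing = [g for g in gene_subset if g not in study.values.index]
        if missing:
            logger.warning("similarity: %d requested genes absent: %s",
                           len(missing), missing[:5])
        genes = [g for g in gene_subset if g in study.values.index]
    if len(genes) < 2:
        raise NetworkError("similarity requires >= 2 present genes")
    x = study.values.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("similarity: dropped %d zero-variance genes: %s",
                       len(dropped), dropped[:5])
        genes = [g for g, k in zip(genes, keep) if k]
        x = x[keep]
    if len(genes) < 2:
        raise NetworkError("fewer than 2 genes with non-zero variance")
    r = np.abs(np.corrcoef(x))
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(labels=genes, values=r)


def clustering_coefficient(network: GeneNetwork) -> float:
    """Mean local clustering coefficient over nodes of degree >= 2."""
    g = network.to_networkx()
    local = nx.clustering(g)
    eligible = [v for v in g.nodes if g.degree(v) >= 2]
    if not eligible:
        return 0.0
    return float(np.mean([local[v] for v in eligible]))


def expected_random_cc(n_nodes: int, n_edges: int) -> float:
    """Expected clustering coefficient of G(N, p): the edge density 2E/(N(N-1))."""
    if n_nodes < 2:
        raise NetworkError("need >= 2 nodes")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise NetworkError(f"{n_edges} edges exceed the {max_edges} possible")
    if n_edges == 0:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def build_network(sim: SimilarityMatrix, tau: float) -> GeneNetwork:
    """Edges are pairs with |r| >= tau (closed rule); isolated genes excluded."""
    if not 0.0 <= tau <= 1.0:
        raise ConfigurationError(f"tau must lie in [0, 1], got {tau}")
    iu, ju = np.triu_indices(len(sim.labels), k=1)
    hit = sim.values[iu, ju] >= tau
    edges = {
        tuple(sorted((sim.labels[i], sim.labels[j])))
        for i, j in zip(iu[hit], ju[hit])
    }
    nodes = {v for e in edges for v in e}
    return GeneNetwork(nodes=nodes, edges=edges, threshold=float(tau))


def threshold_scan(sim: SimilarityMatrix,
                   grid: np.ndarray = DEFAULT_GRID) -> ThresholdScan:
    """Scan the threshold grid recording C, C_o and network sizes per tau."""
    grid = np.asarray(grid, dtype=float)
    n_nodes = np.zeros(grid.size, dtype=int)
    n_edges = np.zeros(grid.size, dtype=int)
    c_obs = np.zeros(grid.size)
    c_rand = np.zeros(grid.size)
    for k, tau in enumerate(grid):
        net = build_network(sim, float(tau))
        n_nodes[k] = net.n_nodes
        n_edges[k] = net.n_edges
        if net.n_nodes >= 2:
            c_obs[k] = clustering_coefficient(net)
            c_rand[k] = expected_random_cc(net.n_nodes, net.n_edges)
    return ThresholdScan(grid=grid, n_active_nodes=n_nodes, n_edges=n_edges,
                         observed_cc=c_obs, random_cc=c_rand)


def select_threshold(scan: ThresholdScan, window: int = 5,
                     min_edges: int = 10) -> float:
    """First local maximum of D = C - C_o with at least ``min_edges`` edges.

    A grid point is a local maximum when its D is >= every D within
    ``window`` grid steps on either side; ties break to the smallest tau.
    Falls back to the global argmax of D subject to ``min_edges``.
    """
    d = scan.excess_cc
    ok = scan.n_edges >= min_edges
    if not ok.any():
        raise NetworkError(
            f"no threshold keeps >= {min_edges} edges; reduce min_edges"
        )
    for k in range(d.size):
        if not ok[k]:
            continue
        lo, hi = max(0, k - window), min(d.size, k + window + 1)
        if d[k] >= d[lo:hi].max() - 1e-15:
            scan.selected = float(scan.grid[k])
            return scan.selected
    masked = np.where(ok, d, -np.inf)
    scan.selected = float(scan.grid[int(np.argmax(masked))])
    return scan.selected


def ccp_intersection(net_a: GeneNetwork, net_b: GeneNetwork) -> GeneNetwork:
    """Common connectivity pattern: the label-matched edge intersection.

    Nodes are the shared edges' endpoints; an empty CCP is allowed.
    """
    edges = net_a.edges & net_b.edges
    nodes = {v for e in edges for v in e}
    return GeneNetwork(nodes=nodes, edges=edges, threshold=None)


def connected_components(network: GeneNetwork) -> list[set[str]]:
    """Connected components, largest first."""
    comps = nx.connected_components(network.to_networkx())
    return sorted((set(c) for c in comps), key=lambda c: (-len(c), min(c)))


def hub_rank(network: GeneNetwork, top_k: int | None = None) -> pd.DataFrame:
    """Genes ranked by descending degree, ties broken lexicographically."""
    if top_k is not None and top_k <= 0:
        raise ConfigurationError(f"top_k must be positive, got {top_k}")
    deg = network.degree()
    ranked = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ranked = ranked[:top_k]
    return pd.DataFrame(ranked, columns=["gene", "degree"]).set_index("gene")
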