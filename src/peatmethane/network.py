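"""Spearman co-occurrence networks and their topology.

Networks are built from per-taxon relative abundance profiles: taxa above a
relative-abundance floor are pairwise rank-correlated, and pairs with
|r| > 0.7 at p < 0.01 (raw, no multiple-testing correction) become edges.
Eight topological descriptors summarise each network: node number, edge
number, average degree, average path length, clustering coefficient,
diameter, graph density and Newman modularity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats

from .community import OTUTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationNetwork",
    "TopologyRecord",
    "filter_taxa",
    "build_network",
    "network_topology",
    "best_modularity_partition",
]


# --------------------------------------------------------------------------
# abundance filter
# --------------------------------------------------------------------------

def filter_taxa(table: OTUTable, min_rel_abundance: float = 0.001) -> OTUTable:
    """Keep taxa whose overall relative abundance strictly exceeds the floor.

    Overall relative abundance is taxon total / grand total; the comparison
    is a strict "greater than", so a taxon sitting exactly on the threshold
    is dropped.
    """
    if not 0.0 <= min_rel_abundance < 1.0:
        raise ValueError("min_rel_abundance must be in [0, 1)")
    totals = table.counts.sum(axis=1)
    grand = totals.sum()
    keep = totals / grand > min_rel_abundance
    keep &= totals > 0
    if not keep.any():
        raise ValueError(
            f"no taxa exceed relative abundance {min_rel_abundance}; nothing to build on"
        )
    return OTUTable(table.counts.loc[keep])


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

@dataclass
class CorrelationNetwork:
    """Undirected simple graph of |r|/p-thresholded Spearman associations."""

    graph: nx.Graph
    edges: pd.DataFrame            # taxon_a, taxon_b, spearman_r, p_value
    r_threshold: float
    p_threshold: float
    n_zero_variance_skipped: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_edge_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    table: OTUTable,
    r_threshold: float = 0.7,
    p_threshold: float = 0.01,
) -> CorrelationNetwork:
    """Spearman co-occurrence network on per-sample relative abundances.

    Correlations use the t-approximation p-value; an edge requires
    |r| > r_threshold AND p < p_threshold. Zero-variance taxa are skipped
    (logged), and taxa left without any edge do not appear in the network.
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for Spearman p-values")
    rel = table.relative_abundance().to_numpy()
    taxa = np.asarray(table.taxon_ids)
    keep = np.ptp(rel, axis=1) > 0  # exact zero-variance test
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("build_network: skipping %d zero-variance taxa", n_skipped)
    rel, taxa = rel[keep], taxa[keep]
    if len(taxa) < 2:
        raise ValueError("fewer than 2 taxa with variance; no correlations to test")
    rho, pval = stats.spearmanr(rel, axis=1)
    if np.ndim(rho) == 0:  # spearmanr collapses to scalars for 2 variables
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[0.0, pval], [pval, 0.0]])
    iu = np.triu_indices(len(taxa), 1)
    mask = (np.abs(rho[iu]) > r_threshold) & (pval[iu] < p_threshold)
    rows = pd.DataFrame(
        {
            "taxon_a": taxa[iu[0][mask]],
            "taxon_b": taxa[iu[1][mask]],
            "spearman_r": rho[iu][mask],
            "p_value": pval[iu][mask],
        }
    )
    g = nx.Graph()
    for rec in rows.itertuples(index=False):
        g.add_edge(rec.taxon_a, rec.taxon_b, spearman_r=rec.spearman_r,
                   p_value=rec.p_value)
    return CorrelationNetwork(
        graph=g,
        edges=rows,
        r_threshold=r_threshold,
        p_threshold=p_threshold,
        n_zero_variance_skipped=n_skipped,
    )


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------

@dataclass
class TopologyRecord:
    node_number: int
    edge_number: int
    average_degree: float
    average_path_length: float    # mean over reachable pairs; NaN if no edges
    clustering_coefficient: float
    diameter: float               # max over reachable pairs; NaN if no edges
    graph_density: float
    modularity: float             # Newman modularity; NaN if no edges

    def to_dict(self) -> dict:
        return {
            "node_number": self.node_number,
            "edge_number": self.edge_number,
            "average_degree": self.average_degree,
            "average_path_length": self.average_path_length,
            "clustering_coefficient": self.clustering_coefficient,
            "diameter": self.diameter,
            "graph_density": self.graph_density,
            "modularity": self.modularity,
        }

    def to_json(self, path: str | Path) -> None:
        rec = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in self.to_dict().items()
        }
        Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")


_EXACT_MODULARITY_MAX_NODES = 10


def _exact_max_modularity_partition(g: nx.Graph) -> list[set]:
    """Globally optimal modularity partition by branch-complete enumeration.

    Walks all set partitions of the node set (nodes in sorted order join an
    existing block or open a new one), maintaining per-block internal edge
    counts and degree sums incrementally so each leaf costs O(#blocks).
    Feasible up to ~10 nodes (Bell(10) = 115,975 partitions).
    """
    nodes = sorted(g.nodes())
    m = g.number_of_edges()
    adj = {u: set(g[u]) for u in nodes}
    deg = {u: g.degree(u) for u in nodes}
    best_q = -np.inf
    best_blocks: list[set] = [set(nodes)]
    blocks: list[list] = []  # [members, internal_edges, degree_sum]

    def rec(i: int) -> None:
        nonlocal best_q, best_blocks
        if i == len(nodes):
            q = sum(L / m - (D / (2.0 * m)) ** 2 for _, L, D in blocks)
            if q > best_q + 1e-15:
                best_q = q
                best_blocks = [set(b[0]) for b in blocks]
            return
        u = nodes[i]
        for b in blocks:
            e = len(adj[u] & b[0])
            b[0].add(u)
            b[1] += e
            b[2] += deg[u]
            rec(i + 1)
            b[0].discard(u)
            b[1] -= e
            b[2] -= deg[u]
        blocks.append([{u}, 0, deg[u]])
        rec(i + 1)
        blocks.pop()

    rec(0)
    return best_blocks


def best_modularity_partition(g: nx.Graph) -> list[set]:
    """Deterministic, seed-free partition maximising Newman modularity.

    Networks with at most 10 nodes are solved exactly by complete partition
    enumeration; larger networks start from Clauset-Newman-Moore greedy
    agglomeration and apply two deterministic improvement passes until fixed
    point — single-node moves between communities (including splitting off a
    singleton) and pairwise community merges, each accepted only on a strict
    modularity increase, nodes visited in sorted ID order.
    """
    if g.number_of_nodes() <= _EXACT_MODULARITY_MAX_NODES:
        return _exact_max_modularity_partition(g)
    communities = [set(c) for c in nx_community.greedy_modularity_communities(g)]

    def q_of(parts: list[set]) -> float:
        return nx_community.modularity(g, [p for p in parts if p])

    best_q = q_of(communities)
    improved = True
    while improved:
        improved = False
        # single-node moves
        for node in sorted(g.nodes()):
            src = next(i for i, c in enumerate(communities) if node in c)
            targets = list(range(len(communities))) + [None]  # None = new singleton
            for dst in targets:
                if dst == src:
                    continue
                trial = [set(c) for c in communities]
                trial[src].discard(node)
                if dst is None:
                    trial.append({node})
                else:
                    trial[dst].add(node)
                trial = [c for c in trial if c]
                q = q_of(trial)
                if q > best_q + 1e-12:
                    communities, best_q, improved = trial, q, True
                    break
        # community merges
        n = len(communities)
        for i in range(n):
            for j in range(i + 1, n):
                if i >= len(communities) or j >= len(communities):
                    continue
                trial = [set(c) for k, c in enumerate(communities) if k not in (i, j)]
                trial.append(communities[i] | communities[j])
                q = q_of(trial)
                if q > best_q + 1e-12:
                    communities, best_q, improved = trial, q, True
                    break
    return [c for c in communities if c]


def network_topology(net: CorrelationNetwork | nx.Graph) -> TopologyRecord:
    """The eight-descriptor topology record of a co-occurrence network.

    Path length and diameter are computed over connected (reachable) pairs
    only, aggregating across components as the mean / max over those pairs;
    the clustering coefficient averages local clustering over all nodes with
    degree-<2 nodes contributing 0. With an empty edge set the path-based
    metrics and modularity are undefined and reported as NaN.
    """
    g = net.graph if isinstance(net, CorrelationNetwork) else net
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("network has no nodes")
    e = g.number_of_edges()
    avg_degree = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    if e == 0:
        return TopologyRecord(n, 0, 0.0, float("nan"), 0.0, float("nan"), density,
                              float("nan"))
    lengths = []
    for _, dists in nx.all_pairs_shortest_path_length(g):
        lengths.extend(v for v in dists.values() if v > 0)
    apl = float(np.mean(lengths))       # each unordered pair counted twice; mean unaffected
    diameter = float(max(lengths))
    clustering = float(nx.average_clustering(g, count_zeros=True))
    parts = best_modularity_partition(g)
    q = float(nx_community.modularity(g, parts))
    return TopologyRecord(
        node_number=n,
        edge_number=e,
        average_degree=avg_degree,
        average_path_length=apl,
        clustering_coefficient=clustering,
        diameter=diameter,
        graph_density=density,
        modularity=q,
    )
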