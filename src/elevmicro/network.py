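"""Spearman co-occurrence networks, topology metrics, and keystone taxa.

The meta-network is built from all pairwise Spearman correlations between
taxa across samples: an edge is kept when the BH-corrected p-value is at or
below ``fdr_alpha`` and |rho| reaches ``rho_threshold`` (0.77 and 0.001 by
default). Group subnetworks are induced from the meta-network on the taxa
present in that group's samples. Betweenness is reported unnormalized
(raw shortest-path counts) because the keystone cutoff is defined on raw
counts; eigenvector centrality is scaled so the maximum node is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CommunityTable
from .gradient_stats import bh_fdr, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


@dataclass
class NetworkParameters:
    """Edge-screen thresholds; defaults follow common co-occurrence practice.

    ``min_mean_rel_abund`` is the 0.01% mean relative-abundance floor,
    ``rho_threshold`` the Spearman cutoff (a fixed constant here; no
    random-matrix-theory scan), ``fdr_alpha`` the BH q-value cutoff. With
    ``signed_edges`` the threshold applies to |rho| so negative
    correlations can form edges; otherwise only positive ones qualify.
    """

    min_mean_rel_abund: float = 0.0001
    rho_threshold: float = 0.77
    fdr_alpha: float = 0.001
    signed_edges: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rho_threshold <= 1:
            raise ValueError("rho_threshold must lie in (0, 1]")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")


@dataclass
class NodeMetrics:
    taxon_id: str
    degree: int
    betweenness: float
    closeness: float
    eigenvector: float


@dataclass
class NetworkMetrics:
    nodes: int
    edges: int
    clustering_coefficient: float
    average_degree: float
    graph_density: float
    modularity: float
    transitivity: float
    positive_edges: int
    negative_edges: int
    group_label: str | None = None


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean node degree, 2E/N."""
    if n_nodes <= 0:
        raise ValueError("need at least one node")
    return 2.0 * n_edges / n_nodes


def graph_density(n_nodes: int, n_edges: int) -> float:
    """Fraction of possible undirected edges present, 2E/(N(N−1))."""
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


# ---------------------------------------------------------------------------
# Edge screen


def filter_rare_taxa(table: CommunityTable, min_mean_rel_abund: float) -> CommunityTable:
    """Drop taxa whose mean relative abundance across samples is below the floor."""
    rel = table.relative_abundance()
    keep = rel.columns[rel.mean(axis=0) >= min_mean_rel_abund]
    if len(keep) == 0:
        raise ValueError("no taxa retained by the abundance floor")
    return table.select_taxa(list(keep))


def spearman_edge_screen(
    table: CommunityTable, params: NetworkParameters | None = None
) -> pd.DataFrame:
    """All-pairs Spearman screen; returns kept edges (taxon_i, taxon_j, rho, p, q).

    Correlations are computed on rank-transformed abundances across samples
    (so the screen is invariant to monotone transforms); p-values use the
    t approximation and are BH-corrected over every tested pair before
    thresholding. Taxa with constant abundance have undefined correlations
    and are skipped with a warning.
    """
    params = params or NetworkParameters()
    counts = table.matrix.astype(float)
    n_samples, n_taxa = counts.shape
    if n_samples < 5:
        raise ValueError("need at least 5 samples for the edge screen")
    ranks = stats.rankdata(counts, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant taxa skipped in edge screen", int(constant.sum()))
    z = np.zeros_like(ranks)
    ok = ~constant
    z[:, ok] = (ranks[:, ok] - ranks[:, ok].mean(axis=0)) / sd[ok]
    rho = (z.T @ z) / n_samples

    iu, ju = np.triu_indices(n_taxa, k=1)
    pair_ok = ok[iu] & ok[ju]
    iu, ju = iu[pair_ok], ju[pair_ok]
    r = np.clip(rho[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_samples - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n_samples - 2))
    q = bh_fdr(p)

    strength = np.abs(r) if params.signed_edges else r
    keep = (q <= params.fdr_alpha) & (strength >= params.rho_threshold)
    taxa = np.asarray(table.taxon_ids)
    return pd.DataFrame(
        {
            "taxon_i": taxa[iu[keep]],
            "taxon_j": taxa[ju[keep]],
            "rho": r[keep],
            "p": p[keep],
            "q": q[keep],
        }
    )


# ---------------------------------------------------------------------------
# Graph construction


def build_network(edges: pd.DataFrame, group_label: str | None = None) -> nx.Graph:
    """Simple undirected graph from a kept-edge table; isolated taxa excluded."""
    g = nx.Graph(group_label=group_label)
    if len(edges) == 0:
        logger.warning("empty edge list: returning empty network")
        return g
    for row in edges.itertuples(index=False):
        u, v = str(row.taxon_i), str(row.taxon_j)
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        g.add_edge(u, v, rho=float(row.rho), sign=1 if row.rho >= 0 else -1)
    return g


def induce_subnetwork(
    meta: nx.Graph, table: CommunityTable, group_samples, group_label: str | None = None
) -> nx.Graph:
    """Subgraph of the meta-network on taxa present in the group's samples."""
    group_samples = list(group_samples)
    if not group_samples:
        raise ValueError("group_samples is empty")
    sub_counts = table.counts.loc[group_samples]
    present = set(sub_counts.columns[(sub_counts > 0).any(axis=0)])
    nodes = [n for n in meta.nodes if n in present]
    sub = nx.Graph(meta.subgraph(nodes))
    sub.graph["group_label"] = group_label
    if sub.number_of_nodes() == 0:
        logger.warning("no meta-network taxa present in group %r", group_label)
    return sub


# ---------------------------------------------------------------------------
# Topology metrics


def node_metrics(net: nx.Graph) -> list[NodeMetrics]:
    """Degree, unnormalized betweenness, within-component closeness, eigenvector.

    Eigenvector centrality is the principal eigenvector of the (unweighted)
    adjacency matrix scaled so the maximum node scores 1 (it concentrates on
    the dominant component of a disconnected graph).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(net.nodes)
    btw = nx.betweenness_centrality(net, normalized=False)
    clo = nx.closeness_centrality(net, wf_improved=False)
    adj = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    if len(nodes) == 1:
        eig = {nodes[0]: 1.0}
    else:
        w, v = np.linalg.eigh(adj)
        vec = np.abs(v[:, np.argmax(w)])
        vec = vec / vec.max() if vec.max() > 0 else np.ones(len(nodes))
        eig = dict(zip(nodes, vec))
    return [
        NodeMetrics(str(n), int(net.degree[n]), float(btw[n]), float(clo[n]), float(eig[n]))
        for n in nodes
    ]


def node_metrics_frame(metrics: list[NodeMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [m.taxon_id for m in metrics],
            "degree": [m.degree for m in metrics],
            "betweenness": [m.betweenness for m in metrics],
            "closeness": [m.closeness for m in metrics],
            "eigenvector": [m.eigenvector for m in metrics],
        }
    )


def network_metrics(net: nx.Graph, modularity_seed: int = 0) -> NetworkMetrics:
    """Whole-network topology summary.

    The clustering coefficient is the mean local clustering over nodes with
    degree >= 2 (global transitivity is reported alongside). Modularity uses
    deterministic greedy agglomeration (Clauset–Newman–Moore) on the
    unweighted graph; the seed argument is accepted for interface stability
    but the algorithm itself is deterministic.
    """
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n < 2:
        raise ValueError("need at least two nodes")
    local = nx.clustering(net)
    eligible = [v for node, v in local.items() if net.degree[node] >= 2]
    clustering = float(np.mean(eligible)) if eligible else 0.0
    if e > 0:
        communities = nx.algorithms.community.greedy_modularity_communities(net)
        modularity = float(nx.algorithms.community.modularity(net, communities))
    else:
        modularity = 0.0
    signs = [d.get("sign", 1) for _, _, d in net.edges(data=True)]
    return NetworkMetrics(
        nodes=n,
        edges=e,
        clustering_coefficient=clustering,
        average_degree=average_degree(n, e),
        graph_density=graph_density(n, e),
        modularity=modularity,
        transitivity=float(nx.transitivity(net)),
        positive_edges=int(sum(1 for s in signs if s >= 0)),
        negative_edges=int(sum(1 for s in signs if s < 0)),
        group_label=net.graph.get("group_label"),
    )


def keystone_species(
    metrics: list[NodeMetrics], degree_min: int = 100, betweenness_max: float = 5000.0
) -> list[str]:
    """Taxa with degree > degree_min and betweenness < betweenness_max.

    Both inequalities are strict (a node at exactly the degree cutoff does
    not qualify). Returned sorted by degree, descending.
    """
    hits = [m for m in metrics if m.degree > degree_min and m.betweenness < betweenness_max]
    hits.sort(key=lambda m: (-m.degree, m.taxon_id))
    return [m.taxon_id for m in hits]


def compare_groups(
    high_metrics: list[NodeMetrics], low_metrics: list[NodeMetrics], feature: str
) -> dict:
    """Wilcoxon rank-sum comparison of one node-level feature between groups."""
    if feature not in ("degree", "betweenness", "closeness", "eigenvector"):
        raise ValueError(f"unknown feature {feature!r}")
    x = [getattr(m, feature) for m in high_metrics]
    y = [getattr(m, feature) for m in low_metrics]
    stat, p = wilcoxon_rank_sum(x, y)
    return {
        "feature": feature,
        "statistic": stat,
        "p_value": p,
        "median_high": float(np.median(x)),
        "median_low": float(np.median(y)),
    }


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
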