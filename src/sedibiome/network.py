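"""Spearman co-occurrence network on dominant OTUs and its topology.

Edges connect OTU pairs whose relative abundances across samples correlate
with Spearman rho above a threshold AND a two-sided p-value below a
threshold (both conditions, no multiple-testing correction by default —
an optional Benjamini-Hochberg mode is provided).  Only positive
correlations form edges unless ``absolute=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CommunityTable
from .diversity import relative_abundance

logger = logging.getLogger("sedibiome")


@dataclass
class NetworkConfig:
    top_n: int = 100
    rho_min: float = 0.6
    p_max: float = 0.01
    module_seed: int = 0
    absolute: bool = False
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.rho_min < 1:
            raise ValueError("rho_min must be in (0, 1)")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    avg_degree: float
    apl: float
    diameter: int
    clustering: float
    modularity: float
    n_modules: int


def select_top_otus(table: CommunityTable, top_n: int) -> CommunityTable:
    """Keep the ``top_n`` OTUs with the highest summed relative abundance.

    Ranking is by the per-OTU sum over samples of within-sample relative
    abundance, descending; ties break lexicographically on OTU id.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > len(table.otu_ids):
        raise ValueError(f"top_n={top_n} exceeds {len(table.otu_ids)} OTUs")
    summed = relative_abundance(table).sum(axis=0)
    order = sorted(summed.index, key=lambda o: (-summed[o], str(o)))
    keep = order[:top_n]
    return CommunityTable(table.counts[keep], table.taxonomy)


def build_network(table: CommunityTable, config: NetworkConfig) -> nx.Graph:
    """Thresholded Spearman co-occurrence graph over the table's OTUs.

    All OTUs become nodes (isolates retained) carrying their summed relative
    abundance and, when taxonomy is present, a phylum; edges carry rho and p.
    Pairs involving a constant abundance vector have undefined rho and are
    skipped with a logged count.
    """
    if len(table.sample_ids) < 4:
        raise ValueError("need >= 4 samples for meaningful Spearman p-values")
    rel = relative_abundance(table)
    otus = list(rel.columns)
    arr = rel.to_numpy()
    res = stats.spearmanr(arr)
    if arr.shape[1] == 2:  # scipy returns scalars for two variables
        rho = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
        pval = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    else:
        rho, pval = res.statistic, res.pvalue

    constant = np.array([np.all(arr[:, i] == arr[0, i]) for i in range(arr.shape[1])])
    n_skipped = 0
    iu = np.triu_indices(len(otus), 1)
    cand_rho = rho[iu]
    cand_p = pval[iu]
    undef = constant[iu[0]] | constant[iu[1]] | np.isnan(cand_rho)
    n_skipped = int(undef.sum())
    if n_skipped:
        logger.info("build_network: %d pairs with undefined rho skipped", n_skipped)

    if config.bh_correct:
        ok = ~undef
        adj = np.full(cand_p.shape, np.nan)
        if ok.any():
            adj[ok] = multipletests(cand_p[ok], method="fdr_bh")[1]
        cand_p = adj

    strength = np.abs(cand_rho) if config.absolute else cand_rho
    keep = (~undef) & (strength > config.rho_min) & (cand_p < config.p_max)

    g = nx.Graph()
    summed = rel.sum(axis=0)
    for o in otus:
        attrs = {"abundance": float(summed[o])}
        if table.taxonomy is not None and o in table.taxonomy.index:
            lineage = str(table.taxonomy[o])
            attrs["phylum"] = lineage.split(";")[1].strip() if ";" in lineage else lineage
        g.add_node(o, **attrs)
    for i, j, r, p, k in zip(iu[0], iu[1], cand_rho, cand_p, keep):
        if k:
            g.add_edge(otus[i], otus[j], rho=float(r), p=float(p))
    return g


def assign_modules(g: nx.Graph, seed: int = 0) -> dict:
    """Louvain modularity maximisation; returns node -> module id."""
    if g.number_of_nodes() == 0:
        return {}
    communities = nx.community.louvain_communities(g, seed=seed)
    membership = {}
    for mid, nodes in enumerate(communities):
        for n in nodes:
            membership[n] = mid
    nx.set_node_attributes(g, membership, "module")
    return membership


def network_metrics(g: nx.Graph, module_seed: int = 0) -> NetworkMetrics:
    """Topology summary of a co-occurrence network.

    APL averages shortest paths over connected node pairs only; the diameter
    is that of the largest connected component; clustering is the mean local
    coefficient with degree<2 nodes contributing 0; modularity is Newman Q
    of a seeded Louvain partition.
    """
    v = g.number_of_nodes()
    if v == 0:
        logger.warning("network_metrics: empty graph, metrics zeroed")
        return NetworkMetrics(0, 0, 0.0, 0.0, 0, 0.0, 0.0, 0)
    e = g.number_of_edges()
    avg_degree = 2.0 * e / v

    path_sum, path_n = 0.0, 0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            if dst != src:
                path_sum += d
                path_n += 1
    apl = path_sum / path_n if path_n else 0.0

    if e:
        giant = g.subgraph(max(nx.connected_components(g), key=len))
        diameter = nx.diameter(giant)
    else:
        diameter = 0
    clustering = nx.average_clustering(g) if v else 0.0

    membership = assign_modules(g, seed=module_seed)
    communities = {}
    for node, mid in membership.items():
        communities.setdefault(mid, set()).add(node)
    comm_list = list(communities.values())
    modularity = nx.community.modularity(g, comm_list) if e else 0.0
    return NetworkMetrics(
        n_nodes=v, n_edges=e, avg_degree=avg_degree, apl=apl,
        diameter=int(diameter), clustering=float(clustering),
        modularity=float(modularity), n_modules=len(comm_list),
    )
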