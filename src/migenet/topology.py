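"""Bipartite topology: degrees, giant component, Latapy coefficients, KS tests.

The clustering coefficient of a node u is the mean, over all same-side
nodes v at distance exactly 2, of the neighborhood Jaccard overlap
|N(u) n N(v)| / |N(u) u N(v)| (the pairwise-Jaccard "dot" variant of the
Latapy bipartite clustering; min- and max-normalized variants are exposed
as options).  The redundancy coefficient of v is the fraction of unordered
neighbor pairs {u, w} of v that share some other neighbor v' != v — the
pairs that would survive in the one-mode projection if v were removed; it
is undefined for degree < 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from networkx.algorithms import bipartite as nx_bipartite
import networkx as nx
from scipy import stats

from migenet.network import BipartiteNetwork

CLUSTERING_MODES = ("jaccard", "min", "max")
_NX_MODE = {"jaccard": "dot", "min": "min", "max": "max"}


def degrees(net: BipartiteNetwork) -> dict[str, dict[str, int]]:
    """Per-side degree maps: {'microbe': {id: k}, 'gene': {id: k}}."""
    out: dict[str, dict[str, int]] = {"microbe": {}, "gene": {}}
    for side in out:
        for v in net.side_nodes(side):
            out[side][v] = net.graph.degree(v)
    return out


def giant_component(net: BipartiteNetwork) -> tuple[set[str], int]:
    """Largest connected component over nodes with degree > 0.

    An edgeless network has no components by this convention: returns
    (empty set, 0).
    """
    active = [v for v in net.graph if net.graph.degree(v) > 0]
    if not active:
        return set(), 0
    sub = net.graph.subgraph(active)
    gcc = max(nx.connected_components(sub), key=len)
    return set(gcc), len(gcc)


def _check_node(net: BipartiteNetwork, node: str) -> None:
    if node not in net.graph:
        raise KeyError(f"unknown node {node!r}")


def bipartite_clustering(net: BipartiteNetwork, node: str,
                         mode: str = "jaccard") -> float:
    """Latapy bipartite clustering coefficient of one node.

    Nodes with no distance-2 neighbor (including isolated nodes) get 0.
    """
    _check_node(net, node)
    if mode not in CLUSTERING_MODES:
        raise ValueError(f"mode must be one of {CLUSTERING_MODES}")
    cc = nx_bipartite.clustering(net.graph, nodes=[node], mode=_NX_MODE[mode])
    return float(cc[node])


def clustering_all(net: BipartiteNetwork, mode: str = "jaccard") -> dict[str, float]:
    if mode not in CLUSTERING_MODES:
        raise ValueError(f"mode must be one of {CLUSTERING_MODES}")
    cc = nx_bipartite.clustering(net.graph, mode=_NX_MODE[mode])
    return {v: float(c) for v, c in cc.items()}


def redundancy(net: BipartiteNetwork, node: str) -> float | None:
    """Redundancy coefficient of one node; None when degree < 2 (undefined)."""
    _check_node(net, node)
    if net.graph.degree(node) < 2:
        return None
    rc = nx_bipartite.node_redundancy(net.graph, [node])
    return float(rc[node])


def redundancy_all(net: BipartiteNetwork) -> dict[str, float | None]:
    defined = [v for v in net.graph if net.graph.degree(v) >= 2]
    rc = nx_bipartite.node_redundancy(net.graph, defined) if defined else {}
    return {v: (float(rc[v]) if v in rc else None) for v in net.graph}


def node_stats(net: BipartiteNetwork, mode: str = "jaccard") -> pd.DataFrame:
    """Per-node table: node_id, side, degree, clustering, redundancy.

    Redundancy is NaN where undefined (degree < 2).
    """
    cc = clustering_all(net, mode)
    rc = redundancy_all(net)
    rows = []
    for side in ("microbe", "gene"):
        for v in net.side_nodes(side):
            r = rc[v]
            rows.append({
                "node_id": v,
                "side": side,
                "degree": net.graph.degree(v),
                "clustering": cc[v],
                "redundancy": float("nan") if r is None else r,
            })
    return pd.DataFrame(rows, columns=["node_id", "side", "degree",
                                       "clustering", "redundancy"])


def ks_two_sample(sample_a, sample_b, method: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_a - ECDF_b|; two-sided p-value from the asymptotic
    Kolmogorov distribution with the standard effective-n scaling by
    default (``method="exact"`` available for small samples).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def rank_by_degree(net: BipartiteNetwork, side: str, k: int = 10) -> list[str]:
    """Top-k nodes of one side by degree, ties broken by node id ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = net.side_nodes(side)
    ranked = sorted(nodes, key=lambda v: (-net.graph.degree(v), v))
    return ranked[:k]


def side_distribution_tests(net: BipartiteNetwork, mode: str = "jaccard",
                            method: str = "asymp") -> dict:
    """KS comparison of microbe vs gene coefficient distributions.

    Degree-0 nodes are excluded from the clustering and redundancy
    comparisons (they carry no topological signal); redundancy further
    excludes degree-1 nodes, where it is undefined.
    """
    table = node_stats(net, mode)
    active = table[table.degree > 0]
    out = {}
    for metric in ("degree", "clustering", "redundancy"):
        sub = active.dropna(subset=[metric]) if metric == "redundancy" else active
        a = sub.loc[sub.side == "microbe", metric].to_numpy()
        b = sub.loc[sub.side == "gene", metric].to_numpy()
        if a.size == 0 or b.size == 0:
            out[metric] = {"D": None, "p_value": None,
                           "n_microbes": int(a.size), "n_genes": int(b.size)}
            continue
        d, p = ks_two_sample(a, b, method=method)
        out[metric] = {"D": d, "p_value": p,
                       "n_microbes": int(a.size), "n_genes": int(b.size)}
    return out
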