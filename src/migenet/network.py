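"""Quantile thresholding of MI matrices and bipartite network construction.

The network keeps *every* measured microbe and gene as a node, whether or
not it participates in any retained edge; edges connect only nodes on
opposite sides.  The edge threshold is the nearest-rank empirical quantile
of all |U| x |V| MI values of the network being built (default quantile
0.995), and only pairs with MI *strictly above* the threshold become edges,
so a fully tied MI matrix yields an edgeless — but valid — network.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import networkx as nx
import numpy as np
from scipy import stats

from migenet.mi import MIResult

Edge = tuple[str, str, float]


class StructuralError(ValueError):
    """Edge violates bipartiteness or references an unknown node."""


class ComparabilityError(ValueError):
    """Two networks share no measurement universe."""


def threshold_edges(mi: MIResult, quantile: float = 0.995) -> tuple[list[Edge], float]:
    """Select microbe-gene pairs strictly above the MI quantile.

    The threshold is the nearest-rank empirical quantile of the flattened
    MI matrix (the value at rank ``ceil(q * P)`` of the sorted P values).
    Returns the retained ``(microbe_id, gene_id, weight)`` edges and the
    threshold value.  With all-distinct values the retained count is
    ``floor((1 - q) * P)`` up to +-1.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    flat = mi.mi.ravel()
    if flat.size == 0:
        raise ValueError("empty MI matrix")
    rank = max(1, math.ceil(quantile * flat.size))
    threshold = float(np.partition(flat, rank - 1)[rank - 1])
    rows, cols = np.nonzero(mi.mi > threshold)
    edges = [
        (mi.microbe_ids[i], mi.gene_ids[j], float(mi.mi[i, j]))
        for i, j in zip(rows.tolist(), cols.tolist())
    ]
    return edges, threshold


@dataclass
class BipartiteNetwork:
    """Weighted bipartite microbe-gene network retaining isolated nodes."""

    graph: nx.Graph
    microbes: list[str]
    genes: list[str]
    threshold_value: float = float("nan")
    quantile: float = float("nan")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        """Unordered edge identity as (microbe, gene) pairs, weights ignored."""
        out = set()
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["side"] == "microbe":
                out.add((u, v))
            else:
                out.add((v, u))
        return out

    def side_nodes(self, side: str) -> list[str]:
        if side == "microbe":
            return list(self.microbes)
        if side == "gene":
            return list(self.genes)
        raise ValueError(f"unknown side {side!r}")

    def degree_of(self, node: str) -> int:
        if node not in self.graph:
            raise KeyError(f"unknown node {node!r}")
        return self.graph.degree(node)


def build_bipartite(
    edges: list[Edge] | list[tuple[str, str]],
    microbe_ids: list[str],
    gene_ids: list[str],
    threshold_value: float = float("nan"),
    quantile: float = float("nan"),
) -> BipartiteNetwork:
    """Assemble the bipartite network from an edge list and full node universes.

    All ids in ``microbe_ids`` and ``gene_ids`` become nodes, including
    those that participate in no edge.  Edges whose endpoints lie on the
    same side, or reference unknown ids, raise :class:`StructuralError`.
    """
    mset, gset = set(microbe_ids), set(gene_ids)
    both = mset & gset
    if both:
        raise StructuralError(f"ids present on both sides: {sorted(both)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(microbe_ids, side="microbe", bipartite=0)
    g.add_nodes_from(gene_ids, side="gene", bipartite=1)
    for edge in edges:
        u, v, *rest = edge
        w = float(rest[0]) if rest else 1.0
        if u in mset and v in gset:
            g.add_edge(u, v, mi_weight=w)
        elif u in gset and v in mset:
            g.add_edge(v, u, mi_weight=w)
        elif u in mset and v in mset or u in gset and v in gset:
            raise StructuralError(f"edge ({u!r}, {v!r}) joins two same-side nodes")
        else:
            unknown = [x for x in (u, v) if x not in mset | gset]
            raise StructuralError(f"edge references unknown ids: {unknown}")
    return BipartiteNetwork(g, list(microbe_ids), list(gene_ids),
                            threshold_value, quantile)


def network_from_mi(mi: MIResult, quantile: float = 0.995) -> BipartiteNetwork:
    """Threshold an MI matrix and build the network in one step."""
    edges, threshold = threshold_edges(mi, quantile)
    return build_bipartite(edges, mi.microbe_ids, mi.gene_ids, threshold, quantile)


@dataclass
class NetworkComparison:
    """Composition and connectivity similarity between two networks.

    Jaccard similarities are percentualized (100 * |A n B| / |A u B|):
    nodes compared over the giant-connected-component membership of each
    network, edges over unordered (microbe, gene) identity ignoring
    weights.  Spearman correlations compare the degree vectors of the two
    networks per side, over the full shared node universe (degree-0 nodes
    included), with average-rank tie handling.
    """

    node_jaccard_gcc: float
    edge_jaccard: float
    spearman_microbes: float
    spearman_genes: float

    def to_dict(self) -> dict:
        return {
            "node_jaccard_gcc_pct": self.node_jaccard_gcc,
            "edge_jaccard_pct": self.edge_jaccard,
            "spearman_microbes": self.spearman_microbes,
            "spearman_genes": self.spearman_genes,
        }


def _jaccard_pct(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 100.0
    return 100.0 * len(a & b) / len(union)


def _degree_spearman(a: BipartiteNetwork, b: BipartiteNetwork, side: str) -> float:
    universe = sorted(set(a.side_nodes(side)) | set(b.side_nodes(side)))
    da = np.array([a.graph.degree(v) if v in a.graph else 0 for v in universe])
    db = np.array([b.graph.degree(v) if v in b.graph else 0 for v in universe])
    if np.array_equal(da, db):
        return 1.0
    if da.std() == 0 or db.std() == 0:
        return float("nan")  # a constant ranking has no rank correlation
    rho = stats.spearmanr(da, db).statistic
    return float(rho)


def compare_networks(a: BipartiteNetwork, b: BipartiteNetwork) -> NetworkComparison:
    """Compare two networks built over comparable measurement universes."""
    from migenet.topology import giant_component

    shared = (set(a.microbes) | set(a.genes)) & (set(b.microbes) | set(b.genes))
    if not shared:
        raise ComparabilityError("networks share no nodes; nothing to compare")
    gcc_a, _ = giant_component(a)
    gcc_b, _ = giant_component(b)
    return NetworkComparison(
        node_jaccard_gcc=_jaccard_pct(gcc_a, gcc_b),
        edge_jaccard=_jaccard_pct(a.edge_set(), b.edge_set()),
        spearman_microbes=_degree_spearman(a, b, "microbe"),
        spearman_genes=_degree_spearman(a, b, "gene"),
    )
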