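"""Over-representation analysis of microbe gene-neighborhoods.

For each of the top-ranked microorganisms by degree, the set of genes
adjacent to it in the bipartite network is tested for over-representation
in each annotated gene set with the hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeom(N, K, n)

where N is the full gene universe of the network (all measured genes by
default — the "full genome" reference), K the gene-set size, n the
neighborhood size and k their overlap.  P-values are Benjamini-Hochberg
adjusted within each microbe's family of tests (a pooled option corrects
across all microbes at once) and rows are flagged significant at
FDR <= 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from migenet.network import BipartiteNetwork
from migenet.topology import rank_by_degree

TABLE_COLUMNS = ["microbe_id", "set_name", "overlap", "set_size",
                 "neighborhood_size", "universe_size", "p_value", "fdr",
                 "significant"]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions over a gene universe.

    ``sets`` maps set name -> (description, frozenset of member gene ids).
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    def harmonize(self, universe, min_size: int = 5,
                  max_size: int = 500) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and apply size guardrails.

        Sets falling outside [min_size, max_size] after intersection are
        dropped.  Genes of the universe absent from every set stay in the
        universe (conservative ORA background).
        """
        universe = frozenset(universe)
        kept = {}
        for name, (desc, members) in self.sets.items():
            inter = members & universe
            if min_size <= len(inter) <= max_size:
                kept[name] = (desc, frozenset(inter))
        return GeneSetCollection(kept, universe)

    def __len__(self) -> int:
        return len(self.sets)


def neighborhood(net: BipartiteNetwork, microbe_id: str) -> set[str]:
    """Genes adjacent to a microbe in the network; empty set allowed."""
    if microbe_id not in net.graph:
        raise KeyError(f"unknown microbe {microbe_id!r}")
    if net.graph.nodes[microbe_id]["side"] != "microbe":
        raise KeyError(f"{microbe_id!r} is not a microbe node")
    return set(net.graph.neighbors(microbe_id))


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a size-n draw from a universe of N genes
    of which K are annotated.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentTable:
    """Per-(microbe, gene set) hypergeometric ORA results.

    ``table`` has one row per test; ``untestable`` lists top-ranked
    microbes with an empty neighborhood (zero test rows).
    """

    table: pd.DataFrame
    untestable: list[str] = field(default_factory=list)
    fdr_threshold: float = 0.05

    def significant(self) -> pd.DataFrame:
        return self.table[self.table.significant]

    def summary(self) -> pd.DataFrame:
        """One row per tested microbe: counts of tests and significant hits."""
        rows = []
        for microbe, grp in self.table.groupby("microbe_id", sort=False):
            rows.append({"microbe_id": microbe, "n_tests": len(grp),
                         "n_significant": int(grp.significant.sum())})
        for microbe in self.untestable:
            rows.append({"microbe_id": microbe, "n_tests": 0, "n_significant": 0})
        return pd.DataFrame(rows, columns=["microbe_id", "n_tests", "n_significant"])

    def heatmap_frame(self) -> pd.DataFrame:
        """Microbe x term matrix of -log10(FDR) for significant rows, else 0."""
        sig = self.significant()
        if sig.empty:
            return pd.DataFrame()
        mat = sig.assign(neglog_fdr=-np.log10(sig.fdr.clip(lower=1e-300)))
        return mat.pivot_table(index="microbe_id", columns="set_name",
                               values="neglog_fdr", fill_value=0.0)


def ora(
    net: BipartiteNetwork,
    sets: GeneSetCollection,
    side_rank_k: int = 10,
    fdr_threshold: float = 0.05,
    universe: str = "all",
    pooled: bool = False,
    min_size: int = 5,
    max_size: int = 500,
) -> EnrichmentTable:
    """ORA over the gene neighborhoods of the top-degree microbes.

    Parameters
    ----------
    universe
        ``"all"`` (default) uses every measured gene in the network as the
        reference set; ``"annotated"`` restricts it to genes appearing in
        at least one harmonized set.
    pooled
        Correct across all microbes' tests at once instead of within each
        microbe's family.
    """
    if not net.genes:
        raise ValueError("network has an empty gene universe")
    if universe not in ("all", "annotated"):
        raise ValueError("universe must be 'all' or 'annotated'")

    gene_universe = frozenset(net.genes)
    harmonized = sets.harmonize(gene_universe, min_size=min_size, max_size=max_size)
    if universe == "annotated":
        annotated = frozenset().union(
            *(m for _, m in harmonized.sets.values())) if harmonized.sets else frozenset()
        gene_universe = annotated
        harmonized = GeneSetCollection(harmonized.sets, gene_universe or frozenset())

    top = rank_by_degree(net, "microbe", side_rank_k)
    rows: list[dict] = []
    untestable: list[str] = []
    n_universe = len(gene_universe)
    for microbe in top:
        neigh = neighborhood(net, microbe) & gene_universe
        if not neigh:
            untestable.append(microbe)
            continue
        for name in sorted(harmonized.sets):
            _, members = harmonized.sets[name]
            k = len(neigh & members)
            rows.append({
                "microbe_id": microbe,
                "set_name": name,
                "overlap": k,
                "set_size": len(members),
                "neighborhood_size": len(neigh),
                "universe_size": n_universe,
                "p_value": hypergeom_pvalue(k, len(members), len(neigh), n_universe),
            })

    table = pd.DataFrame(rows, columns=TABLE_COLUMNS[:-2])
    if table.empty:
        table = table.reindex(columns=TABLE_COLUMNS)
        return EnrichmentTable(table, untestable, fdr_threshold)

    if pooled:
        table["fdr"] = bh_adjust(table.p_value.to_numpy())
    else:
        table["fdr"] = np.nan
        for _, idx in table.groupby("microbe_id", sort=False).groups.items():
            table.loc[idx, "fdr"] = bh_adjust(table.loc[idx, "p_value"].to_numpy())
    table["significant"] = table.fdr <= fdr_threshold
    return EnrichmentTable(table, untestable, fdr_threshold)
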