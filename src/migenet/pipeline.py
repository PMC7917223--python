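"""End-to-end pipeline: matrices -> MI -> networks -> topology -> ORA -> tokens.

For each condition group (early: tumor stages I/II; late: stages III/IV)
the pipeline computes the pairwise MI matrix on that group's samples,
thresholds it at the configured quantile (default 0.995) into a bipartite
network retaining all measured features, writes per-node topology and
microbe-vs-gene KS distribution tests, runs neighborhood ORA for the
top-degree microbes, and summarizes the significant terms' tokens.  It
then compares the two networks (Jaccard similarities, degree-rank
Spearman) and writes a machine-readable manifest with every parameter,
realized threshold and edge count, so a run can be reproduced
bit-identically from the manifest alone.
"""

from __future__ import annotations

import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from migenet import io as mio
from migenet.containers import AlignmentError, OmicsMatrix
from migenet.enrichment import GeneSetCollection, ora
from migenet.mi import BIN_RULES, pairwise_mi
from migenet.network import compare_networks, network_from_mi
from migenet.tokens import TokenSummary, venn_partition
from migenet.topology import node_stats, rank_by_degree, side_distribution_tests

logger = logging.getLogger("migenet")

_STAGE_RE = re.compile(r"^(?:stage\s*)?(i{1,3}v?|iv)[a-c]?$", re.IGNORECASE)
_EARLY = {"i", "ii"}
_LATE = {"iii", "iv"}


def normalize_stage(label: str) -> str | None:
    """Map a tumor-stage label to 'early' or 'late'; None if unrecognized.

    Stages I/II group as early, III/IV as late; sub-stage suffixes (IIIa,
    IVb, ...) collapse to their Roman base.  Labels already reading
    'early'/'late' pass through.
    """
    s = str(label).strip().lower()
    if s in ("early", "late"):
        return s
    m = _STAGE_RE.match(s)
    if not m:
        return None
    base = m.group(1).lower()
    if base in _EARLY:
        return "early"
    if base in _LATE:
        return "late"
    return None


@dataclass
class RunConfig:
    """Paths and parameters for one end-to-end run."""

    gene_matrix: str
    microbe_matrix: str
    stage_labels: str
    gene_sets: str | None = None
    out_dir: str = "migenet_out"
    nbins: int | None = None
    bin_rule: str = "cube-root"
    quantile: float = 0.995
    top_k: int = 10
    fdr_threshold: float = 0.05
    token_k: int = 20
    mi_unit: str = "nats"
    clustering_mode: str = "jaccard"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.quantile < 1.0):
            raise ValueError(f"quantile must be in (0, 1), got {self.quantile}")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.top_k < 1 or self.token_k < 1:
            raise ValueError("top_k and token_k must be >= 1")
        if self.bin_rule not in BIN_RULES:
            raise ValueError(f"bin_rule must be one of {BIN_RULES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_groups(labels: pd.Series, samples: list[str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {"early": [], "late": []}
    dropped = []
    for s in samples:
        if s not in labels.index:
            dropped.append(s)
            continue
        stage = normalize_stage(labels.loc[s])
        if stage is None:
            dropped.append(s)
        else:
            groups[stage].append(s)
    if dropped:
        logger.info("excluded %d samples with missing/unrecognized stage: %s",
                    len(dropped), dropped[:5])
    groups["_dropped"] = dropped  # type: ignore[assignment]
    return groups


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Deterministic given the config: every output file is written with
    sorted keys and fixed float formatting, so two runs from the same
    config are byte-identical.
    """
    genes = mio.read_matrix(config.gene_matrix, "gene")
    microbes = mio.read_matrix(config.microbe_matrix, "microbe")
    genes.check_aligned(microbes)
    labels = mio.read_stage_labels(config.stage_labels)
    gene_sets = mio.read_gmt(config.gene_sets) if config.gene_sets else None

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    groups = _stage_groups(labels, genes.sample_ids)
    dropped = groups.pop("_dropped")
    for stage in ("early", "late"):
        if not groups[stage]:
            raise ValueError(f"no samples labeled {stage!r} after grouping")

    from migenet import __version__

    manifest: dict = {
        "version": __version__,
        "parameters": config.to_dict(),
        "n_genes": genes.n_features,
        "n_microbes": microbes.n_features,
        "samples": {s: groups[s] for s in ("early", "late")},
        "excluded_samples": dropped,
        "stages": {},
    }

    networks = {}
    tokens = {}
    for stage in ("early", "late"):
        cols = groups[stage]
        g = genes.subset_samples(cols)
        m = microbes.subset_samples(cols)
        logger.info("stage %s: %d samples, %d genes, %d microbes",
                    stage, len(cols), g.n_features, m.n_features)
        mi = pairwise_mi(m, g, nbins=config.nbins, unit=config.mi_unit,
                         bin_rule=config.bin_rule)
        mio.write_mi(mi, dense_path=out / f"mi_{stage}.tsv")
        net = network_from_mi(mi, config.quantile)
        networks[stage] = net
        mio.write_edge_list(net, out / f"edges_{stage}.tsv")
        mio.write_graphml(net, out / f"network_{stage}.graphml")

        stats = node_stats(net, config.clustering_mode)
        stats.to_csv(out / f"node_stats_{stage}.tsv", sep="\t", index=False,
                     float_format=mio.FLOAT_FMT)
        ks = side_distribution_tests(net, config.clustering_mode)
        mio.write_json(ks, out / f"ks_tests_{stage}.json")

        stage_info = {
            "n_samples": len(cols),
            "nbins_used": mi.nbins_used,
            "threshold_value": net.threshold_value,
            "n_edges": net.n_edges,
            "top_microbes": rank_by_degree(net, "microbe", config.top_k),
        }
        logger.info("stage %s: threshold %.6g, %d edges", stage,
                    net.threshold_value, net.n_edges)

        if gene_sets is not None:
            result = ora(net, gene_sets, side_rank_k=config.top_k,
                         fdr_threshold=config.fdr_threshold)
            result.table.to_csv(out / f"enrichment_{stage}.tsv", sep="\t",
                                index=False, float_format=mio.FLOAT_FMT)
            heat = result.heatmap_frame()
            heat.to_csv(out / f"enrichment_heatmap_{stage}.tsv", sep="\t",
                        float_format=mio.FLOAT_FMT)
            sig = result.significant()
            descs = [gene_sets.sets[name][0] for name in sig.set_name]
            summary = TokenSummary.from_terms(
                stage, list(sig.set_name) + descs, k=config.token_k)
            tokens[stage] = summary
            counts = pd.DataFrame(
                sorted(summary.counts.items(), key=lambda kv: (-kv[1], kv[0])),
                columns=["token", "count"])
            counts.to_csv(out / f"tokens_{stage}.tsv", sep="\t", index=False)
            stage_info["n_significant"] = int(sig.shape[0])
            stage_info["untestable_microbes"] = result.untestable
        manifest["stages"][stage] = stage_info

    comparison = compare_networks(networks["early"], networks["late"])
    mio.write_json(comparison.to_dict(), out / "comparison.json")
    manifest["comparison"] = comparison.to_dict()

    if tokens:
        only_e, shared, only_l = venn_partition(
            set(tokens["early"].top_k), set(tokens["late"].top_k))
        venn = {"only_early": sorted(only_e), "shared": sorted(shared),
                "only_late": sorted(only_l)}
        mio.write_json(venn, out / "token_venn.json")
        manifest["token_venn_sizes"] = {k: len(v) for k, v in venn.items()}

    mio.write_json(manifest, out / "manifest.json")
    return manifest
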