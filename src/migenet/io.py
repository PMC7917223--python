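"""File formats: TSV matrices, stage labels, GMT gene sets, GraphML, JSON.

Matrix dialect: tab-separated, first column feature ids, header row of
sample ids.  MI results are written both as a dense matrix TSV (microbes
as rows) and a long-format TSV (microbe_id, gene_id, mi).  Networks are
written as GraphML (node attribute ``side``, edge attribute ``mi_weight``)
and a 3-column TSV edge list.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from migenet.containers import OmicsMatrix
from migenet.mi import MIResult
from migenet.network import BipartiteNetwork, build_bipartite


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or id."""


FLOAT_FMT = "%.10g"


def read_matrix(path, side: str) -> OmicsMatrix:
    """Read a feature x sample TSV matrix.

    Rejects duplicate feature ids, ragged rows and non-numeric cells,
    naming the line (1-based, header = line 1) or id in the error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate feature id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at line "
                f"{row + 2}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        raise ParseError(f"{path}: missing values are not supported")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None  # round-trip identity with in-memory matrices
    return OmicsMatrix(df, side)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id",
                       float_format=FLOAT_FMT)


def read_stage_labels(path) -> pd.Series:
    """Two-column TSV (sample_id, stage) -> Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (sample_id, stage)")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="stage")
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    return s


def write_stage_labels(labels: pd.Series, path) -> None:
    labels.rename_axis("sample_id").to_frame().to_csv(path, sep="\t")


def read_gmt(path):
    """Read a GMT file (set name, description, member genes per line)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    universe: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected name, description and "
                    "at least one gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set {name!r}")
            if not genes:
                raise ParseError(f"{path}: line {lineno}: set {name!r} is empty")
            sets[name] = (desc, frozenset(genes))
            universe.update(genes)
    from migenet.enrichment import GeneSetCollection as GSC

    return GSC(sets, frozenset(universe))


def write_gmt(collection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc, members = collection.sets[name]
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_mi(result: MIResult, dense_path=None, long_path=None) -> None:
    if dense_path is not None:
        result.to_dense_frame().to_csv(dense_path, sep="\t",
                                       index_label="microbe_id",
                                       float_format=FLOAT_FMT)
    if long_path is not None:
        result.to_long_frame().to_csv(long_path, sep="\t", index=False,
                                      float_format=FLOAT_FMT)


def write_edge_list(net: BipartiteNetwork, path) -> None:
    rows = sorted(
        (u, v, net.graph.edges[u, v].get("mi_weight", float("nan")))
        for u, v in net.edge_set())
    df = pd.DataFrame(rows, columns=["microbe_id", "gene_id", "mi"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edge_list(path, microbe_ids, gene_ids, **kwargs) -> BipartiteNetwork:
    df = pd.read_csv(path, sep="\t", header=0)
    edges = [(str(r.microbe_id), str(r.gene_id), float(r.mi))
             for r in df.itertuples()]
    return build_bipartite(edges, microbe_ids, gene_ids, **kwargs)


def write_graphml(net: BipartiteNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_sanitize(obj), fh, indent=2, sort_keys=True,
                  allow_nan=False, default=_json_default)
        fh.write("\n")


def _sanitize(obj):
    """NaN/inf -> null (strict JSON); recurse through containers."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    return obj


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_dataset(dataset, out_dir) -> dict[str, str]:
    """Write a synthetic dataset's components as TSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_matrix": str(out / "gene_matrix.tsv"),
        "microbe_matrix": str(out / "microbe_matrix.tsv"),
        "stage_labels": str(out / "stage_labels.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    write_matrix(dataset.gene_matrix, paths["gene_matrix"])
    write_matrix(dataset.microbe_matrix, paths["microbe_matrix"])
    write_stage_labels(dataset.stage_labels, paths["stage_labels"])
    pd.DataFrame(dataset.truth).to_csv(paths["truth"], sep="\t", index=False)
    return paths
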