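"""Readers and writers for every external text representation.

Formats: tab-separated expression matrices (miRNA rows, sample columns),
two-column sample label files, GEO series-matrix files, two-column
miRNA->gene target tables, GMT pathway files, and SIF/GraphML network
exports readable by Cytoscape and friends.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PathwayAnnotation, TargetMap

MISSING_TOKENS = ("", "NA", "NaN", "nan", "null")


# ---------------------------------------------------------------------------
# expression matrices

def read_expression(path: str | Path, labels_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a TSV expression matrix (and optionally its label file).

    Missing cells (empty, ``NA``, ``NaN``) enter the missing mask as NaN.
    Duplicate miRNA or sample ids raise, naming the duplicate.
    """
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS), keep_default_na=False
    )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    groups = read_labels(labels_path) if labels_path is not None else None
    return ExpressionMatrix(frame, groups)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    """Write matrix (and optionally labels) as TSV; missing cells become ``NA``."""
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="mirna_id")
    if labels_path is not None:
        if matrix.groups is None:
            raise ValueError("matrix has no group labels to write")
        matrix.groups.rename("group").to_csv(labels_path, sep="\t", index_label="sample")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample, group) TSV with a header row."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (sample, group)")
    return pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].values)


def read_geo_series_matrix(path: str | Path) -> ExpressionMatrix:
    """Parse a GEO series-matrix text file into an expression matrix.

    Only the probe table between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is read; sample titles/accessions form the
    column names and group labels are left unset for the caller to assign.
    """
    lines = Path(path).read_text().splitlines()
    try:
        begin = next(i for i, l in enumerate(lines)
                     if l.strip().lower().startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.strip().lower().startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError(
            f"{path}: missing series_matrix_table_begin/end markers"
        ) from None
    if end <= begin + 1:
        raise ValueError(f"{path}: empty series-matrix table")

    def split(line: str) -> list[str]:
        return [f.strip().strip('"') for f in line.rstrip("\n").split("\t")]

    header = split(lines[begin + 1])
    sample_ids = header[1:]
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for line in lines[begin + 2 : end]:
        if not line.strip():
            continue
        fields = split(line)
        probe_ids.append(fields[0])
        rows.append(
            [np.nan if f in MISSING_TOKENS else float(f) for f in fields[1:]]
        )
    frame = pd.DataFrame(rows, index=probe_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(frame, groups=None)


# ---------------------------------------------------------------------------
# annotations

def read_target_table(path: str | Path) -> set[tuple[str, str]]:
    """Read one two-column (miRNA, gene) TSV into a set of links."""
    table = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    return {(str(m), str(g)) for m, g in zip(table.iloc[:, 0], table.iloc[:, 1])}


def read_consensus_targets(db_paths: Sequence[str | Path], min_db: int = 4) -> TargetMap:
    """Assemble a consensus target map from several prediction databases.

    A (miRNA, gene) link is kept iff it occurs in at least ``min_db``
    distinct source files.  The default of 4 reads "more than 3 databases"
    literally; pass ``min_db=3`` for the inclusive reading.
    """
    if min_db < 1:
        raise ValueError("min_db must be >= 1")
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for path in db_paths:
        for link in read_target_table(path):
            counts[link] += 1
    kept: dict[str, set[str]] = defaultdict(set)
    for (mirna, gene), c in counts.items():
        if c >= min_db:
            kept[mirna].add(gene)
    if not kept:
        warnings.warn(f"no (miRNA, gene) link present in >= {min_db} databases", stacklevel=2)
    return TargetMap({m: frozenset(g) for m, g in kept.items()})


def write_targets(target_map: TargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna in sorted(target_map.targets):
            for gene in sorted(target_map.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_gmt(path: str | Path) -> PathwayAnnotation:
    """Read a GMT file (set name, optional description, member genes)."""
    gene_sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            # tolerate files without a description column
            pid, genes = fields[0], fields[1:]
            desc = ""
        else:
            pid, desc, genes = fields[0], fields[1], fields[2:]
        gene_sets[pid] = frozenset(g for g in genes if g)
        names[pid] = desc
    return PathwayAnnotation(gene_sets, names)


def write_gmt(pathways: PathwayAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways.gene_sets):
            desc = pathways.names.get(pid, pid)
            genes = "\t".join(sorted(pathways.gene_sets[pid]))
            fh.write(f"{pid}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# networks

def write_network(network: nx.Graph, path: str | Path, format: str = "SIF") -> None:
    """Export a synergy network for graph viewers.

    SIF rows are ``a <pos|neg> b`` by the sign of the edge's Pearson CE;
    GraphML carries ``ce`` and ``n_significant_pathways`` edge attributes.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    fmt = format.upper()
    if fmt == "SIF":
        with open(path, "w") as fh:
            for a, b, data in sorted(network.edges(data=True)):
                relation = "pos" if data.get("ce", 0.0) > 0 else "neg"
                fh.write(f"{a}\t{relation}\t{b}\n")
    elif fmt == "GRAPHML":
        export = nx.Graph()
        export.add_nodes_from(network.nodes())
        for a, b, data in network.edges(data=True):
            export.add_edge(
                a, b,
                ce=float(data.get("ce", 0.0)),
                n_significant_pathways=int(len(data.get("pathways", ()))),
            )
        nx.write_graphml(export, path)
    else:
        raise ValueError(f"unknown network format: {format!r} (use SIF or GraphML)")
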