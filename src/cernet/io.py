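"""Readers and writers for the plain-text formats used across stages.

Expression: TSV with feature ids in the first column, one column per
sample, plus a two-column sample->group TSV. Targets: TSV with
``source_id, target_id, database``. Gene sets: GMT. PPI: SIF or
two-column edge list. GEO series-matrix files ("!"-prefixed metadata,
tab-separated matrix block) are also accepted for real accessions.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd

from cernet.dge import ExpressionDataset, ValidationError


# ---------------------------------------------------------------- expression

def read_expression(matrix_path, groups_path, case_label: str = "TAD") -> ExpressionDataset:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    groups.index = groups.index.astype(str)
    return ExpressionDataset(matrix, groups, case_label=case_label)


def write_expression(dataset: ExpressionDataset, matrix_path, groups_path) -> None:
    mat = dataset.matrix.copy()
    mat.index.name = "feature_id"
    mat.to_csv(matrix_path, sep="\t")
    grp = dataset.groups.rename("group").to_frame()
    grp.index.name = "sample_id"
    grp.to_csv(groups_path, sep="\t")


def read_series_matrix(path, case_label: str = "TAD",
                       case_samples: list[str] | None = None) -> ExpressionDataset:
    """Parse a GEO series-matrix TSV (comment lines prefixed '!').

    Group labels must be supplied via ``case_samples`` (sample accessions
    of the case group); remaining samples become controls.
    """
    rows: list[list[str]] = []
    header: list[str] | None = None
    in_table = False
    with open(path, "rt", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not in_table or not line:
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None:
        raise ValidationError(f"no series-matrix table block found in {path}")
    matrix = pd.DataFrame(rows, columns=header).set_index(header[0])
    matrix = matrix.apply(pd.to_numeric, errors="coerce")
    matrix = matrix.loc[~matrix.index.duplicated(keep="first")]
    if case_samples is None:
        raise ValidationError("case_samples required for series-matrix input")
    missing = set(case_samples) - set(matrix.columns)
    if missing:
        raise ValidationError(f"case samples absent from matrix: {sorted(missing)}")
    groups = pd.Series(
        ["TAD" if c in set(case_samples) else "CON" for c in matrix.columns],
        index=matrix.columns,
    )
    if case_label != "TAD":
        groups = groups.replace({"TAD": case_label})
    return ExpressionDataset(matrix, groups, case_label=case_label)


# ------------------------------------------------------------------- targets

TARGET_COLUMNS = ["source_id", "target_id", "database"]


def read_target_tsv(path) -> pd.DataFrame:
    """Read a target table; malformed rows raise with their line number."""
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != TARGET_COLUMNS:
            raise ValidationError(
                f"{path}: expected header {TARGET_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3 or any(not f.strip() for f in row[:3]):
                raise ValidationError(f"{path}:{lineno}: malformed row {row!r}")
            records.append([f.strip() for f in row[:3]])
    return pd.DataFrame(records, columns=TARGET_COLUMNS)


def write_target_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.loc[:, TARGET_COLUMNS].to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- gene sets

def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT -> {term_id: (description, member gene set)}."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT row needs >= 3 fields")
            term, desc = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            sets[term] = (desc, genes)
    return sets


def write_gmt(sets: dict[str, tuple[str, frozenset[str]]], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for term in sorted(sets):
            desc, genes = sets[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ----------------------------------------------------------------------- PPI

def read_ppi(path) -> nx.Graph:
    """Read a PPI graph from SIF (node1 <tab> relation <tab> node2) or a
    two-column edge list; extra columns ignored, undirected, deduplicated,
    self-loops dropped. A header row naming its columns is skipped."""
    path = Path(path)
    graph = nx.Graph()
    header_words = {"node1", "node2", "source", "target", "protein1", "protein2"}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and any(p.lower() in header_words for p in parts[:3]):
                continue
            if path.suffix.lower() == ".sif":
                if len(parts) < 3:
                    if len(parts) == 1:  # isolated node, legal SIF
                        graph.add_node(parts[0])
                        continue
                    raise ValidationError(f"{path}:{lineno}: bad SIF row {line!r}")
                a, b = parts[0], parts[2]
            else:
                if len(parts) < 2:
                    raise ValidationError(f"{path}:{lineno}: bad edge row {line!r}")
                a, b = parts[0], parts[1]
            if a != b:
                graph.add_edge(a, b)
    return graph


def write_sif(graph: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(n for n in graph.nodes() if graph.degree(n) == 0):
            fh.write(f"{node}\n")


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node1\tnode2\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")
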