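"""ceRNA network assembly.

Co-miRNAs / co-mRNAs are set intersections between per-layer DEG lists
and predicted-target tables; miRNA->mRNA pairs must carry multi-database
support (default: all three databases); triplets are enumerated
exhaustively over the filtered bipartite relations. An optional filter
keeps only expression-direction-consistent triplets (circRNA and mRNA
co-directional, miRNA opposite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from cernet.dge import ValidationError
from cernet.io import TARGET_COLUMNS, read_target_tsv

logger = logging.getLogger(__name__)

CIRC_MI = "circRNA->miRNA"
MI_M = "miRNA->mRNA"


def normalize_id(identifier: str) -> str:
    """Optional id normalization hook: trim whitespace, fold 'miR'/'mir'
    prefix case. Off by default everywhere; exact string match is the rule."""
    s = identifier.strip()
    parts = s.split("-")
    if len(parts) >= 3 and parts[0].lower() == "hsa" and parts[1].lower() in ("mir", "let"):
        return "-".join([parts[0].lower(), parts[1].lower(), *parts[2:]])
    if len(parts) >= 2 and parts[0].lower() == "mir":
        return "-".join([parts[0].lower(), *parts[1:]])
    return s


@dataclass
class TargetTable:
    """Directed regulator->target pairs with database provenance."""

    pairs: pd.DataFrame  # columns: source_id, target_id, database
    kind: str  # CIRC_MI or MI_M

    def __post_init__(self) -> None:
        if self.kind not in (CIRC_MI, MI_M):
            raise ValidationError(f"unknown target-table kind {self.kind!r}")
        missing = [c for c in TARGET_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise ValidationError(f"target table missing columns {missing}")
        pairs = self.pairs.loc[:, TARGET_COLUMNS].astype(str)
        if (pairs.map(len) == 0).any(axis=None):
            raise ValidationError("empty ids in target table")
        n_raw = len(pairs)
        pairs = pairs.drop_duplicates(ignore_index=True)
        if n_raw != len(pairs):
            logger.info(
                "%s: dropped %d duplicate rows (%d kept)",
                self.kind, n_raw - len(pairs), len(pairs),
            )
        self.pairs = pairs

    @classmethod
    def from_tsv(cls, path, kind: str) -> "TargetTable":
        return cls(read_target_tsv(path), kind)

    def __len__(self) -> int:
        return len(self.pairs)


def load_target_table(path, kind: str) -> TargetTable:
    """Read and deduplicate a target TSV (source_id, target_id, database)."""
    return TargetTable.from_tsv(path, kind)


def intersect_database_support(
    table: TargetTable, min_databases: int = 3
) -> set[tuple[str, str]]:
    """Pairs reported by >= min_databases distinct database tags."""
    if min_databases < 1:
        raise ValidationError("min_databases must be >= 1")
    counts = table.pairs.groupby(["source_id", "target_id"])["database"].nunique()
    return set(counts.index[counts >= min_databases])


def derive_co_set(deg_ids, predicted_target_ids) -> set[str]:
    """Plain set intersection (the Venn step)."""
    return set(deg_ids) & set(predicted_target_ids)


@dataclass
class CeRNANetwork:
    """Tripartite circRNA-miRNA-mRNA network of complete sponge triplets.

    Node sets are derived from the triplets only, so every node
    participates in at least one complete triplet by construction.
    """

    triplets: list[tuple[str, str, str]]
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.triplets = sorted(set(self.triplets))

    @property
    def ce_circrnas(self) -> set[str]:
        return {c for c, _, _ in self.triplets}

    @property
    def ce_mirnas(self) -> set[str]:
        return {mi for _, mi, _ in self.triplets}

    @property
    def ce_mrnas(self) -> set[str]:
        return {m for _, _, m in self.triplets}

    def node_table(self) -> pd.DataFrame:
        rows = [
            *(("circRNA", c) for c in sorted(self.ce_circrnas)),
            *(("miRNA", mi) for mi in sorted(self.ce_mirnas)),
            *(("mRNA", m) for m in sorted(self.ce_mrnas)),
        ]
        return pd.DataFrame(
            {
                "id": [n for _, n in rows],
                "layer": [layer for layer, _ in rows],
                "direction": [self.directions.get(n, "") for _, n in rows],
            }
        )

    def triplet_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.triplets, columns=["circRNA", "miRNA", "mRNA"])

    def to_graph(self) -> nx.Graph:
        graph = nx.Graph()
        for layer, nodes in (
            ("circRNA", self.ce_circrnas),
            ("miRNA", self.ce_mirnas),
            ("mRNA", self.ce_mrnas),
        ):
            for n in sorted(nodes):
                graph.add_node(n, layer=layer, direction=self.directions.get(n, ""))
        for c, mi, m in self.triplets:
            graph.add_edge(c, mi)
            graph.add_edge(mi, m)
        return graph

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)

    def write_sif(self, path) -> None:
        edges = set()
        for c, mi, m in self.triplets:
            edges.add((c, "sponges", mi))
            edges.add((mi, "targets", m))
        with open(path, "wt", encoding="utf-8") as fh:
            for a, rel, b in sorted(edges):
                fh.write(f"{a}\t{rel}\t{b}\n")


def assemble_network(
    deg_circ_ids,
    deg_mi_ids,
    deg_m_ids,
    circ_mi_pairs: set[tuple[str, str]],
    supported_mi_m_pairs: set[tuple[str, str]],
    directions: dict[str, str] | None = None,
) -> CeRNANetwork:
    """Enumerate all (circRNA, miRNA, mRNA) triplets whose two links exist
    in the (filtered) target relations and whose nodes are DEGs.

    co-miRNAs = DEG miRNAs that are predicted targets of DEG circRNAs;
    co-mRNAs = DEG mRNAs that are supported targets of co-miRNAs.
    """
    deg_circ = set(deg_circ_ids)
    deg_mi = set(deg_mi_ids)
    deg_m = set(deg_m_ids)
    circ_mi = {(c, mi) for c, mi in circ_mi_pairs if c in deg_circ}
    co_mirnas = derive_co_set(deg_mi, {mi for _, mi in circ_mi})
    mi_m = {
        (mi, m) for mi, m in supported_mi_m_pairs if mi in co_mirnas
    }
    co_mrnas = derive_co_set(deg_m, {m for _, m in mi_m})

    targets_of = {}
    for mi, m in mi_m:
        if m in co_mrnas:
            targets_of.setdefault(mi, set()).add(m)
    triplets = [
        (c, mi, m)
        for c, mi in sorted(circ_mi)
        if mi in co_mirnas
        for m in sorted(targets_of.get(mi, ()))
    ]
    return CeRNANetwork(triplets, dict(directions or {}))


def direction_consistency_filter(
    network: CeRNANetwork, directions: dict[str, str]
) -> CeRNANetwork:
    """Keep triplets with the sponge direction pattern: circRNA and mRNA
    share a direction and the miRNA has the opposite one."""
    kept = []
    for c, mi, m in network.triplets:
        try:
            dc, dmi, dm = directions[c], directions[mi], directions[m]
        except KeyError as exc:
            raise ValidationError(f"node missing from DGE tables: {exc}") from exc
        if dc == dm and dmi != dc:
            kept.append((c, mi, m))
    merged = {**network.directions, **directions}
    return CeRNANetwork(kept, merged)
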