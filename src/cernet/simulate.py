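"""Synthetic multi-layer fixtures with planted ground truth.

Generates log2-scale expression matrices for the three RNA layers
(case/control designs shaped like the real cohorts: 3v3, 6v5, 7v5),
target-prediction tables with controlled multi-database overlap, a PPI
edge list with a recoverable dense module, and a gene-set collection
containing one set enriched for planted-axis mRNAs. Every planted sponge
axis follows the circRNA-down / miRNA-up / mRNA-down direction pattern,
and its two links are wired into the target tables with full
three-database support on the miRNA->mRNA side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from cernet.cerna import CIRC_MI, MI_M, TargetTable
from cernet.dge import CASE_LABEL, CONTROL_LABEL, ExpressionDataset, ValidationError
from cernet.enrichment import GeneSetCollection
from cernet import io

LAYERS = ("circ", "mir", "m")
CIRC_MI_DATABASES = ("CSCD", "circBase")
MI_M_DATABASES = ("miRDB", "TargetScan", "miRTarbase")

_ID_PREFIX = {"circ": "circ_", "mir": "mir_", "m": "m_"}


def _layer_dict(value) -> dict[str, int]:
    if isinstance(value, dict):
        return {k: int(v) for k, v in value.items()}
    return {layer: int(value) for layer in LAYERS}


@dataclass
class SimulationConfig:
    """Knobs for the fixture generator; defaults mirror the real cohort
    shapes (circRNA 3v3, miRNA 6v5, mRNA 7v5)."""

    n_case: dict[str, int] = field(
        default_factory=lambda: {"circ": 3, "mir": 6, "m": 7}
    )
    n_control: dict[str, int] = field(
        default_factory=lambda: {"circ": 3, "mir": 5, "m": 5}
    )
    n_features: dict[str, int] = field(
        default_factory=lambda: {"circ": 200, "mir": 100, "m": 300}
    )
    n_planted_deg: dict[str, int] = field(
        default_factory=lambda: {"circ": 10, "mir": 10, "m": 25}
    )
    baseline_mean: float = 8.0
    baseline_sd: float = 0.3
    effect_size: float = 2.0
    n_planted_axes: int = 5
    db_overlap_prob: float = 0.5
    decoy_pair_rate: float = 0.01
    ppi_background_rate: float = 0.005
    ppi_extra_clique: int = 3
    n_gene_sets: int = 20
    gene_set_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_case = _layer_dict(self.n_case)
        self.n_control = _layer_dict(self.n_control)
        self.n_features = _layer_dict(self.n_features)
        self.n_planted_deg = _layer_dict(self.n_planted_deg)
        for name in ("n_case", "n_control", "n_features", "n_planted_deg"):
            per_layer = getattr(self, name)
            if set(per_layer) != set(LAYERS):
                raise ValidationError(f"{name} must cover layers {LAYERS}")
            if any(v <= 0 for v in per_layer.values()):
                raise ValidationError(f"{name} entries must be positive")
        for prob_name in ("db_overlap_prob", "decoy_pair_rate", "ppi_background_rate"):
            prob = getattr(self, prob_name)
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(f"{prob_name} must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.baseline_sd <= 0:
            raise ValidationError("baseline_sd must be positive")
        if self.n_planted_axes < 0 or self.n_planted_axes > min(
            self.n_planted_deg.values()
        ):
            raise ValidationError(
                "n_planted_axes must be <= min per-layer n_planted_deg"
            )
        if any(
            self.n_planted_deg[l] > self.n_features[l] for l in LAYERS
        ):
            raise ValidationError("n_planted_deg exceeds n_features")


@dataclass
class GroundTruth:
    """What was planted: DEG ids with directions per layer, the sponge
    axes, and every simulated target pair with its database tag."""

    planted_degs: dict[str, dict[str, str]]
    planted_axes: list[tuple[str, str, str]]
    target_pairs: dict[str, list[tuple[str, str, str]]]

    def to_json(self, path) -> None:
        payload = {
            "planted_degs": self.planted_degs,
            "planted_axes": [list(a) for a in self.planted_axes],
            "target_pairs": {
                k: [list(p) for p in v] for k, v in self.target_pairs.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_degs=payload["planted_degs"],
            planted_axes=[tuple(a) for a in payload["planted_axes"]],
            target_pairs={
                k: [tuple(p) for p in v]
                for k, v in payload["target_pairs"].items()
            },
        )


@dataclass
class SyntheticBundle:
    datasets: dict[str, ExpressionDataset]
    circ_mi: TargetTable
    mi_m: TargetTable
    ppi: nx.Graph
    gene_sets: GeneSetCollection
    truth: GroundTruth


def _feature_ids(layer: str, n: int) -> list[str]:
    return [f"{_ID_PREFIX[layer]}{i:04d}" for i in range(n)]


def _expression_layer(
    rng: np.random.Generator,
    ids: list[str],
    n_case: int,
    n_control: int,
    cfg: SimulationConfig,
    directions: dict[str, str],
) -> ExpressionDataset:
    n = len(ids)
    values = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=(n, n_case + n_control))
    index = pd.Index(ids, name="feature_id")
    for fid, direction in directions.items():
        row = index.get_loc(fid)
        shift = cfg.effect_size if direction == "up" else -cfg.effect_size
        values[row, :n_case] += shift
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_control)
    ]
    groups = pd.Series(
        [CASE_LABEL] * n_case + [CONTROL_LABEL] * n_control, index=samples
    )
    return ExpressionDataset(pd.DataFrame(values, index=index, columns=samples), groups)


def _decoy_pairs(
    rng: np.random.Generator, sources: list[str], targets: list[str], rate: float
) -> list[tuple[str, str]]:
    """Bernoulli(rate) over the full source x target grid."""
    if rate == 0.0:
        return []
    hits = rng.random((len(sources), len(targets))) < rate
    rows, cols = np.nonzero(hits)
    return [(sources[i], targets[j]) for i, j in zip(rows, cols)]


def generate_dataset(config: SimulationConfig) -> SyntheticBundle:
    """Deterministic fixture bundle for one seed (identical seed ->
    bit-identical serialization)."""
    rng = np.random.default_rng(config.seed)
    ids = {layer: _feature_ids(layer, config.n_features[layer]) for layer in LAYERS}

    # planted DEGs; the first n_planted_axes per layer carry the axes and
    # get the sponge direction pattern (circ down, mir up, m down)
    planted: dict[str, list[str]] = {}
    directions: dict[str, dict[str, str]] = {}
    axis_direction = {"circ": "down", "mir": "up", "m": "down"}
    for layer in LAYERS:
        chosen = [
            str(f)
            for f in rng.choice(
                ids[layer], size=config.n_planted_deg[layer], replace=False
            )
        ]
        planted[layer] = chosen
        dirs = {}
        for rank, fid in enumerate(chosen):
            if rank < config.n_planted_axes:
                dirs[fid] = axis_direction[layer]
            else:
                dirs[fid] = "up" if rng.random() < 0.5 else "down"
        directions[layer] = dirs
    axes = [
        (planted["circ"][i], planted["mir"][i], planted["m"][i])
        for i in range(config.n_planted_axes)
    ]

    datasets = {
        layer: _expression_layer(
            rng, ids[layer], config.n_case[layer], config.n_control[layer],
            config, directions[layer],
        )
        for layer in LAYERS
    }

    # circRNA->miRNA table: planted links in both sources, decoys per source
    circ_mi_rows: list[tuple[str, str, str]] = []
    for c, mi, _ in axes:
        for db in CIRC_MI_DATABASES:
            circ_mi_rows.append((c, mi, db))
    for c, mi in _decoy_pairs(rng, ids["circ"], ids["mir"], config.decoy_pair_rate):
        primary = CIRC_MI_DATABASES[int(rng.integers(len(CIRC_MI_DATABASES)))]
        circ_mi_rows.append((c, mi, primary))
        for db in CIRC_MI_DATABASES:
            if db != primary and rng.random() < config.db_overlap_prob:
                circ_mi_rows.append((c, mi, db))

    # miRNA->mRNA tables: planted links forced into all three databases;
    # background pairs drawn at decoy_pair_rate, each reported per database
    # independently with db_overlap_prob
    mi_m_rows: list[tuple[str, str, str]] = []
    for _, mi, m in axes:
        for db in MI_M_DATABASES:
            mi_m_rows.append((mi, m, db))
    for mi, m in _decoy_pairs(rng, ids["mir"], ids["m"], config.decoy_pair_rate):
        for db in MI_M_DATABASES:
            if rng.random() < config.db_overlap_prob:
                mi_m_rows.append((mi, m, db))

    circ_mi = TargetTable(
        pd.DataFrame(circ_mi_rows, columns=io.TARGET_COLUMNS), CIRC_MI
    )
    mi_m = TargetTable(pd.DataFrame(mi_m_rows, columns=io.TARGET_COLUMNS), MI_M)

    # PPI: planted-axis mRNAs plus a few partners form a clique that MCODE
    # can recover (clique of size n_axes + extras has score = size > 5);
    # sparse Erdos-Renyi background over the remaining mRNAs
    ppi = nx.Graph()
    non_planted_m = [m for m in ids["m"] if m not in directions["m"]]
    clique = [m for _, _, m in axes] + non_planted_m[: config.ppi_extra_clique]
    for i, a in enumerate(clique):
        for b in clique[i + 1:]:
            ppi.add_edge(a, b)
    background = [m for m in ids["m"] if m not in set(clique)]
    for i, a in enumerate(background):
        for b in background[i + 1:]:
            if rng.random() < config.ppi_background_rate:
                ppi.add_edge(a, b)
    # light attachment of the clique to the background so it is not a
    # disconnected component
    if background and clique:
        ppi.add_edge(clique[0], background[0])

    # gene sets over the mRNA universe; set_0000 is enriched for axis mRNAs
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    axis_mrnas = [m for _, _, m in axes]
    padding = [m for m in non_planted_m if m not in set(clique)]
    enriched = frozenset(
        axis_mrnas + padding[: max(0, config.gene_set_size - len(axis_mrnas))]
    )
    if enriched:
        sets["set_0000"] = ("planted axis module", enriched)
    for i in range(1, config.n_gene_sets):
        members = rng.choice(ids["m"], size=config.gene_set_size, replace=False)
        sets[f"set_{i:04d}"] = (f"random set {i}", frozenset(str(g) for g in members))
    gene_sets = GeneSetCollection(sets, universe=frozenset(ids["m"]))

    truth = GroundTruth(
        planted_degs=directions,
        planted_axes=axes,
        target_pairs={
            "circ_mi": sorted(set(map(tuple, circ_mi.pairs.itertuples(index=False)))),
            "mi_m": sorted(set(map(tuple, mi_m.pairs.itertuples(index=False)))),
        },
    )
    return SyntheticBundle(datasets, circ_mi, mi_m, ppi, gene_sets, truth)


def write_fixture_bundle(bundle: SyntheticBundle, directory) -> dict[str, Path]:
    """Serialize the bundle as plain-text fixtures; returns emitted paths.

    Files round-trip losslessly through the package readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for layer, dataset in bundle.datasets.items():
        mpath = directory / f"expression_{layer}.tsv"
        gpath = directory / f"groups_{layer}.tsv"
        io.write_expression(dataset, mpath, gpath)
        paths[f"expression_{layer}"] = mpath
        paths[f"groups_{layer}"] = gpath
    paths["circ_mi"] = directory / "targets_circ_mi.tsv"
    io.write_target_tsv(bundle.circ_mi.pairs, paths["circ_mi"])
    paths["mi_m"] = directory / "targets_mi_m.tsv"
    io.write_target_tsv(bundle.mi_m.pairs, paths["mi_m"])
    paths["ppi"] = directory / "ppi.sif"
    io.write_sif(bundle.ppi, paths["ppi"])
    paths["ppi_edges"] = directory / "ppi_edges.tsv"
    io.write_edge_list(bundle.ppi, paths["ppi_edges"])
    paths["gene_sets"] = directory / "gene_sets.gmt"
    io.write_gmt(bundle.gene_sets.sets, paths["gene_sets"])
    paths["truth"] = directory / "truth.json"
    bundle.truth.to_json(paths["truth"])
    return paths
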