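"""End-to-end orchestration: per-layer DGE -> ceRNA assembly -> PPI
modules -> enrichment -> single-gene ROC, with every intermediate
persisted as TSV and a machine-readable JSON run report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import cernet
from cernet import cerna, diagnostics, enrichment, io, mcode
from cernet.dge import (
    DEGThresholds,
    ValidationError,
    filter_degs,
    test_differential,
)

logger = logging.getLogger(__name__)

LAYERS = ("circ", "mir", "m")


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run. Expression inputs follow the
    fixture-bundle layout (expression_<layer>.tsv / groups_<layer>.tsv)."""

    input_dir: str
    output_dir: str
    thresholds: dict[str, DEGThresholds] = field(
        default_factory=lambda: {layer: DEGThresholds() for layer in LAYERS}
    )
    dge_method: str = "moderated"
    min_databases: int = 3
    direction_filter: bool = False
    mcode_params: mcode.MCODEParams = field(default_factory=mcode.MCODEParams)
    hub_top_k: int = 4
    enrichment_min_count: int = 2
    roc_feature: str | None = None  # mRNA feature id; default = top hub
    circ_whitelist: list[str] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = {
            layer: DEGThresholds(**raw.get("thresholds", {}).get(layer, {}))
            for layer in LAYERS
        }
        mcode_params = mcode.MCODEParams(**raw.get("mcode", {}))
        keys = (
            "input_dir", "output_dir", "dge_method", "min_databases",
            "direction_filter", "hub_top_k", "enrichment_min_count",
            "roc_feature", "circ_whitelist", "seed",
        )
        kwargs = {k: raw[k] for k in keys if k in raw}
        return cls(thresholds=thresholds, mcode_params=mcode_params, **kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the run report (also written
    to <output_dir>/report.json). On stage failure, partial outputs are
    kept and a FAILED marker file names the stage."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": cernet.__version__,
        "config": {
            "input_dir": str(config.input_dir),
            "output_dir": str(config.output_dir),
            "dge_method": config.dge_method,
            "min_databases": config.min_databases,
            "direction_filter": config.direction_filter,
            "hub_top_k": config.hub_top_k,
            "enrichment_min_count": config.enrichment_min_count,
            "roc_feature": config.roc_feature,
            "seed": config.seed,
            "thresholds": {
                layer: vars(t) for layer, t in config.thresholds.items()
            },
            "mcode": vars(config.mcode_params),
        },
        "counts": {},
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage = "init"
    try:
        in_dir = Path(config.input_dir)

        # ---- differential expression per layer
        stage = "dge"
        dge_tables: dict[str, pd.DataFrame] = {}
        degs: dict[str, pd.DataFrame] = {}
        directions: dict[str, str] = {}
        for layer in LAYERS:
            dataset = io.read_expression(
                in_dir / f"expression_{layer}.tsv", in_dir / f"groups_{layer}.tsv"
            )
            table = test_differential(dataset, method=config.dge_method)
            dge_tables[layer] = table
            deg = filter_degs(table, config.thresholds[layer])
            degs[layer] = deg
            directions.update(deg["direction"].to_dict())
            _write_tsv(table, out / f"dge_{layer}.tsv", index=True)
            _write_tsv(deg, out / f"degs_{layer}.tsv", index=True)
            logger.info("dge[%s]: %d features, %d DEGs", layer, len(table), len(deg))
            report["counts"][f"degs_{layer}"] = int(len(deg))

        # ---- ceRNA assembly
        stage = "cerna"
        circ_mi = cerna.load_target_table(in_dir / "targets_circ_mi.tsv", cerna.CIRC_MI)
        mi_m = cerna.load_target_table(in_dir / "targets_mi_m.tsv", cerna.MI_M)
        deg_circ = set(degs["circ"].index)
        if config.circ_whitelist is not None:
            deg_circ &= set(config.circ_whitelist)
        circ_mi_pairs = cerna.intersect_database_support(circ_mi, min_databases=1)
        mi_m_pairs = cerna.intersect_database_support(
            mi_m, min_databases=config.min_databases
        )
        network = cerna.assemble_network(
            deg_circ,
            set(degs["mir"].index),
            set(degs["m"].index),
            circ_mi_pairs,
            mi_m_pairs,
            directions=directions,
        )
        if config.direction_filter:
            # nodes in the network are DEGs, so their directions are known
            network = cerna.direction_consistency_filter(network, directions)
        _write_tsv(network.node_table(), out / "cerna_nodes.tsv")
        _write_tsv(network.triplet_table(), out / "cerna_triplets.tsv")
        network.write_graphml(out / "cerna_network.graphml")
        network.write_sif(out / "cerna_network.sif")
        report["counts"]["triplets"] = len(network.triplets)
        report["counts"]["ce_circRNAs"] = len(network.ce_circrnas)
        report["counts"]["ce_miRNAs"] = len(network.ce_mirnas)
        report["counts"]["ce_mRNAs"] = len(network.ce_mrnas)
        logger.info(
            "cerna: %d triplets (%d/%d/%d nodes)",
            len(network.triplets), len(network.ce_circrnas),
            len(network.ce_mirnas), len(network.ce_mrnas),
        )

        # ---- PPI modules and hubs
        stage = "modules"
        ppi_path = in_dir / "ppi.sif"
        if not ppi_path.exists():
            ppi_path = in_dir / "ppi_edges.tsv"
        ppi = io.read_ppi(ppi_path)
        modules = mcode.find_complexes(ppi, config.mcode_params)
        _write_tsv(mcode.modules_table(modules), out / "modules.tsv")
        mcode.write_modules_graphml(ppi, modules, out / "ppi_modules.graphml")
        hub_source = ppi
        if modules:
            hub_source = ppi.subgraph(modules[0].members)
        hubs = mcode.rank_hubs(hub_source, config.hub_top_k) if len(hub_source) else []
        pd.DataFrame(hubs, columns=["gene", "degree"]).to_csv(
            out / "hubs.tsv", sep="\t", index=False
        )
        report["counts"]["modules"] = len(modules)
        report["hubs"] = [g for g, _ in hubs]
        logger.info("modules: %d kept, hubs=%s", len(modules), report["hubs"])

        # ---- enrichment of ce-mRNAs
        stage = "enrichment"
        gmt_path = in_dir / "gene_sets.gmt"
        if gmt_path.exists() and network.ce_mrnas:
            collection = enrichment.GeneSetCollection.from_gmt(gmt_path)
            query = network.ce_mrnas & collection.universe
            if query:
                table = enrichment.enrich(
                    query, collection, min_count=config.enrichment_min_count
                )
            else:
                table = pd.DataFrame()
        else:
            table = pd.DataFrame()
        _write_tsv(table, out / "enrichment.tsv")
        report["counts"]["enriched_terms"] = int(
            (table["adj_p"] < 0.05).sum() if "adj_p" in table else 0
        )
        report["counts"]["tested_terms"] = int(len(table))

        # ---- single-feature ROC on the headline mRNA
        stage = "roc"
        roc_feature = config.roc_feature
        if roc_feature is None and report["hubs"]:
            roc_feature = report["hubs"][0]
        if roc_feature is not None:
            dataset = io.read_expression(
                in_dir / "expression_m.tsv", in_dir / "groups_m.tsv"
            )
            if roc_feature in dataset.matrix.index:
                result = diagnostics.roc_auc(
                    dataset.matrix.loc[roc_feature].to_numpy(),
                    dataset.groups.to_numpy(),
                )
                pd.DataFrame({"fpr": result.fpr, "tpr": result.tpr}).to_csv(
                    out / "roc_points.tsv", sep="\t", index=False
                )
                (out / "roc_summary.json").write_text(
                    json.dumps(
                        {"feature": roc_feature, **result.summary()}, indent=1
                    )
                )
                report["roc"] = {"feature": roc_feature, **result.summary()}
            else:
                logger.warning("roc feature %s absent from mRNA layer", roc_feature)

        report["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _audit_report(report, out)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        return report
    except Exception as exc:  # noqa: BLE001 - stage name must reach the user
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(stage, exc) from exc


def _audit_report(report: dict, out: Path) -> None:
    """Self-consistency: reported counts must equal emitted table rows."""
    audits = {
        "degs_circ": "degs_circ.tsv",
        "degs_mir": "degs_mir.tsv",
        "degs_m": "degs_m.tsv",
        "triplets": "cerna_triplets.tsv",
        "modules": "modules.tsv",
        "tested_terms": "enrichment.tsv",
    }
    for key, filename in audits.items():
        path = out / filename
        if not path.exists():
            continue
        with open(path, "rt", encoding="utf-8") as fh:
            n_rows = max(0, sum(1 for _ in fh) - 1)
        if n_rows != report["counts"][key]:
            raise ValidationError(
                f"report count {key}={report['counts'][key]} does not match "
                f"{filename} rows ({n_rows})"
            )
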