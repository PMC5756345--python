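"""End-to-end orchestration of the driver-detection and validation stages.

Two entry points mirror the two halves of the study design:

* :func:`run_drivers` — pathways + multiplex layers → centrality records,
  criterion calls, per-layer driver sets, Venn region counts and the
  aggregated multiplex driver list.
* :func:`run_condition` — counts + labels (+ a driver list) → DEG table,
  driver∩DEG intersection, FDR comparison, per-gene AUC table and top-k.

All randomness derives from one top-level seed: stage generators are
spawned from ``SeedSequence([seed, stage_tag])`` (see ``simulate``) and the
random-forest seed is the top-level seed itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io
from .centrality import build_centrality_records, records_to_frame
from .dea import run_dea
from .drivers import make_calls, multiplex_drivers, venn_region_counts
from .pancancer import fdr_comparison, intersect_driver_degs
from .validation import RFConfig, auc_records_to_frame, auc_table, rank_top_k

logger = logging.getLogger("driverplex")

__all__ = ["PipelineConfig", "run_drivers", "run_condition"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a YAML mapping."""

    pathways: Optional[str] = None
    layers: dict[str, str] = field(default_factory=dict)  # name -> path
    counts: Optional[str] = None
    labels: Optional[str] = None
    drivers_file: Optional[str] = None
    out_dir: str = "results"
    condition_id: str = "condition"
    criterion_mode: str = "literal"
    aggregation: str = "per_gene"
    min_layers: int = 2
    k_mode: str = "annotated"
    logfc_thr: float = 1.0
    fdr_thr: float = 0.01
    rounding: str = "round1"
    rf_n_trees: int = 500
    rf_n_folds: int = 10
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.logfc_thr <= 0 or self.fdr_thr <= 0:
            raise ValueError("DEA thresholds must be positive")
        if self.min_layers < 1:
            raise ValueError("min_layers must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, **overrides) -> "PipelineConfig":
        """Point a config at a ``generate_study`` bundle directory."""
        bundle_dir = Path(bundle_dir)
        layers = {
            p.stem.removeprefix("layer_"): str(p)
            for p in sorted(bundle_dir.glob("layer_*.tsv"))
        }
        defaults = dict(
            pathways=str(bundle_dir / "pathways.gmt"),
            layers=layers,
            counts=str(bundle_dir / "counts.tsv"),
            labels=str(bundle_dir / "labels.tsv"),
            out_dir=str(bundle_dir / "results"),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def rf_config(self) -> RFConfig:
        return RFConfig(n_trees=self.rf_n_trees, n_folds=self.rf_n_folds, seed=self.seed)


def _require(path: Optional[str], what: str) -> Path:
    if not path:
        raise ValueError(f"config is missing the {what} path")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} input not found: {p}")
    return p


def run_drivers(config: PipelineConfig):
    """Driver-detection half of the pipeline; writes reports under out_dir.

    Outputs: ``centrality_records.tsv``, ``driver_calls.tsv``, per-layer
    driver lists, ``venn_counts.tsv``, ``drivers.txt`` and
    ``drivers_summary.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pathways = io.read_gene_sets(_require(config.pathways, "pathways"))
    if not config.layers:
        raise ValueError("config lists no network layers")
    layers = [
        io.read_network_layer(_require(path, f"layer {name}"), "edge_tsv", name)
        for name, path in sorted(config.layers.items())
    ]
    from .datatypes import MultiplexNetwork

    multiplex = MultiplexNetwork.from_layers(layers)
    logger.info(
        "drivers: %d pathways, %d layers", len(pathways), multiplex.n_layers
    )

    records = build_centrality_records(multiplex, pathways, k_mode=config.k_mode)
    calls = make_calls(records, mode=config.criterion_mode)
    result = multiplex_drivers(
        calls, min_layers=config.min_layers, aggregation=config.aggregation
    )
    venn = venn_region_counts(result.per_layer_sets)
    logger.info(
        "drivers: %d records, %d passing calls, %d multiplex drivers",
        len(records), sum(c.passes for c in calls), len(result.driver_genes),
    )

    records_to_frame(records).to_csv(out / "centrality_records.tsv", sep="\t", index=False)
    import pandas as pd

    pd.DataFrame(
        [
            {"gene": c.gene, "pathway": c.pathway_id, "layer": c.layer_name,
             "passes": c.passes, "criterion_mode": c.criterion_mode}
            for c in calls
        ]
    ).to_csv(out / "driver_calls.tsv", sep="\t", index=False)
    for name, genes in result.per_layer_sets.items():
        io.write_gene_list(genes, out / f"drivers_{name}.txt")
    pd.DataFrame(
        [{"layers": "&".join(sig), "count": n} for sig, n in venn.items()]
    ).to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    io.write_gene_list(result.driver_genes, out / "drivers.txt")
    io.write_json(
        {
            "n_pathways": len(pathways),
            "n_layers": multiplex.n_layers,
            "n_records": len(records),
            "n_passing_calls": int(sum(c.passes for c in calls)),
            "per_layer_driver_counts": {
                name: len(genes) for name, genes in result.per_layer_sets.items()
            },
            "n_driver_genes": len(result.driver_genes),
            "criterion_mode": config.criterion_mode,
            "aggregation": config.aggregation,
            "min_layers": config.min_layers,
            "seed": config.seed,
        },
        out / "drivers_summary.json",
    )
    return result


def run_condition(config: PipelineConfig, driver_genes: Optional[set[str]] = None):
    """Condition half: DEA, driver∩DEG, FDR comparison, AUC ranking.

    ``driver_genes`` may be passed in memory; otherwise ``drivers_file``
    (or ``out_dir/drivers.txt`` from a previous :func:`run_drivers`) is
    read.  Every sample of the count matrix must be labelled.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression(_require(config.counts, "counts"))
    labels = io.read_labels(_require(config.labels, "labels"))
    unlabelled = sorted(set(expr.samples) - set(labels.samples))
    if unlabelled:
        raise ValueError(
            f"{len(unlabelled)} matrix sample(s) without labels, e.g. {unlabelled[:3]}"
        )
    if driver_genes is None:
        drivers_path = config.drivers_file or str(out / "drivers.txt")
        driver_genes = io.read_gene_list(_require(drivers_path, "drivers"))

    deg_table = run_dea(
        expr, labels, config.condition_id,
        logfc_thr=config.logfc_thr, fdr_thr=config.fdr_thr,
    )
    deg_table.to_tsv(out / f"degs_{config.condition_id}.tsv")
    result = intersect_driver_degs(driver_genes, deg_table, rounding=config.rounding)
    io.write_gene_list(result.driver_degs, out / f"driver_degs_{config.condition_id}.txt")
    comparison = fdr_comparison(deg_table, result.driver_degs & deg_table.genes)
    comparison.to_csv(out / f"fdr_comparison_{config.condition_id}.tsv", sep="\t", index=False)

    records = auc_table(expr, labels, result.driver_degs, config.rf_config())
    auc_records_to_frame(records).to_csv(
        out / f"auc_{config.condition_id}.tsv", sep="\t", index=False
    )
    top = rank_top_k(records, k=config.top_k)
    io.write_gene_list([r.gene for r in top], out / f"top{config.top_k}_{config.condition_id}.txt")

    summary = {
        "condition_id": config.condition_id,
        "n_genes_tested": int(len(deg_table.df)),
        "n_degs": len(result.degs),
        "n_drivers": len(driver_genes),
        "n_driver_degs": len(result.driver_degs),
        "pct_of_network_drivers": result.pct_of_network_drivers,
        "top_genes": [r.gene for r in top],
        "top_aucs": [r.auc for r in top],
        "seed": config.seed,
    }
    assert summary["n_driver_degs"] <= min(summary["n_degs"], summary["n_drivers"])
    io.write_json(summary, out / f"condition_summary_{config.condition_id}.json")
    logger.info(
        "condition %s: %d DEGs, %d driver DEGs, top gene %s",
        config.condition_id, summary["n_degs"], summary["n_driver_degs"],
        top[0].gene if top else "-",
    )
    return result, records, top
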