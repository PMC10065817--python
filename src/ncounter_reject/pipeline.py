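"""End-to-end orchestration: ingest/simulate -> QC -> background filter ->
normalize -> differential expression -> clustering -> classifier.

A run is driven by one :class:`PipelineConfig` and a single global seed;
per-stage seeds are derived by hashing the stage name so any stage can be
rerun in isolation with the stream it would see in a full run.  Every
intermediate artifact is plain CSV/JSON and the manifest records the seed,
a config hash and per-stage attrition, so rerunning the same config twice
produces an identical output tree.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from .background import apply_probe_filter
from .classify import cv_evaluate, train_panel_classifier, transfer_evaluate
from .cluster import cluster_diagnostics, linkage_to_newick
from .dge import dge_table, volcano_frame
from .panelio import (
    CountMatrix,
    assemble_matrix,
    read_panel_csv,
    read_rcc,
    read_sample_sheet,
)
from .qc import QCThresholds, filter_samples, lane_qc
from .refnorm import genorm_rank, normalize
from .synthetic import (
    SyntheticSpec,
    bhot_like_spec,
    elements_like_spec,
    fast_spec,
    generate_dataset,
    write_dataset,
)

_PRESETS = {
    "fast": fast_spec,
    "bhot_like": bhot_like_spec,
    "elements_like": elements_like_spec,
}

DEFAULT_COMPARISONS = (
    ("AMR", "NoRejection"),
    ("AMR", "BLorTCMR"),
    ("BLorTCMR", "NoRejection"),
)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # input: either a dataset directory (rcc/, panel.csv, samples.csv) ...
    input_dir: str | None = None
    # ... or a synthetic preset with field overrides
    synthetic_preset: str | None = "fast"
    synthetic_overrides: dict = field(default_factory=dict)
    qc_thresholds: dict = field(default_factory=dict)
    genorm_k: int = 3
    use_positive_norm: bool = True
    comparisons: tuple = DEFAULT_COMPARISONS
    alpha: float = 0.05
    cluster_kmax: int = 10
    classifier_folds: int = 10
    lambda_override: float | None = None
    run_classifier: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "comparisons" in data:
            data["comparisons"] = tuple(tuple(c) for c in data["comparisons"])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.input_dir is None and self.synthetic_preset not in _PRESETS:
            raise ValueError(
                f"unknown preset {self.synthetic_preset!r}; options: {sorted(_PRESETS)}"
            )
        if self.genorm_k < 2:
            raise ValueError("genorm_k must be >=2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        QCThresholds(**self.qc_thresholds)  # raises on bad windows
        for pair in self.comparisons:
            if len(pair) != 2:
                raise ValueError(f"bad comparison {pair!r}")


def load_dataset_dir(path) -> CountMatrix:
    """Assemble a CountMatrix from a dataset directory (rcc/, panel, samples)."""
    root = Path(path)
    panel = read_panel_csv(root / "panel.csv")
    metadata = read_sample_sheet(root / "samples.csv")
    lanes = [read_rcc(p) for p in sorted((root / "rcc").glob("*.RCC"))]
    return assemble_matrix(lanes, panel, metadata)


def make_synthetic_spec(preset: str, seed: int, overrides: dict) -> SyntheticSpec:
    if "qc_failures" in overrides:
        overrides = dict(overrides)
        overrides["qc_failures"] = dict(overrides["qc_failures"])
    return _PRESETS[preset](seed=seed, **overrides)


def _acquire_matrix(config: PipelineConfig, out: Path):
    if config.input_dir is not None:
        return load_dataset_dir(config.input_dir), None
    spec = make_synthetic_spec(
        config.synthetic_preset,
        derive_seed(config.seed, "simulate"),
        config.synthetic_overrides,
    )
    lanes, panel, metadata, truth = generate_dataset(spec)
    write_dataset(out / "dataset", lanes, panel, metadata, truth)
    return assemble_matrix(lanes, panel, metadata), truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the in-memory results bundle.

    Artifacts land under ``config.out_dir``; ``manifest.json`` records the
    seed, config hash and sample/probe attrition at every stage (counts in
    always equal counts out plus exclusions).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    bundle: dict = {"config": config}
    current = ["ingest"]

    def stage(name):
        current[0] = name
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        current[0] = "ingest"
        matrix, truth = _acquire_matrix(config, out)
        bundle["raw"], bundle["truth"] = matrix, truth
        stage("ingest").update(
            samples=matrix.n_samples, probes=len(matrix.panel.probe_ids)
        )
        matrix.values.to_csv(out / "counts_raw.csv")

        current[0] = "qc"
        thresholds = QCThresholds(**config.qc_thresholds)
        report = lane_qc(matrix, thresholds=thresholds)
        report.to_csv(out / "qc_report.csv")
        qc_matrix = filter_samples(matrix, report)
        bundle["qc_report"], bundle["qc_matrix"] = report, qc_matrix
        stage("qc").update(
            samples_in=matrix.n_samples,
            samples_out=qc_matrix.n_samples,
            excluded=report.excluded_samples,
        )

        current[0] = "background_filter"
        bg = apply_probe_filter(qc_matrix)
        bundle["background"] = bg
        pd.Series(bg.excluded_probes, name="probe_id").to_csv(
            out / "background_excluded_probes.csv", index=False
        )
        bg.to_frame().to_csv(out / "background_per_sample.csv")
        stage("background_filter").update(
            probes_in=len(qc_matrix.panel.probe_ids),
            probes_out=len(bg.kept_matrix.panel.probe_ids),
            excluded=len(bg.excluded_probes),
            study_threshold=bg.study_threshold,
        )

        current[0] = "normalize"
        gn = genorm_rank(bg.kept_matrix, k=config.genorm_k)
        bundle["genorm"] = gn
        pd.DataFrame(
            {
                "stability_M": pd.Series(gn.stability_M),
                "rank": pd.Series({g: i + 1 for i, g in enumerate(gn.ranking)}),
                "selected": pd.Series(
                    {g: g in gn.selected_references for g in gn.stability_M}
                ),
            }
        ).sort_values("rank").to_csv(out / "genorm.csv")
        norm = normalize(bg.kept_matrix, gn.selected_references,
                         use_positive=config.use_positive_norm)
        norm.values.to_csv(out / "normalized.csv")
        bundle["normalized"] = norm
        stage("normalize").update(
            references=[
                norm.panel.probe(p).gene_symbol for p in norm.references_used
            ],
        )

        current[0] = "dge"
        tables = {}
        for group_a, group_b in config.comparisons:
            tbl = dge_table(norm, group_a, group_b, alpha=config.alpha)
            key = f"{group_a}_vs_{group_b}"
            tables[key] = tbl
            tbl.to_csv(out / f"dge_{key}.csv")
            volcano_frame(tbl).to_csv(out / f"volcano_{key}.csv")
        bundle["dge"] = tables
        stage("dge").update(
            {k: int(t.significant.shape[0]) for k, t in tables.items()}
        )

        current[0] = "cluster"
        diag = cluster_diagnostics(
            norm, kmax=config.cluster_kmax, seed=derive_seed(config.seed, "cluster")
        )
        bundle["cluster"] = diag
        with open(out / "cluster_report.json", "w") as fh:
            json.dump(diag.summary(), fh, indent=1, sort_keys=True)
        with open(out / "dendrogram.nwk", "w") as fh:
            fh.write(linkage_to_newick(diag.linkage, list(norm.values.columns)) + "\n")
        stage("cluster").update(diag.summary())

        current[0] = "classifier"
        if config.run_classifier:
            model, x_f = train_panel_classifier(
                norm,
                folds=config.classifier_folds,
                seed=derive_seed(config.seed, "classifier"),
                lambda_override=config.lambda_override,
            )
            model.to_json(out / "model.json")
            evaluation = cv_evaluate(
                x_f,
                (norm.samples["diagnosis"] == "AMR").to_numpy(int),
                lambda_=model.lambda_,
                folds=config.classifier_folds,
                seed=derive_seed(config.seed, "classifier"),
            )
            with open(out / "eval.json", "w") as fh:
                json.dump(evaluation.summary(), fh, indent=1, sort_keys=True)
            bundle["model"], bundle["evaluation"] = model, evaluation
            stage("classifier").update(
                lambda_=model.lambda_,
                n_genes=len(model.coefficients),
                nzv_removed=len(model.nzv_removed),
                corr_removed=len(model.corr_removed),
                auc=evaluation.auc,
            )
    except Exception as err:
        manifest["failed_stage"] = current[0]
        manifest["error"] = str(err)
        _write_manifest(manifest, out)
        raise RuntimeError(
            f"pipeline failed in stage {manifest['failed_stage']!r}: {err}"
        ) from err

    _write_manifest(manifest, out)
    bundle["manifest"] = manifest
    return bundle


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def run_transfer_study(
    large_config: PipelineConfig,
    small_preset: str = "elements_like",
    seed: int = 0,
) -> dict:
    """Train on a small (AMR-focused) panel, test on the large panel's cohort.

    Both cohorts realize the same ground truth; the small-panel model is
    applied to the large panel's normalized data by gene symbol.
    """
    large = run_pipeline(large_config)
    small_config = dataclasses.replace(
        large_config,
        out_dir=str(Path(large_config.out_dir) / "transfer_panel"),
        synthetic_preset=small_preset,
        seed=derive_seed(seed, "transfer"),
    )
    small = run_pipeline(small_config)
    transfer = transfer_evaluate(small["model"], large["normalized"])
    with open(Path(large_config.out_dir) / "transfer_eval.json", "w") as fh:
        json.dump(transfer.summary(), fh, indent=1, sort_keys=True)
    return {"large": large, "small": small, "transfer": transfer}
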