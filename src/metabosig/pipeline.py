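"""End-to-end orchestration: simulate (optional) -> QC filter -> log ->
impute -> Pareto -> differential -> correlation/PCA -> network signatures
-> subset screen, with every intermediate written under one run directory
and a JSON run report tying the stages together."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

from . import correlate, differential, io, network, predict, qc, synthetic
from .containers import SampleMetadata
from .predict import hash_name

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """Paths, stage parameters, and the single governing seed."""

    outdir: Union[str, Path] = "metabosig_run"
    matrix_path: Optional[str] = None
    metadata_path: Optional[str] = None
    qc_path: Optional[str] = None
    simulate: bool = False
    simulation: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    dilution_threshold: float = 0.70
    rsd_threshold_pct: float = 25.0
    knn_k: int = 10
    de_method: str = "moderated"  # or "univariate"
    fdr_method: str = "BY"
    cfdna_fdr_method: str = "BH"
    alpha: float = 0.05
    lam: Union[str, float] = network.DEFAULT_BATTERY_LAMBDA
    loo_cohort: str = "case-only"
    consensus_threshold: float = 0.5
    n_repeats: int = 50
    n_trees: int = 500
    max_signature_size: int = 16
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim:
            cfg.simulation = synthetic.SimulationConfig(**sim)
        return cfg


@dataclass
class RunReport:
    """Per-stage record of parameters, counts, and the output manifest."""

    seed: int
    stages: List[Dict[str, Any]] = field(default_factory=list)
    manifest: List[str] = field(default_factory=list)

    def record(self, stage: str, **info: Any) -> None:
        self.stages.append({"stage": stage, **info})

    def add_outputs(self, *paths: Path) -> None:
        self.manifest.extend(str(p) for p in paths)

    def to_json(self, path: Union[str, Path]) -> None:
        io.write_json({"seed": self.seed, "stages": self.stages, "manifest": self.manifest}, path)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one by stable name hashing."""
    return int((seed * 1000003 + hash_name(stage)) % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; any stage failure aborts with the stage
    name while preserving the partial manifest on disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    truth = None

    # ---- inputs -----------------------------------------------------
    if config.simulate:
        sim_cfg = dataclasses.replace(config.simulation, seed=stage_seed(config.seed, "simulate"))
        plasma, tissue, metadata, qc_series, truth = synthetic.simulate_cohort(sim_cfg)
        io.write_feature_matrix(plasma, outdir / "plasma_raw.tsv")
        io.write_metadata(metadata, outdir / "metadata.tsv")
        io.write_qc_series(qc_series, outdir / "qc_series.tsv")
        io.write_json(
            {
                "true_de_set": truth.true_de_set,
                "effect_sizes": truth.effect_sizes,
                "true_consensus_set": truth.true_consensus_set,
                "true_edge_set": [sorted(e) for e in sorted(truth.true_edge_set, key=sorted)],
                "case_only_edges": [sorted(e) for e in sorted(truth.case_only_edges, key=sorted)],
            },
            outdir / "truth.json",
        )
        report.add_outputs(
            outdir / "plasma_raw.tsv", outdir / "metadata.tsv",
            outdir / "qc_series.tsv", outdir / "truth.json",
        )
        matrix = plasma
        report.record("simulate", n_samples=matrix.n_samples, n_features=matrix.n_features)
    else:
        if not config.matrix_path or not config.metadata_path:
            raise ValueError("matrix_path and metadata_path are required unless simulate=True")
        matrix = io.read_feature_matrix(config.matrix_path)
        metadata = SampleMetadata(io.read_metadata(config.metadata_path).table.loc[matrix.sample_ids])
        qc_series = io.read_qc_series(config.qc_path) if config.qc_path else None
        report.record("load", n_samples=matrix.n_samples, n_features=matrix.n_features)

    try:
        # ---- QC filtering -------------------------------------------
        n_in = matrix.n_features
        if qc_series is not None and qc_series.feature_ids:
            dil = qc.dilution_correlation_filter(qc_series, config.dilution_threshold)
            rsd = qc.rsd_filter(qc_series, config.rsd_threshold_pct)
            qc_report = qc.combine_qc_reports(dil, rsd)
            qc_report.to_csv(outdir / "qc_report.tsv", sep="\t")
            report.add_outputs(outdir / "qc_report.tsv")
            matrix = qc.apply_qc_filter(matrix, qc_report)
            n_fail_dilution = int((~dil["passed"].astype(bool)).sum())
            n_fail_rsd_only = int(
                ((~rsd["passed"].astype(bool)) & rsd.index.isin(dil.index[dil["passed"].astype(bool)])).sum()
            )
            report.record(
                "qc_filter",
                n_input=n_in,
                n_pass=matrix.n_features,
                n_fail_dilution=n_fail_dilution,
                n_fail_rsd_only=n_fail_rsd_only,
            )
        else:
            report.record("qc_filter", n_input=n_in, n_pass=n_in, skipped=True)

        # ---- normalisation ------------------------------------------
        logged = qc.log_transform(matrix)
        imputed = qc.knn_impute(logged, k=config.knn_k)
        pareto = qc.pareto_scale(imputed)
        io.write_feature_matrix(pareto, outdir / "matrix_log_pareto.tsv")
        report.add_outputs(outdir / "matrix_log_pareto.tsv")
        report.record(
            "preprocess",
            n_missing_imputed=int(logged.values.isna().sum().sum()),
            scale_state=pareto.scale_state,
        )

        # ---- differential analysis ----------------------------------
        if config.de_method == "moderated":
            design = differential.build_design(metadata)
            design = design.loc[imputed.sample_ids]
            de = differential.moderated_fit(
                imputed, design, alpha=config.alpha, fdr_method=config.fdr_method
            )
        else:
            de = differential.univariate_fit(
                imputed, metadata, alpha=config.alpha, fdr_method=config.fdr_method
            )
        de.to_csv(outdir / "differential.tsv", sep="\t")
        report.add_outputs(outdir / "differential.tsv")
        report.record(
            "differential",
            method=config.de_method,
            fdr=config.fdr_method,
            n_significant=int(de["significant"].sum()),
        )

        # ---- correlation / unsupervised -----------------------------
        corr = correlate.spearman_matrix(pareto, axis="samples")
        corr.rho.to_csv(outdir / "spearman_samples.tsv", sep="\t")
        labels, _ = correlate.hierarchical_cluster(pareto, n_clusters=2)
        pca = correlate.pca_scores(pareto, n_components=2)
        pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        cfdna_edges = None
        if metadata.cfdna is not None and metadata.cfdna.notna().sum() >= 10:
            cfdna_edges = correlate.cfdna_network(
                imputed, metadata, fdr_method=config.cfdna_fdr_method
            )
            cfdna_edges.to_csv(outdir / "cfdna_edges.tsv", sep="\t")
            report.add_outputs(outdir / "cfdna_edges.tsv")
        report.add_outputs(outdir / "spearman_samples.tsv", outdir / "pca_scores.tsv")
        report.record(
            "correlate",
            pc1_explained_pct=float(pca.explained_variance_pct[0]),
            n_cfdna_edges=0 if cfdna_edges is None else int(len(cfdna_edges)),
        )

        # ---- network signatures -------------------------------------
        battery = network.run_signature_battery(
            pareto, metadata, lam=config.lam,
            threshold=config.consensus_threshold, loo_cohort=config.loo_cohort,
        )
        io.write_network_tsv(battery.disease_network, outdir / "disease_network.tsv")
        io.write_network_graphml(battery.disease_network, outdir / "disease_network.graphml")
        io.write_signatures(battery.signatures, outdir / "patient_signatures.json")
        io.write_consensus(battery.consensus, outdir / "consensus.json")
        report.add_outputs(
            outdir / "disease_network.tsv", outdir / "disease_network.graphml",
            outdir / "patient_signatures.json", outdir / "consensus.json",
        )
        report.record(
            "network_signature",
            lam=battery.lam,
            n_disease_edges=battery.disease_network.n_edges,
            n_signatures=len(battery.signatures),
            consensus_size=len(battery.consensus.selected),
        )

        # ---- subset screen ------------------------------------------
        selected = sorted(battery.consensus.selected)
        if selected and len(selected) <= config.max_signature_size:
            screen_cfg = predict.ScreenConfig(
                n_repeats=config.n_repeats,
                n_trees=config.n_trees,
                max_subset_size=config.max_signature_size,
                seed=stage_seed(config.seed, "predict"),
            )
            results = predict.screen_signature(imputed, metadata, selected, screen_cfg)
            table = predict.models_table(results)
            table.to_csv(outdir / "subset_models.tsv", sep="\t", index=False)
            report.add_outputs(outdir / "subset_models.tsv")
            report.record(
                "predict",
                n_models=len(results),
                best_subset=table.iloc[0]["subset"],
                best_auc=float(table.iloc[0]["auc"]),
            )
        else:
            report.record("predict", skipped=True, consensus_size=len(selected))
    except Exception as exc:
        report.record("aborted", error=f"{type(exc).__name__}: {exc}")
        report.to_json(outdir / "run_report.json")
        raise

    report.to_json(outdir / "run_report.json")
    return report
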