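"""Pipeline orchestration: simulate -> qc -> quantify -> diff -> classify.

Each stage reads its inputs from, and writes its reports to, the
configured output directory, so any single stage can be re-run from the
persisted intermediates of an earlier full run and produce the same
result.  Every run writes ``pipeline_log.json`` recording the master seed,
the effective parameters, per-stage row counts, and completion status;
all randomness derives from the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import srm_data, synthetic, assay_qc, quantify, cohort_stats, classify
from .srm_data import ValidationError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "stage_simulate", "stage_qc", "stage_quantify", "stage_diff",
           "stage_classify"]

log = logging.getLogger("srmquant")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of the five-stage pipeline.

    Thresholds: ``cv_threshold_percent`` is the peptide acceptance and
    LLOQ bound (20% by default), ``fold_tolerance`` the interference
    exclusion bound, ``fdr_level`` the BH q-value call level.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    # calibration design
    levels: tuple[float, ...] = synthetic.DEFAULT_LEVELS
    n_blanks: int = 3
    n_replicates: int = 3
    counterpart_fmol: float = 100.0
    # replicate design
    replicate_levels: tuple[float, ...] = (5.0, 50.0, 500.0)
    light_fmol: float = 30.0
    days: int = 5
    reps_per_day: int = 3
    # cohort
    n_control: int = 28
    n_cirrhosis: int = 15
    n_hcc: int = 19
    hcc_effect: float = 1.0
    cirrhosis_fraction: float = 0.5
    cohort_noise_sd: float = 0.5
    # analysis thresholds
    cv_threshold_percent: float = 20.0
    fold_tolerance: float = 2.0
    fdr_level: float = 0.05
    rollup_scheme: str = "inverse_variance"
    # classification
    algorithms: tuple[str, ...] = tuple(classify.ALGORITHMS)
    max_panel: int | None = None
    rank_once: bool = False

    def __post_init__(self):
        for name in ("cv_threshold_percent", "fold_tolerance", "fdr_level"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        self.seed = int(self.seed) % (2 ** 31)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _outdir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _truth(cfg: PipelineConfig) -> synthetic.GroundTruth:
    return synthetic.default_ground_truth(
        hcc_effect=cfg.hcc_effect,
        cirrhosis_fraction=cfg.cirrhosis_fraction,
        cohort_noise_sd=cfg.cohort_noise_sd,
    )


def _update_log(outdir: Path, stage: str, info: dict) -> None:
    path = outdir / "pipeline_log.json"
    data = {}
    if path.exists():
        data = json.loads(path.read_text())
    data.setdefault("stages", {})[stage] = info
    path.write_text(json.dumps(data, indent=2, sort_keys=True))


def stage_simulate(cfg: PipelineConfig) -> dict:
    """Generate the three experiment classes and persist them."""
    outdir = _outdir(cfg)
    truth = _truth(cfg)
    cal, cal_meta = synthetic.generate_calibration(
        truth, levels=cfg.levels, n_blanks=cfg.n_blanks,
        n_replicates=cfg.n_replicates, counterpart_fmol=cfg.counterpart_fmol,
        seed=cfg.seed)
    rep, rep_meta = synthetic.generate_replicate_design(
        truth, levels=cfg.replicate_levels, light_fmol=cfg.light_fmol,
        days=cfg.days, reps_per_day=cfg.reps_per_day, seed=cfg.seed + 1)
    design = synthetic.CohortDesign(n_control=cfg.n_control,
                                    n_cirrhosis=cfg.n_cirrhosis,
                                    n_hcc=cfg.n_hcc)
    cohort, cohort_meta = synthetic.generate_cohort(design, truth,
                                                    seed=cfg.seed + 2)
    srm_data.write_transition_report(cal, outdir / "calibration_transitions.csv")
    srm_data.write_run_metadata(cal_meta, outdir / "calibration_metadata.csv")
    srm_data.write_transition_report(rep, outdir / "replicate_transitions.csv")
    srm_data.write_run_metadata(rep_meta, outdir / "replicate_metadata.csv")
    cohort.to_csv(outdir / "cohort_peptides.csv")
    srm_data.write_run_metadata(cohort_meta, outdir / "cohort_metadata.csv")
    truth.save(outdir / "ground_truth.yaml")
    info = dict(seed=cfg.seed, calibration_rows=len(cal),
                replicate_rows=len(rep),
                cohort_samples=len(cohort), status="complete")
    _update_log(outdir, "simulate", info)
    return info


def stage_qc(cfg: PipelineConfig) -> dict:
    """Assay characterization from the persisted calibration/replicate runs."""
    outdir = _outdir(cfg)
    cal = srm_data.read_transition_report(outdir / "calibration_transitions.csv")
    cal_meta = srm_data.read_run_metadata(outdir / "calibration_metadata.csv")
    rep = srm_data.read_transition_report(outdir / "replicate_transitions.csv")
    rep_meta = srm_data.read_run_metadata(outdir / "replicate_metadata.csv")
    # interference is judged on spiked runs only; blank ratios are noise
    blank_runs = set(cal_meta.loc[cal_meta["run_type"] == "blank", "run_id"])
    spiked = cal[~cal["run_id"].isin(blank_runs)]
    excluded, warns = quantify.flag_interference(spiked, cfg.fold_tolerance)
    report = assay_qc.build_assay_report(
        cal, cal_meta, rep, rep_meta,
        cv_threshold_percent=cfg.cv_threshold_percent, excluded=excluded)
    srm_data.write_report(report, outdir / "assay_report")
    n_acc = int(report.peptides["accepted"].sum())
    if n_acc == 0:
        log.warning("qc: no peptide passed the CV acceptance filter")
    info = dict(seed=cfg.seed, n_peptides=len(report.peptides),
                n_accepted=n_acc, n_excluded_transitions=len(excluded),
                warnings=warns[:20], status="complete")
    _update_log(outdir, "qc", info)
    return info


def stage_quantify(cfg: PipelineConfig) -> dict:
    """Roll accepted peptides up into the protein abundance matrix."""
    outdir = _outdir(cfg)
    cohort = pd.read_csv(outdir / "cohort_peptides.csv", index_col="sample_id")
    report = srm_data.read_assay_report(outdir / "assay_report")
    accepted = report.peptides.loc[report.peptides["accepted"], "peptide"]
    kept = [p for p in cohort.columns if p in set(accepted)]
    warnings = []
    if not kept:
        warnings.append("no accepted peptides: protein matrix is empty")
        matrix = srm_data.ProteinAbundanceMatrix(
            values=pd.DataFrame(index=cohort.index))
    else:
        mapping = dict(report.peptides[["peptide", "protein"]].values)
        matrix = quantify.rollup(cohort[kept],
                                 {p: mapping[p] for p in kept},
                                 scheme=cfg.rollup_scheme)
    matrix.write(outdir / "protein_matrix.csv")
    with open(outdir / "rollup_weights.json", "w") as fh:
        json.dump(matrix.provenance, fh, indent=2, sort_keys=True)
    for w in warnings:
        log.warning("quantify: %s", w)
    info = dict(seed=cfg.seed, n_peptides_used=len(kept),
                n_proteins=len(matrix.proteins), warnings=warnings,
                status="complete")
    _update_log(outdir, "quantify", info)
    return info


def stage_diff(cfg: PipelineConfig) -> dict:
    """Differential abundance, PCA, and protein clustering."""
    outdir = _outdir(cfg)
    matrix = srm_data.ProteinAbundanceMatrix.read(outdir / "protein_matrix.csv")
    meta = srm_data.read_run_metadata(outdir / "cohort_metadata.csv")
    warnings = []
    if not matrix.proteins:
        warnings.append("empty protein matrix: differential stage skipped")
        pd.DataFrame(columns=["protein", "contrast", "effect", "F_statistic",
                              "p_value", "q_value"]).to_csv(
            outdir / "differential.csv", index=False)
        info = dict(seed=cfg.seed, n_significant=0, warnings=warnings,
                    status="complete")
        _update_log(outdir, "diff", info)
        for w in warnings:
            log.warning("diff: %s", w)
        return info
    results = cohort_stats.fit_condition_model(matrix, meta)
    results.to_csv(outdir / "differential.csv", index=False)
    pca = cohort_stats.run_pca(matrix)
    pca.scores.to_csv(outdir / "pca_scores.csv")
    pca.loadings.to_csv(outdir / "pca_loadings.csv")
    pd.DataFrame({"component": pca.scores.columns,
                  "variance_fraction": pca.variance_explained}).to_csv(
        outdir / "pca_variance.csv", index=False)
    k = 2 if len(matrix.proteins) >= 2 else 1
    clus = cohort_stats.cluster_proteins(matrix, k=k)
    (outdir / "protein_dendrogram.nwk").write_text(clus.newick + "\n")
    pd.DataFrame({"protein": clus.proteins,
                  "cluster": [clus.assignments[p] for p in clus.proteins]}
                 ).to_csv(outdir / "protein_clusters.csv", index=False)
    sig = results[(results["contrast"] != "overall")
                  & (results["q_value"] < cfg.fdr_level)]
    info = dict(seed=cfg.seed, n_significant=int(len(sig)),
                warnings=warnings + pca.warnings, status="complete")
    _update_log(outdir, "diff", info)
    return info


def stage_classify(cfg: PipelineConfig) -> dict:
    """Panel evaluation grid and the final model report."""
    outdir = _outdir(cfg)
    matrix = srm_data.ProteinAbundanceMatrix.read(outdir / "protein_matrix.csv")
    meta = srm_data.read_run_metadata(outdir / "cohort_metadata.csv")
    warnings = []
    if len(matrix.proteins) < 1:
        warnings.append("empty protein matrix: classification skipped")
        (outdir / "classification_report.json").write_text(
            json.dumps({"status": "skipped", "warnings": warnings}, indent=2))
        info = dict(seed=cfg.seed, warnings=warnings, status="complete")
        _update_log(outdir, "classify", info)
        log.warning("classify: %s", warnings[0])
        return info
    labels = meta.set_index("sample_id").loc[matrix.sample_ids, "condition"].values
    values = cohort_stats.impute_half_min(matrix)
    grid, grid_warns = classify.evaluate_panels(
        values, labels, algorithms=list(cfg.algorithms),
        max_panel=cfg.max_panel, seed=cfg.seed + 3, rank_once=cfg.rank_once)
    grid.to_csv(outdir / "accuracy_grid.csv")
    # best cell: highest LOOCV accuracy, ties to the smaller panel then
    # algorithm list order
    best_acc, best_k, best_algo = -1.0, None, None
    for k in grid.index:
        for a in grid.columns:
            acc = grid.loc[k, a]
            if np.isfinite(acc) and acc > best_acc:
                best_acc, best_k, best_algo = float(acc), int(k), a
    ranking = classify.rank_proteins_anova(values, labels)["protein"].tolist()
    panel = ranking[:best_k]
    report = classify.final_model_report(values, labels, panel, best_algo,
                                         seed=cfg.seed + 3,
                                         accuracy_grid=grid)
    report.warnings = grid_warns[:20]
    srm_data.write_report(report, outdir / "classification_report.json")
    for c, roc in report.roc_curves.items():
        roc.to_csv(outdir / f"roc_{c}.csv", index=False)
    info = dict(seed=cfg.seed, best_panel_size=best_k, best_algorithm=best_algo,
                loocv_accuracy=report.out_of_sample_accuracy,
                in_sample_accuracy=report.in_sample_accuracy,
                warnings=warnings, status="complete")
    _update_log(outdir, "classify", info)
    return info


_STAGES = [("simulate", stage_simulate), ("qc", stage_qc),
           ("quantify", stage_quantify), ("diff", stage_diff),
           ("classify", stage_classify)]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all five stages in order; deterministic given config + seed.

    Any stage error aborts with the stage name and cause; the log file
    marks the failed stage so partial outputs are identifiable.
    """
    outdir = _outdir(cfg)
    (outdir / "pipeline_config.yaml").write_text(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    summary = {}
    for name, fn in _STAGES:
        log.info("running stage %s", name)
        try:
            summary[name] = fn(cfg)
        except Exception as exc:
            _update_log(outdir, name, dict(status="incomplete",
                                           error=str(exc)))
            raise PipelineError(name, exc) from exc
    return summary
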