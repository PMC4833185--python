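"""End-to-end orchestration: discovery on a training series, validation on others.

Discovery runs the full chain — driver-quartile split, Q4-vs-Q1 differential
expression, KNN-LOOCV signature selection over the high-driver set, 2-way
cluster partition, ROC ranking of the signature probes, cumulative-score
construction, and survival statistics for both the cluster partition and the
median-split score.  Validation applies a frozen signature + score model to
an independent series.  File-level wrappers read a YAML config and emit
plain TSV/JSON reports plus a deterministic run manifest.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster_assign import assign_clusters, association_odds_ratio
from .ingest import (
    ClinicalTable,
    ExpressionMatrix,
    ValidationError,
    align,
    load_clinical,
    load_expression,
)
from .knn_signature import (
    KnnConfig,
    Signature,
    outcome_labels,
    select_optimal_signature,
)
from .quartile_de import high_driver_set, split_quartiles
from .score_model import ScoreModel, build_score, median_split, rank_by_auc, sweep_k
from .survival_stats import cox_fit, km_fit, logrank, ppv_npv

logger = logging.getLogger("wt1sig")


@dataclass
class RunConfig:
    """File-level run description, loadable from a single YAML document."""

    expression_path: str
    clinical_path: str
    driver_probe: str
    output_dir: str
    expression_format: str = "tsv"
    fdr_threshold: float = 0.05
    knn: KnnConfig = field(default_factory=KnnConfig)
    score_k: int = 4
    score_normalized: bool = False
    threshold_mode: str = "cohort"    # or "transfer"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        knn_raw = raw.pop("knn", {})
        if "n_features_grid" in knn_raw:
            knn_raw["n_features_grid"] = tuple(knn_raw["n_features_grid"])
        cfg = cls(**raw, knn=KnnConfig(**knn_raw))
        cfg.knn.validate()
        return cfg

    def validate_paths(self) -> None:
        for p in (self.expression_path, self.clinical_path):
            if not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")


@dataclass
class SurvivalSummary:
    """Group-comparison summary for one endpoint and one binary partition."""

    endpoint: str
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    hr_p: float
    median_high: float
    median_other: float

    def as_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "hr": self.hr,
            "hr_ci_lower": self.hr_ci[0],
            "hr_ci_upper": self.hr_ci[1],
            "hr_p": self.hr_p,
            "median_high": self.median_high,
            "median_other": self.median_other,
        }


def _partition_survival(high: np.ndarray, clin: ClinicalTable) -> list[SurvivalSummary]:
    out = []
    for ep in ("os", "efs", "rfs"):
        if not clin.has_endpoint(ep):
            continue
        time, event = clin.endpoint(ep)
        chi2, p = logrank(high.astype(int), time, event)
        try:
            cox = cox_fit(pd.DataFrame({"high": high.astype(float)}), time, event)
            row = cox.table.loc["high"]
            hr, lo, hi, hp = row["hr"], row["ci_lower"], row["ci_upper"], row["p"]
        except ValidationError as exc:
            logger.warning("Cox failed for endpoint %s: %s", ep, exc)
            hr = lo = hi = hp = np.nan
        km_hi = km_fit(time[high], event[high])
        km_ot = km_fit(time[~high], event[~high])
        out.append(
            SurvivalSummary(
                endpoint=ep,
                logrank_chi2=chi2,
                logrank_p=p,
                hr=float(hr),
                hr_ci=(float(lo), float(hi)),
                hr_p=float(hp),
                median_high=km_hi.median,
                median_other=km_ot.median,
            )
        )
    return out


@dataclass
class DiscoveryResult:
    signature: Signature | None
    score_model: ScoreModel | None
    de_table: pd.DataFrame
    selection_report: pd.DataFrame
    cluster_groups: pd.Series | None
    cluster_survival: list[SurvivalSummary]
    score_survival: list[SurvivalSummary]
    roc_ranking: pd.DataFrame | None
    score_sweep: pd.DataFrame | None
    high_wt1_odds_ratio: tuple[float, float] | None   # cluster vs driver-Q4 membership
    flags: list[str]


def discover(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    driver_probe: str,
    fdr_threshold: float = 0.05,
    knn_config: KnnConfig | None = None,
    score_k: int = 4,
    score_normalized: bool = False,
    signature_name: str = "signature",
) -> DiscoveryResult:
    """Run the discovery chain on an aligned training series."""
    expr, clin = align(expr, clin)
    if not clin.has_endpoint("efs"):
        raise ValidationError("discovery requires EFS endpoints on the training series")
    flags: list[str] = []

    split = split_quartiles(expr, driver_probe)
    de = high_driver_set(expr, split, fdr_threshold)
    sig_probes = de.index[de["significant"]].tolist()
    logger.info("high-driver set: %d significant probes", len(sig_probes))
    if len(sig_probes) < 2:
        flags.append("no prognostic signature: high-driver set empty")
        return DiscoveryResult(
            None, None, de, pd.DataFrame(), None, [], [], None, None, None, flags
        )

    high_expr = expr.subset_probes(sig_probes)
    labels = outcome_labels(clin)
    signature, report = select_optimal_signature(
        high_expr, labels, clin, knn_config, name=signature_name
    )
    if signature is None:
        flags.append("no prognostic signature: no grid size produced a valid partition")
        return DiscoveryResult(
            None, None, de, report, None, [], [], None, None, None, flags
        )

    assignment = assign_clusters(expr, signature)
    high = (assignment.groups == "high").to_numpy()
    cluster_surv = _partition_survival(high, clin)
    q4_member = clin.data.index.isin(split.q4).astype(int)
    odds = association_odds_ratio(high.astype(int), q4_member)

    _, efs_event = clin.endpoint("efs")
    ranking = rank_by_auc(expr, signature, efs_event)
    k = min(score_k, len(ranking))
    if k < score_k:
        flags.append(f"score k reduced to {k}: signature shorter than requested")
    model = build_score(expr, ranking, k, normalized=score_normalized)
    scores = model.scores(expr)
    risk = median_split(model, scores)
    score_surv = _partition_survival((risk == "high").to_numpy(), clin)
    efs_time, _ = clin.endpoint("efs")
    sweep = sweep_k(
        expr, ranking, len(ranking), efs_event, time=efs_time, event=efs_event
    )

    return DiscoveryResult(
        signature=signature,
        score_model=model,
        de_table=de,
        selection_report=report,
        cluster_groups=assignment.groups,
        cluster_survival=cluster_surv,
        score_survival=score_surv,
        roc_ranking=ranking,
        score_sweep=sweep,
        high_wt1_odds_ratio=odds,
        flags=flags,
    )


@dataclass
class ValidationResult:
    cluster_groups: pd.Series
    cluster_survival: list[SurvivalSummary]
    scores: pd.Series
    risk_groups: pd.Series
    score_survival: list[SurvivalSummary]
    ppv_npv_os: tuple[float, float] | None
    threshold_used: float
    flags: list[str]


def validate_series(
    signature: Signature,
    score_model: ScoreModel,
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    threshold_mode: str = "cohort",
) -> ValidationResult:
    """Apply a frozen signature and score model to an independent series.

    ``threshold_mode="cohort"`` re-computes the median threshold on the
    validation cohort; ``"transfer"`` keeps the training threshold.
    """
    expr, clin = align(expr, clin)
    flags: list[str] = []
    assignment = assign_clusters(expr, signature)   # raises if < 2 probes usable
    high = (assignment.groups == "high").to_numpy()
    cluster_surv = _partition_survival(high, clin)

    scores = score_model.scores(expr)
    if threshold_mode == "cohort":
        threshold = float(np.median(scores))
    elif threshold_mode == "transfer":
        threshold = score_model.threshold
    else:
        raise ValidationError(f"unknown threshold_mode {threshold_mode!r}")
    local = ScoreModel(
        k=score_model.k,
        probes=score_model.probes,
        directions=score_model.directions,
        threshold=threshold,
        normalized=score_model.normalized,
        norm_means=score_model.norm_means,
        norm_sds=score_model.norm_sds,
    )
    risk = median_split(local, scores)
    high_risk = (risk == "high").to_numpy()
    if high_risk.all() or not high_risk.any():
        flags.append("score split degenerate on validation series")
        score_surv: list[SurvivalSummary] = []
        pv = None
    else:
        score_surv = _partition_survival(high_risk, clin)
        if clin.has_endpoint("os"):
            _, os_event = clin.endpoint("os")
            pv = ppv_npv(high_risk.astype(int), os_event)
        else:
            pv = None
    return ValidationResult(
        cluster_groups=assignment.groups,
        cluster_survival=cluster_surv,
        scores=scores,
        risk_groups=risk,
        score_survival=score_surv,
        ppv_npv_os=pv,
        threshold_used=threshold,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# file-level wrappers


def _write_manifest(outdir: Path, config_payload: dict, outputs: list[str]) -> None:
    manifest = {
        "package": "wt1sig",
        "version": __version__,
        "config": config_payload,
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )


def run_discovery(config: RunConfig) -> DiscoveryResult:
    """Load inputs per ``config``, run discovery, write the report bundle."""
    config.validate_paths()
    t0 = _time.monotonic()
    expr = load_expression(config.expression_path, format=config.expression_format)
    clin = load_clinical(config.clinical_path)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = discover(
        expr,
        clin,
        config.driver_probe,
        fdr_threshold=config.fdr_threshold,
        knn_config=config.knn,
        score_k=config.score_k,
        score_normalized=config.score_normalized,
    )
    outputs = []

    def _tsv(name: str, df: pd.DataFrame) -> None:
        df.to_csv(outdir / name, sep="\t")
        outputs.append(name)

    _tsv("de_table.tsv", result.de_table)
    if not result.selection_report.empty:
        _tsv("selection_report.tsv", result.selection_report)
    if result.signature is not None:
        _tsv("signature.tsv", result.signature.to_frame())
        _tsv("cluster_assignment.tsv", result.cluster_groups.to_frame())
        _tsv("roc_ranking.tsv", result.roc_ranking)
        _tsv("score_sweep.tsv", result.score_sweep)
        result.score_model.to_json(outdir / "score_model.json")
        outputs.append("score_model.json")
        surv = pd.DataFrame(
            [s.as_dict() for s in result.cluster_survival]
            + [dict(s.as_dict(), partition="score") for s in result.score_survival]
        )
        _tsv("survival_summary.tsv", surv.set_index("endpoint"))
    summary = {
        "flags": result.flags,
        "n_significant_probes": int(result.de_table["significant"].sum()),
        "signature_size": None if result.signature is None else len(result.signature.probes),
        "high_wt1_odds_ratio": None
        if result.high_wt1_odds_ratio is None
        else list(result.high_wt1_odds_ratio),
    }
    (outdir / "discovery_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    outputs.append("discovery_summary.json")
    payload = {
        "expression_path": config.expression_path,
        "clinical_path": config.clinical_path,
        "driver_probe": config.driver_probe,
        "fdr_threshold": config.fdr_threshold,
        "score_k": config.score_k,
        "score_normalized": config.score_normalized,
        "threshold_mode": config.threshold_mode,
        "seed": config.seed,
        "knn": {
            "k_neighbours": config.knn.k_neighbours,
            "n_features_grid": list(config.knn.n_features_grid),
            "distance": config.knn.distance,
            "vote": config.knn.vote,
            "stability_threshold": config.knn.stability_threshold,
        },
    }
    _write_manifest(outdir, payload, outputs)
    logger.info("discovery finished in %.1fs", _time.monotonic() - t0)
    return result


def run_validation(
    signature_path,
    score_model_path,
    expression_path,
    clinical_path,
    output_dir,
    expression_format: str = "tsv",
    threshold_mode: str = "cohort",
) -> ValidationResult:
    """Apply a frozen signature/score to a series on disk; write the bundle."""
    sig = Signature.from_frame(pd.read_csv(signature_path, sep="\t", index_col=0))
    model = ScoreModel.from_json(score_model_path)
    expr = load_expression(expression_path, format=expression_format)
    clin = load_clinical(clinical_path)
    result = validate_series(sig, model, expr, clin, threshold_mode=threshold_mode)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    result.cluster_groups.to_frame().to_csv(outdir / "cluster_assignment.tsv", sep="\t")
    outputs.append("cluster_assignment.tsv")
    pd.DataFrame({"score": result.scores, "risk_group": result.risk_groups}).to_csv(
        outdir / "scores.tsv", sep="\t"
    )
    outputs.append("scores.tsv")
    surv = pd.DataFrame(
        [dict(s.as_dict(), partition="cluster") for s in result.cluster_survival]
        + [dict(s.as_dict(), partition="score") for s in result.score_survival]
    )
    if not surv.empty:
        surv.set_index("endpoint").to_csv(outdir / "survival_summary.tsv", sep="\t")
        outputs.append("survival_summary.tsv")
    summary = {
        "flags": result.flags,
        "threshold_used": result.threshold_used,
        "ppv_npv_os": None if result.ppv_npv_os is None else list(result.ppv_npv_os),
    }
    (outdir / "validation_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    outputs.append("validation_summary.json")
    _write_manifest(
        outdir,
        {
            "signature_path": str(signature_path),
            "score_model_path": str(score_model_path),
            "expression_path": str(expression_path),
            "clinical_path": str(clinical_path),
            "threshold_mode": threshold_mode,
        },
        outputs,
    )
    return result
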