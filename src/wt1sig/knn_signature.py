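"""KNN leave-one-out outcome prediction with t-test(median) feature selection.

Re-implements, as deterministic library code, the GenePattern-style KNN
cross-validation workflow used to derive a prognostic signature: in each
leave-one-out fold, probes are ranked by the absolute t-statistic with group
medians substituted for means, the top-m are used to classify the held-out
sample by k-nearest-neighbours, and the per-fold feature lists are trimmed
to those recurring in at least a given fraction of folds.  Candidate list
sizes (10-50 by default) are compared by the prognostic strength of the
cluster partition each trimmed list induces, and the best becomes the
signature (the S17 analogue).

Class labels follow the event-free-survival convention: samples with no
EFS event are "favourable", all others (death, no remission, relapse)
"adverse"; the adverse class is the positive class throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_assign import assign_clusters
from .ingest import ClinicalTable, ExpressionMatrix, ValidationError
from .survival_stats import cox_fit, logrank

logger = logging.getLogger("wt1sig")

FAVOURABLE = "favourable"
ADVERSE = "adverse"

#: cap used when a t-statistic denominator is exactly zero
LARGE_T = 1e12


@dataclass
class KnnConfig:
    k_neighbours: int = 3
    n_features_grid: tuple = tuple(range(10, 51))
    distance: str = "euclidean"          # or "one_minus_pearson"
    vote: str = "majority"               # or "distance_weighted"
    stability_threshold: float = 0.9

    def validate(self) -> None:
        if self.k_neighbours < 1:
            raise ValidationError("k_neighbours must be >= 1")
        if self.vote == "majority" and self.k_neighbours % 2 == 0:
            raise ValidationError("majority vote needs odd k")
        if any(m < 2 for m in self.n_features_grid):
            raise ValidationError("feature-grid sizes must be >= 2")
        if not (0 < self.stability_threshold <= 1):
            raise ValidationError("stability_threshold must be in (0, 1]")
        if self.distance not in ("euclidean", "one_minus_pearson"):
            raise ValidationError(f"unknown distance {self.distance!r}")
        if self.vote not in ("majority", "distance_weighted"):
            raise ValidationError(f"unknown vote {self.vote!r}")


@dataclass
class FoldRecord:
    held_out: str
    features: list[str]
    predicted: str
    true: str


@dataclass
class Signature:
    """Ordered probe list with per-probe direction (+1 adverse-up, -1 adverse-down)."""

    name: str
    probes: list[str]
    directions: dict[str, int]

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValidationError("signature must be nonempty")
        if len(set(self.probes)) != len(self.probes):
            raise ValidationError("signature contains duplicate probes")
        missing = [p for p in self.probes if p not in self.directions]
        if missing:
            raise ValidationError(f"missing directions for {missing[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"direction": ["+" if self.directions[p] > 0 else "-" for p in self.probes]},
            index=pd.Index(self.probes, name="probe"),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "signature") -> "Signature":
        probes = list(df.index)
        directions = {
            p: (1 if str(d) in ("+", "1") else -1) for p, d in df["direction"].items()
        }
        return cls(name, probes, directions)


def outcome_labels(clin: ClinicalTable) -> pd.Series:
    """EFS-based class labels: event-free samples favourable, all others adverse."""
    time, event = clin.endpoint("efs")
    del time
    labels = np.where(event == 1, ADVERSE, FAVOURABLE)
    return pd.Series(labels, index=clin.data.index, name="label")


def tstat_median(x, y) -> float:
    """t-statistic with group medians in place of means.

    ``(med(x) - med(y)) / sqrt(s2_x/n_x + s2_y/n_y)`` with the usual sample
    variances.  A zero denominator maps the statistic to ±LARGE (0 when the
    medians also agree).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("tstat_median needs at least 2 observations per group")
    num = np.median(x) - np.median(y)
    den = np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
    if den == 0:
        if num == 0:
            return 0.0
        logger.warning("tstat_median: zero variance in both groups, statistic capped")
        return float(np.sign(num) * LARGE_T)
    return float(num / den)


def _tstat_median_matrix(values: np.ndarray, adverse_mask: np.ndarray) -> np.ndarray:
    """Vectorised tstat_median (adverse minus favourable) for every probe row."""
    xa = values[:, adverse_mask]
    xf = values[:, ~adverse_mask]
    num = np.median(xa, axis=1) - np.median(xf, axis=1)

    def _var_term(x: np.ndarray) -> np.ndarray:
        # a singleton group contributes no variance information
        if x.shape[1] < 2:
            return np.zeros(x.shape[0])
        return x.var(axis=1, ddof=1) / x.shape[1]

    den = np.sqrt(_var_term(xa) + _var_term(xf))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    zero = den == 0
    t[zero] = np.sign(num[zero]) * LARGE_T
    return t


def rank_features(expr: ExpressionMatrix, labels: pd.Series) -> list[str]:
    """Probes ordered by |tstat_median(adverse, favourable)| descending, ties by ID."""
    labels = labels.loc[expr.sample_ids]
    adverse = (labels == ADVERSE).to_numpy()
    if adverse.all() or (~adverse).all():
        raise ValidationError("both outcome classes must be present")
    t = _tstat_median_matrix(expr.values.to_numpy(float), adverse)
    order = sorted(range(len(t)), key=lambda i: (-abs(t[i]), expr.probe_ids[i]))
    return [expr.probe_ids[i] for i in order]


def _zscore_train(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature z-scoring using training-fold statistics only."""
    mu = train.mean(axis=1, keepdims=True)
    sd = train.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _distances(train: np.ndarray, test: np.ndarray, metric: str) -> np.ndarray:
    """Distance from each test column to each training column (features x cols)."""
    if metric == "euclidean":
        diff = train[:, :, None] - test[:, None, :]
        return np.sqrt((diff**2).sum(axis=0)).T  # (n_test, n_train)
    # one minus Pearson correlation over features
    tr = train - train.mean(axis=0, keepdims=True)
    te = test - test.mean(axis=0, keepdims=True)
    tr_n = np.linalg.norm(tr, axis=0)
    te_n = np.linalg.norm(te, axis=0)
    tr_n[tr_n == 0] = 1.0
    te_n[te_n == 0] = 1.0
    corr = (te / te_n).T @ (tr / tr_n)
    return 1.0 - corr


def knn_predict(
    train: np.ndarray,
    train_labels: np.ndarray,
    test: np.ndarray,
    config: KnnConfig,
) -> list[str]:
    """Classify test columns by k-nearest-neighbours over feature rows.

    Features are z-scored on training statistics; neighbour order on tied
    distances follows training-sample order; tied votes fall back to the
    training class prior, then to label (alphabetical) order.
    """
    train_z, test_z = _zscore_train(train, test)
    dist = _distances(train_z, test_z, config.distance)
    k = min(config.k_neighbours, train.shape[1])
    classes = sorted(set(train_labels))
    prior = {c: np.sum(train_labels == c) for c in classes}
    out = []
    for row in dist:
        nn = np.argsort(row, kind="stable")[:k]
        if config.vote == "majority":
            votes = {c: np.sum(train_labels[nn] == c) for c in classes}
        else:
            w = 1.0 / np.maximum(row[nn], 1e-12)
            votes = {c: float(w[train_labels[nn] == c].sum()) for c in classes}
        best = max(votes.values())
        tied = [c for c in classes if votes[c] == best]
        if len(tied) > 1:
            logger.warning("knn_predict: vote tie broken by class prior")
            best_prior = max(prior[c] for c in tied)
            tied = sorted(c for c in tied if prior[c] == best_prior)
        out.append(tied[0])
    return out


def _fold_rankings(expr: ExpressionMatrix, labels: pd.Series) -> list[list[int]]:
    """Full feature ranking (probe indices) for every leave-one-out fold."""
    values = expr.values.to_numpy(float)
    labels = labels.loc[expr.sample_ids]
    adverse = (labels == ADVERSE).to_numpy()
    n = values.shape[1]
    probe_ids = expr.probe_ids
    rankings = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        sub_adverse = adverse[mask]
        if sub_adverse.all() or (~sub_adverse).all():
            raise ValidationError(
                "a leave-one-out fold lost one outcome class entirely"
            )
        t = _tstat_median_matrix(values[:, mask], sub_adverse)
        order = sorted(range(len(t)), key=lambda g: (-abs(t[g]), probe_ids[g]))
        rankings.append(order)
    return rankings


def knn_loocv(
    expr: ExpressionMatrix,
    labels: pd.Series,
    config: KnnConfig,
    n_features: int,
    _rankings: list[list[int]] | None = None,
) -> list[FoldRecord]:
    """Leave-one-out cross-validation with per-fold feature re-selection.

    For each sample, the top ``n_features`` probes by |tstat_median| are
    selected on the remaining n-1 samples, a KNN classifier is fit on those
    samples/features, and the held-out sample is predicted.
    """
    config.validate()
    n = len(expr.sample_ids)
    if n < config.k_neighbours + 2:
        raise ValidationError("need at least k+2 samples for LOOCV")
    labels = labels.loc[expr.sample_ids]
    values = expr.values.to_numpy(float)
    lab = labels.to_numpy()
    probe_ids = expr.probe_ids
    rankings = _rankings if _rankings is not None else _fold_rankings(expr, labels)
    records = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        feat_idx = rankings[i][:n_features]
        train = values[np.ix_(feat_idx, np.where(mask)[0])]
        test = values[np.ix_(feat_idx, [i])]
        pred = knn_predict(train, lab[mask], test, config)[0]
        records.append(
            FoldRecord(
                held_out=expr.sample_ids[i],
                features=[probe_ids[g] for g in feat_idx],
                predicted=pred,
                true=lab[i],
            )
        )
    return records


def stable_features(folds: list[FoldRecord], threshold: float = 0.9) -> list[str]:
    """Probes selected in at least ``threshold`` of folds.

    Ordered by selection frequency (descending), then mean within-fold rank,
    then probe ID; an empty result is allowed but logged.
    """
    if not folds:
        raise ValidationError("stable_features needs at least one fold")
    counts: dict[str, int] = {}
    rank_sums: dict[str, float] = {}
    for rec in folds:
        for r, probe in enumerate(rec.features):
            counts[probe] = counts.get(probe, 0) + 1
            rank_sums[probe] = rank_sums.get(probe, 0.0) + r
    n_folds = len(folds)
    kept = [p for p, c in counts.items() if c / n_folds >= threshold]
    kept.sort(key=lambda p: (-counts[p], rank_sums[p] / counts[p], p))
    if not kept:
        logger.warning("stable_features: no probe met the stability threshold")
    return kept


def signature_directions(expr: ExpressionMatrix, labels: pd.Series, probes) -> dict[str, int]:
    """Per-probe sign of the adverse-vs-favourable median t-statistic."""
    labels = labels.loc[expr.sample_ids]
    adverse = (labels == ADVERSE).to_numpy()
    sub = expr.values.loc[list(probes)].to_numpy(float)
    t = _tstat_median_matrix(sub, adverse)
    return {p: (1 if t[i] >= 0 else -1) for i, p in enumerate(probes)}


def select_optimal_signature(
    expr: ExpressionMatrix,
    labels: pd.Series,
    clin: ClinicalTable,
    config: KnnConfig | None = None,
    name: str = "signature",
) -> tuple[Signature | None, pd.DataFrame]:
    """Scan candidate list sizes and pick the most prognostic trimmed list.

    For each grid size: LOOCV with per-fold selection, stability trimming,
    2-way cluster partition on the trimmed list, then log-rank p and Cox HR
    of the partition on EFS and OS.  The winner minimises the rank-sum of
    (p ascending, HR descending) over the endpoints; the full per-size table
    is returned so the choice can be overridden.  Sizes whose trimmed list
    or partition degenerates are skipped with a warning.
    """
    config = config or KnnConfig()
    config.validate()
    rankings = _fold_rankings(expr, labels)
    endpoints = [ep for ep in ("efs", "os") if clin.has_endpoint(ep)]
    if not endpoints:
        raise ValidationError("survival endpoints required for signature selection")
    rows = []
    stable_lists: dict[int, list[str]] = {}
    for m in config.n_features_grid:
        folds = knn_loocv(expr, labels, config, m, _rankings=rankings)
        accuracy = float(np.mean([r.predicted == r.true for r in folds]))
        stable = stable_features(folds, config.stability_threshold)
        row: dict = {
            "size": m,
            "n_stable": len(stable),
            "loocv_accuracy": accuracy,
            "usable": False,
        }
        if len(stable) < 2:
            logger.warning("size %d skipped: fewer than 2 stable probes", m)
            rows.append(row)
            continue
        directions = signature_directions(expr, labels, stable)
        sig = Signature(f"{name}_m{m}", stable, directions)
        try:
            assignment = assign_clusters(expr, sig)
        except ValidationError as exc:
            logger.warning("size %d skipped: %s", m, exc)
            rows.append(row)
            continue
        high = assignment.groups.loc[clin.data.index] == "high"
        if high.all() or (~high).all():
            logger.warning("size %d skipped: single cluster", m)
            rows.append(row)
            continue
        ok = True
        for ep in endpoints:
            time, event = clin.endpoint(ep)
            chi2, p = logrank(high.to_numpy().astype(int), time, event)
            try:
                cox = cox_fit(
                    pd.DataFrame({"high": high.to_numpy().astype(float)}),
                    time,
                    event,
                )
                hr = float(cox.table.loc["high", "hr"])
            except ValidationError as exc:
                logger.warning("size %d: Cox failed on %s (%s)", m, ep, exc)
                ok = False
                break
            row[f"logrank_p_{ep}"] = p
            row[f"hr_{ep}"] = hr
        if not ok:
            rows.append(row)
            continue
        row["usable"] = True
        rows.append(row)
        stable_lists[m] = stable
    report = pd.DataFrame(rows).set_index("size")
    usable = report[report["usable"]]
    if usable.empty:
        logger.warning("no grid size produced a valid prognostic partition")
        return None, report
    score = pd.Series(0.0, index=usable.index)
    for ep in endpoints:
        score += usable[f"logrank_p_{ep}"].rank(ascending=True)
        score += usable[f"hr_{ep}"].rank(ascending=False)
    best = int(score.idxmin())
    probes = stable_lists[best]
    signature = Signature(name, probes, signature_directions(expr, labels, probes))
    report = report.copy()
    report["selected"] = report.index == best
    return signature, report
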