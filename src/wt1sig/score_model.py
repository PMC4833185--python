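"""Signed cumulative expression score from ROC-ranked signature probes.

Each signature probe is scored by the AUC of its expression against the
adverse-EFS outcome; probes are ranked by |AUC - 0.5| and signed (+ if
AUC > 0.5, i.e. higher expression in adverse cases).  The k-probe score of
a sample is the sum of direction * expression over the top-k probes — the
W-k family, with the four-gene W4 as the motivating instance — and the
training-median score dichotomises samples into risk groups.  A z-scored
("normalized") variant supports cross-platform transfer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import ExpressionMatrix, ValidationError


def roc_auc(score, outcome) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie) over all +/- pairs.

    Computed through the Mann-Whitney U identity (midrank tie handling).
    """
    score = np.asarray(score, float)
    outcome = np.asarray(outcome, int)
    if not set(np.unique(outcome)) <= {0, 1}:
        raise ValidationError("outcome must be binary")
    pos = score[outcome == 1]
    neg = score[outcome == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both outcome classes must be present")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def _delong_p(score, outcome) -> float:
    """DeLong test of AUC = 0.5 via structural components (two-sided)."""
    score = np.asarray(score, float)
    outcome = np.asarray(outcome, int)
    pos = score[outcome == 1]
    neg = score[outcome == 0]
    m, n = len(pos), len(neg)
    # placement values
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m for y in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    if var <= 0:
        return 1.0 if auc == 0.5 else 0.0
    z = (auc - 0.5) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def rank_by_auc(
    expr: ExpressionMatrix, signature, efs_outcome
) -> pd.DataFrame:
    """Per-probe AUC of expression vs the adverse outcome, ranked by |AUC - 0.5|.

    Returns a DataFrame (index probe, ordered by rank) with columns
    ``auc``, ``direction`` (+1 if AUC > 0.5 else -1), ``delong_p`` and
    ``rank``.  Ties in |AUC - 0.5| are broken by probe ID.
    """
    outcome = np.asarray(efs_outcome, int)
    present = [p for p in signature.probes if p in expr.values.index]
    if not present:
        raise ValidationError("no signature probes present in matrix")
    rows = []
    for probe in present:
        vals = expr.probe(probe)
        auc = roc_auc(vals, outcome)
        rows.append(
            {
                "probe": probe,
                "auc": auc,
                "direction": 1 if auc > 0.5 else -1,
                "delong_p": _delong_p(vals, outcome),
            }
        )
    df = pd.DataFrame(rows).set_index("probe")
    df["dist"] = (df["auc"] - 0.5).abs()
    df = df.sort_values(["dist", "probe"], ascending=[False, True], kind="stable")
    df = df.drop(columns="dist")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class ScoreModel:
    """Frozen cumulative-score definition: top-k signed probes + training threshold."""

    k: int
    probes: list[str]                 # top-k, in rank order
    directions: dict[str, int]
    threshold: float                  # training-median score
    normalized: bool = False
    norm_means: dict[str, float] = field(default_factory=dict)
    norm_sds: dict[str, float] = field(default_factory=dict)

    def scores(self, expr: ExpressionMatrix) -> pd.Series:
        """Per-sample cumulative score on any matrix containing the probes."""
        missing = [p for p in self.probes if p not in expr.values.index]
        if missing:
            raise ValidationError(f"score probes missing from matrix: {missing}")
        sub = expr.values.loc[self.probes].to_numpy(float)
        if self.normalized:
            mu = np.array([self.norm_means[p] for p in self.probes])
            sd = np.array([self.norm_sds[p] for p in self.probes])
            sub = (sub - mu[:, None]) / sd[:, None]
        dirs = np.array([self.directions[p] for p in self.probes], float)
        return pd.Series(dirs @ sub, index=expr.values.columns, name="score")

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "probes": self.probes,
            "directions": self.directions,
            "threshold": self.threshold,
            "normalized": self.normalized,
            "norm_means": self.norm_means,
            "norm_sds": self.norm_sds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["directions"] = {k: int(v) for k, v in payload["directions"].items()}
        return cls(**payload)


def build_score(
    expr: ExpressionMatrix,
    ranking: pd.DataFrame,
    k: int,
    normalized: bool = False,
) -> ScoreModel:
    """Fit a k-probe cumulative score on training data.

    The per-sample score is the sum over the top-k ranked probes of
    direction * expression (expression z-scored with training statistics
    when ``normalized``); the dichotomisation threshold is the training
    median score.
    """
    if not (2 <= k <= len(ranking)):
        raise ValidationError(f"k must be in [2, {len(ranking)}], got {k}")
    top = ranking.index[:k].tolist()
    directions = {p: int(ranking.loc[p, "direction"]) for p in top}
    norm_means: dict[str, float] = {}
    norm_sds: dict[str, float] = {}
    if normalized:
        sub = expr.values.loc[top]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
        norm_means = {p: float(mu[p]) for p in top}
        norm_sds = {p: float(sd[p]) for p in top}
    model = ScoreModel(
        k=k,
        probes=top,
        directions=directions,
        threshold=0.0,
        normalized=normalized,
        norm_means=norm_means,
        norm_sds=norm_sds,
    )
    train_scores = model.scores(expr)
    model.threshold = float(np.median(train_scores))
    return model


def median_split(model: ScoreModel, scores) -> pd.Series:
    """Risk groups from the model threshold: high if score > threshold, ties low."""
    scores = pd.Series(scores)
    return pd.Series(
        np.where(scores.to_numpy(float) > model.threshold, "high", "low"),
        index=scores.index,
        name="risk_group",
    )


def sweep_k(
    expr: ExpressionMatrix,
    ranking: pd.DataFrame,
    k_max: int,
    efs_outcome,
    time=None,
    event=None,
) -> pd.DataFrame:
    """Score AUC (and optionally median-split log-rank p) for every k in 2..k_max."""
    from .survival_stats import logrank  # local import: avoids a module cycle

    if k_max > len(ranking):
        raise ValidationError(f"k_max {k_max} exceeds ranking size {len(ranking)}")
    outcome = np.asarray(efs_outcome, int)
    rows = []
    for k in range(2, k_max + 1):
        model = build_score(expr, ranking, k)
        s = model.scores(expr)
        row = {"k": k, "auc": roc_auc(s.to_numpy(), outcome)}
        if time is not None and event is not None:
            groups = (median_split(model, s) == "high").to_numpy().astype(int)
            if groups.all() or not groups.any():
                row["logrank_p"] = np.nan
            else:
                _, row["logrank_p"] = logrank(groups, time, event)
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")
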