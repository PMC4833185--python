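"""Two-way sample partition on a signature: the supervised-clustering step.

Replaces an interactive clustering tool with a fixed recipe: z-score the
signature rows, hierarchically cluster samples (average linkage on
1 - Pearson correlation), cut the tree into two clusters, and call "high"
the cluster with the larger mean signed signature expression.  The signed
mean (rather than the driver probe itself) decides the label, so the
partition works on validation platforms lacking the driver probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .ingest import ExpressionMatrix, ValidationError

logger = logging.getLogger("wt1sig")


@dataclass
class ClusterAssignment:
    """Per-sample group ('high' vs 'other') plus bookkeeping."""

    groups: pd.Series             # sample_id -> {"high", "other"}
    fraction_high: float
    linkage_method: str
    distance: str
    dendrogram_order: list[str]   # samples in leaf order, for heatmap export


def assign_clusters(expr: ExpressionMatrix, signature) -> ClusterAssignment:
    """Partition samples into a high-signature cluster versus the rest.

    Requires at least 2 signature probes present in the matrix; probes
    missing from the platform are dropped with a log message.
    """
    present = [p for p in signature.probes if p in expr.values.index]
    missing = len(signature.probes) - len(present)
    if missing:
        logger.info("assign_clusters: %d signature probes missing, dropped", missing)
    if len(present) < 2:
        raise ValidationError("fewer than 2 signature probes present in matrix")
    sub = expr.values.loc[present].to_numpy(float)
    sd = sub.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValidationError("signature expression constant across samples")
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd_safe[:, None]

    dist = pdist(z.T, metric="correlation")
    if not np.all(np.isfinite(dist)):
        logger.warning("assign_clusters: degenerate sample profiles; distance set to 1")
        dist = np.nan_to_num(dist, nan=1.0)
    link = hierarchy.linkage(dist, method="average")
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    if len(set(cut)) < 2:
        raise ValidationError("tree cut produced a single cluster")

    dirs = np.array([signature.directions[p] for p in present], float)
    signed = dirs @ z / len(present)   # per-sample mean of direction * z
    mean1 = signed[cut == 1].mean()
    mean2 = signed[cut == 2].mean()
    high_label = 1 if mean1 > mean2 else 2
    groups = pd.Series(
        np.where(cut == high_label, "high", "other"),
        index=pd.Index(expr.sample_ids, name="sample_id"),
        name="group",
    )
    n_high = int((groups == "high").sum())
    if min(n_high, len(groups) - n_high) == 1:
        logger.warning("assign_clusters: singleton cluster")
    order = hierarchy.leaves_list(link)
    return ClusterAssignment(
        groups=groups,
        fraction_high=n_high / len(groups),
        linkage_method="average",
        distance="one_minus_pearson",
        dendrogram_order=[expr.sample_ids[i] for i in order],
    )


def association_odds_ratio(group_a, group_b) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for two binary indicators.

    The OR uses the Haldane 0.5 correction whenever a 2x2 cell is zero; the
    Fisher p is computed on the uncorrected table.
    """
    a = np.asarray(group_a, int)
    b = np.asarray(group_b, int)
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    if not (set(np.unique(a)) <= {0, 1} and set(np.unique(b)) <= {0, 1}):
        raise ValidationError("vectors must be binary")
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    table = np.array([[n11, n10], [n01, n00]], float)
    if (table == 0).any():
        table = table + 0.5
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return float(odds), float(p)
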