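"""Driver-quartile stratification and Q4-vs-Q1 differential expression.

Samples are sorted by the expression of a single driver probe (WT1 in the
motivating application); the top and bottom quartiles are contrasted
probe-by-probe with a two-sided Welch t-test, and the set of probes that
survive Benjamini-Hochberg FDR control forms the "high-driver" gene set.
A concordance report compares two such sets from independent series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import ExpressionMatrix, ValidationError

logger = logging.getLogger("wt1sig")


@dataclass
class QuartileSplit:
    """Quartile labels from sorting samples by driver expression.

    Q1 holds the ``floor(n/4)`` lowest-driver samples, Q4 the highest; the
    middle quartiles absorb any remainder. Ties in driver expression are
    broken by sample-ID lexicographic order, so the split is deterministic.
    """

    driver_probe_id: str
    labels: pd.Series            # sample_id -> quartile in {1,2,3,4}
    q1: list[str]
    q4: list[str]


def split_quartiles(expr: ExpressionMatrix, driver_probe: str) -> QuartileSplit:
    n = len(expr.sample_ids)
    if n < 8:
        raise ValidationError(f"need at least 8 samples for quartiles, got {n}")
    driver = expr.probe(driver_probe)  # raises if absent
    order = sorted(range(n), key=lambda i: (driver[i], expr.sample_ids[i]))
    if len(np.unique(driver)) < n:
        logger.warning(
            "split_quartiles: ties in driver expression broken by sample ID"
        )
    q = n // 4
    samples = expr.sample_ids
    sorted_ids = [samples[i] for i in order]
    q1 = sorted_ids[:q]
    q4 = sorted_ids[-q:]
    labels = pd.Series(0, index=pd.Index(samples, name="sample_id"), dtype=int)
    bounds = [q, n // 2, n - q, n]
    lo = 0
    for quartile, hi in enumerate(bounds, start=1):
        labels[sorted_ids[lo:hi]] = quartile
        lo = hi
    return QuartileSplit(driver_probe, labels, q1, q4)


def welch_t(x, y) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test on two samples.

    The degenerate case of zero variance in both groups with equal means is
    defined as (t=0, p=1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_t needs at least 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def high_driver_set(
    expr: ExpressionMatrix,
    split: QuartileSplit,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-probe Q4-vs-Q1 differential-expression table.

    Returns a DataFrame indexed by probe with columns ``mean_q4, mean_q1,
    delta_log2, fold, t, p, q, significant, direction``; significant rows
    form the high-driver gene set.  ``fold`` is ``2**delta_log2`` since the
    inputs are log2-scale.
    """
    vals = expr.values
    m4 = vals[split.q4].to_numpy(float)
    m1 = vals[split.q1].to_numpy(float)
    n4, n1 = m4.shape[1], m1.shape[1]
    mean4, mean1 = m4.mean(axis=1), m1.mean(axis=1)
    var4 = m4.var(axis=1, ddof=1)
    var1 = m1.var(axis=1, ddof=1)

    # vectorised Welch test; both-constant equal-mean probes get t=0, p=1
    se2 = var4 / n4 + var1 / n1
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean4 - mean1) / np.sqrt(se2)
        df = se2**2 / (
            (var4 / n4) ** 2 / (n4 - 1) + (var1 / n1) ** 2 / (n1 - 1)
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t[degenerate & (mean4 == mean1)] = 0.0
    p[degenerate & (mean4 == mean1)] = 1.0
    if np.any(degenerate & (mean4 != mean1)):
        # zero within-group variance but different means: infinitely significant
        t[degenerate & (mean4 != mean1)] = np.sign(
            (mean4 - mean1)[degenerate & (mean4 != mean1)]
        ) * np.inf
        p[degenerate & (mean4 != mean1)] = 0.0

    q = bh_fdr(p)
    delta = mean4 - mean1
    table = pd.DataFrame(
        {
            "mean_q4": mean4,
            "mean_q1": mean1,
            "delta_log2": delta,
            "fold": 2.0**delta,
            "t": t,
            "p": p,
            "q": q,
            "significant": q < fdr_threshold,
            "direction": np.where(delta > 0, "up", "down"),
        },
        index=vals.index.rename("probe"),
    )
    return table


@dataclass
class ConcordanceReport:
    """Agreement between two high-driver sets from independent series."""

    overlap_fraction: float     # |sigA ∩ sigB| / |sigA|
    sign_agreement: float       # same-direction fraction over the intersection
    slope: float
    intercept: float
    r_squared: float
    n_shared: int
    regression_defined: bool


def concordance(set_a: pd.DataFrame, set_b: pd.DataFrame) -> ConcordanceReport:
    """Compare two DE tables sharing a probe universe.

    Overlap is measured on the significant sets; sign agreement and the
    linear regression of delta_B on delta_A are computed over the shared
    significant probes.
    """
    sig_a = set_a.index[set_a["significant"]]
    sig_b = set_b.index[set_b["significant"]]
    shared = sig_a.intersection(sig_b)
    overlap = len(shared) / len(sig_a) if len(sig_a) else 0.0
    if len(shared) == 0:
        return ConcordanceReport(overlap, np.nan, np.nan, np.nan, np.nan, 0, False)
    da = set_a.loc[shared, "delta_log2"].to_numpy()
    db = set_b.loc[shared, "delta_log2"].to_numpy()
    agree = float(np.mean(np.sign(da) == np.sign(db)))
    if len(shared) < 2 or np.allclose(da, da[0]):
        return ConcordanceReport(overlap, agree, np.nan, np.nan, np.nan, len(shared), False)
    res = stats.linregress(da, db)
    return ConcordanceReport(
        overlap_fraction=overlap,
        sign_agreement=agree,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_shared=int(len(shared)),
        regression_defined=True,
    )
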