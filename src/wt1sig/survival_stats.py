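"""Survival analysis layer: Kaplan-Meier, log-rank, Cox, PPV/NPV.

Thin, validated wrappers around lifelines that return plain containers
mirroring the tables a clinical expression study reports: product-limit
curves with median survival (Brookmeyer-Crowley CI) and fixed-horizon
survival, the Mantel-Cox log-rank statistic, Cox proportional-hazards
fits with the univariate-screen-then-multivariate rule (candidates with
p < 0.1 enter the joint model), and predictive values of a binary marker.
Times are in months throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .ingest import ValidationError

logger = logging.getLogger("wt1sig")


@dataclass
class KmFit:
    """Product-limit estimate with median and horizon summaries."""

    times: np.ndarray              # event/censor time grid of the step function
    survival: np.ndarray           # S(t) at those times
    median: float                  # NaN when the curve never reaches 0.5
    median_ci: tuple[float, float]
    _kmf: KaplanMeierFitter = None

    def survival_at(self, horizon: float) -> tuple[float, float, float]:
        """S(horizon) with its (log-log Greenwood) confidence band."""
        est = float(self._kmf.predict(horizon))
        ci = self._kmf.confidence_interval_survival_function_
        idx = ci.index[ci.index <= horizon]
        if len(idx) == 0:
            return est, 0.0, 1.0
        lo, hi = ci.loc[idx[-1]]
        return est, float(lo), float(hi)


def km_fit(time, event) -> KmFit:
    """Kaplan-Meier estimate of a single group's survival."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(time) == 0:
        raise ValidationError("km_fit needs at least one subject")
    if np.any(time < 0):
        raise ValidationError("times must be non-negative")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(time, event)
    median = kmf.median_survival_time_
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    if not np.isfinite(median):
        logger.warning("km_fit: median survival not reached")
        median = np.nan
    sf = kmf.survival_function_
    return KmFit(
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        median=float(median),
        median_ci=(lo, hi),
        _kmf=kmf,
    )


def logrank(groups, time, event) -> tuple[float, float]:
    """Mantel-Cox log-rank test across >= 2 nonempty groups.

    Returns (chi-square statistic, two-sided p); 1 degree of freedom in the
    two-group case.
    """
    groups = np.asarray(groups)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("log-rank needs at least 2 nonempty groups")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs, plus the model log-likelihood."""

    table: pd.DataFrame            # index covariate; columns hr, ci_lower, ci_upper, p
    log_likelihood: float


def cox_fit(covariates: pd.DataFrame, time, event) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling, lifelines backend)."""
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(covariates) != len(time):
        raise ValidationError("covariates and endpoints differ in length")
    for col in covariates.columns:
        if covariates[col].nunique() <= 1:
            raise ValidationError(f"constant covariate {col!r}")
    corr = covariates.corr().abs()
    np.fill_diagonal(corr.to_numpy(), 0.0)
    if (corr > 0.9999).any().any():
        pair = corr.stack().idxmax()
        raise ValidationError(f"collinear covariates {pair[0]!r} and {pair[1]!r}")
    if int(event.sum()) < covariates.shape[1]:
        raise ValidationError("fewer events than covariates")
    df = covariates.copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except (ConvergenceError, ValueError) as exc:
        raise ValidationError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    table.index.name = "covariate"
    return CoxResult(table=table, log_likelihood=float(cph.log_likelihood_))


def expand_eln(clin_df: pd.DataFrame, column: str = "ELN") -> pd.DataFrame:
    """Expand an ELN genetic-group column (levels 1-4) into indicator contrasts.

    Produces ELN2/ELN3/ELN4 columns contrasted against group 1.
    """
    if column not in clin_df.columns:
        raise ValidationError(f"no column {column!r}")
    out = clin_df.drop(columns=[column]).copy()
    for level in (2, 3, 4):
        out[f"{column}{level}"] = (clin_df[column] == level).astype(int)
    return out


def screen_then_multivariate(
    candidates: pd.DataFrame, time, event, alpha_in: float = 0.1
) -> tuple[pd.DataFrame, CoxResult | None]:
    """Univariate Cox screen, then one joint model on the survivors.

    Every candidate is fit alone; those with univariate p < ``alpha_in``
    enter a single multivariate model.  Returns the screening table
    (covariate, hr, ci, p, selected) and the joint CoxResult (None, with a
    log message, when nothing passes).
    """
    if candidates.shape[1] == 0:
        raise ValidationError("need at least one candidate covariate")
    rows = []
    for col in candidates.columns:
        try:
            uni = cox_fit(candidates[[col]], time, event)
            rec = uni.table.loc[col].to_dict()
        except ValidationError as exc:
            logger.warning("univariate Cox failed for %s: %s", col, exc)
            rec = {"hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan}
        rec["covariate"] = col
        rows.append(rec)
    screen = pd.DataFrame(rows).set_index("covariate")
    screen["selected"] = screen["p"] < alpha_in
    chosen = screen.index[screen["selected"]].tolist()
    if not chosen:
        logger.warning("no candidate passed the univariate screen")
        return screen, None
    joint = cox_fit(candidates[chosen], time, event)
    return screen, joint


def ppv_npv(marker, adverse) -> tuple[float, float]:
    """Predictive values of a binary marker for a binary adverse outcome.

    PPV = P(adverse | marker+), NPV = P(not adverse | marker-).  An empty
    marker arm yields NaN for the corresponding value, with a log message.
    """
    marker = np.asarray(marker, int)
    adverse = np.asarray(adverse, int)
    if marker.shape != adverse.shape:
        raise ValidationError("marker and outcome must have equal length")
    if not (set(np.unique(marker)) <= {0, 1} and set(np.unique(adverse)) <= {0, 1}):
        raise ValidationError("marker and outcome must be binary")
    n_pos = int(marker.sum())
    n_neg = len(marker) - n_pos
    if n_pos == 0:
        logger.warning("ppv undefined: no marker-positive samples")
        ppv = np.nan
    else:
        ppv = float(adverse[marker == 1].mean())
    if n_neg == 0:
        logger.warning("npv undefined: no marker-negative samples")
        npv = np.nan
    else:
        npv = float(1.0 - adverse[marker == 0].mean())
    return ppv, npv
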