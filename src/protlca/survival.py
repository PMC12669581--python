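"""Survival association of cluster membership and protein values.

Kaplan-Meier curves, multi-group log-rank tests, Cox proportional-hazards
models with administrative truncation of follow-up, and Harrell's
concordance index.  The model fitting is delegated to lifelines (Efron tie
handling); this module owns the truncation rule, the covariate construction
(cluster dummies against a declared reference cluster, optional per-SD
standardization of continuous covariates), and the tidy result containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index

__all__ = [
    "SurvivalResult",
    "truncate_followup",
    "truncate_outcome_table",
    "km_logrank",
    "cox_fit",
    "concordance",
]


@dataclass
class SurvivalResult:
    """Tidy summary of one endpoint's cluster-outcome association."""

    endpoint: str
    reference: int | str | None
    hazard_ratios: pd.DataFrame  # index: covariate; HR, ci_low, ci_high, p
    logrank_chi2: float | None
    logrank_df: int | None
    logrank_p: float | None
    c_statistic: float
    n: int
    n_events: int
    km: dict = field(default_factory=dict)  # group -> survival_function_ frame

    def to_frame(self) -> pd.DataFrame:
        df = self.hazard_ratios.copy()
        df.insert(0, "endpoint", self.endpoint)
        df["logrank_chi2"] = self.logrank_chi2
        df["logrank_p"] = self.logrank_p
        df["c_statistic"] = self.c_statistic
        df["n"] = self.n
        df["n_events"] = self.n_events
        return df


def truncate_followup(
    time: np.ndarray, event: np.ndarray, horizon: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Administratively censor follow-up at ``horizon``.

    Times beyond the horizon are set to the horizon with the event flag
    cleared; events exactly at the horizon are retained.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    over = time > horizon
    return np.where(over, horizon, time), np.where(over, 0, event)


def truncate_outcome_table(outcomes: pd.DataFrame, horizon: float = 3.0) -> pd.DataFrame:
    """Apply :func:`truncate_followup` to every time_/event_ column pair."""
    out = outcomes.copy()
    for col in outcomes.columns:
        if col.startswith("time_"):
            ep = col[len("time_"):]
            t, e = truncate_followup(outcomes[col], outcomes[f"event_{ep}"], horizon)
            out[col], out[f"event_{ep}"] = t, e
    return out


def km_logrank(
    time, event, groups
) -> tuple[dict, float, int, float]:
    """Kaplan-Meier estimates per group plus the unweighted log-rank test.

    Returns ``(km_curves, chi2, df, p)`` where ``km_curves`` maps each group
    label to its survival-function DataFrame.  Empty groups are dropped with
    a warning; at least two non-empty groups are required.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups) if np.sum(groups == g) > 0]
    if len(labels) < len(pd.unique(groups)):
        warnings.warn("empty groups dropped from the log-rank comparison")
    if len(labels) < 2:
        raise ValueError("log-rank test requires at least two non-empty groups")
    curves = {}
    for g in sorted(labels):
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(g))
        curves[g] = kmf.survival_function_
    res = multivariate_logrank_test(time, groups, event)
    return curves, float(res.test_statistic), len(labels) - 1, float(res.p_value)


def _cluster_dummies(labels: np.ndarray, reference) -> pd.DataFrame:
    labels = np.asarray(labels)
    uniq = sorted(pd.unique(labels))
    if reference is None:
        reference = uniq[0]
    if reference not in uniq:
        raise ValueError(f"reference cluster {reference!r} not present in labels")
    cols = {}
    for g in uniq:
        if g == reference:
            continue
        cols[f"cluster_{g}"] = (labels == g).astype(float)
    return pd.DataFrame(cols)


def cox_fit(
    time,
    event,
    labels=None,
    covariates: pd.DataFrame | None = None,
    reference=None,
    standardize: bool = False,
    endpoint: str = "endpoint",
) -> SurvivalResult:
    """Cox proportional-hazards fit (Efron ties) for clusters and/or covariates.

    ``labels`` become indicator covariates against ``reference`` (default:
    first cluster in sorted order).  ``covariates`` are continuous or coded
    columns; with ``standardize=True`` they are z-scored so hazard ratios
    read per-SD-increase.  The c-statistic is Harrell's C of the fitted
    linear predictor.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("Cox model requires at least one event")
    parts = []
    if labels is not None:
        parts.append(_cluster_dummies(labels, reference).reset_index(drop=True))
        if reference is None:
            reference = sorted(pd.unique(np.asarray(labels)))[0]
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        if standardize:
            sds = cov.std(ddof=1)
            if (sds <= 0).any():
                raise ValueError(
                    f"constant covariates cannot be standardized: {list(sds.index[sds <= 0])}"
                )
            cov = (cov - cov.mean()) / sds
        parts.append(cov)
    if not parts:
        raise ValueError("provide labels and/or covariates")
    X = pd.concat(parts, axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    df = X.copy()
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as err:  # convergence failure / monotone likelihood
        raise RuntimeError(f"Cox fit failed for covariates {list(X.columns)}: {err}") from err
    summ = cph.summary
    hr = pd.DataFrame(
        {
            "HR": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "ci_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "p": summ["p"],
            "coef": summ["coef"],
            "se": summ["se(coef)"],
        }
    )
    lp = X.to_numpy() @ summ["coef"].to_numpy()
    cstat = concordance(time, event, lp)
    return SurvivalResult(
        endpoint=endpoint,
        reference=reference,
        hazard_ratios=hr,
        logrank_chi2=None,
        logrank_df=None,
        logrank_p=None,
        c_statistic=cstat,
        n=len(time),
        n_events=int(event.sum()),
    )


def concordance(time, event, risk) -> float:
    """Harrell's concordance of a risk score (higher risk -> earlier event).

    A pair is usable when the shorter observed time corresponds to an event;
    score ties count 1/2.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    if event.sum() == 0:
        raise ValueError("no usable pairs: no events observed")
    # lifelines scores concordance with higher prediction = longer survival
    return float(concordance_index(time, -risk, event))
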