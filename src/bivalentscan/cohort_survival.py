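"""Survival stratification of a tumor cohort by oncogenic-alteration context.

Patients are classified as RAS-driven (oncogenic alteration in KRAS, NRAS,
HRAS, RIT1 or NF1) or RAS-activated (the same list plus EGFR, ERBB2, MET,
BRAF and MAP2K1), optionally restricted to TP53 loss-of-function carriers,
then stratified at the upper quartile of target-gene expression and compared
with a Kaplan-Meier product-limit estimator and the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "RAS_DRIVER_GENES",
    "RAS_ACTIVATED_GENES",
    "CLASSIFICATION_GENES",
    "classify_ras",
    "stratify_upper_quartile",
    "SurvivalCurve",
    "km_curve",
    "LogrankResult",
    "logrank_test",
    "run_stratified_survival",
    "StratifiedSurvivalResult",
]

RAS_DRIVER_GENES = ("KRAS", "NRAS", "HRAS", "RIT1", "NF1")
RAS_ACTIVATED_GENES = RAS_DRIVER_GENES + ("EGFR", "ERBB2", "MET", "BRAF", "MAP2K1")
#: the ten RTK/RAS/BRAF-pathway genes plus TP53 (loss-of-function flag)
CLASSIFICATION_GENES = RAS_ACTIVATED_GENES + ("TP53_LOF",)


def classify_ras(flags) -> dict:
    """RAS-pathway context of one patient from per-gene alteration flags.

    ``flags`` is a mapping (or Series) gene -> bool covering the ten
    RTK/RAS/BRAF classification genes.  RAS-driven implies RAS-activated by
    list containment.
    """
    for gene in RAS_ACTIVATED_GENES:
        if gene not in flags:
            raise KeyError(f"missing alteration flag for gene {gene!r}")
    ras_driven = any(bool(flags[g]) for g in RAS_DRIVER_GENES)
    ras_activated = any(bool(flags[g]) for g in RAS_ACTIVATED_GENES)
    return {"ras_driven": ras_driven, "ras_activated": ras_activated}


def classify_ras_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_ras` over a cohort table."""
    missing = [g for g in RAS_ACTIVATED_GENES if g not in cohort.columns]
    if missing:
        raise KeyError(f"missing alteration flag column(s) {missing}")
    driven = cohort[list(RAS_DRIVER_GENES)].astype(bool).any(axis=1)
    activated = cohort[list(RAS_ACTIVATED_GENES)].astype(bool).any(axis=1)
    return pd.DataFrame({"ras_driven": driven, "ras_activated": activated}, index=cohort.index)


def stratify_upper_quartile(values) -> tuple[np.ndarray, float]:
    """Split samples at the 75th percentile (linear interpolation).

    Returns (labels, threshold) with labels 'high' for values >= Q3 (boundary
    ties go to 'high') and 'low' otherwise.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        raise ValueError("need at least 8 samples for quartile stratification")
    if np.ptp(values) == 0:
        raise ValueError("all expression values identical; cannot stratify")
    q3 = float(np.percentile(values, 75, method="linear"))
    labels = np.where(values >= q3, "high", "low")
    return labels, q3


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate."""

    event_times: np.ndarray      # distinct death times, ascending
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray          # risk-set size just before each event time
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def median(self) -> float:
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.event_times[below[0]]) if len(below) else float("inf")


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator; censored-only times shrink the risk set
    without producing steps."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    distinct = np.unique(times[events == 1])
    surv = []
    at_risk = []
    s = 1.0
    for t in distinct:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    return SurvivalCurve(
        event_times=distinct,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n=len(times),
        n_events=int(events.sum()),
    )


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    observed_a: float
    expected_a: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test (1 df).

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk sets; tied
    event times are handled natively by the hypergeometric variance.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    obs_a = 0.0
    exp_a = 0.0
    for t in event_times:
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        n = na + nb
        da = int(((ta == t) & (ea == 1)).sum())
        db = int(((tb == t) & (eb == 1)).sum())
        d = da + db
        if n < 2 or d == 0:
            continue
        e = d * na / n
        v = d * (na / n) * (nb / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += da - e
        var += v
        obs_a += da
        exp_a += e
    if var == 0:
        raise ValueError("zero variance in log-rank statistic")
    stat = o_minus_e**2 / var
    return LogrankResult(
        chi_square=float(stat),
        p_value=float(chi2.sf(stat, df=1)),
        observed_a=obs_a,
        expected_a=exp_a,
    )


@dataclass
class StratifiedSurvivalResult:
    context: str
    require_tp53_lof: bool
    n_high: int
    n_low: int
    expression_threshold: float
    curve_high: SurvivalCurve
    curve_low: SurvivalCurve
    logrank: LogrankResult


def run_stratified_survival(
    cohort: pd.DataFrame,
    context: str = "all",
    require_tp53_lof: bool = False,
    expression_col: str = "expression",
) -> StratifiedSurvivalResult:
    """Filter a cohort by oncogenic context, stratify by upper-quartile
    expression, and compare survival between the strata.

    ``context`` is one of ``all``, ``ras_driven``, ``ras_activated``; the
    quartile threshold is computed within the filtered subset.
    """
    if context not in ("all", "ras_driven", "ras_activated"):
        raise ValueError(f"unknown context {context!r}")
    sub = cohort
    if context != "all":
        ras = classify_ras_cohort(cohort)
        sub = cohort.loc[ras[context]]
    if require_tp53_lof:
        if "TP53_LOF" not in sub.columns:
            raise KeyError("cohort lacks TP53_LOF column")
        sub = sub.loc[sub["TP53_LOF"].astype(bool)]
    if len(sub) < 8:
        raise ValueError(
            f"context {context!r} (tp53_lof={require_tp53_lof}) leaves only "
            f"{len(sub)} patients; need at least 8"
        )
    labels, q3 = stratify_upper_quartile(sub[expression_col].to_numpy(float))
    high = sub.loc[labels == "high"]
    low = sub.loc[labels == "low"]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("empty expression stratum after filtering")
    curve_high = km_curve(high["time"], high["event"])
    curve_low = km_curve(low["time"], low["event"])
    lr = logrank_test(high["time"], high["event"], low["time"], low["event"])
    return StratifiedSurvivalResult(
        context=context,
        require_tp53_lof=require_tp53_lof,
        n_high=len(high),
        n_low=len(low),
        expression_threshold=q3,
        curve_high=curve_high,
        curve_low=curve_low,
        logrank=lr,
    )
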