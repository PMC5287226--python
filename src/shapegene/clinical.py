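"""Clinical association: ordered trend test, survival dichotomization,
Kaplan-Meier / log-rank, and Cox proportional hazards.

Survival analysis proper (KM curves, log-rank, Cox partial likelihood with
Efron ties) is delegated to lifelines; the Jonckheere-Terpstra trend test is
implemented here with tie-corrected normal approximation and an exact
permutation p at small n.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "jonckheere_terpstra",
    "dichotomize",
    "km_logrank",
    "cox_fit",
    "truncate_followup",
    "StratificationResult",
    "CoxResult",
    "CLINICAL_COLUMNS",
]

#: documented clinical column names of a cohort CSV; remaining columns are genes
CLINICAL_COLUMNS = (
    "patient_id", "time_months", "event", "grade", "subtype",
    "nodes_positive", "tumor_size_cm",
)


# ----------------------------------------------------------------------
# Jonckheere-Terpstra


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            diff = b[None, :] - a[:, None]
            jt += float((diff > 0).sum()) + 0.5 * float((diff == 0).sum())
    return jt


def _jt_null_moments(groups: list[np.ndarray]) -> tuple[float, float]:
    """Mean and tie-corrected variance of JT under the null."""
    sizes = np.array([len(g) for g in groups], dtype=float)
    n = sizes.sum()
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)

    mean = (n * n - (sizes ** 2).sum()) / 4.0
    a = (
        n * (n - 1) * (2 * n + 5)
        - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    b = (
        (sizes * (sizes - 1) * (sizes - 2)).sum()
        * (t * (t - 1) * (t - 2)).sum()
    ) / (36.0 * n * (n - 1) * (n - 2))
    c = (
        (sizes * (sizes - 1)).sum() * (t * (t - 1)).sum()
    ) / (8.0 * n * (n - 1))
    return mean, a + b + c


def _jt_exact_pvalue(groups: list[np.ndarray], observed: float) -> float:
    """Two-sided exact p by enumerating all group assignments of the pooled
    values (doubled one-tail, capped at 1)."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    idx = list(range(n))
    ge = le = total = 0

    def recurse(avail: list[int], gi: int, chosen: list[np.ndarray]):
        nonlocal ge, le, total
        if gi == len(sizes) - 1:
            stat = _jt_statistic(chosen + [pooled[avail]])
            total += 1
            if stat >= observed - 1e-9:
                ge += 1
            if stat <= observed + 1e-9:
                le += 1
            return
        for combo in itertools.combinations(avail, sizes[gi]):
            remaining = [i for i in avail if i not in set(combo)]
            recurse(remaining, gi + 1, chosen + [pooled[list(combo)]])

    recurse(idx, 0, [])
    return min(1.0, 2.0 * min(ge / total, le / total))


def jonckheere_terpstra(
    values: np.ndarray | pd.Series,
    group_labels: np.ndarray | pd.Series,
    order: list | None = None,
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Jonckheere-Terpstra trend test across ordered groups.

    Returns ``(statistic, two-sided p)``.  The statistic sums Mann-Whitney
    counts over ordered group pairs (ties count one half).  The p-value uses
    the tie-corrected normal approximation, or exhaustive permutation
    enumeration when the pooled sample size is at most ``exact_max_n``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if order is None:
        order = sorted(pd.unique(labels).tolist())
    groups = [values[labels == g] for g in order]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty ordered groups")

    jt = _jt_statistic(groups)
    n = sum(len(g) for g in groups)
    if n <= exact_max_n:
        return jt, _jt_exact_pvalue(groups, jt)
    mean, var = _jt_null_moments(groups)
    if var <= 0:
        return jt, 1.0
    # continuity correction toward the mean (JT is integer/half-integer valued)
    z = (abs(jt - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return jt, float(min(1.0, 2.0 * stats.norm.sf(z)))


# ----------------------------------------------------------------------
# survival helpers


def truncate_followup(
    time: pd.Series, event: pd.Series, horizon: float = 120.0
) -> tuple[pd.Series, pd.Series]:
    """Administrative censoring at a follow-up horizon (months)."""
    over = time > horizon
    return time.where(~over, horizon), event.where(~over, 0).astype(int)


def _logrank(time: pd.Series, event: pd.Series, mask: pd.Series) -> tuple[float, float]:
    """Two-group log-rank statistic and p for a boolean split."""
    res = logrank_test(
        time[mask], time[~mask],
        event_observed_A=event[mask], event_observed_B=event[~mask],
    )
    return float(res.test_statistic), float(res.p_value)


def km_logrank(
    time: pd.Series,
    event: pd.Series,
    labels: pd.Series,
) -> tuple[pd.DataFrame, float, float]:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    ``labels`` must take exactly two values.  Returns a tidy curve frame
    (group, time, survival, at_risk), the log-rank chi-square statistic, and
    its p-value.
    """
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError("labels must define exactly 2 non-empty groups")
    curves = []
    for g in uniq:
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(g))
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
        curves.append(pd.DataFrame({
            "group": str(g),
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }))
    res = logrank_test(
        time[labels == uniq[0]], time[labels == uniq[1]],
        event_observed_A=event[labels == uniq[0]],
        event_observed_B=event[labels == uniq[1]],
    )
    return pd.concat(curves, ignore_index=True), float(res.test_statistic), float(res.p_value)


@dataclass
class StratificationResult:
    """Outcome of quantile-grid dichotomization of one metagene."""

    metagene: str
    quantile: float
    cutoff: float
    group_sizes: dict[str, int]
    statistic: float
    p: float
    curves: pd.DataFrame
    validation_p: float | None = None
    validation_statistic: float | None = None
    per_quantile: pd.DataFrame | None = None


def dichotomize(
    scores: pd.Series,
    time: pd.Series,
    event: pd.Series,
    config: PipelineConfig,
    name: str = "metagene",
    validation: tuple[pd.Series, pd.Series, pd.Series] | None = None,
) -> StratificationResult:
    """Choose the quantile split best separating discovery survival.

    Each candidate quantile in ``config.cut_quantiles`` splits patients into
    low (score <= cutoff) / high groups; the quantile with the smallest
    discovery log-rank p wins, ties resolved toward 0.5.  Splits leaving a
    group with zero events are skipped.  The chosen cutoff *value* is then
    applied to the validation cohort when given.
    """
    if int(event.sum()) < 10:
        raise ValueError("discovery cohort must have at least 10 events")
    rows = []
    for q in config.cut_quantiles:
        cutoff = float(scores.quantile(q))
        high = scores > cutoff
        if high.all() or (~high).all():
            logger.info("%s: quantile %.2f gives a degenerate split; skipped", name, q)
            continue
        if event[high].sum() == 0 or event[~high].sum() == 0:
            logger.info("%s: quantile %.2f leaves a group with 0 events; skipped", name, q)
            continue
        stat, p = _logrank(time, event, high)
        rows.append({"quantile": q, "cutoff": cutoff, "statistic": stat, "p": p})
    if not rows:
        raise ValueError(f"{name}: every candidate split is degenerate")
    table = pd.DataFrame(rows)
    best = min(rows, key=lambda r: (r["p"], abs(r["quantile"] - 0.5)))

    high = scores > best["cutoff"]
    labels = high.map({True: "high", False: "low"})
    curves, stat, p = km_logrank(time, event, labels)
    result = StratificationResult(
        metagene=name,
        quantile=float(best["quantile"]),
        cutoff=float(best["cutoff"]),
        group_sizes={"low": int((~high).sum()), "high": int(high.sum())},
        statistic=stat,
        p=p,
        curves=curves,
        per_quantile=table,
    )
    if validation is not None:
        v_scores, v_time, v_event = validation
        v_high = v_scores > best["cutoff"]
        if v_high.all() or (~v_high).all():
            logger.warning("%s: validation split degenerate at cutoff %.4f",
                           name, best["cutoff"])
        else:
            v_stat, v_p = _logrank(v_time, v_event, v_high)
            result.validation_p = v_p
            result.validation_statistic = v_stat
    return result


# ----------------------------------------------------------------------
# Cox models


@dataclass
class CoxResult:
    """Univariate and multivariate Cox fits for one metagene."""

    metagene: str
    univariate: pd.DataFrame     # covariate x [coef, hazard_ratio, wald_z, p]
    multivariate: pd.DataFrame
    coding: dict[str, str] = field(default_factory=dict)


def _summarize(fitter: CoxPHFitter) -> pd.DataFrame:
    s = fitter.summary
    return pd.DataFrame({
        "coef": s["coef"],
        "hazard_ratio": s["exp(coef)"],
        "wald_z": s["z"],
        "p": s["p"],
    })


def code_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Binary codings: node = 1 if any positive node; size = 1 if > 2 cm."""
    return pd.DataFrame({
        "node": (cohort["nodes_positive"] >= 1).astype(int),
        "size": (cohort["tumor_size_cm"] > 2.0).astype(int),
        "grade": cohort["grade"].astype(float),
    }, index=cohort.index)


def cox_fit(
    cohort: pd.DataFrame,
    scores: pd.Series,
    name: str = "metagene",
) -> CoxResult:
    """Univariate (metagene alone) and multivariate (+ size, grade, node)
    Cox proportional-hazards fits with Efron tie handling and Wald tests.

    ``cohort`` must carry ``time_months``, ``event``, ``grade``,
    ``nodes_positive`` and ``tumor_size_cm`` columns aligned with ``scores``.
    """
    if int(cohort["event"].sum()) < 10:
        raise ValueError("need at least 10 events for a Cox fit")
    covs = code_covariates(cohort)
    base = pd.DataFrame({
        "time": cohort["time_months"].astype(float),
        "event": cohort["event"].astype(int),
        name: scores.astype(float),
    })

    def fit(df: pd.DataFrame) -> pd.DataFrame:
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # lifelines raises ConvergenceError/Warning
            raise RuntimeError(f"Cox fit failed for {name}: {exc}") from exc
        return _summarize(cph)

    uni = fit(base)
    multi = fit(base.join(covs))
    return CoxResult(
        metagene=name,
        univariate=uni,
        multivariate=multi,
        coding={"node": ">=1 positive node -> 1",
                "size": ">2 cm -> 1",
                "grade": "ordinal 1-3"},
    )
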