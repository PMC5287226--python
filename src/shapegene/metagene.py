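"""Metagene regression: forward sequential feature selection and scoring.

A metagene is an ordinary-least-squares model predicting a per-line response
(a morphological statistic, or the TNF response of nuclear RELA
translocation) from a small ordered subset of gene expression profiles,
selected greedily by residual sum of squares.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "MetageneModel",
    "forward_select_fit",
    "random_metagene",
    "score_cohort",
    "rela_response",
]


@dataclass
class MetageneModel:
    """Fitted metagene: intercept + ordered per-gene coefficients."""

    response: str
    intercept: float
    coefficients: dict[str, float]            # insertion order = selection order
    trace: list[dict] = field(default_factory=list)  # per step: gene, rss, r2
    candidates: list[str] = field(default_factory=list)
    r_squared: float = float("nan")

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "response": self.response,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "trace": self.trace,
            "candidates": self.candidates,
            "r_squared": self.r_squared,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MetageneModel":
        d = json.loads(Path(path).read_text())
        return cls(response=d["response"], intercept=d["intercept"],
                   coefficients=d["coefficients"], trace=d["trace"],
                   candidates=d.get("candidates", []),
                   r_squared=d.get("r_squared", float("nan")))


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept; returns (coefs incl. intercept, rss)."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - design @ beta
    return beta, float(resid @ resid)


def forward_select_fit(
    response: pd.Series,
    candidates: pd.DataFrame,
    config: PipelineConfig,
    response_name: str | None = None,
) -> MetageneModel:
    """Greedy forward selection of an OLS metagene.

    At each step the candidate minimizing the residual sum of squares is
    added (ties broken by input column order).  Selection continues while
    fewer than ``min_genes`` are chosen, or while R-squared is below
    ``r2_stop`` and fewer than ``max_genes`` are chosen.  Candidates whose
    addition makes the design rank-deficient are dropped with a log message.
    Coefficients are refit jointly at the end (identical to the last greedy
    fit).
    """
    if candidates.shape[1] < 2:
        raise ValueError("need at least 2 candidate genes")
    samples = list(response.index)
    if list(candidates.index) != samples:
        candidates = candidates.loc[samples]
    y = response.to_numpy(dtype=float)
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("response has zero variance")

    selected: list[str] = []
    remaining = list(candidates.columns)
    dropped: list[str] = []
    trace: list[dict] = []
    r2 = 0.0
    beta = np.array([y.mean()])

    while remaining:
        if len(selected) >= config.max_genes:
            break
        if len(selected) >= config.min_genes and r2 >= config.r2_stop:
            break
        best = None  # (rss, order index, gene, beta)
        for pos, gene in enumerate(remaining):
            X = candidates[selected + [gene]].to_numpy(dtype=float)
            try:
                b, rss = _ols(X, y)
            except np.linalg.LinAlgError:
                continue
            if best is None or rss < best[0] - 1e-12:
                best = (rss, pos, gene, b)
        if best is None:
            # every remaining candidate is collinear with the selection
            for gene in remaining:
                logger.info("dropping rank-deficient candidate %s", gene)
            dropped.extend(remaining)
            break
        rss, _, gene, beta = best
        selected.append(gene)
        remaining.remove(gene)
        r2 = 1.0 - rss / tss
        trace.append({"gene": gene, "rss": rss, "r2": r2})

    if len(selected) < config.min_genes:
        raise ValueError(
            f"only {len(selected)} fittable genes; min_genes={config.min_genes}"
        )
    if n < len(selected) + 2:
        warnings.warn(
            f"{n} samples for {len(selected)} selected genes; fit is fragile",
            stacklevel=2,
        )
    coefs = {g: float(b) for g, b in zip(selected, beta[1:])}
    return MetageneModel(
        response=response_name or str(response.name or "response"),
        intercept=float(beta[0]),
        coefficients=coefs,
        trace=trace,
        candidates=list(candidates.columns),
        r_squared=r2,
    )


def random_metagene(
    expression: pd.DataFrame,
    config: PipelineConfig,
    seed: int,
    pool_size: int = 20,
) -> MetageneModel:
    """Control model: standard-normal response over the samples, fitted on
    ``pool_size`` genes drawn uniformly without replacement."""
    if expression.shape[1] < pool_size:
        raise ValueError(f"need at least {pool_size} genes")
    rng = np.random.default_rng(seed)
    response = pd.Series(rng.standard_normal(len(expression.index)),
                         index=expression.index, name="random")
    pool = list(rng.choice(expression.columns, size=pool_size, replace=False))
    return forward_select_fit(response, expression[pool], config, "random")


def score_cohort(model: MetageneModel, cohort_expr: pd.DataFrame) -> pd.Series:
    """Score patients: intercept + sum of coef * per-gene z expression.

    Cohort expression (patients x genes) is standardized per gene across
    patients; model genes absent from the cohort contribute 0 (logged);
    no model gene present is an error.  Constant genes get z = 0.
    """
    present = [g for g in model.genes if g in cohort_expr.columns]
    missing = [g for g in model.genes if g not in cohort_expr.columns]
    if not present:
        raise ValueError("no model gene present in cohort expression")
    if missing:
        logger.warning("cohort missing model genes (scored as 0): %s", missing)
    sub = cohort_expr[present].astype(float)
    sd = sub.std(axis=0, ddof=1).replace(0.0, np.nan)
    z = sub.sub(sub.mean(axis=0), axis=1).div(sd, axis=1).fillna(0.0)
    scores = model.intercept + sum(model.coefficients[g] * z[g] for g in present)
    scores.name = model.response
    return scores


def rela_response(measurements: pd.DataFrame) -> pd.Series:
    """TNF response of nuclear RELA translocation per line.

    ``measurements`` has one row per line with columns ``ratio_plus_tnf``
    and ``ratio_minus_tnf`` (mean nuclear/cytoplasmic intensity ratios).
    Returns the natural log of the ratio of means.
    """
    required = {"ratio_plus_tnf", "ratio_minus_tnf"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    out = {}
    for line, row in measurements.iterrows():
        plus, minus = float(row["ratio_plus_tnf"]), float(row["ratio_minus_tnf"])
        if plus <= 0 or minus <= 0:
            raise ValueError(f"non-positive RELA ratio for line {line!r}")
        out[line] = math.log(plus / minus)
    return pd.Series(out, name="rela_tnf_response")
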