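"""Per-line morphology summaries and the shape-gene correlation screen.

Single-cell feature tables are aggregated to per-cell-line means and sample
standard deviations ("feature statistics"); gene expression is then screened
for Spearman correlation against every statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "summarize_features",
    "filter_variable_genes",
    "correlate_shape",
    "spearman_rho",
    "spearman_pvalue",
    "statistic_name",
]

#: column holding the cell-line label in a single-cell table
LINE_COLUMN = "cell_line"


def statistic_name(feature: str, stat: str) -> str:
    """Canonical name of a feature statistic, e.g. ``cell_area|mean``."""
    if stat not in ("mean", "sd"):
        raise ValueError(f"unknown statistic {stat!r}")
    return f"{feature}|{stat}"


# ----------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionMatrix:
    """Probe-level expression with a probe-to-gene map.

    ``values`` is probes x samples; ``probe_genes`` maps each probe id to
    exactly one gene symbol.
    """

    values: pd.DataFrame
    probe_genes: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        missing = self.values.index.difference(self.probe_genes.index)
        if len(missing):
            raise ValueError(f"probes without gene mapping: {list(missing[:5])}")
        self.probe_genes = self.probe_genes.loc[self.values.index]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def collapse_probes(self) -> pd.DataFrame:
        """Average multi-probe genes into one profile per gene.

        Returns a genes x samples frame; gene order follows first probe
        occurrence.
        """
        gene_order = list(dict.fromkeys(self.probe_genes.tolist()))
        collapsed = self.values.groupby(self.probe_genes, sort=False).mean()
        return collapsed.loc[gene_order]

    # -- plain-text round trip (first column probe id, second gene symbol)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene", self.probe_genes.values)
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "gene" not in df.columns:
            raise ValueError(f"{path}: expected a 'gene' column after the probe id")
        genes = df["gene"].astype(str)
        values = df.drop(columns="gene").astype(float)
        return cls(values=values, probe_genes=genes)


# ----------------------------------------------------------------------
# feature summaries


def summarize_features(cells: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a single-cell table to per-line feature statistics.

    The derived elongation feature ``cell_wl`` (width/length) is computed per
    cell before aggregation when both dimensions are present.  Returns a
    lines x statistics frame whose columns are ``feature|mean`` and
    ``feature|sd`` (sample SD, n-1 denominator).
    """
    if LINE_COLUMN not in cells.columns:
        raise ValueError(f"single-cell table must have a {LINE_COLUMN!r} column")
    feats = cells.drop(columns=[LINE_COLUMN]).astype(float)
    if feats.isna().any().any():
        raise ValueError("single-cell table contains missing feature values")
    if {"cell_width", "cell_length"} <= set(feats.columns) and "cell_wl" not in feats:
        feats = feats.assign(cell_wl=feats["cell_width"] / feats["cell_length"])

    counts = cells.groupby(LINE_COLUMN).size()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"cell line {small.index[0]!r} has fewer than 2 cells")

    grouped = feats.groupby(cells[LINE_COLUMN].values)
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    out = {}
    for feature in feats.columns:
        out[statistic_name(feature, "mean")] = means[feature]
        out[statistic_name(feature, "sd")] = sds[feature]
    summary = pd.DataFrame(out)
    summary.index.name = LINE_COLUMN
    return summary


# ----------------------------------------------------------------------
# variability filter


def filter_variable_genes(expr: ExpressionMatrix, sd_cutoff: float) -> list[str]:
    """Genes whose collapsed cross-sample SD exceeds ``sd_cutoff``.

    Multi-probe genes are collapsed (probe average) before the SD is taken.
    Order follows the input probe order.
    """
    collapsed = expr.collapse_probes()
    if collapsed.shape[1] < 3:
        raise ValueError("need at least 3 samples to assess variability")
    sds = collapsed.std(axis=1, ddof=1)
    return [g for g in collapsed.index if sds[g] > sd_cutoff]


# ----------------------------------------------------------------------
# Spearman screen


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation with average-rank tie handling."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan")
    return float(rx @ ry) / denom


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the t approximation.

    t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom.  |rho| = 1
    maps to the smallest positive float.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if abs(rho) >= 1:
        return float(np.nextafter(0.0, 1.0))
    t = abs(rho) * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(t, n - 2))


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam)) if len(p) else 1.0
    pi0 = max(pi0, 1.0 / max(len(p), 1))
    return np.minimum(_bh_qvalues(p) * pi0, 1.0)


def correlate_shape(
    expr: ExpressionMatrix,
    summary: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every gene x feature-statistic pair for Spearman correlation.

    Returns ``(records, significant)``: all tested pairs with rho, two-sided
    p (t approximation) and FDR q; and the subset with |rho| above
    ``config.rho_cutoff``.  Expression samples and summary lines must be the
    same set.  Zero-variance statistics yield rho = NaN records that are
    excluded from testing.
    """
    if set(expr.samples) != set(summary.index):
        raise ValueError("expression samples and summary cell lines differ")
    n = len(summary.index)
    if n < 4:
        raise ValueError("need at least 4 shared samples")

    genes = filter_variable_genes(expr, config.sd_cutoff)
    collapsed = expr.collapse_probes().loc[genes, list(summary.index)]

    rows = []
    for stat in summary.columns:
        y = summary[stat].to_numpy(dtype=float)
        if np.std(y) == 0:
            logger.warning("statistic %s has zero variance; excluded from testing", stat)
            for gene in genes:
                rows.append((gene, stat, np.nan, np.nan))
            continue
        ry = stats.rankdata(y, method="average")
        ry_c = ry - ry.mean()
        ry_norm = math.sqrt(float(ry_c @ ry_c))
        X = collapsed.to_numpy(dtype=float)
        rx = np.apply_along_axis(stats.rankdata, 1, X)
        rx_c = rx - rx.mean(axis=1, keepdims=True)
        rx_norm = np.sqrt((rx_c * rx_c).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rhos = (rx_c @ ry_c) / (rx_norm * ry_norm)
        for gene, rho in zip(genes, rhos):
            if not np.isfinite(rho):
                rows.append((gene, stat, np.nan, np.nan))
            else:
                rows.append((gene, stat, float(rho), spearman_pvalue(float(rho), n)))

    records = pd.DataFrame(rows, columns=["gene", "statistic", "rho", "p"])
    tested = records["p"].notna()
    q = np.full(len(records), np.nan)
    if tested.any():
        pvals = records.loc[tested, "p"].to_numpy()
        qfun = _storey_qvalues if config.fdr_method == "storey" else _bh_qvalues
        q[tested.to_numpy()] = qfun(pvals)
    records["q"] = q

    significant = records[tested & (records["rho"].abs() > config.rho_cutoff)]
    return records, significant.reset_index(drop=True)
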