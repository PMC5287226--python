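"""Regulator/effector classification from a gene-knockdown expression panel.

A raw panel (measured genes x perturbations, z-score-like values) is
consolidated to one column per targeted gene, re-z-scored, and each
(gene, TF) pair is classified under three scenarios: regulator of TF
expression, regulator of TF activation (activator/inhibitor via sign
concordance with the TF's own knockdown signature), and TF effector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "RawKnockdownPanel",
    "KnockdownPanel",
    "TFTargetSet",
    "RegulationCall",
    "preprocess_panel",
    "define_targets",
    "classify",
    "call_direction",
    "infer_edge_directions",
    "hypergeom_upper_tail",
]


@dataclass
class RawKnockdownPanel:
    """Unconsolidated panel: possibly several perturbation columns per gene."""

    values: pd.DataFrame          # measured genes x perturbation ids
    pert_targets: pd.Series       # perturbation id -> targeted gene

    def __post_init__(self) -> None:
        missing = self.values.columns.difference(self.pert_targets.index)
        if len(missing):
            raise ValueError(f"perturbations without target mapping: {list(missing[:5])}")

    def to_tsv(self, panel_path: str | Path, map_path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(panel_path, sep="\t")
        m = self.pert_targets.rename("target_gene")
        m.index.name = "perturbation"
        m.to_csv(map_path, sep="\t")

    @classmethod
    def from_tsv(cls, panel_path: str | Path, map_path: str | Path) -> "RawKnockdownPanel":
        values = pd.read_csv(panel_path, sep="\t", index_col=0)
        mapping = pd.read_csv(map_path, sep="\t", index_col=0)["target_gene"].astype(str)
        return cls(values=values.astype(float), pert_targets=mapping)


@dataclass
class KnockdownPanel:
    """Consolidated panel: one z-scored column per validly targeted gene."""

    z: pd.DataFrame               # measured genes x targeted genes
    dropped: dict[str, str] = field(default_factory=dict)  # pert id -> reason

    @property
    def measured_genes(self) -> list[str]:
        return list(self.z.index)

    @property
    def knocked_genes(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class TFTargetSet:
    """Genes significantly changed by a TF knockdown, with change signs."""

    tf: str
    signs: dict[str, int]         # target gene -> +1 / -1

    @property
    def size(self) -> int:
        return len(self.signs)


@dataclass
class RegulationCall:
    """One classified gene-TF relationship."""

    gene: str
    tf: str
    mode: str                     # expression_regulator | activation_regulator | tf_effector
    direction: str                # activator | inhibitor | up | down | ambiguous
    k: int = 0                    # overlap with TF targets
    n: int = 0                    # size of the gene-KD changed set
    K: int = 0                    # TF target count (within the universe)
    N: int = 0                    # universe size
    p: float = float("nan")       # hypergeometric upper-tail p
    concordance: float = float("nan")


# ----------------------------------------------------------------------
# preprocessing


def preprocess_panel(raw: RawKnockdownPanel, config: PipelineConfig) -> KnockdownPanel:
    """Validate, consolidate and re-z-score a raw knockdown panel.

    A perturbation is valid only if its targeted gene is measured and its
    value in that column is strictly below ``config.kd_valid_z``.  Valid
    columns for the same gene are averaged; the consolidated matrix is then
    z-scored per measured gene across all remaining knockdowns (sample SD).
    """
    dropped: dict[str, str] = {}
    by_gene: dict[str, list[str]] = {}
    for pert in raw.values.columns:
        target = raw.pert_targets[pert]
        if target not in raw.values.index:
            dropped[pert] = "target not measured"
            continue
        z_target = float(raw.values.at[target, pert])
        if z_target >= config.kd_valid_z:
            dropped[pert] = f"target z {z_target:.3f} >= {config.kd_valid_z}"
            continue
        by_gene.setdefault(target, []).append(pert)

    if dropped:
        logger.info("dropped %d invalid perturbations", len(dropped))
    if not by_gene:
        raise ValueError("no valid perturbations in panel")

    cols = {gene: raw.values[perts].mean(axis=1) for gene, perts in by_gene.items()}
    consolidated = pd.DataFrame(cols)

    mu = consolidated.mean(axis=1)
    sd = consolidated.std(axis=1, ddof=1)
    sd = sd.replace(0.0, np.nan)
    z = consolidated.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return KnockdownPanel(z=z, dropped=dropped)


# ----------------------------------------------------------------------
# target definition and classification


def define_targets(panel: KnockdownPanel, tf: str, config: PipelineConfig) -> TFTargetSet:
    """Genes (excluding the TF itself) with |z| strictly above ``target_z``
    in the TF's knockdown column, with their change signs."""
    if tf not in panel.z.columns:
        raise ValueError(f"TF {tf!r} has no valid consolidated knockdown column")
    col = panel.z[tf]
    signs = {
        gene: int(math.copysign(1, col[gene]))
        for gene in panel.z.index
        if gene != tf and abs(col[gene]) > config.target_z
    }
    return TFTargetSet(tf=tf, signs=signs)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def _changed_set(panel: KnockdownPanel, column: str, target_z: float) -> set[str]:
    col = panel.z[column]
    return {g for g in panel.z.index if abs(col[g]) > target_z}


def call_direction(
    gene: str,
    tf: str,
    panel: KnockdownPanel,
    targetset: TFTargetSet,
    config: PipelineConfig,
) -> tuple[str, float]:
    """Activator/inhibitor call by sign concordance over overlapping targets.

    The overlap is the set of TF targets whose expression the gene knockdown
    changes (|z| > target_z).  Concordance is the fraction of that overlap
    whose change sign matches the sign under TF knockdown; > 0.5 activator,
    < 0.5 inhibitor, exactly 0.5 ambiguous.  Zero overlap is an error — the
    caller must only reach this after an activation call exists.
    """
    col = panel.z[gene]
    changed = _changed_set(panel, gene, config.target_z) - {tf, gene}
    overlap = sorted(t for t in targetset.signs if t in changed)
    if not overlap:
        raise ValueError(f"no overlapping changed targets for {gene!r} vs {tf!r}")
    agree = sum(
        1 for t in overlap
        if int(math.copysign(1, col[t])) == targetset.signs[t]
    )
    concordance = agree / len(overlap)
    if concordance > 0.5:
        return "activator", concordance
    if concordance < 0.5:
        return "inhibitor", concordance
    return "ambiguous", concordance


def classify(
    gene: str,
    tf: str,
    panel: KnockdownPanel,
    targetset: TFTargetSet,
    config: PipelineConfig,
) -> list[RegulationCall]:
    """Classify one gene-TF pair; zero or more calls.

    (a) expression_regulator: the gene's knockdown changes the TF itself
        (|z| > target_z); direction is the change sign.
    (b) activation_regulator: the gene knockdown's changed set overlaps the
        TF target set by k >= ceil(coverage_frac * K) targets and the
        upper-tail hypergeometric p is below hyper_alpha; direction by sign
        concordance.  The universe excludes the TF and the knocked-down gene.
    (c) tf_effector: the TF's knockdown changes the gene; direction up/down.
    """
    calls: list[RegulationCall] = []
    if gene not in panel.z.columns or tf not in panel.z.columns:
        logger.info("skipping %s-%s: missing consolidated column", gene, tf)
        return calls
    tz = config.target_z

    # (a) regulator of TF expression
    z_tf_in_gene_kd = float(panel.z.at[tf, gene]) if tf in panel.z.index else 0.0
    if abs(z_tf_in_gene_kd) > tz:
        calls.append(RegulationCall(
            gene=gene, tf=tf, mode="expression_regulator",
            direction="up" if z_tf_in_gene_kd > 0 else "down",
        ))

    # (b) regulator of TF activation
    universe = [g for g in panel.z.index if g not in (tf, gene)]
    N = len(universe)
    targets_u = {t for t in targetset.signs if t in set(universe)}
    changed = _changed_set(panel, gene, tz) - {tf, gene}
    K = len(targets_u)
    n = len(changed)
    k = len(changed & targets_u)
    if K > 0 and k >= max(1, math.ceil(config.coverage_frac * K)):
        p = hypergeom_upper_tail(k, N, K, n)
        if p < config.hyper_alpha:
            direction, concordance = call_direction(gene, tf, panel, targetset, config)
            calls.append(RegulationCall(
                gene=gene, tf=tf, mode="activation_regulator", direction=direction,
                k=k, n=n, K=K, N=N, p=p, concordance=concordance,
            ))

    # (c) TF effector
    z_gene_in_tf_kd = float(panel.z.at[gene, tf]) if gene in panel.z.index else 0.0
    if abs(z_gene_in_tf_kd) > tz:
        calls.append(RegulationCall(
            gene=gene, tf=tf, mode="tf_effector",
            direction="up" if z_gene_in_tf_kd > 0 else "down",
        ))
    return calls


# ----------------------------------------------------------------------
# edge directionality


def infer_edge_directions(
    subnet: nx.Graph,
    panel: KnockdownPanel,
    config: PipelineConfig,
) -> list[tuple[str, str]]:
    """Directed annotations for interaction edges: A->B when knocking down A
    significantly changes B.  Both directions may hold.  Returns the list of
    directed pairs and sets a ``directions`` attribute on each edge."""
    directed: list[tuple[str, str]] = []
    for a, b, data in subnet.edges(data=True):
        if data.get("edge_type") == "correlation":
            continue
        dirs = []
        for src, dst in ((a, b), (b, a)):
            if src in panel.z.columns and dst in panel.z.index:
                if abs(float(panel.z.at[dst, src])) > config.target_z:
                    dirs.append((src, dst))
        data["directions"] = ";".join(f"{s}->{t}" for s, t in dirs)
        directed.extend(dirs)
    return directed


# ----------------------------------------------------------------------
# serialization


def calls_to_frame(calls: list[RegulationCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls], columns=[
        "gene", "tf", "mode", "direction", "k", "n", "K", "N", "p", "concordance",
    ])
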