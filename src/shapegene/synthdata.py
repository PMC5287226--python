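"""Synthetic inputs with planted ground truth.

Emulates the five input kinds the pipeline consumes — single-cell feature
table, expression matrix, interaction edge table, knockdown panel and
patient cohorts — with a :class:`PlantedTruth` record that makes every
downstream answer recoverable: shape-correlated genes, TF regulons,
regulators of TF expression/activation, a linear metagene, and a metagene
to hazard/grade association.

All draws come from a single seeded generator, so identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .morphology import ExpressionMatrix, LINE_COLUMN, statistic_name
from .rnai import RawKnockdownPanel

__all__ = [
    "PlantedTruth",
    "PatientCohort",
    "SyntheticStudy",
    "make_truth",
    "simulate_cell_table",
    "simulate_expression",
    "simulate_edges",
    "simulate_knockdown_panel",
    "simulate_cohort",
    "generate_study",
    "write_study",
]

#: raw per-cell features: name -> (population mean, between-line SD, within-line SD)
RAW_FEATURES: dict[str, tuple[float, float, float]] = {
    "cell_width": (40.0, 6.0, 8.0),
    "cell_length": (60.0, 8.0, 10.0),
    "cell_area": (2000.0, 350.0, 400.0),
    "nucleus_width": (15.0, 2.0, 3.0),
    "nucleus_length": (20.0, 2.5, 4.0),
    "nucleus_area": (250.0, 45.0, 60.0),
    "nc_area": (0.15, 0.03, 0.04),
    "centers_distance": (5.0, 1.0, 1.5),
    "neighbor_fraction": (0.4, 0.1, 0.12),
    "protrusion_area": (120.0, 30.0, 40.0),
    "ruffliness": (0.25, 0.05, 0.07),
}

#: feature statistics that carry planted shape-correlated genes
DEFAULT_PLANTED_STATS = (
    "cell_area|mean", "cell_wl|mean", "neighbor_fraction|sd",
    "protrusion_area|mean", "cell_area|sd",
)

_FLOAT_FMT = "%.10g"


class TruthValidationError(ValueError):
    """Raised when a planted truth is internally inconsistent."""


# ----------------------------------------------------------------------
# planted truth


@dataclass
class PlantedTruth:
    """Everything planted into the synthetic inputs.

    ``shape_genes`` maps a feature statistic to (gene, direction, effect)
    triples; ``regulons`` maps a TF to target signs; ``regulators`` maps
    (gene, TF) to (mode, direction) with mode in {"expression",
    "activation"}; ``metagene_beta`` maps a response name to
    (coefficients, intercept, noise SD).
    """

    shape_genes: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)
    regulons: dict[str, dict[str, int]] = field(default_factory=dict)
    regulators: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    metagene_beta: dict[str, tuple[dict[str, float], float, float]] = field(default_factory=dict)
    hazard_beta: float = 0.7
    cut_quantile: float = 0.6
    latent_means: pd.DataFrame | None = None   # lines x features
    latent_sds: pd.DataFrame | None = None

    def validate(self) -> None:
        for (gene, tf), (mode, direction) in self.regulators.items():
            if tf not in self.regulons:
                raise TruthValidationError(
                    f"regulator ({gene}, {tf}) references TF absent from regulons")
            if mode not in ("expression", "activation"):
                raise TruthValidationError(f"unknown regulator mode {mode!r}")
            expected = {"expression": ("up", "down"),
                        "activation": ("activator", "inhibitor")}[mode]
            if direction not in expected:
                raise TruthValidationError(
                    f"direction {direction!r} invalid for mode {mode!r}")
        if not 0 < self.cut_quantile < 1:
            raise TruthValidationError("cut_quantile must lie in (0, 1)")

    def planted_genes(self) -> set[str]:
        genes: set[str] = set()
        for triples in self.shape_genes.values():
            genes.update(g for g, _, _ in triples)
        for tf, targets in self.regulons.items():
            genes.add(tf)
            genes.update(targets)
        for gene, tf in self.regulators:
            genes.update((gene, tf))
        for coefs, _, _ in self.metagene_beta.values():
            genes.update(coefs)
        return genes

    # -- JSON round trip

    def to_json(self, path: str | Path) -> None:
        payload = {
            "shape_genes": {
                stat: [[g, d, e] for g, d, e in triples]
                for stat, triples in self.shape_genes.items()
            },
            "regulons": self.regulons,
            "regulators": [
                [gene, tf, mode, direction]
                for (gene, tf), (mode, direction) in self.regulators.items()
            ],
            "metagene_beta": {
                name: {"coefficients": coefs, "intercept": b0, "noise_sd": sd}
                for name, (coefs, b0, sd) in self.metagene_beta.items()
            },
            "hazard_beta": self.hazard_beta,
            "cut_quantile": self.cut_quantile,
            "latent_means": None if self.latent_means is None
            else self.latent_means.to_dict(orient="index"),
            "latent_sds": None if self.latent_sds is None
            else self.latent_sds.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        truth = cls(
            shape_genes={
                stat: [(g, int(dr), float(e)) for g, dr, e in triples]
                for stat, triples in d["shape_genes"].items()
            },
            regulons={tf: {g: int(s) for g, s in t.items()}
                      for tf, t in d["regulons"].items()},
            regulators={(g, tf): (m, dr) for g, tf, m, dr in d["regulators"]},
            metagene_beta={
                name: (rec["coefficients"], rec["intercept"], rec["noise_sd"])
                for name, rec in d["metagene_beta"].items()
            },
            hazard_beta=d["hazard_beta"],
            cut_quantile=d["cut_quantile"],
        )
        if d.get("latent_means") is not None:
            truth.latent_means = pd.DataFrame.from_dict(d["latent_means"], orient="index")
        if d.get("latent_sds") is not None:
            truth.latent_sds = pd.DataFrame.from_dict(d["latent_sds"], orient="index")
        return truth


def make_truth(
    config: PipelineConfig,
    planted_stats: tuple[str, ...] = DEFAULT_PLANTED_STATS,
    genes_per_stat: int = 4,
    regulon_size: int = 12,
    hazard_beta: float = 0.7,
    cut_quantile: float = 0.6,
) -> PlantedTruth:
    """Deterministic planted structure (no randomness needed).

    Shape genes SGxxx alternate correlation direction per statistic; SMAD3
    and RELA regulons contain dedicated target genes plus two shape genes
    (planted TF effectors); selected shape genes act as regulators of TF
    activation (activator + inhibitor) and of TF expression.  The cohort's
    latent score is a linear combination of the genes planted on the last
    statistic, with coefficient signs matching their correlation
    directions so a metagene fitted on cell lines transfers to the cohort.
    """
    truth = PlantedTruth(hazard_beta=hazard_beta, cut_quantile=cut_quantile)
    idx = 0
    for stat in planted_stats:
        triples = []
        for j in range(genes_per_stat):
            gene = f"SG{idx:03d}"
            direction = 1 if j % 2 == 0 else -1
            triples.append((gene, direction, 1.0))
            idx += 1
        truth.shape_genes[stat] = triples

    shape_gene_ids = [g for t in truth.shape_genes.values() for g, _, _ in t]
    for tf, effector in (("SMAD3", shape_gene_ids[2]), ("RELA", shape_gene_ids[7])):
        targets = {f"TG_{tf}_{j:02d}": (1 if j % 2 == 0 else -1)
                   for j in range(regulon_size - 1)}
        targets[effector] = 1
        truth.regulons[tf] = targets

    truth.regulators = {
        (shape_gene_ids[0], "SMAD3"): ("activation", "activator"),
        (shape_gene_ids[1], "SMAD3"): ("activation", "inhibitor"),
        (shape_gene_ids[4], "SMAD3"): ("expression", "up"),
        (shape_gene_ids[5], "RELA"): ("activation", "activator"),
        (shape_gene_ids[6], "RELA"): ("activation", "inhibitor"),
        (shape_gene_ids[8], "RELA"): ("expression", "down"),
    }

    metagene_stat = planted_stats[-1]
    magnitudes = (0.30, 0.30, 0.25, 0.25)
    truth.metagene_beta[metagene_stat] = (
        {
            gene: direction * mag
            for (gene, direction, _), mag in zip(
                truth.shape_genes[metagene_stat], magnitudes)
        },
        1.21,
        0.0,
    )
    truth.validate()
    return truth


# ----------------------------------------------------------------------
# single-cell table


def simulate_cell_table(
    config: PipelineConfig,
    n_lines: int,
    n_cells_per_line: int,
    noise_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Single-cell feature table with recorded latent per-line parameters.

    Per-line latent means are Gaussian over lines around each feature's
    population mean; cells are Gaussian around their line mean with a
    line-specific SD scaled by ``noise_scale`` (0 gives zero within-line
    spread).  Returns ``(cells, latent_means, latent_sds)``.
    """
    if n_lines < 2 or n_cells_per_line < 2:
        raise ValueError("need n_lines >= 2 and n_cells_per_line >= 2")
    rng = rng or np.random.default_rng(config.seed)
    lines = [f"BCL{i + 1:02d}" for i in range(n_lines)]
    features = list(RAW_FEATURES)

    means = {}
    sds = {}
    for feat, (mu, between, within) in RAW_FEATURES.items():
        m = mu + between * rng.standard_normal(n_lines)
        m = np.maximum(m, 0.05 * mu)  # keep strictly positive geometry
        s = np.abs(within * (1.0 + 0.3 * rng.standard_normal(n_lines))) * noise_scale
        means[feat] = m
        sds[feat] = s
    latent_means = pd.DataFrame(means, index=lines)
    latent_sds = pd.DataFrame(sds, index=lines)

    blocks = []
    for i, line in enumerate(lines):
        cells = {
            feat: latent_means.at[line, feat]
            + latent_sds.at[line, feat] * rng.standard_normal(n_cells_per_line)
            for feat in features
        }
        block = pd.DataFrame(cells)
        # features are physical quantities; keep them positive
        for feat, (mu, _, _) in RAW_FEATURES.items():
            block[feat] = block[feat].clip(lower=0.01 * mu)
        block.insert(0, LINE_COLUMN, line)
        blocks.append(block)
    table = pd.concat(blocks, ignore_index=True)
    return table, latent_means, latent_sds


# ----------------------------------------------------------------------
# expression matrix


def simulate_expression(
    config: PipelineConfig,
    truth: PlantedTruth,
    summary: pd.DataFrame,
    n_genes: int,
    effect_noise: float = 0.25,
    low_sd_frac: float = 0.3,
    multiprobe_frac: float = 0.1,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Expression matrix over the summary's cell lines.

    Planted shape genes follow a monotone (linear) transform of their
    feature statistic plus Gaussian noise of SD ``effect_noise`` (0 gives
    Spearman rho of exactly +/-1).  All other planted identifiers (TF list,
    regulon targets, metagene genes) and background fillers are i.i.d.
    Gaussian per line; ``low_sd_frac`` of the background fillers receive a
    cross-line SD below ``config.sd_cutoff`` to exercise the variability
    filter; ``multiprobe_frac`` of genes are emitted twice as distinct
    probes.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    truth.validate()
    lines = list(summary.index)
    n_lines = len(lines)
    if n_lines < 3:
        raise ValueError("summary must cover at least 3 lines")

    profiles: dict[str, np.ndarray] = {}
    for stat, triples in truth.shape_genes.items():
        if stat not in summary.columns:
            raise ValueError(f"planted statistic {stat!r} absent from summary")
        y = summary[stat].to_numpy(dtype=float)
        z = (y - y.mean()) / (y.std(ddof=1) or 1.0)
        for gene, direction, effect in triples:
            profiles[gene] = (
                8.0 + direction * effect * z
                + effect_noise * rng.standard_normal(n_lines)
            )

    other_planted = sorted(
        (truth.planted_genes() | set(config.tf_list)) - set(profiles)
    )
    for gene in other_planted:
        mu = rng.normal(8.0, 1.5)
        profiles[gene] = mu + rng.uniform(0.5, 1.5) * rng.standard_normal(n_lines)

    n_background = n_genes - len(profiles)
    if n_background < 0:
        raise ValueError(
            f"n_genes={n_genes} smaller than {len(profiles)} planted genes")
    n_low = int(round(low_sd_frac * n_background))
    for i in range(n_background):
        gene = f"BG{i:04d}"
        mu = rng.normal(8.0, 1.5)
        sd = rng.uniform(0.02, 0.25) if i < n_low else rng.uniform(0.5, 1.5)
        profiles[gene] = mu + sd * rng.standard_normal(n_lines)

    genes = list(profiles)
    n_multi = int(round(multiprobe_frac * len(genes)))
    multi = set(genes[-n_multi:]) if n_multi else set()

    probe_rows = {}
    probe_genes = {}
    for gene in genes:
        probe_rows[gene] = profiles[gene]
        probe_genes[gene] = gene
        if gene in multi:
            pid = f"{gene}_p2"
            probe_rows[pid] = profiles[gene] + 0.05 * rng.standard_normal(n_lines)
            probe_genes[pid] = gene
    values = pd.DataFrame(probe_rows, index=lines).T
    return ExpressionMatrix(values=values, probe_genes=pd.Series(probe_genes))


# ----------------------------------------------------------------------
# interaction edge table


def simulate_edges(
    config: PipelineConfig,
    truth: PlantedTruth,
    n_background_edges: int = 40,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """STRING-dialect edge table (integer 0-1000 scores).

    Every planted regulator gets an edge to its TF above the score floor, so
    feature-to-TF paths through regulators exist; background gene-gene edges
    (some deliberately below the floor) and a few reversed duplicate rows
    exercise filtering and deduplication.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    rows = []

    def channels():
        return {
            "neighborhood": int(rng.integers(0, 400)),
            "coexpression": int(rng.integers(0, 700)),
            "experiments": int(rng.integers(0, 900)),
        }

    for (gene, tf) in truth.regulators:
        rows.append({"protein1": gene, "protein2": tf,
                     **channels(),
                     "combined_score": int(rng.integers(
                         int(config.string_min_score * 1000) + 50, 951))})

    shape_gene_ids = [g for t in truth.shape_genes.values() for g, _, _ in t]
    pool = shape_gene_ids + [g for t in truth.regulons.values() for g in t]
    pool = list(dict.fromkeys(pool))
    for _ in range(n_background_edges):
        a, b = rng.choice(pool, size=2, replace=False)
        rows.append({"protein1": str(a), "protein2": str(b),
                     **channels(),
                     "combined_score": int(rng.integers(150, 951))})

    # reversed duplicates of the first two regulator edges, lower score
    for row in rows[:2]:
        dup = dict(row)
        dup["protein1"], dup["protein2"] = row["protein2"], row["protein1"]
        dup["combined_score"] = max(1, row["combined_score"] - 100)
        rows.append(dup)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# knockdown panel


def simulate_knockdown_panel(
    config: PipelineConfig,
    truth: PlantedTruth,
    n_measured: int = 80,
    n_perturbations: int | None = None,
    coverage: float = 0.6,
    effect: float = 3.0,
    noise_sd: float = 0.1,
    invalid_genes: tuple[str, ...] = (),
    duplicate_genes: tuple[str, ...] = (),
    rng: np.random.Generator | None = None,
) -> RawKnockdownPanel:
    """Raw knockdown panel with planted knockdown effects.

    Each perturbation drives its targeted gene to about -2 (or to -0.2 for
    ``invalid_genes``, which downstream validation must drop).  A TF column
    shifts its regulon by the planted signs; an activation-regulator column
    shifts a ``coverage`` fraction of the TF's targets concordantly
    (activator) or discordantly (inhibitor); an expression-regulator column
    shifts the TF's own row.  ``duplicate_genes`` get two probe columns.
    """
    truth.validate()
    rng = rng or np.random.default_rng(config.seed + 3)

    tfs = list(truth.regulons)
    targets = [g for t in truth.regulons.values() for g in t]
    regulator_genes = [g for g, _ in truth.regulators]
    shape_gene_ids = [g for t in truth.shape_genes.values() for g, _, _ in t]
    measured = list(dict.fromkeys(tfs + targets + regulator_genes + shape_gene_ids))
    if n_measured < len(measured):
        raise ValueError(f"n_measured={n_measured} < {len(measured)} planted genes")
    measured += [f"KB{i:03d}" for i in range(n_measured - len(measured))]

    perturbed = list(dict.fromkeys(tfs + regulator_genes + shape_gene_ids))
    if n_perturbations is not None:
        if n_perturbations < len(perturbed):
            raise ValueError(
                f"n_perturbations={n_perturbations} < {len(perturbed)} required")
        extra = [g for g in measured if g not in set(perturbed)]
        perturbed += extra[: n_perturbations - len(perturbed)]

    cols: dict[str, np.ndarray] = {}
    pert_targets: dict[str, str] = {}
    mi = {g: i for i, g in enumerate(measured)}

    def build_column(gene: str) -> np.ndarray:
        col = noise_sd * rng.standard_normal(len(measured))
        col[mi[gene]] = (-0.2 if gene in invalid_genes else -2.0) \
            + 0.1 * noise_sd * rng.standard_normal()
        if gene in truth.regulons:
            for target, sign in truth.regulons[gene].items():
                if target != gene:
                    col[mi[target]] += sign * effect
        for (reg, tf), (mode, direction) in truth.regulators.items():
            if reg != gene:
                continue
            if mode == "expression":
                col[mi[tf]] += effect if direction == "up" else -effect
            else:
                items = sorted(truth.regulons[tf].items())
                k = max(1, math.ceil(coverage * len(items)))
                chosen = [items[i] for i in
                          rng.choice(len(items), size=k, replace=False)]
                flip = 1 if direction == "activator" else -1
                for target, sign in chosen:
                    if target != gene:
                        col[mi[target]] += flip * sign * effect
        return col

    for gene in perturbed:
        reps = 2 if gene in duplicate_genes else 1
        for r in range(1, reps + 1):
            pid = f"sh{gene}_{r}"
            cols[pid] = build_column(gene)
            pert_targets[pid] = gene

    values = pd.DataFrame(cols, index=measured)
    return RawKnockdownPanel(values=values, pert_targets=pd.Series(pert_targets))


# ----------------------------------------------------------------------
# patient cohorts


@dataclass
class PatientCohort:
    """Clinical table plus per-patient gene expression."""

    clinical: pd.DataFrame        # patient_id, time_months, event, grade, ...
    expression: pd.DataFrame      # patients x genes (index = patient_id)
    latent: pd.Series | None = None

    def to_csv(self, path: str | Path) -> None:
        out = self.clinical.set_index("patient_id").join(self.expression)
        out.to_csv(path, float_format=_FLOAT_FMT)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PatientCohort":
        from .clinical import CLINICAL_COLUMNS

        df = pd.read_csv(path)
        clin_cols = [c for c in CLINICAL_COLUMNS if c in df.columns]
        clinical = df[clin_cols].copy()
        gene_cols = [c for c in df.columns if c not in clin_cols]
        expression = df.set_index("patient_id")[gene_cols].astype(float)
        return cls(clinical=clinical, expression=expression)


def simulate_cohort(
    config: PipelineConfig,
    truth: PlantedTruth,
    n_patients: int,
    grade_noise: float = 0.5,
    censor_rate: float = 0.004,
    censor_frac: float | None = None,
    base_rate: float = 1.0 / 80.0,
    hazard_mode: str = "linear",
    step_beta: float = 1.5,
    n_background_genes: int = 30,
    gene_universe: list[str] | None = None,
    id_prefix: str = "P",
    rng: np.random.Generator | None = None,
) -> PatientCohort:
    """Patient cohort with a planted metagene-to-outcome association.

    The latent score is the planted linear combination of the metagene
    genes' (standard-normal) expression.  Grade is a noisy tertile
    discretization of the latent; survival is exponential with log-hazard
    ``hazard_beta * latent`` (``hazard_mode="linear"``) or ``step_beta``
    applied above the planted ``cut_quantile`` (``hazard_mode="step"``);
    censoring is an independent exponential (``censor_frac=1.0`` censors
    everyone).  Node status and tumor size correlate mildly with grade.
    """
    if n_patients < 20:
        raise ValueError("need n_patients >= 20")
    if hazard_mode not in ("linear", "step"):
        raise ValueError(f"unknown hazard_mode {hazard_mode!r}")
    rng = rng or np.random.default_rng(config.seed + 4)
    truth.validate()

    coefs, intercept, noise_sd = next(iter(truth.metagene_beta.values()))
    shape_gene_ids = [g for t in truth.shape_genes.values() for g, _, _ in t]
    genes = list(dict.fromkeys(
        list(coefs) + shape_gene_ids + list(gene_universe or [])
    )) + [f"CG{i:03d}" for i in range(n_background_genes)]
    ids = [f"{id_prefix}{i:04d}" for i in range(n_patients)]
    X = pd.DataFrame(rng.standard_normal((n_patients, len(genes))),
                     index=ids, columns=genes)
    latent = intercept + sum(coefs[g] * X[g] for g in coefs)
    if noise_sd > 0:
        latent = latent + noise_sd * rng.standard_normal(n_patients)
    latent_std = (latent - latent.mean()) / latent.std(ddof=1)

    graded = latent_std + grade_noise * rng.standard_normal(n_patients)
    cuts = graded.quantile([1 / 3, 2 / 3])
    grade = np.where(graded <= cuts.iloc[0], 1,
                     np.where(graded <= cuts.iloc[1], 2, 3))

    if hazard_mode == "linear":
        log_hr = truth.hazard_beta * latent_std
    else:
        threshold = latent_std.quantile(truth.cut_quantile)
        log_hr = step_beta * (latent_std > threshold).astype(float)
    rate = base_rate * np.exp(log_hr)
    t_event = rng.exponential(1.0 / rate)
    if censor_frac is not None and censor_frac >= 1.0:
        time = t_event
        event = np.zeros(n_patients, dtype=int)
    else:
        c = rng.exponential(1.0 / censor_rate, size=n_patients)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    time = np.maximum(time, 1e-3)

    nodes = rng.binomial(3, 0.12 + 0.14 * (grade - 1))
    size = np.clip(rng.normal(1.4 + 0.4 * grade, 0.5), 0.2, None)
    subtype_flip = rng.random(n_patients) < 0.1
    subtype = np.where((latent_std > 0) ^ subtype_flip, "basal", "luminal")

    clinical = pd.DataFrame({
        "patient_id": ids,
        "time_months": time,
        "event": event,
        "grade": grade,
        "subtype": subtype,
        "nodes_positive": nodes,
        "tumor_size_cm": size,
    })
    return PatientCohort(clinical=clinical, expression=X,
                         latent=pd.Series(latent_std.to_numpy(), index=ids, name="latent"))


# ----------------------------------------------------------------------
# whole-study orchestration


@dataclass
class SyntheticStudy:
    """All synthetic inputs plus their planted truth."""

    config: PipelineConfig
    truth: PlantedTruth
    cells: pd.DataFrame
    summary: pd.DataFrame
    expression: ExpressionMatrix
    edges: pd.DataFrame
    panel: RawKnockdownPanel
    discovery: PatientCohort
    validation: PatientCohort


def generate_study(
    config: PipelineConfig,
    n_lines: int = 18,
    n_cells_per_line: int = 60,
    n_genes: int = 300,
    n_measured: int = 80,
    n_patients: int = 400,
    hazard_mode: str = "linear",
    genes_per_stat: int = 4,
) -> SyntheticStudy:
    """Generate every input kind from one seed, with consistent truth."""
    from .morphology import summarize_features

    rng = np.random.default_rng(config.seed)
    truth = make_truth(config, genes_per_stat=genes_per_stat)
    cells, latent_means, latent_sds = simulate_cell_table(
        config, n_lines, n_cells_per_line, rng=rng)
    truth.latent_means = latent_means
    truth.latent_sds = latent_sds
    summary = summarize_features(cells)
    expression = simulate_expression(config, truth, summary, n_genes, rng=rng)
    edges = simulate_edges(config, truth, rng=rng)
    # SG013 is a planted shape gene with no regulator role: its deliberately
    # invalid knockdown exercises the validity filter without hiding truth
    panel = simulate_knockdown_panel(
        config, truth, n_measured=n_measured,
        invalid_genes=("SG013",),
        duplicate_genes=("SMAD3",),
        rng=rng,
    )
    # cohorts cover the full gene universe so any fitted metagene is scorable
    universe = list(dict.fromkeys(expression.probe_genes))
    discovery = simulate_cohort(config, truth, n_patients,
                                hazard_mode=hazard_mode, id_prefix="D",
                                gene_universe=universe, rng=rng)
    validation = simulate_cohort(config, truth, n_patients,
                                 hazard_mode=hazard_mode, id_prefix="V",
                                 gene_universe=universe, rng=rng)
    return SyntheticStudy(config=config, truth=truth, cells=cells,
                          summary=summary, expression=expression, edges=edges,
                          panel=panel, discovery=discovery, validation=validation)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as delimited text plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": outdir / "cells.tsv",
        "summary": outdir / "feature_summary.tsv",
        "expression": outdir / "expression.tsv",
        "edges": outdir / "edges.tsv",
        "panel": outdir / "panel.tsv",
        "panel_map": outdir / "panel_map.tsv",
        "cohort_discovery": outdir / "cohort_discovery.csv",
        "cohort_validation": outdir / "cohort_validation.csv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    study.cells.to_csv(paths["cells"], sep="\t", index=False, float_format=_FLOAT_FMT)
    study.summary.to_csv(paths["summary"], sep="\t", float_format=_FLOAT_FMT)
    study.expression.to_tsv(paths["expression"])
    study.edges.to_csv(paths["edges"], sep="\t", index=False)
    study.panel.to_tsv(paths["panel"], paths["panel_map"])
    study.discovery.to_csv(paths["cohort_discovery"])
    study.validation.to_csv(paths["cohort_validation"])
    study.truth.to_json(paths["truth"])
    study.config.to_json(paths["config"])
    return paths
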