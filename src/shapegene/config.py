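"""Pipeline configuration: every numeric threshold lives here.

Stage code must read thresholds from a :class:`PipelineConfig` instance and
never hard-code them, so a single config file fully determines a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

__all__ = [
    "PipelineConfig",
    "ConfigParseError",
    "ConfigValidationError",
    "load_config",
    "write_config",
    "DEFAULT_TF_LIST",
]

#: Preselected transcription factors included as network nodes.
DEFAULT_TF_LIST = (
    "KLF4", "MYC", "RELA", "SOX2", "SMAD2", "SMAD3",
    "SNAI1", "SNAI2", "TWIST1", "ZEB1", "ZEB2", "YAP1",
)


class ConfigParseError(ValueError):
    """Raised when a config file cannot be parsed."""


class ConfigValidationError(ValueError):
    """Raised when a config value violates an invariant."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, serializable bundle of all pipeline thresholds.

    Attributes
    ----------
    sd_cutoff:
        Expression-SD floor across cell lines; genes with cross-line SD at
        or below this are dropped before the correlation screen.
    rho_cutoff:
        Absolute Spearman correlation threshold for calling a gene
        shape-correlated.
    string_min_score:
        Combined interaction-score floor (0-1 scale) for keeping an edge.
    kd_valid_z:
        A knockdown is valid only if it pushes the targeted gene's z-score
        strictly below this (negative) ceiling.
    target_z:
        Absolute z-score above which a gene counts as significantly changed.
    coverage_frac:
        Minimum fraction of a TF's targets a candidate regulator must
        perturb for an activation-regulator call.
    hyper_alpha:
        Significance level for the hypergeometric overlap test.
    dz_cutoff:
        Cluster-mean z difference above which a gene is differential.
    expr_floor:
        Raw-expression floor for retaining non-differential genes.
    r2_stop:
        Forward selection keeps adding genes while the model R-squared is
        below this bound (subject to the size bounds).
    min_genes, max_genes:
        Lower / upper bounds on metagene size.
    cut_quantiles:
        Ordered candidate quantiles for survival dichotomization.
    path_slack:
        Extra hops beyond the shortest path allowed for suboptimal paths.
    tf_list:
        Preselected TF identifiers.
    fdr_method:
        "bh" (Benjamini-Hochberg, default) or "storey" q-values.
    metagene_standardize:
        Whether metagene fits use per-gene z-scored expression.
    seed:
        Master random seed for synthetic data.
    """

    sd_cutoff: float = 0.3
    rho_cutoff: float = 0.7
    string_min_score: float = 0.4
    kd_valid_z: float = -0.4
    target_z: float = 1.5
    coverage_frac: float = 0.10
    hyper_alpha: float = 0.05
    dz_cutoff: float = 0.5
    expr_floor: float = 7.0
    r2_stop: float = 0.9
    min_genes: int = 4
    max_genes: int = 10
    cut_quantiles: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    path_slack: int = 1
    tf_list: tuple[str, ...] = DEFAULT_TF_LIST
    fdr_method: str = "bh"
    metagene_standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every invariant; raise :class:`ConfigValidationError`."""
        def bad(fieldname: str, msg: str) -> None:
            raise ConfigValidationError(f"{fieldname}: {msg}")

        if self.sd_cutoff < 0:
            bad("sd_cutoff", "must be >= 0")
        if not 0 < self.rho_cutoff < 1:
            bad("rho_cutoff", "must lie strictly between 0 and 1")
        if not 0 <= self.string_min_score <= 1:
            bad("string_min_score", "must lie in [0, 1]")
        if not self.kd_valid_z < 0:
            bad("kd_valid_z", "must be negative")
        if not self.target_z > 0:
            bad("target_z", "must be positive")
        if not 0 < self.coverage_frac < 1:
            bad("coverage_frac", "must lie strictly between 0 and 1")
        if not 0 < self.hyper_alpha < 1:
            bad("hyper_alpha", "must lie strictly between 0 and 1")
        if self.dz_cutoff < 0:
            bad("dz_cutoff", "must be >= 0")
        if not 0 < self.r2_stop <= 1:
            bad("r2_stop", "must lie in (0, 1]")
        if self.min_genes < 1:
            bad("min_genes", "must be >= 1")
        if self.min_genes > self.max_genes:
            bad("min_genes", "must be <= max_genes")
        qs = tuple(self.cut_quantiles)
        if len(qs) == 0:
            bad("cut_quantiles", "must be nonempty")
        if any(not 0 < q < 1 for q in qs):
            bad("cut_quantiles", "entries must lie strictly between 0 and 1")
        if any(b <= a for a, b in zip(qs, qs[1:])):
            bad("cut_quantiles", "must be strictly increasing")
        if self.path_slack < 0:
            bad("path_slack", "must be >= 0")
        if len(self.tf_list) == 0:
            bad("tf_list", "must be nonempty")
        if len(set(self.tf_list)) != len(self.tf_list):
            bad("tf_list", "entries must be unique")
        if self.fdr_method not in ("bh", "storey"):
            bad("fdr_method", "must be 'bh' or 'storey'")

    # ------------------------------------------------------------------
    # serialization

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cut_quantiles"] = list(self.cut_quantiles)
        d["tf_list"] = list(self.tf_list)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def _parse_value(key: str, raw: str, lineno: int):
    raw = raw.strip()
    try:
        if key in ("min_genes", "max_genes", "path_slack", "seed"):
            return int(raw)
        if key == "cut_quantiles":
            return tuple(float(x) for x in raw.split(",") if x.strip())
        if key == "tf_list":
            return tuple(x.strip() for x in raw.split(",") if x.strip())
        if key == "fdr_method":
            return raw
        if key == "metagene_standardize":
            low = raw.lower()
            if low in ("true", "1", "yes"):
                return True
            if low in ("false", "0", "no"):
                return False
            raise ValueError(f"not a boolean: {raw!r}")
        return float(raw)
    except ValueError as exc:
        raise ConfigParseError(f"line {lineno}: cannot parse {key}={raw!r}: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load a key=value plain-text config file.

    Absent keys take their defaults; unknown keys are rejected with the
    offending line number.  Blank lines and ``#`` comments are ignored.
    """
    overrides: dict = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigParseError(f"line {lineno}: expected key=value, got {line!r}")
        key, _, raw = stripped.partition("=")
        key = key.strip()
        if key not in _FIELD_TYPES:
            raise ConfigParseError(f"line {lineno}: unknown key {key!r}")
        overrides[key] = _parse_value(key, raw, lineno)
    return PipelineConfig(**overrides)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config as key=value text that :func:`load_config` round-trips."""
    lines = []
    for key, value in config.to_dict().items():
        if isinstance(value, (list, tuple)):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
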