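"""Analysis configuration: thresholds, endpoints, covariates and seeds.

Every tunable of the discovery pipeline lives here so that a single
:class:`Config` object (or its YAML/JSON serialisation) fully determines
the analysis.  Defaults follow the conventional settings for this kind of
staged screen: FDR 0.05 for the molecular-landscape stage, 0.1 for the
arm-specific screen, 0.2 for the interaction stage, a minimum group size
of 10 patients, 1000 treatment-label permutations and 500 bootstrap
resamples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

ENDPOINTS = ("OS", "PFS", "ORR")
SURVIVAL_ENDPOINTS = ("OS", "PFS")


@dataclass
class Config:
    """All adjustable thresholds and structural choices of the pipeline.

    Parameters
    ----------
    fdr_mol : float
        BH threshold for subtype enrichment/depletion calls.
    fdr_alpha : float
        BH threshold for the arm-specific biomarker screen.
    fdr_beta : float
        BH threshold for the treatment-interaction (predictive) stage.
    n_min : int
        Minimum number of patients required in every compared group
        (mutant and wild type; per arm for interaction tests).
    n_permutations, n_bootstrap : int
        Resampling depth for multiplicity adjustment and bias correction.
    endpoints : list of str
        Subset of ``{"OS", "PFS", "ORR"}`` to analyse.
    covariate_names : list of str
        Clinical columns entered unpenalised into every regression.
    subtype_schemes : list of str
        Clinical columns holding categorical tumour subtype labels.
    custom_modules : dict
        Named feature unions added to the tested feature set
        (e.g. ``{"RAS": ["KRAS", "NRAS"]}``).
    effect_reporting : str
        ``"reciprocal"`` reports every effect ratio <= 1 with a direction
        flag; ``"raw"`` reports ratios as estimated.
    mutex_alpha : float
        Growth threshold of the mutual-exclusivity module search.
    cv_fdr_beta : float
        Relaxed interaction threshold used inside cross-validation.
    missing_as : str
        ``"error"`` rejects missing alteration values; ``"zero"`` imputes 0.
    include_treatment_main : bool
        Adds a treatment main-effect term to the interaction model
        (sensitivity analysis; the default model omits it).
    add_one_permutation : bool
        Report (1 + hits) / (1 + U) instead of hits / U.
    """

    fdr_mol: float = 0.05
    fdr_alpha: float = 0.1
    fdr_beta: float = 0.2
    n_min: int = 10
    n_permutations: int = 1000
    n_bootstrap: int = 500
    seed: int = 0
    endpoints: list[str] = field(default_factory=lambda: list(ENDPOINTS))
    covariate_names: list[str] = field(default_factory=list)
    subtype_schemes: list[str] = field(default_factory=list)
    custom_modules: dict[str, list[str]] = field(default_factory=dict)
    effect_reporting: str = "reciprocal"
    mutex_alpha: float = 0.05
    cv_fdr_beta: float = 0.3
    missing_as: str = "error"
    include_treatment_main: bool = False
    add_one_permutation: bool = False

    def replace(self, **kwargs: Any) -> "Config":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range threshold values."""


_FRACTIONS = ("fdr_mol", "fdr_alpha", "fdr_beta", "mutex_alpha", "cv_fdr_beta")


def validate_config(raw: dict[str, Any] | Config | None = None) -> Config:
    """Build a validated :class:`Config`, filling defaults for absent keys.

    Unknown keys are rejected (they are silent no-ops otherwise, which is
    how threshold typos slip through an analysis unnoticed).
    """
    if raw is None:
        raw = {}
    if isinstance(raw, Config):
        raw = raw.to_dict()
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = Config(**raw)

    for key in _FRACTIONS:
        value = getattr(cfg, key)
        if not (0.0 < float(value) < 1.0):
            raise ConfigError(f"{key} out of range (0, 1): {value!r}")
    if int(cfg.n_min) < 2:
        raise ConfigError(f"n_min must be >= 2, got {cfg.n_min!r}")
    if int(cfg.n_permutations) < 1:
        raise ConfigError("n_permutations must be >= 1")
    if int(cfg.n_bootstrap) < 1:
        raise ConfigError("n_bootstrap must be >= 1")
    bad = [e for e in cfg.endpoints if e not in ENDPOINTS]
    if bad:
        raise ConfigError(f"unknown endpoints {bad}; choose from {list(ENDPOINTS)}")
    if not cfg.endpoints:
        raise ConfigError("endpoints must be non-empty")
    if cfg.effect_reporting not in ("reciprocal", "raw"):
        raise ConfigError(f"effect_reporting must be 'reciprocal' or 'raw', got {cfg.effect_reporting!r}")
    if cfg.missing_as not in ("error", "zero"):
        raise ConfigError(f"missing_as must be 'error' or 'zero', got {cfg.missing_as!r}")
    for name, members in cfg.custom_modules.items():
        if len(members) < 2:
            raise ConfigError(f"custom module {name!r} needs >= 2 members")
    return cfg


def load_config(path: str | Path) -> Config:
    """Read a YAML or JSON config file and validate it."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return validate_config(raw)


def save_config(config: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
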