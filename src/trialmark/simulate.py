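"""Seeded synthetic two-arm trial generator.

Emulates the structure the discovery pipeline assumes: a ~1:1
randomised cohort with a binary somatic-alteration matrix (configurable
marginal frequencies, hard mutually exclusive groups, feature-subtype
enrichment), categorical subtype schemes, exponential survival for OS
and PFS with independent exponential censoring, and a correlated binary
response.  Because hazards are constant, proportional hazards holds
exactly and the log-hazard effects written into a design are the very
estimands the screening/interaction/CATE models target — simulated
truth and model coefficient live on the same scale.

Effects are specified as log hazard ratios (or log odds ratios for the
response): `prognostic_loghr` applies to both arms, `predictive_loghr`
adds a treatment-arm-only term inside a (feature, scheme, level,
status) subgroup, so a negative value means the experimental arm
benefits that subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .data import TrialDataset, default_feature_meta

ALL = "ALL"


@dataclass
class SimulationDesign:
    """Complete recipe for one synthetic trial."""

    n_patients: int = 400
    arm_probability: float = 0.5
    feature_frequencies: dict[str, float] = field(default_factory=dict)
    mutex_groups: list[list[str]] = field(default_factory=list)
    schemes: dict[str, dict[str, float]] = field(default_factory=dict)
    # (feature, scheme, level) -> odds multiplier on the alteration probability
    enrichment_odds: dict[tuple[str, str, str], float] = field(default_factory=dict)
    prognostic_loghr: dict[str, float] = field(default_factory=dict)
    treatment_loghr: float = 0.0
    # (feature, scheme, level, status) -> added treatment log-HR in that subgroup
    predictive_loghr: dict[tuple[str, str, str, str], float] = field(
        default_factory=dict
    )
    os_baseline_rate: float = 0.028  # events/month; median OS ~25 months
    os_censor_rate: float = 0.008
    pfs_baseline_rate: float = 0.069  # median PFS ~10 months
    pfs_censor_rate: float = 0.008
    orr_intercept: float = 0.3
    orr_prognostic: dict[str, float] = field(default_factory=dict)
    orr_treatment: float = 0.0
    orr_predictive: dict[tuple[str, str, str, str], float] = field(
        default_factory=dict
    )
    covariate_specs: dict[str, Any] = field(default_factory=dict)
    covariate_loghr: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> "SimulationDesign":
        if not self.feature_frequencies:
            raise ValueError("feature_frequencies must be non-empty")
        for name, freq in self.feature_frequencies.items():
            if not (0.0 <= freq <= 1.0):
                raise ValueError(f"frequency of {name!r} outside [0, 1]: {freq}")
        if not (0.0 < self.arm_probability < 1.0):
            raise ValueError("arm_probability must be in (0, 1)")
        for rate in (
            self.os_baseline_rate, self.os_censor_rate,
            self.pfs_baseline_rate, self.pfs_censor_rate,
        ):
            if rate <= 0:
                raise ValueError("baseline and censoring rates must be > 0")
        seen: set[str] = set()
        for group in self.mutex_groups:
            unknown = [g for g in group if g not in self.feature_frequencies]
            if unknown:
                raise ValueError(f"mutex group references unknown features {unknown}")
            if seen & set(group):
                raise ValueError("features may belong to at most one mutex group")
            seen |= set(group)
            total = sum(self.feature_frequencies[g] for g in group)
            if total > 1.0:
                raise ValueError(
                    f"mutex group {group} frequencies sum to {total:.3f} > 1; "
                    "hard exclusivity is infeasible"
                )
        for scheme, levels in self.schemes.items():
            if abs(sum(levels.values()) - 1.0) > 1e-9:
                raise ValueError(f"level probabilities of {scheme!r} must sum to 1")
            if len(levels) < 2:
                raise ValueError(f"scheme {scheme!r} needs >= 2 levels")
        return self


def _subgroup_mask(
    key: tuple[str, str, str, str],
    X: pd.DataFrame,
    subtypes: pd.DataFrame,
) -> np.ndarray:
    feature, scheme, level, status = key
    mask = (X[feature].to_numpy() == (1 if status == "mutant" else 0))
    if scheme != "none" and level != ALL:
        mask = mask & (subtypes[scheme].to_numpy() == level)
    return mask


def simulate_trial(design: SimulationDesign) -> TrialDataset:
    """Draw one trial from the design (deterministic given the seed)."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_patients
    feature_names = list(design.feature_frequencies)

    # subtype labels, drawn independently per scheme
    subtypes = pd.DataFrame(index=range(n))
    for scheme, levels in design.schemes.items():
        names = list(levels)
        subtypes[scheme] = rng.choice(names, size=n, p=[levels[k] for k in names])

    # per-patient alteration probabilities with enrichment odds applied
    prob = np.tile(
        np.array([design.feature_frequencies[f] for f in feature_names]), (n, 1)
    )
    for (feature, scheme, level), odds in design.enrichment_odds.items():
        jcol = feature_names.index(feature)
        rows = subtypes[scheme].to_numpy() == level
        base = prob[rows, jcol]
        prob[rows, jcol] = odds * base / (1.0 - base + odds * base)

    X = (rng.random((n, len(feature_names))) < prob).astype(np.int8)

    # hard exclusivity: one categorical draw per patient within each group
    for group in design.mutex_groups:
        cols = [feature_names.index(g) for g in group]
        p_group = prob[:, cols]
        total = p_group.sum(axis=1, keepdims=True)
        if (total > 1.0).any():
            raise ValueError(f"mutex group {group} infeasible after enrichment")
        cum = np.cumsum(p_group, axis=1)
        u = rng.random((n, 1))
        X[:, cols] = 0
        chosen = (u < cum) & (u >= cum - p_group)
        for i, c in enumerate(cols):
            X[:, c] = chosen[:, i]

    Xdf = pd.DataFrame(X, columns=feature_names)
    treatment = (rng.random(n) < design.arm_probability).astype(np.int64)

    covariates = pd.DataFrame(index=range(n))
    for name, spec in design.covariate_specs.items():
        kind = spec[0]
        if kind == "normal":
            covariates[name] = rng.normal(spec[1], spec[2], size=n)
        elif kind == "poisson":
            covariates[name] = rng.poisson(spec[1], size=n)
        elif kind == "categorical":
            levels = spec[1]
            covariates[name] = rng.choice(
                list(levels), size=n, p=list(levels.values())
            )
        elif kind == "bernoulli":
            covariates[name] = rng.binomial(1, spec[1], size=n)
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")

    def _linear_predictor(predictive: dict, prognostic: dict, main: float):
        eta = np.zeros(n)
        for feature, loghr in prognostic.items():
            eta += loghr * Xdf[feature].to_numpy()
        for name, loghr in design.covariate_loghr.items():
            col = covariates[name]
            eta += loghr * (
                col.to_numpy(dtype=np.float64)
                if pd.api.types.is_numeric_dtype(col)
                else (col == col.mode()[0]).to_numpy(dtype=np.float64)
            )
        arm_effect = np.full(n, main)
        for key, loghr in predictive.items():
            arm_effect += loghr * _subgroup_mask(key, Xdf, subtypes)
        return eta + treatment * arm_effect

    def _survival(base_rate: float, censor_rate: float):
        eta = _linear_predictor(
            design.predictive_loghr, design.prognostic_loghr, design.treatment_loghr
        )
        hazard = base_rate * np.exp(eta)
        event_time = rng.exponential(1.0 / hazard)
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
        observed = np.minimum(event_time, censor_time)
        return observed, (event_time <= censor_time).astype(np.int64)

    os_time, os_event = _survival(design.os_baseline_rate, design.os_censor_rate)
    pfs_time, pfs_event = _survival(design.pfs_baseline_rate, design.pfs_censor_rate)

    logit = np.full(n, design.orr_intercept, dtype=np.float64)
    for feature, coef in design.orr_prognostic.items():
        logit += coef * Xdf[feature].to_numpy()
    arm_effect = np.full(n, design.orr_treatment)
    for key, coef in design.orr_predictive.items():
        arm_effect += coef * _subgroup_mask(key, Xdf, subtypes)
    logit += treatment * arm_effect
    orr = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))

    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "treatment": treatment,
            "os_time": os_time,
            "os_event": os_event,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "orr": orr,
        }
    )
    for col in subtypes.columns:
        clinical[col] = subtypes[col]
    for col in covariates.columns:
        clinical[col] = covariates[col]

    return TrialDataset(
        clinical=clinical,
        alterations=Xdf,
        feature_meta=default_feature_meta(feature_names),
    )


def mcrc_trial_design(seed: int = 0, n_patients: int = 400) -> SimulationDesign:
    """Packaged default design echoing a metastatic-CRC trial cohort.

    ~400 patients, 1:1 randomisation, 30 binary features spanning 3-50%
    prevalence, one 3-member hard-exclusivity group, two subtype schemes
    (primary tumour sidedness; four molecular subtypes) with a couple of
    feature-subtype enrichments, two prognostic effects and one planted
    predictive effect (experimental-arm benefit, HR 0.5, in mutants of
    gene G01 restricted to left-sided tumours), plus two clinical
    covariates with mild prognostic impact.
    """
    freqs = {
        f"G{j:02d}": float(f)
        for j, f in enumerate(np.geomspace(0.5, 0.03, 30).round(3), start=1)
    }
    return SimulationDesign(
        n_patients=n_patients,
        feature_frequencies=freqs,
        mutex_groups=[["G05", "G06", "G07"]],
        schemes={
            "side": {"left": 0.65, "right": 0.35},
            "cms": {"CMS1": 0.12, "CMS2": 0.45, "CMS3": 0.12, "CMS4": 0.31},
        },
        enrichment_odds={
            ("G03", "side", "right"): 3.0,
            ("G10", "cms", "CMS1"): 4.0,
        },
        prognostic_loghr={"G02": 0.35, "G08": -0.3},
        predictive_loghr={("G01", "side", "left", "mutant"): float(np.log(0.5))},
        orr_prognostic={"G02": -0.4},
        covariate_specs={
            "n_met_sites": ("poisson", 1.6),
            "prior_resection": ("bernoulli", 0.45),
        },
        covariate_loghr={"n_met_sites": 0.12, "prior_resection": -0.2},
        seed=seed,
    )
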