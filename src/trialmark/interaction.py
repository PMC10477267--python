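"""Cross-arm predictive testing and subgroup treatment-effect estimation.

Predictive (treatment-modifying) biomarkers are found by fitting, per
endpoint and stratum, the interaction model

    f(x, t) = beta0_j + beta1_j * x_j + beta2_j * x_j * t + sum_l C_l

where beta1 captures the prognostic and beta2 the predictive component
of feature x_j.  The model is used exactly in this form — without a
treatment main effect — matching the staged screen it follows; a config
switch adds the main effect for sensitivity analyses.  Wald p-values of
beta2 are BH-adjusted within (endpoint, scheme) families.  A biomarker
is called putatively predictive when its interaction q falls below
``fdr_beta`` and the arm-specific screen flagged the same (endpoint,
feature, level) in at least one arm at ``fdr_alpha``.

For each predictive biomarker the conditional average treatment effect
(CATE) is then estimated inside the mutant and the wild-type
population via

    f(x, t) = gamma0 + gamma1 * t + sum_l C_l

and the population with the larger |gamma1| is selected as the reported
subgroup (ties go to the mutant population; if one population is
degenerate the other is selected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config
from .data import TrialDataset
from .engine import TrialArrays, coef_offset
from .fitters import Z975, bh_adjust, safe_exp
from .landscape import build_feature_set
from .screening import screen_arms

INTERACTION_COLUMNS = [
    "endpoint", "feature", "scheme", "level", "n", "beta0", "beta1", "beta2",
    "se2", "p_int", "q_int", "converged", "eligible", "family_id",
    "screen_hit", "predictive",
]

MUTANT, WILDTYPE = "mutant", "wildtype"


@dataclass
class SubgroupDefinition:
    """One candidate subgroup: feature status within a subtype level."""

    endpoint: str
    feature: str
    scheme: str
    level: str
    status: str  # "mutant" | "wildtype"

    def __post_init__(self) -> None:
        if self.status not in (MUTANT, WILDTYPE):
            raise ValueError(f"status must be mutant/wildtype, got {self.status!r}")


@dataclass
class SubgroupEffect:
    """Naive CATE of one subgroup, later augmented by the resampling stage."""

    definition: SubgroupDefinition
    gamma0: float
    gamma1: float
    se: float
    effect_naive: float
    ci95: tuple[float, float]
    p_gamma: float
    n0: int
    n1: int
    converged: bool
    companion_gamma1: float = np.nan  # same model in the non-selected population
    p_adj: float = np.nan
    gamma_corrected: float = np.nan
    ci_boot: tuple[float, float] = (np.nan, np.nan)
    n_boot_used: int = 0
    unstable: bool = False
    extras: dict = field(default_factory=dict)


def _arrays_from(
    dataset: TrialDataset,
    features: pd.DataFrame | None,
    feature_meta: pd.DataFrame | None,
    config: Config,
) -> TrialArrays:
    if features is None:
        features, feature_meta = build_feature_set(dataset, [], config)
    elif feature_meta is None:
        from .data import default_feature_meta

        feature_meta = default_feature_meta(list(features.columns))
    return TrialArrays(dataset, features, feature_meta, config)


def interaction_scan(
    arrays: TrialArrays,
    treatment: np.ndarray | None = None,
    screening: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Engine-level interaction enumeration on prebuilt arrays."""
    config = arrays.config
    T = arrays.treatment if treatment is None else treatment
    n_min = config.n_min
    rows_out: list[dict] = []

    for ep_name, ep in arrays.endpoints.items():
        off = coef_offset(ep.kind)
        for ci, ctx in enumerate(arrays.contexts):
            rows = arrays.orders[(ep_name, ci)]
            t_rows = T[rows].astype(np.float64)
            Xsub = arrays.X[rows]
            arm1 = t_rows == 1
            n_arm = np.array([(~arm1).sum(), arm1.sum()])
            mut_by_arm = np.vstack([Xsub[~arm1].sum(axis=0), Xsub[arm1].sum(axis=0)])
            redistribution_ok = {
                j: arrays.module_redistribution_ok(j, rows)
                for j in arrays.module_members
            }
            for j, feature in enumerate(arrays.feature_names):
                base = {
                    "endpoint": ep_name, "feature": feature,
                    "scheme": ctx.scheme, "level": ctx.level,
                    "family_id": f"{ep_name}|{ctx.scheme}",
                }
                n_mut = mut_by_arm[:, j]
                n_wt = n_arm - n_mut
                eligible = bool(
                    (n_mut >= n_min).all()
                    and (n_wt >= n_min).all()
                    and redistribution_ok.get(j, True)
                )
                if not eligible:
                    rows_out.append(
                        {**base, "n": len(rows), "beta0": np.nan, "beta1": np.nan,
                         "beta2": np.nan, "se2": np.nan, "p_int": np.nan,
                         "converged": False, "eligible": False}
                    )
                    continue
                x = Xsub[:, j].astype(np.float64)
                lead = [x, x * t_rows]
                if config.include_treatment_main:
                    lead.append(t_rows)
                design = arrays.design_with_covariates(rows, *lead)
                fit = arrays.fit_rows(ep_name, rows, design)
                if fit is None:
                    rows_out.append(
                        {**base, "n": len(rows), "beta0": np.nan, "beta1": np.nan,
                         "beta2": np.nan, "se2": np.nan, "p_int": np.nan,
                         "converged": False, "eligible": False}
                    )
                    continue
                rows_out.append(
                    {
                        **base,
                        "n": fit.n,
                        "beta0": float(fit.beta[0]) if off else np.nan,
                        "beta1": float(fit.beta[off]),
                        "beta2": float(fit.beta[off + 1]),
                        "se2": float(fit.se[off + 1]),
                        "p_int": fit.wald_p(off + 1),
                        "converged": fit.converged,
                        "eligible": True,
                    }
                )

    results = pd.DataFrame(rows_out, columns=INTERACTION_COLUMNS[:14])
    results["q_int"] = np.nan
    results["screen_hit"] = False
    results["predictive"] = False
    if not len(results):
        return results[INTERACTION_COLUMNS]

    usable = results["eligible"] & results["converged"] & results["p_int"].notna()
    for _, sub in results[usable].groupby("family_id"):
        results.loc[sub.index, "q_int"] = bh_adjust(sub["p_int"].to_numpy())

    if screening is None:
        screening, _ = screen_arms(None, arrays=arrays, treatment=T)
    hits = screening.loc[screening["significant"].astype(bool)]
    hit_keys = set(
        zip(hits["endpoint"], hits["feature"], hits["scheme"], hits["level"])
    )
    keys = list(
        zip(results["endpoint"], results["feature"], results["scheme"],
            results["level"])
    )
    results["screen_hit"] = [k in hit_keys for k in keys]
    results["predictive"] = (
        results["eligible"]
        & results["screen_hit"]
        & (results["q_int"] < config.fdr_beta)
    )
    return results[INTERACTION_COLUMNS]


def test_interaction(
    dataset: TrialDataset,
    features: pd.DataFrame | None = None,
    config: Config | None = None,
    feature_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Public interaction scan: one row per (endpoint, feature, stratum)."""
    if config is None:
        raise ValueError("config is required")
    return interaction_scan(_arrays_from(dataset, features, feature_meta, config))


def fit_cate(
    arrays: TrialArrays,
    definition: SubgroupDefinition,
    treatment: np.ndarray | None = None,
) -> SubgroupEffect | None:
    """Fit the treatment-effect model inside one subgroup.

    Returns None when the subgroup outcome (or an arm) is degenerate.
    """
    T = arrays.treatment if treatment is None else treatment
    ep = arrays.endpoints[definition.endpoint]
    ci = next(
        i
        for i, c in enumerate(arrays.contexts)
        if c.scheme == definition.scheme and c.level == definition.level
    )
    rows = arrays.orders[(definition.endpoint, ci)]
    j = arrays.feature_names.index(definition.feature)
    want = 1 if definition.status == MUTANT else 0
    rows = rows[arrays.X[rows, j] == want]
    t_rows = T[rows].astype(np.float64)
    n1 = int(t_rows.sum())
    n0 = len(rows) - n1
    if n0 == 0 or n1 == 0:
        return None
    design = arrays.design_with_covariates(rows, t_rows)
    fit = arrays.fit_rows(definition.endpoint, rows, design)
    if fit is None:
        return None
    off = coef_offset(ep.kind)
    gamma1 = float(fit.beta[off])
    se = float(fit.se[off])
    return SubgroupEffect(
        definition=definition,
        gamma0=float(fit.beta[0]) if off else np.nan,
        gamma1=gamma1,
        se=se,
        effect_naive=safe_exp(gamma1),
        ci95=(safe_exp(gamma1 - Z975 * se), safe_exp(gamma1 + Z975 * se)),
        p_gamma=fit.wald_p(off),
        n0=n0,
        n1=n1,
        converged=fit.converged,
    )


def estimate_cate(
    dataset: TrialDataset,
    definition: SubgroupDefinition,
    config: Config,
    features: pd.DataFrame | None = None,
) -> SubgroupEffect:
    """Public CATE estimate for an explicit subgroup definition."""
    arrays = _arrays_from(dataset, features, None, config)
    effect = fit_cate(arrays, definition)
    if effect is None:
        raise ValueError(f"degenerate outcome in subgroup {definition}")
    return effect


def select_between(
    mutant: SubgroupEffect | None, wildtype: SubgroupEffect | None
) -> SubgroupEffect | None:
    """Pick the population with larger |gamma1| (tie -> mutant)."""
    if mutant is None and wildtype is None:
        return None
    if wildtype is None:
        return mutant
    if mutant is None:
        return wildtype
    if abs(mutant.gamma1) >= abs(wildtype.gamma1):
        mutant.companion_gamma1 = wildtype.gamma1
        return mutant
    wildtype.companion_gamma1 = mutant.gamma1
    return wildtype


def select_subgroup(
    dataset: TrialDataset,
    interaction_row: pd.Series | dict,
    config: Config,
    features: pd.DataFrame | None = None,
    arrays: TrialArrays | None = None,
    treatment: np.ndarray | None = None,
) -> SubgroupEffect | None:
    """Estimate the CATE in both populations of a predictive biomarker and
    return the subgroup with the larger absolute treatment effect."""
    if arrays is None:
        arrays = _arrays_from(dataset, features, None, config)
    row = interaction_row
    get = row.get if isinstance(row, dict) else row.__getitem__
    candidates = {}
    for status in (MUTANT, WILDTYPE):
        definition = SubgroupDefinition(
            endpoint=get("endpoint"), feature=get("feature"),
            scheme=get("scheme"), level=get("level"), status=status,
        )
        candidates[status] = fit_cate(arrays, definition, treatment=treatment)
    return select_between(candidates[MUTANT], candidates[WILDTYPE])
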