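"""Treatment-arm-specific biomarker screening.

Within each treatment arm, each endpoint and each stratum (the whole
cohort plus every subtype level), every feature x_j is entered into

    f(x) = alpha0_j + alpha1_j * x_j + sum_l C_l

a Cox proportional-hazards model for survival endpoints (no intercept;
absorbed by the baseline hazard) or a logistic model for the binary
response.  exp(alpha1) is the mutant-vs-wild-type hazard/odds ratio in
that arm.  Wald p-values of alpha1 are BH-adjusted within one family
per (endpoint, arm, scheme); the unstratified results form their own
family (scheme "none").

Eligibility filters (all adjustable through the config):
* at least ``n_min`` mutant and ``n_min`` wild-type patients in the
  analysed stratum-arm;
* a module-union column is tested only where it redistributes at least
  ``n_min`` patients over every single member in the stratum;
* fits with a degenerate outcome are skipped, non-converged fits are
  excluded from the BH family; every skipped combination lands in the
  audit table with its reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config
from .data import TrialDataset
from .engine import ALL_LEVEL, NO_SCHEME, TrialArrays, coef_offset
from .fitters import Z975, bh_adjust, safe_exp
from .landscape import build_feature_set

RESULT_COLUMNS = [
    "endpoint", "arm", "feature", "scheme", "level", "n", "n_events",
    "n_mut", "n_wt", "alpha0", "alpha1", "se", "effect", "ci_low", "ci_high",
    "p", "q", "converged", "family_id", "significant",
]


@dataclass
class ArmModelSpec:
    """Addresses one arm-specific fit."""

    endpoint: str
    arm: int
    feature: str
    scheme: str = NO_SCHEME
    level: str = ALL_LEVEL


@dataclass
class ArmBiomarkerResult:
    spec: ArmModelSpec
    alpha0: float
    alpha1: float
    se: float
    effect: float
    ci95: tuple[float, float]
    p: float
    n_mut: int
    n_wt: int
    converged: bool
    q: float = np.nan


def screen_arms(
    dataset: TrialDataset,
    features: pd.DataFrame | None = None,
    config: Config | None = None,
    feature_meta: pd.DataFrame | None = None,
    arrays: TrialArrays | None = None,
    treatment: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full arm-specific screen.

    Returns ``(results, audit)``: one row per fitted model with BH q and
    significance flag, and one audit row per enumerated-but-untested
    combination with its reason.
    """
    if arrays is None:
        if config is None:
            raise ValueError("config is required")
        if features is None:
            features, feature_meta = build_feature_set(dataset, [], config)
        elif feature_meta is None:
            from .data import default_feature_meta

            feature_meta = default_feature_meta(list(features.columns))
        arrays = TrialArrays(dataset, features, feature_meta, config)
    config = arrays.config
    T = arrays.treatment if treatment is None else treatment

    rows_out: list[dict] = []
    audit: list[dict] = []
    n_min = config.n_min

    for ep_name, ep in arrays.endpoints.items():
        off = coef_offset(ep.kind)
        for ci, ctx in enumerate(arrays.contexts):
            stratum = arrays.orders[(ep_name, ci)]
            redistribution_ok = {
                j: arrays.module_redistribution_ok(j, stratum)
                for j in arrays.module_members
            }
            for arm in (0, 1):
                rows = stratum[T[stratum] == arm]
                Xsub = arrays.X[rows]
                n_mut_all = Xsub.sum(axis=0)
                n_tot = len(rows)
                for j, feature in enumerate(arrays.feature_names):
                    n_mut = int(n_mut_all[j])
                    n_wt = n_tot - n_mut
                    base = {
                        "endpoint": ep_name, "arm": arm, "feature": feature,
                        "scheme": ctx.scheme, "level": ctx.level,
                    }
                    if n_mut < n_min:
                        audit.append({**base, "reason": "n_mut < n_min"})
                        continue
                    if n_wt < n_min:
                        audit.append({**base, "reason": "n_wt < n_min"})
                        continue
                    if not redistribution_ok.get(j, True):
                        audit.append(
                            {**base, "reason": "module redistribution < n_min"}
                        )
                        continue
                    design = arrays.design_with_covariates(
                        rows, Xsub[:, j].astype(np.float64)
                    )
                    fit = arrays.fit_rows(ep_name, rows, design)
                    if fit is None:
                        reason = (
                            "no events" if ep.kind == "survival"
                            else "single response class"
                        )
                        audit.append({**base, "reason": reason})
                        continue
                    alpha1 = float(fit.beta[off])
                    se = float(fit.se[off])
                    rows_out.append(
                        {
                            **base,
                            "n": fit.n, "n_events": fit.n_events,
                            "n_mut": n_mut, "n_wt": n_wt,
                            "alpha0": float(fit.beta[0]) if off else np.nan,
                            "alpha1": alpha1, "se": se,
                            "effect": safe_exp(alpha1),
                            "ci_low": safe_exp(alpha1 - Z975 * se),
                            "ci_high": safe_exp(alpha1 + Z975 * se),
                            "p": fit.wald_p(off),
                            "converged": fit.converged,
                            "family_id": f"{ep_name}|arm{arm}|{ctx.scheme}",
                        }
                    )

    results = pd.DataFrame(rows_out, columns=RESULT_COLUMNS[:-2] + ["family_id"])
    results["q"] = np.nan
    results["significant"] = False
    if len(results):
        usable = results["converged"] & results["p"].notna()
        for _, sub in results[usable].groupby("family_id"):
            q = bh_adjust(sub["p"].to_numpy())
            results.loc[sub.index, "q"] = q
            results.loc[sub.index, "significant"] = q < config.fdr_alpha
        if (~usable).any():
            for _, row in results[~usable].iterrows():
                audit.append(
                    {
                        "endpoint": row.endpoint, "arm": row.arm,
                        "feature": row.feature, "scheme": row.scheme,
                        "level": row.level, "reason": "not converged",
                    }
                )
    audit_df = pd.DataFrame(
        audit, columns=["endpoint", "arm", "feature", "scheme", "level", "reason"]
    )
    return results[RESULT_COLUMNS], audit_df


def fit_arm_model(
    dataset: TrialDataset,
    spec: ArmModelSpec,
    config: Config,
    features: pd.DataFrame | None = None,
) -> ArmBiomarkerResult:
    """Fit a single arm-specific model for one feature (no BH context)."""
    if features is None:
        features = dataset.alterations
    from .data import default_feature_meta

    arrays = TrialArrays(
        dataset, features, default_feature_meta(list(features.columns)), config
    )
    if spec.endpoint not in arrays.endpoints:
        raise ValueError(f"endpoint {spec.endpoint!r} not available")
    ep = arrays.endpoints[spec.endpoint]
    ci = next(
        i
        for i, c in enumerate(arrays.contexts)
        if c.scheme == spec.scheme and c.level == spec.level
    )
    stratum = arrays.orders[(spec.endpoint, ci)]
    rows = stratum[arrays.treatment[stratum] == spec.arm]
    j = arrays.feature_names.index(spec.feature)
    x = arrays.X[rows, j].astype(np.float64)
    n_mut = int(x.sum())
    n_wt = len(rows) - n_mut
    fit = arrays.fit_rows(spec.endpoint, rows, arrays.design_with_covariates(rows, x))
    if fit is None:
        raise ValueError(
            f"degenerate outcome for {spec} (no events / single response class)"
        )
    off = coef_offset(ep.kind)
    alpha1 = float(fit.beta[off])
    se = float(fit.se[off])
    return ArmBiomarkerResult(
        spec=spec,
        alpha0=float(fit.beta[0]) if off else np.nan,
        alpha1=alpha1,
        se=se,
        effect=safe_exp(alpha1),
        ci95=(safe_exp(alpha1 - Z975 * se), safe_exp(alpha1 + Z975 * se)),
        p=fit.wald_p(off),
        n_mut=n_mut,
        n_wt=n_wt,
        converged=fit.converged,
    )
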