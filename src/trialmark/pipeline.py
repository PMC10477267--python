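"""Pipeline orchestration, reporting tables and CV stability analysis.

``run_pipeline`` executes the five stages in order — molecular
landscape, arm-specific screening, interaction testing, subgroup
selection, resampling correction — and writes every result as TSV plus
one JSON summary.  All outputs are plot-ready coordinates/tables
(Kaplan-Meier curves with Greenwood 95% bands, forest-plot rows, an
oncoprint-ready feature matrix); no figures are rendered.

Effect reporting follows the convention that ratios <= 1 denote benefit:
with ``effect_reporting = "reciprocal"`` any reported HR/OR above 1 is
flipped to its reciprocal and tagged with the direction it favours.
Stored coefficients always stay on the raw scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import Config
from .data import TrialDataset, load_trial
from .engine import TrialArrays
from .interaction import MUTANT, SubgroupEffect, interaction_scan
from .landscape import (
    MutexModule,
    build_feature_set,
    enrichment_table,
    find_mutex_modules,
    modules_table,
    test_subtype_enrichment,
)
from .resampling import SearchProcedure, adjust_subgroups
from .screening import screen_arms

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    config: Config
    enrichment: pd.DataFrame
    modules: list[MutexModule]
    feature_set: pd.DataFrame
    arm_results: pd.DataFrame
    audit: pd.DataFrame
    interactions: pd.DataFrame
    subgroups: list[SubgroupEffect]
    km_curves: pd.DataFrame
    version: str = __version__

    @property
    def n_predictive(self) -> int:
        return len(self.subgroups)


def reported_effect(effect: float, config: Config) -> tuple[float, str]:
    """Apply the reciprocal reporting convention to a ratio estimate.

    Returns (reported ratio, direction flag).  A raw ratio above 1 means
    the wild-type/reference group fares better; under reciprocal
    reporting it is flipped so the printed ratio is always <= 1.
    """
    if config.effect_reporting == "reciprocal" and effect > 1.0:
        return 1.0 / effect, "benefit-in-reference"
    return effect, "benefit-in-index"


def subgroup_treatment_effect(effect: float, config: Config) -> tuple[float, str]:
    """Reciprocal convention for subgroup treatment effects: ratios < 1
    favour the experimental arm, flipped ratios favour control."""
    if config.effect_reporting == "reciprocal" and effect > 1.0:
        return 1.0 / effect, "benefit-in-control-arm"
    return effect, "benefit-in-experimental-arm"


def subgroups_table(subgroups: list[SubgroupEffect], config: Config) -> pd.DataFrame:
    rows = []
    for s in subgroups:
        d = s.definition
        reported, direction = subgroup_treatment_effect(s.effect_naive, config)
        corrected = float(np.exp(s.gamma_corrected)) if np.isfinite(
            s.gamma_corrected
        ) else np.nan
        corrected_reported, corrected_direction = (
            subgroup_treatment_effect(corrected, config)
            if np.isfinite(corrected)
            else (np.nan, "")
        )
        rows.append(
            {
                "endpoint": d.endpoint, "feature": d.feature, "scheme": d.scheme,
                "level": d.level, "status": d.status, "n0": s.n0, "n1": s.n1,
                "gamma1": s.gamma1, "se": s.se, "effect_naive": s.effect_naive,
                "ci_low": s.ci95[0], "ci_high": s.ci95[1], "p_gamma": s.p_gamma,
                "companion_gamma1": s.companion_gamma1,
                "p_adj": s.p_adj,
                "gamma_corrected": s.gamma_corrected,
                "effect_corrected": corrected,
                "ci_boot_low": np.exp(s.ci_boot[0]) if np.isfinite(s.ci_boot[0])
                else np.nan,
                "ci_boot_high": np.exp(s.ci_boot[1]) if np.isfinite(s.ci_boot[1])
                else np.nan,
                "n_boot_used": s.n_boot_used, "unstable": s.unstable,
                "reported_effect": reported, "direction": direction,
                "reported_effect_corrected": corrected_reported,
                "direction_corrected": corrected_direction,
                "q_int": s.extras.get("q_int", np.nan),
            }
        )
    columns = [
        "endpoint", "feature", "scheme", "level", "status", "n0", "n1",
        "gamma1", "se", "effect_naive", "ci_low", "ci_high", "p_gamma",
        "companion_gamma1", "p_adj", "gamma_corrected", "effect_corrected",
        "ci_boot_low", "ci_boot_high", "n_boot_used", "unstable",
        "reported_effect", "direction", "reported_effect_corrected",
        "direction_corrected", "q_int",
    ]
    return pd.DataFrame(rows, columns=columns)


def km_coordinates(
    dataset: TrialDataset,
    subgroups: list[SubgroupEffect],
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Product-limit survival coordinates (Greenwood 95% bands) per
    reported subgroup and arm, for survival endpoints.

    ``features`` is the augmented feature set when subgroups refer to
    module-union columns; defaults to the raw alteration matrix."""
    from lifelines import KaplanMeierFitter

    if features is None:
        features = dataset.alterations
    frames = []
    for s in subgroups:
        d = s.definition
        if d.endpoint not in ("OS", "PFS"):
            continue
        tcol, ecol = d.endpoint.lower() + "_time", d.endpoint.lower() + "_event"
        clin = dataset.clinical
        mask = clin[tcol].notna() & clin[ecol].notna()
        want = 1 if d.status == MUTANT else 0
        mask &= features[d.feature].to_numpy() == want
        if d.scheme != "none":
            mask &= clin[d.scheme] == d.level
        for arm in (0, 1):
            sel = mask & (clin["treatment"] == arm)
            if sel.sum() == 0:
                continue
            km = KaplanMeierFitter()
            km.fit(clin.loc[sel, tcol], clin.loc[sel, ecol])
            ci = km.confidence_interval_survival_function_
            frames.append(
                pd.DataFrame(
                    {
                        "endpoint": d.endpoint, "feature": d.feature,
                        "scheme": d.scheme, "level": d.level, "status": d.status,
                        "arm": arm,
                        "time": km.survival_function_.index.to_numpy(),
                        "survival": km.survival_function_.iloc[:, 0].to_numpy(),
                        "ci_low": ci.iloc[:, 0].to_numpy(),
                        "ci_high": ci.iloc[:, 1].to_numpy(),
                    }
                )
            )
    columns = ["endpoint", "feature", "scheme", "level", "status", "arm",
               "time", "survival", "ci_low", "ci_high"]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]


def run_pipeline(
    clinical_path: str | Path | None,
    alterations_path: str | Path | None,
    config: Config,
    outdir: str | Path | None = None,
    dataset: TrialDataset | None = None,
    n_permutations: int | None = None,
    n_bootstrap: int | None = None,
) -> PipelineReport:
    """Execute the full discovery pipeline and (optionally) write outputs."""
    manifest: list[str] = []
    writer = _OutputWriter(outdir, manifest)
    try:
        if dataset is None:
            dataset = load_trial(clinical_path, alterations_path, config)
        writer.stage("load")

        enrichment = enrichment_table(test_subtype_enrichment(dataset, config))
        modules = find_mutex_modules(dataset, config)
        features, feature_meta = build_feature_set(dataset, modules, config)
        writer.write_tsv("enrichment.tsv", enrichment)
        writer.write_tsv("modules.tsv", modules_table(modules))
        oncoprint = features.copy()
        oncoprint.insert(0, "patient_id", dataset.clinical["patient_id"].to_numpy())
        writer.write_tsv("feature_set.tsv", oncoprint)
        writer.stage("landscape")

        arrays = TrialArrays(dataset, features, feature_meta, config)
        arm_results, audit = screen_arms(None, arrays=arrays)
        writer.write_tsv("arm_biomarkers.tsv", arm_results)
        writer.write_tsv("audit.tsv", audit)
        writer.stage("screening")

        interactions = interaction_scan(arrays, screening=arm_results)
        writer.write_tsv("interactions.tsv", interactions)
        writer.stage("interaction")

        search = SearchProcedure(
            dataset, config, features=features, feature_meta=feature_meta
        )
        found = search.run()
        writer.stage("selection")

        adjust_subgroups(
            dataset, found, config, search=search,
            n_permutations=n_permutations, n_bootstrap=n_bootstrap,
        )
        writer.write_tsv("subgroups_adjusted.tsv", subgroups_table(found, config))
        writer.stage("resampling")

        km = km_coordinates(dataset, found, features=features)
        writer.write_tsv("km_curves.tsv", km)
        writer.stage("km")

        report = PipelineReport(
            config=config, enrichment=enrichment, modules=modules,
            feature_set=features, arm_results=arm_results, audit=audit,
            interactions=interactions, subgroups=found, km_curves=km,
        )
        writer.write_json(
            "report.json",
            {
                "version": __version__,
                "seed": config.seed,
                "config": config.to_dict(),
                "n_patients": dataset.n_patients,
                "n_features_tested": len(features.columns),
                "n_modules": len(modules),
                "n_arm_tests": int(len(arm_results)),
                "n_significant_arm_results": int(arm_results["significant"].sum())
                if len(arm_results) else 0,
                "n_interaction_tests": int(interactions["eligible"].sum())
                if len(interactions) else 0,
                "n_predictive": len(found),
                "subgroups": json.loads(
                    subgroups_table(found, config).to_json(orient="records")
                ),
            },
        )
        writer.finish()
        return report
    except Exception as exc:
        writer.finish(error=str(exc))
        raise


class _OutputWriter:
    def __init__(self, outdir: str | Path | None, manifest: list[str]) -> None:
        self.outdir = Path(outdir) if outdir is not None else None
        self.manifest = manifest
        if self.outdir is not None:
            self.outdir.mkdir(parents=True, exist_ok=True)

    def stage(self, name: str) -> None:
        self.manifest.append(f"stage:{name}")
        self._flush()

    def write_tsv(self, name: str, frame: pd.DataFrame) -> None:
        if self.outdir is None:
            return
        frame.to_csv(self.outdir / name, sep="\t", index=False, float_format="%.10g")
        self.manifest.append(f"file:{name}")
        self._flush()

    def write_json(self, name: str, payload: dict) -> None:
        if self.outdir is None:
            return
        (self.outdir / name).write_text(json.dumps(payload, indent=2, default=str))
        self.manifest.append(f"file:{name}")
        self._flush()

    def _flush(self, error: str | None = None) -> None:
        if self.outdir is None:
            return
        lines = list(self.manifest)
        if error:
            lines.append(f"error:{error}")
        (self.outdir / "MANIFEST").write_text("\n".join(lines) + "\n")

    def finish(self, error: str | None = None) -> None:
        self._flush(error)


def stability_cv(
    dataset: TrialDataset,
    config: Config,
    folds: int = 5,
    repeats: int = 5,
    top_k: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Repeated k-fold stability of the interaction ranking.

    For every training split (arm-stratified), the screening +
    interaction stages run with the relaxed CV interaction threshold
    (``config.cv_fdr_beta``); the ``top_k`` candidates by interaction
    p-value are tallied.  Resampling correction is skipped inside CV —
    the tally concerns identification stability, not effect sizes.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cv_config = config.replace(fdr_beta=config.cv_fdr_beta)

    modules = find_mutex_modules(dataset, cv_config)
    features, feature_meta = build_feature_set(dataset, modules, cv_config)
    T = dataset.clinical["treatment"].to_numpy()
    counts: dict[tuple[str, str, str, str], int] = {}

    for _rep in range(repeats):
        fold_of = np.empty(len(T), dtype=int)
        for arm in (0, 1):
            idx = np.flatnonzero(T == arm)
            idx = rng.permutation(idx)
            fold_of[idx] = np.arange(len(idx)) % folds
        for fold in range(folds):
            train = np.flatnonzero(fold_of != fold)
            sub = TrialDataset(
                clinical=dataset.clinical.iloc[train].reset_index(drop=True),
                alterations=dataset.alterations.iloc[train].reset_index(drop=True),
                feature_meta=dataset.feature_meta,
            )
            try:
                arrays = TrialArrays(sub, features.iloc[train].reset_index(
                    drop=True), feature_meta, cv_config)
                screening, _ = screen_arms(None, arrays=arrays)
                inter = interaction_scan(arrays, screening=screening)
            except ValueError:
                logger.warning("degenerate training fold skipped")
                continue
            ranked = inter[inter["eligible"] & inter["p_int"].notna()]
            ranked = ranked.nsmallest(top_k, "p_int")
            for _, row in ranked.iterrows():
                key = (row["feature"], row["scheme"], row["level"], row["endpoint"])
                counts[key] = counts.get(key, 0) + 1

    table = pd.DataFrame(
        [
            {"feature": k[0], "scheme": k[1], "level": k[2], "endpoint": k[3],
             "n_splits": v}
            for k, v in counts.items()
        ],
        columns=["feature", "scheme", "level", "endpoint", "n_splits"],
    )
    return table.sort_values(
        ["n_splits", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
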