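"""Multiplicity adjustment and winner's-curse correction for selected
subgroups.

Because subgroups are the end product of a staged search (arm screen ->
interaction test -> population selection), their naive treatment-effect
p-values and estimates are optimistically biased.  Two resampling
schemes address this:

Permutation adjustment
    Treatment labels are permuted U times across the whole cohort
    (arm sizes preserved, alterations and subtypes untouched).  The
    complete treatment-dependent search runs on every null dataset with
    identical thresholds; the smallest subgroup p-value found (or 1 when
    the null search returns nothing) gives the null distribution p^(u).
    The adjusted p-value of a found subgroup is the fraction of p^(u)
    at or below its naive p.  An optional add-one variant reports
    (1 + hits) / (1 + U).

Bootstrap bias correction
    Patients are resampled with replacement B times.  For each
    originally found (feature, level), the mutant-vs-wild-type selection
    is replayed on the resample, giving a population A^(b); the
    difference between the effect of A^(b) on the resample and on the
    original data estimates the selection bias.  The corrected log
    effect is the mean over b of gamma1(A) + gamma1(A^(b)) -
    gamma1^(b)(A^(b)), with the 2.5/97.5 percentiles of the same per-b
    quantity as the interval.  All arithmetic stays on the log scale;
    exponentiation happens only at reporting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import Config
from .data import TrialDataset
from .engine import TrialArrays
from .interaction import (
    MUTANT,
    WILDTYPE,
    SubgroupDefinition,
    SubgroupEffect,
    fit_cate,
    interaction_scan,
    select_between,
)
from .landscape import build_feature_set
from .screening import screen_arms

logger = logging.getLogger(__name__)


class SearchProcedure:
    """The full treatment-dependent subgroup search as a reusable operator.

    Encapsulates screening -> interaction -> selection with the config's
    thresholds so the identical strategy can be replayed on permuted or
    bootstrapped data.  With ``force_best=True`` the significance gates
    are bypassed and every eligible (endpoint, feature, level) candidate
    is scored, which is the variant used for calibration studies where a
    best subgroup must always exist.
    """

    def __init__(
        self,
        dataset: TrialDataset,
        config: Config,
        features: pd.DataFrame | None = None,
        feature_meta: pd.DataFrame | None = None,
        force_best: bool = False,
    ) -> None:
        if features is None:
            features, feature_meta = build_feature_set(dataset, [], config)
        elif feature_meta is None:
            from .data import default_feature_meta

            feature_meta = default_feature_meta(list(features.columns))
        self.config = config
        self.force_best = force_best
        self.arrays = TrialArrays(dataset, features, feature_meta, config)

    # -- search -------------------------------------------------------------

    def run(
        self,
        treatment: np.ndarray | None = None,
        arrays: TrialArrays | None = None,
    ) -> list[SubgroupEffect]:
        """Run the search; returns the selected subgroups (possibly empty)."""
        arrays = self.arrays if arrays is None else arrays
        if self.force_best:
            return self._forced_subgroups(arrays, treatment)
        screening, _ = screen_arms(None, arrays=arrays, treatment=treatment)
        inter = interaction_scan(arrays, treatment=treatment, screening=screening)
        found: list[SubgroupEffect] = []
        for _, row in inter[inter["predictive"]].iterrows():
            effect = None
            try:
                effect = _select_for_row(arrays, row, treatment)
            except Exception:  # pragma: no cover - defensive per-fit guard
                logger.exception("subgroup selection failed for %s", dict(row))
            if effect is not None:
                effect.extras["q_int"] = float(row["q_int"]) if np.isfinite(
                    row.get("q_int", np.nan)
                ) else np.nan
                effect.extras["p_int"] = float(row["p_int"])
                found.append(effect)
        return found

    def _forced_subgroups(
        self, arrays: TrialArrays, treatment: np.ndarray | None
    ) -> list[SubgroupEffect]:
        """Gate-free enumeration: the CATE-selected subgroup of every
        eligible (endpoint, feature, level) candidate.

        Avoids the tabular screening/interaction machinery entirely —
        this path runs inside permutation and bootstrap loops.
        """
        T = arrays.treatment if treatment is None else treatment
        n_min = self.config.n_min
        out: list[SubgroupEffect] = []
        for ep_name in arrays.endpoints:
            for ci, ctx in enumerate(arrays.contexts):
                rows = arrays.orders[(ep_name, ci)]
                arm1 = T[rows] == 1
                Xsub = arrays.X[rows]
                n_arm = np.array([(~arm1).sum(), arm1.sum()])
                mut_by_arm = np.vstack(
                    [Xsub[~arm1].sum(axis=0), Xsub[arm1].sum(axis=0)]
                )
                for j, feature in enumerate(arrays.feature_names):
                    n_mut = mut_by_arm[:, j]
                    n_wt = n_arm - n_mut
                    if not (
                        (n_mut >= n_min).all()
                        and (n_wt >= n_min).all()
                        and arrays.module_redistribution_ok(j, rows)
                    ):
                        continue
                    candidates = {}
                    for status in (MUTANT, WILDTYPE):
                        candidates[status] = fit_cate(
                            arrays,
                            SubgroupDefinition(
                                ep_name, feature, ctx.scheme, ctx.level, status
                            ),
                            treatment=T,
                        )
                    selected = select_between(
                        candidates[MUTANT], candidates[WILDTYPE]
                    )
                    if selected is not None and np.isfinite(selected.p_gamma):
                        out.append(selected)
        return out

    def best_null_p(self, treatment: np.ndarray) -> float:
        """Smallest subgroup p-value of the search on permuted labels
        (1.0 when the null search selects nothing)."""
        ps = [
            s.p_gamma
            for s in self.run(treatment=treatment)
            if np.isfinite(s.p_gamma)
        ]
        return min(ps) if ps else 1.0


def _select_for_row(
    arrays: TrialArrays, row: pd.Series, treatment: np.ndarray | None
) -> SubgroupEffect | None:
    candidates = {}
    for status in (MUTANT, WILDTYPE):
        definition = SubgroupDefinition(
            endpoint=row["endpoint"], feature=row["feature"],
            scheme=row["scheme"], level=row["level"], status=status,
        )
        candidates[status] = fit_cate(arrays, definition, treatment=treatment)
    return select_between(candidates[MUTANT], candidates[WILDTYPE])


def substreams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent, reproducible generators for permutation and bootstrap."""
    root = np.random.SeedSequence(seed)
    perm_seq, boot_seq = root.spawn(2)
    return np.random.default_rng(perm_seq), np.random.default_rng(boot_seq)


def permutation_adjust(
    search: SearchProcedure,
    found: list[SubgroupEffect],
    config: Config,
    rng: np.random.Generator | None = None,
    n_permutations: int | None = None,
) -> np.ndarray:
    """Permutation-adjusted p-values for the found subgroups.

    Fills ``p_adj`` on every element of ``found`` and returns the null
    distribution p^(u) for inspection.
    """
    U = int(
        config.n_permutations if n_permutations is None else n_permutations
    )
    if U < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = substreams(config.seed)[0]
    T = search.arrays.treatment
    null_p = np.empty(U)
    for u in range(U):
        permuted = rng.permutation(T)
        try:
            null_p[u] = search.best_null_p(permuted)
        except Exception:  # pragma: no cover - conservative fallback
            logger.exception("permutation %d failed; counted as p=1", u)
            null_p[u] = 1.0
    for subgroup in found:
        hits = int((null_p <= subgroup.p_gamma).sum())
        if config.add_one_permutation:
            subgroup.p_adj = (1 + hits) / (1 + U)
        else:
            subgroup.p_adj = hits / U
    return null_p


def bootstrap_bias_correct(
    search: SearchProcedure,
    found: list[SubgroupEffect],
    config: Config,
    rng: np.random.Generator | None = None,
    n_bootstrap: int | None = None,
) -> dict[int, np.ndarray]:
    """Bootstrap bias correction of the selected subgroup effects.

    Fills ``gamma_corrected``, ``ci_boot``, ``n_boot_used`` and
    ``unstable`` on every element of ``found``; returns the per-b
    corrected values keyed by position in ``found``.

    The selection replayed on each resample mirrors the search that
    produced ``found``: for the thresholded pipeline search the
    mutant-vs-wild-type choice is re-made per originally found
    (feature, level); for a ``force_best`` search (calibration studies)
    the entire best-subgroup selection across all eligible candidates
    is re-run on the resample.
    """
    B = int(config.n_bootstrap if n_bootstrap is None else n_bootstrap)
    if B < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if rng is None:
        rng = substreams(config.seed)[1]
    arrays = search.arrays
    n = arrays.n

    # gamma1 on the *original* data for both candidate populations of
    # every found (feature, level): reused across all B replicates.
    original: list[dict[str, float]] = []
    for subgroup in found:
        d = subgroup.definition
        both = {}
        for status in (MUTANT, WILDTYPE):
            eff = fit_cate(
                arrays,
                SubgroupDefinition(d.endpoint, d.feature, d.scheme, d.level, status),
            )
            both[status] = eff.gamma1 if eff is not None else np.nan
        original.append(both)

    original_cache: dict[tuple, float] = {}

    def _gamma_on_original(definition: SubgroupDefinition) -> float:
        key = (definition.endpoint, definition.feature, definition.scheme,
               definition.level, definition.status)
        if key not in original_cache:
            eff = fit_cate(arrays, definition)
            original_cache[key] = eff.gamma1 if eff is not None else np.nan
        return original_cache[key]

    draws: dict[int, list[float]] = {i: [] for i in range(len(found))}
    for _b in range(B):
        idx = rng.integers(0, n, size=n)
        arrays_b = arrays.resample(idx)
        if search.force_best:
            # Replay the whole best-subgroup selection on the resample.
            # Because that selection is two-sided (largest effect in
            # either direction), the optimism is measured on the
            # selection-aligned |effect| scale and mapped back to the
            # original subgroup's direction; the raw signed difference
            # would cancel across resamples with opposite-sign winners.
            subs_b = search.run(arrays=arrays_b)
            best_b = min(subs_b, key=lambda s: s.p_gamma) if subs_b else None
            for i, subgroup in enumerate(found):
                if best_b is None:
                    continue
                gamma_orig_ab = _gamma_on_original(best_b.definition)
                if not np.isfinite(gamma_orig_ab):
                    continue
                direction_b = 1.0 if best_b.gamma1 >= 0 else -1.0
                optimism = abs(best_b.gamma1) - direction_b * gamma_orig_ab
                direction_a = 1.0 if subgroup.gamma1 >= 0 else -1.0
                draws[i].append(subgroup.gamma1 - direction_a * optimism)
            continue
        for i, subgroup in enumerate(found):
            d = subgroup.definition
            candidates = {}
            for status in (MUTANT, WILDTYPE):
                candidates[status] = fit_cate(
                    arrays_b,
                    SubgroupDefinition(
                        d.endpoint, d.feature, d.scheme, d.level, status
                    ),
                )
            selected = select_between(candidates[MUTANT], candidates[WILDTYPE])
            if selected is None:
                continue  # degenerate replicate for this subgroup
            gamma_orig_ab = original[i][selected.definition.status]
            if not np.isfinite(gamma_orig_ab):
                continue
            draws[i].append(subgroup.gamma1 + gamma_orig_ab - selected.gamma1)

    out: dict[int, np.ndarray] = {}
    for i, subgroup in enumerate(found):
        values = np.asarray(draws[i], dtype=np.float64)
        out[i] = values
        subgroup.n_boot_used = len(values)
        subgroup.unstable = len(values) < 0.8 * B
        if len(values) == 0:
            continue
        subgroup.gamma_corrected = float(values.mean())
        subgroup.ci_boot = (
            float(np.quantile(values, 0.025)),
            float(np.quantile(values, 0.975)),
        )
    return out


def adjust_subgroups(
    dataset: TrialDataset,
    found: list[SubgroupEffect],
    config: Config,
    features: pd.DataFrame | None = None,
    feature_meta: pd.DataFrame | None = None,
    search: SearchProcedure | None = None,
    n_permutations: int | None = None,
    n_bootstrap: int | None = None,
) -> list[SubgroupEffect]:
    """Convenience wrapper: permutation adjust + bootstrap correct in-place."""
    if search is None:
        search = SearchProcedure(dataset, config, features, feature_meta)
    if not found:
        return found
    perm_rng, boot_rng = substreams(config.seed)
    permutation_adjust(
        search, found, config, rng=perm_rng, n_permutations=n_permutations
    )
    bootstrap_bias_correct(
        search, found, config, rng=boot_rng, n_bootstrap=n_bootstrap
    )
    return found
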