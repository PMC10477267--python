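"""Molecular landscape: subtype enrichment and mutual-exclusivity modules.

This stage looks at the alteration matrix and subtype labels only —
treatment assignment and outcomes play no role, so everything here can
be computed once and reused across treatment-label permutations.

Enrichment/depletion of each feature in each subtype level is scored
with one-sided hypergeometric tests, BH-corrected per (scheme,
direction) family.  Mutually exclusive feature groups are found with a
network-free greedy search: starting from each seed feature, the module
grows by the candidate that keeps the worst member-wise exclusivity
p-value (one-sided Fisher test of a member against the union of the
other members) smallest, while that score stays below a growth
threshold.  Externally derived groupings can always be supplied as
custom modules in the config instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Config
from .data import TrialDataset
from .fitters import bh_adjust


@dataclass
class EnrichmentRecord:
    feature: str
    scheme: str
    level: str
    direction: str  # "enriched" | "depleted"
    k: int  # feature-positive patients inside the level
    K: int  # feature-positive patients overall
    n_s: int  # level size
    N: int  # cohort size (with a label for this scheme)
    p: float
    q: float = np.nan
    significant: bool = False


@dataclass
class MutexModule:
    members: tuple[str, ...]
    union_count: int
    score: float  # worst member-wise exclusivity p

    @property
    def label(self) -> str:
        return ";".join(self.members)


def hypergeom_enrichment_p(k: int, K: int, n_s: int, N: int) -> float:
    """Upper-tail P(X >= k) for overlap of a size-K set and size-n_s set in N."""
    return float(stats.hypergeom.sf(k - 1, N, K, n_s))


def hypergeom_depletion_p(k: int, K: int, n_s: int, N: int) -> float:
    """Lower-tail P(X <= k)."""
    return float(stats.hypergeom.cdf(k, N, K, n_s))


def test_subtype_enrichment(
    dataset: TrialDataset, config: Config
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment/depletion of features across subtype levels.

    Only features altered in at least ``config.n_min`` labelled patients
    are tested.  BH correction is applied within each (scheme,
    direction) family; records with q below ``config.fdr_mol`` are
    flagged significant.
    """
    records: list[EnrichmentRecord] = []
    for scheme in config.subtype_schemes:
        labels = dataset.clinical[scheme]
        labelled = labels.notna().to_numpy()
        if labelled.sum() == 0:
            continue
        levels = dataset.subtype_levels(scheme)
        if len(levels) < 2:
            raise ValueError(
                f"scheme {scheme!r} has a single level; stratification is undefined"
            )
        N = int(labelled.sum())
        X = dataset.alterations.to_numpy()[labelled]
        lab = labels.to_numpy()[labelled]
        scheme_records: list[EnrichmentRecord] = []
        for j, feature in enumerate(dataset.feature_names):
            K = int(X[:, j].sum())
            if K < config.n_min:
                continue
            for level in levels:
                in_level = lab == level
                n_s = int(in_level.sum())
                k = int(X[in_level, j].sum())
                scheme_records.append(
                    EnrichmentRecord(
                        feature, scheme, str(level), "enriched", k, K, n_s, N,
                        hypergeom_enrichment_p(k, K, n_s, N),
                    )
                )
                scheme_records.append(
                    EnrichmentRecord(
                        feature, scheme, str(level), "depleted", k, K, n_s, N,
                        hypergeom_depletion_p(k, K, n_s, N),
                    )
                )
        for direction in ("enriched", "depleted"):
            family = [r for r in scheme_records if r.direction == direction]
            if not family:
                continue
            q = bh_adjust(np.array([r.p for r in family]))
            for rec, qv in zip(family, q):
                rec.q = float(qv)
                rec.significant = bool(qv < config.fdr_mol)
        records.extend(scheme_records)
    return records


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature, "scheme": r.scheme, "level": r.level,
                "direction": r.direction, "k": r.k, "K": r.K, "n_s": r.n_s,
                "N": r.N, "p": r.p, "q": r.q, "significant": r.significant,
            }
            for r in records
        ]
    )


def member_exclusivity_p(member: np.ndarray, others_union: np.ndarray) -> float:
    """One-sided Fisher p for under-representation of co-occurrence.

    Tests whether the member co-occurs with the union of the other
    module members less often than expected under independence
    (lower tail of the overlap count).
    """
    member = member.astype(bool)
    others_union = others_union.astype(bool)
    a = int((member & others_union).sum())
    b = int((member & ~others_union).sum())
    c = int((~member & others_union).sum())
    d = int((~member & ~others_union).sum())
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="less")[1])


def module_score(X: np.ndarray, member_idx: list[int]) -> float:
    """Worst (largest) member-wise exclusivity p over the module members."""
    worst = 0.0
    cols = X[:, member_idx].astype(bool)
    for i in range(len(member_idx)):
        others = np.delete(cols, i, axis=1).any(axis=1)
        worst = max(worst, member_exclusivity_p(cols[:, i], others))
    return worst


def find_mutex_modules(dataset: TrialDataset, config: Config) -> list[MutexModule]:
    """Greedy search for mutually exclusive feature modules.

    Seeds on every eligible feature (altered in >= n_min patients) and
    grows by the candidate minimising the module score; growth stops
    when no addition keeps the score below ``config.mutex_alpha``.
    Duplicate member sets are removed; output is sorted by score, then
    by descending union coverage, then label.
    """
    X = dataset.alterations.to_numpy()
    names = dataset.feature_names
    eligible = [j for j in range(X.shape[1]) if X[:, j].sum() >= config.n_min]
    if len(eligible) < 2:
        return []

    found: dict[frozenset[int], MutexModule] = {}
    for seed in eligible:
        members = [seed]
        score = 1.0
        while True:
            best: tuple[float, int, str, int] | None = None
            for cand in eligible:
                if cand in members:
                    continue
                trial = members + [cand]
                s = module_score(X, trial)
                if s >= config.mutex_alpha:
                    continue
                union = int(X[:, trial].any(axis=1).sum())
                # prefer smaller score, then larger coverage, then name
                key = (s, -union, names[cand], cand)
                if best is None or key < best:
                    best = key
            if best is None:
                break
            score = best[0]
            members.append(best[3])
        if len(members) >= 2:
            key = frozenset(members)
            if key not in found:
                union_count = int(X[:, members].any(axis=1).sum())
                found[key] = MutexModule(
                    members=tuple(sorted(names[j] for j in members)),
                    union_count=union_count,
                    score=module_score(X, members),
                )
    return sorted(found.values(), key=lambda m: (m.score, -m.union_count, m.label))


def modules_table(modules: list[MutexModule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"label": m.label, "members": m.label, "n_members": len(m.members),
             "union_count": m.union_count, "score": m.score}
            for m in modules
        ]
    )


def build_feature_set(
    dataset: TrialDataset,
    modules: list[MutexModule] | None,
    config: Config,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Augment the alteration matrix with module-union pseudo-features.

    Returns (feature matrix, feature metadata).  One binary column per
    mutual-exclusivity module (class MODULE) and per configured custom
    module (class CUSTOM) is appended; a union column is 1 iff any
    member is altered.  Original columns are retained unchanged.
    """
    feats = dataset.alterations.copy()
    meta = dataset.feature_meta.copy()
    meta["members"] = [""] * len(meta)

    def _add_union(label: str, members: list[str], cls: str) -> None:
        unknown = [m for m in members if m not in dataset.alterations.columns]
        if unknown:
            raise ValueError(f"module {label!r} references unknown features {unknown}")
        if label in feats.columns:
            return  # identical name already present (e.g. rediscovered custom)
        feats[label] = dataset.alterations[members].any(axis=1).astype(np.int8)
        meta.loc[label] = {"gene": label, "class": cls, "members": ";".join(members)}

    for module in modules or []:
        _add_union(module.label, list(module.members), "MODULE")
    for label, members in config.custom_modules.items():
        _add_union(label, list(members), "CUSTOM")
    return feats, meta
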