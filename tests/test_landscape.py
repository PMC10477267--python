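"""Enrichment arithmetic, mutual-exclusivity search, feature-set unions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trialmark.config import validate_config
from trialmark.data import TrialDataset
from trialmark import landscape
from trialmark.landscape import (
    build_feature_set,
    find_mutex_modules,
    hypergeom_depletion_p,
    hypergeom_enrichment_p,
    member_exclusivity_p,
    module_score,
)

subtype_enrichment_scan = landscape.test_subtype_enrichment


def brute_force_enrichment_p(k, K, n_s, N):
    """Exhaustive hypergeometric upper tail via binomial coefficients."""
    total = math.comb(N, n_s)
    return sum(
        math.comb(K, x) * math.comb(N - K, n_s - x)
        for x in range(k, min(K, n_s) + 1)
    ) / total


def make_dataset(X, labels=None, scheme="sub"):
    n = X.shape[0]
    clinical = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "treatment": np.arange(n) % 2,
            "os_time": np.linspace(1, 30, n),
            "os_event": np.ones(n, dtype=int),
        }
    )
    if labels is not None:
        clinical[scheme] = labels
    alterations = pd.DataFrame(
        X, columns=[f"F{j}" for j in range(X.shape[1])]
    ).astype(np.int8)
    return TrialDataset(clinical=clinical, alterations=alterations)


class TestHypergeometric:
    def test_small_exact_value(self):
        # C(3,3)*C(3,0)/C(6,3) = 1/20
        assert hypergeom_enrichment_p(3, 3, 3, 6) == pytest.approx(0.05, abs=1e-12)

    def test_feature_in_everyone_is_null(self):
        for n_s in (2, 5, 9):
            assert hypergeom_enrichment_p(n_s, 10, n_s, 10) == pytest.approx(1.0)

    def test_matches_brute_force_summation(self):
        assert hypergeom_enrichment_p(5, 50, 10, 100) == pytest.approx(
            brute_force_enrichment_p(5, 50, 10, 100), abs=1e-12
        )
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(4, 200))
            K = int(rng.integers(1, N))
            n_s = int(rng.integers(1, N))
            k = int(rng.integers(max(0, K + n_s - N), min(K, n_s) + 1))
            assert hypergeom_enrichment_p(k, K, n_s, N) == pytest.approx(
                brute_force_enrichment_p(k, K, n_s, N), abs=1e-12
            )

    def test_tails_overlap_at_k(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            N = int(rng.integers(4, 100))
            K = int(rng.integers(1, N))
            n_s = int(rng.integers(1, N))
            k = int(rng.integers(max(0, K + n_s - N), min(K, n_s) + 1))
            assert (
                hypergeom_enrichment_p(k, K, n_s, N)
                + hypergeom_depletion_p(k, K, n_s, N)
                >= 1.0 - 1e-12
            )


class TestEnrichmentScan:
    def test_records_and_bh_families(self):
        rng = np.random.default_rng(3)
        n = 120
        labels = np.where(rng.random(n) < 0.4, "A", "B")
        X = rng.binomial(1, 0.3, size=(n, 4))
        X[:, 0] = (labels == "A").astype(int)  # perfectly enriched in A
        ds = make_dataset(X, labels)
        cfg = validate_config({"subtype_schemes": ["sub"]})
        records = subtype_enrichment_scan(ds, cfg)
        rec = next(
            r for r in records
            if r.feature == "F0" and r.level == "A" and r.direction == "enriched"
        )
        assert rec.p < 1e-10 and rec.significant
        for r in records:
            assert 0 <= r.k <= min(r.K, r.n_s) <= r.N
            assert r.q >= r.p - 1e-15

    def test_low_frequency_features_not_tested(self):
        rng = np.random.default_rng(4)
        X = np.zeros((60, 2), dtype=int)
        X[:5, 0] = 1  # below n_min
        X[rng.random(60) < 0.5, 1] = 1
        ds = make_dataset(X, np.where(np.arange(60) < 30, "A", "B"))
        cfg = validate_config({"subtype_schemes": ["sub"]})
        features = {r.feature for r in subtype_enrichment_scan(ds, cfg)}
        assert features == {"F1"}

    def test_single_level_scheme_errors(self):
        X = np.ones((30, 1), dtype=int)
        ds = make_dataset(X, ["A"] * 30)
        cfg = validate_config({"subtype_schemes": ["sub"]})
        with pytest.raises(ValueError, match="single level"):
            subtype_enrichment_scan(ds, cfg)


class TestMutexModules:
    def test_disjoint_pair_found(self):
        X = np.zeros((100, 2), dtype=int)
        X[:30, 0] = 1
        X[30:65, 1] = 1
        ds = make_dataset(X)
        modules = find_mutex_modules(ds, validate_config({}))
        assert len(modules) == 1
        assert modules[0].members == ("F0", "F1")
        assert modules[0].union_count == 65

    def test_identical_columns_yield_nothing(self):
        X = np.zeros((100, 2), dtype=int)
        X[:15, 0] = 1
        X[:15, 1] = 1
        ds = make_dataset(X)
        assert find_mutex_modules(ds, validate_config({})) == []

    def test_agrees_with_exhaustive_subset_search(self):
        # three mutually disjoint features + one co-occurring with all
        rng = np.random.default_rng(7)
        n = 120
        X = np.zeros((n, 4), dtype=int)
        X[:35, 0] = 1
        X[35:70, 1] = 1
        X[70:100, 2] = 1
        X[:, 3] = (X[:, :3].sum(axis=1) > 0).astype(int)  # rides along all
        ds = make_dataset(X)
        cfg = validate_config({})
        modules = find_mutex_modules(ds, cfg)
        best = min(modules, key=lambda m: m.score)
        assert best.members == ("F0", "F1", "F2")

        # oracle: enumerate every subset of size 2..4 and keep those whose
        # worst member-wise exclusivity p stays below the growth threshold
        Xa = ds.alterations.to_numpy()
        admissible = {
            frozenset(c)
            for size in (2, 3, 4)
            for c in itertools.combinations(range(4), size)
            if module_score(Xa, list(c)) < cfg.mutex_alpha
        }
        assert frozenset({0, 1, 2}) in admissible
        for m in modules:
            idx = frozenset(
                ds.alterations.columns.get_loc(name) for name in m.members
            )
            assert idx in admissible

    def test_exclusivity_direction_never_cooccurrence(self, mcrc_dataset,
                                                      mcrc_config):
        modules = find_mutex_modules(mcrc_dataset, mcrc_config)
        X = mcrc_dataset.alterations
        n = len(X)
        for m in modules:
            cols = X[list(m.members)].to_numpy().astype(bool)
            for i in range(cols.shape[1]):
                others = np.delete(cols, i, axis=1).any(axis=1)
                observed = (cols[:, i] & others).sum()
                expected = cols[:, i].sum() * others.sum() / n
                assert observed <= expected + 1e-9

    def test_fewer_than_two_eligible_features(self):
        X = np.zeros((50, 2), dtype=int)
        X[:12, 0] = 1  # only one feature reaches n_min
        X[:3, 1] = 1
        ds = make_dataset(X)
        assert find_mutex_modules(ds, validate_config({})) == []


class TestFeatureSet:
    def test_union_is_boolean_or(self):
        X = np.array([[1, 0], [0, 1], [0, 0]], dtype=int)
        ds = make_dataset(X)
        from trialmark.landscape import MutexModule

        module = MutexModule(members=("F0", "F1"), union_count=2, score=0.01)
        feats, meta = build_feature_set(ds, [module], validate_config({}))
        assert feats["F0;F1"].tolist() == [1, 1, 0]
        assert meta.loc["F0;F1", "class"] == "MODULE"

    def test_custom_ras_module_column(self):
        X = np.array([[1, 0, 0], [0, 1, 1], [0, 0, 0]], dtype=int)
        ds = make_dataset(X)
        ds.alterations.columns = ["KRAS", "NRAS", "TP53"]
        ds.feature_meta = ds.feature_meta.rename(
            index={"F0": "KRAS", "F1": "NRAS", "F2": "TP53"}
        )
        cfg = validate_config({"custom_modules": {"RAS": ["KRAS", "NRAS"]}})
        feats, meta = build_feature_set(ds, [], cfg)
        assert feats["RAS"].tolist() == [1, 1, 0]
        assert meta.loc["RAS", "class"] == "CUSTOM"

    def test_empty_module_list_is_identity(self):
        X = np.array([[1, 0], [0, 1]], dtype=int)
        ds = make_dataset(X)
        feats, _ = build_feature_set(ds, [], validate_config({}))
        pd.testing.assert_frame_equal(feats, ds.alterations)

    def test_unknown_member_errors(self):
        X = np.array([[1, 0], [0, 1]], dtype=int)
        ds = make_dataset(X)
        cfg = validate_config({"custom_modules": {"M": ["F0", "NOPE"]}})
        with pytest.raises(ValueError, match="NOPE"):
            build_feature_set(ds, [], cfg)


def test_member_exclusivity_p_directionality():
    rng = np.random.default_rng(9)
    a = rng.binomial(1, 0.3, 200)
    # disjoint partner -> small p; identical partner -> p == 1
    disjoint = (1 - a) * rng.binomial(1, 0.4, 200)
    assert member_exclusivity_p(a, disjoint) < 0.01
    assert member_exclusivity_p(a, a) == pytest.approx(1.0)
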