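"""Interaction testing, CATE estimation and subgroup selection."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_binary_trial
from trialmark import interaction as interaction_mod
from trialmark.config import validate_config
from trialmark.data import TrialDataset
from trialmark.interaction import (
    SubgroupDefinition,
    estimate_cate,
    select_subgroup,
)
from trialmark.simulate import SimulationDesign, simulate_trial

interaction_scan_op = interaction_mod.test_interaction


def _orr_config(**kw):
    return validate_config({"endpoints": ["ORR"], "n_min": 5, **kw})


class TestInteractionModel:
    def test_arm_swap_symmetry_forces_null_interaction(self):
        # identical response pattern in both arms within each x stratum
        ds = make_binary_trial(
            {
                (1, 0): (10, 20), (1, 1): (10, 20),
                (0, 0): (8, 20), (0, 1): (8, 20),
            }
        )
        results = interaction_scan_op(ds, config=_orr_config())
        assert abs(results.iloc[0]["beta2"]) < 1e-6

    def test_planted_interaction_ranks_first(self):
        """A planted treatment-by-marker interaction (HR 0.4 in mutants of
        one subtype level, ~22% censoring) should top the p_int ranking.

        Bounds frozen from the generative-truth oracle at these study
        conditions: the exact (feature, level) ranks first in about 64%
        of replicates and the planted feature (counting attribution to
        the unstratified stratum) in about 80%.
        """
        exact_hits = feature_hits = 0
        n_reps = 50
        for rep in range(n_reps):
            design = SimulationDesign(
                n_patients=600,
                feature_frequencies={f"G{j}": 0.3 for j in range(8)},
                schemes={"sub": {"L": 0.4, "R": 0.6}},
                predictive_loghr={("G0", "sub", "L", "mutant"): float(np.log(0.4))},
                seed=500 + rep,
            )
            ds = simulate_trial(design)
            cfg = validate_config(
                {"endpoints": ["OS"], "subtype_schemes": ["sub"], "seed": 0}
            )
            results = interaction_scan_op(ds, config=cfg)
            fitted = results[results["p_int"].notna()]
            best = fitted.loc[fitted["p_int"].idxmin()]
            if best["feature"] == "G0":
                feature_hits += 1
                if best["level"] == "L":
                    exact_hits += 1
        assert exact_hits >= 25
        assert feature_hits >= 35

    def test_undersized_arm_population_ineligible(self):
        # 8 mutants in arm 0 -> below n_min for that arm
        ds = make_binary_trial(
            {
                (1, 0): (3, 8), (1, 1): (10, 25),
                (0, 0): (10, 30), (0, 1): (12, 30),
            }
        )
        results = interaction_scan_op(ds, config=_orr_config(n_min=10))
        assert not results.iloc[0]["eligible"]
        assert np.isnan(results.iloc[0]["beta2"])

    def test_treatment_main_effect_switch_changes_model(self):
        rng = np.random.default_rng(3)
        n = 400
        clinical = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "treatment": rng.integers(0, 2, n),
                "orr": rng.integers(0, 2, n),
            }
        )
        ds = TrialDataset(
            clinical=clinical,
            alterations=pd.DataFrame({"G1": rng.binomial(1, 0.4, n)}).astype(
                np.int8
            ),
        )
        a = interaction_scan_op(ds, config=_orr_config())
        b = interaction_scan_op(
            ds, config=_orr_config(include_treatment_main=True)
        )
        assert a.iloc[0]["beta2"] != pytest.approx(b.iloc[0]["beta2"], abs=1e-12)


class TestEstimateCate:
    def test_2x2_odds_ratio_closed_form(self):
        # subgroup: arm1 12/20 responders vs arm0 6/20 -> OR = (12*14)/(8*6)
        ds = make_binary_trial({(1, 1): (12, 20), (1, 0): (6, 20),
                                (0, 1): (5, 15), (0, 0): (5, 15)})
        eff = estimate_cate(
            ds,
            SubgroupDefinition("ORR", "G1", "none", "ALL", "mutant"),
            _orr_config(),
        )
        assert eff.gamma1 == pytest.approx(np.log(3.5), abs=1e-6)
        assert eff.effect_naive == pytest.approx(3.5, abs=1e-5)
        assert (eff.n0, eff.n1) == (20, 20)

    def test_contingency_or_matches_model_without_covariates(self, mcrc_dataset):
        cfg = validate_config({"endpoints": ["ORR"], "seed": 0})
        eff = estimate_cate(
            mcrc_dataset,
            SubgroupDefinition("ORR", "G01", "none", "ALL", "mutant"),
            cfg,
        )
        clin = mcrc_dataset.clinical
        mask = mcrc_dataset.alterations["G01"].to_numpy() == 1
        sub = clin[mask]
        a = ((sub["treatment"] == 1) & (sub["orr"] == 1)).sum()
        b = ((sub["treatment"] == 1) & (sub["orr"] == 0)).sum()
        c = ((sub["treatment"] == 0) & (sub["orr"] == 1)).sum()
        d = ((sub["treatment"] == 0) & (sub["orr"] == 0)).sum()
        assert eff.effect_naive == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_permuted_labels_centre_gamma_on_zero(self):
        ds = make_binary_trial({(1, 1): (12, 30), (1, 0): (11, 30),
                                (0, 1): (9, 30), (0, 0): (10, 30)})
        cfg = _orr_config()
        rng = np.random.default_rng(17)
        clin = ds.clinical
        gammas = []
        for _ in range(200):
            permuted = TrialDataset(
                clinical=clin.assign(
                    treatment=rng.permutation(clin["treatment"].to_numpy())
                ),
                alterations=ds.alterations,
            )
            eff = estimate_cate(
                permuted,
                SubgroupDefinition("ORR", "G1", "none", "ALL", "mutant"),
                cfg,
            )
            gammas.append(eff.gamma1)
        mean = np.mean(gammas)
        assert abs(mean) < 3 * np.std(gammas) / np.sqrt(len(gammas)) + 0.05

    def test_recovers_planted_subgroup_loghr(self):
        design = SimulationDesign(
            n_patients=1000,
            feature_frequencies={"G1": 1.0},  # subgroup = everyone
            predictive_loghr={("G1", "none", "ALL", "mutant"): -0.9},
            seed=77,
        )
        ds = simulate_trial(design)
        cfg = validate_config({"endpoints": ["OS"], "seed": 0})
        eff = estimate_cate(
            ds, SubgroupDefinition("OS", "G1", "none", "ALL", "mutant"), cfg
        )
        assert eff.gamma1 == pytest.approx(-0.9, abs=0.15)

    def test_degenerate_subgroup_raises_with_definition(self):
        ds = make_binary_trial({(1, 1): (20, 20), (1, 0): (20, 20),
                                (0, 1): (5, 15), (0, 0): (5, 15)})
        with pytest.raises(ValueError, match="mutant"):
            estimate_cate(
                ds,
                SubgroupDefinition("ORR", "G1", "none", "ALL", "mutant"),
                _orr_config(),
            )


class TestSelectSubgroup:
    @staticmethod
    def _interaction_row(**kw):
        row = {"endpoint": "ORR", "feature": "G1", "scheme": "none",
               "level": "ALL"}
        row.update(kw)
        return row

    def test_larger_absolute_estimate_wins(self):
        # strong effect in mutants, none in wild types
        ds = make_binary_trial({(1, 1): (16, 20), (1, 0): (6, 20),
                                (0, 1): (10, 25), (0, 0): (10, 25)})
        eff = select_subgroup(ds, self._interaction_row(), _orr_config())
        assert eff.definition.status == "mutant"
        assert abs(eff.companion_gamma1) < abs(eff.gamma1)

    def test_exact_tie_selects_mutant(self):
        # mirrored tables -> |gamma1| identical in both populations
        ds = make_binary_trial({(1, 1): (12, 20), (1, 0): (6, 20),
                                (0, 1): (12, 20), (0, 0): (6, 20)})
        eff = select_subgroup(ds, self._interaction_row(), _orr_config())
        assert eff.definition.status == "mutant"

    def test_wildtype_only_benefit_selected(self):
        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            design = SimulationDesign(
                n_patients=600,
                feature_frequencies={"G1": 0.35},
                predictive_loghr={("G1", "none", "ALL", "wildtype"): float(
                    np.log(0.5)
                )},
                seed=900 + rep,
            )
            ds = simulate_trial(design)
            cfg = validate_config({"endpoints": ["OS"], "seed": 0})
            eff = select_subgroup(
                ds, self._interaction_row(endpoint="OS"), cfg
            )
            if eff.definition.status == "wildtype":
                hits += 1
        assert hits >= 0.9 * n_reps

    def test_degenerate_population_falls_back_to_other(self):
        ds = make_binary_trial({(1, 1): (20, 20), (1, 0): (20, 20),
                                (0, 1): (9, 25), (0, 0): (15, 25)})
        eff = select_subgroup(ds, self._interaction_row(), _orr_config())
        assert eff.definition.status == "wildtype"
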