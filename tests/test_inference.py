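"""Mixed-model fitting, simulated CIs, and the variability screens."""

import numpy as np
import pandas as pd
import pytest

from sharkstress.inference import (
    TRAIT_NAMES,
    correlation_screen,
    cv_screen,
    effect_ci,
    fit_trait_model,
    lateralisation_tests,
    make_trait_table,
)
from sharkstress.synthetic import (
    StudyDesign,
    TraitGroundTruth,
    generate_design,
    generate_trait_table_arrays,
)


def _table(truths, seed=0, **design_kw):
    design = StudyDesign(seed=seed, **design_kw)
    roster = generate_design(design)
    cols = generate_trait_table_arrays(roster, truths, design, seed=seed)
    return make_trait_table(roster, cols), design, roster


class TestFitTraitModel:
    def test_noise_free_balanced_design_recovers_cell_contrasts(self):
        truth = TraitGroundTruth(
            name="t", intercept=100.0, temperature_ratio=1.2,
            pco2_ratio=1.1, interaction_ratio=1.05,
        )
        table, _, _ = _table([truth], sharks_per_group=(4, 4))
        fit = fit_trait_model(table, "t")
        expect = {
            "intercept": 100.0,
            "temperature": 20.0,
            "pco2": 10.0,
            "interaction": 5.0,
        }
        for term, val in zip(fit.terms, fit.params):
            assert val == pytest.approx(expect[term], abs=1e-6)

    def test_zero_group_variance_fits_near_boundary(self):
        # truth has no group effect; across seeds the REML estimate sits
        # at or near the zero boundary, flagged singular when it collapses
        gvars, singulars = [], []
        for seed in (0, 1, 7, 8):
            truth = TraitGroundTruth(name="t", intercept=50.0, residual_sd=1.0)
            table, _, _ = _table([truth], seed=seed)
            fit = fit_trait_model(table, "t")
            gvars.append(fit.group_var)
            singulars.append(fit.singular)
        assert max(gvars) < 1e-3  # group sd ~ 0 for these seeds
        assert all(singulars)

    def test_group_variance_estimated_when_present(self):
        truth = TraitGroundTruth(
            name="t", intercept=50.0, group_sd=8.0, residual_sd=2.0
        )
        table, _, _ = _table([truth], seed=4)
        fit = fit_trait_model(table, "t")
        assert fit.group_var > 10.0  # clearly non-zero

    def test_all_missing_trait_rejected(self):
        truth = TraitGroundTruth(name="t", intercept=1.0)
        table, _, _ = _table([truth])
        table["t"] = np.nan
        with pytest.raises(ValueError, match="non-missing"):
            fit_trait_model(table, "t")

    def test_missing_rows_dropped_complete_case(self):
        truth = TraitGroundTruth(name="t", intercept=10.0, residual_sd=1.0)
        table, _, _ = _table([truth], seed=5)
        table.loc[table.index[:4], "t"] = np.nan
        fit = fit_trait_model(table, "t")
        assert fit.n_obs == len(table) - 4

    def test_shift_equivariance_moves_only_intercept(self):
        truth = TraitGroundTruth(
            name="t", intercept=20.0, temperature_ratio=1.3, residual_sd=2.0,
            group_sd=1.0,
        )
        table, _, _ = _table([truth], seed=6)
        fit0 = fit_trait_model(table, "t")
        shifted = table.copy()
        shifted["t"] = shifted["t"] + 100.0
        fit1 = fit_trait_model(shifted, "t")
        assert fit1.params[0] == pytest.approx(fit0.params[0] + 100.0, abs=1e-4)
        assert fit1.params[1:] == pytest.approx(fit0.params[1:], abs=1e-4)


class TestEffectCI:
    def test_vanishing_covariance_collapses_to_point(self):
        truth = TraitGroundTruth(name="t", intercept=100.0, temperature_ratio=1.2)
        table, _, _ = _table([truth], sharks_per_group=(4, 4))
        fit = fit_trait_model(table, "t")
        fit.cov = np.zeros_like(fit.cov)
        for est in effect_ci(fit, seed=0):
            assert est.ci_low == pytest.approx(est.mean, abs=1e-9)
            assert est.ci_high == pytest.approx(est.mean, abs=1e-9)

    def test_interval_ordering_and_containment(self):
        truth = TraitGroundTruth(
            name="t", intercept=10.0, group_sd=2.0, residual_sd=3.0
        )
        table, _, _ = _table([truth], seed=7)
        fit = fit_trait_model(table, "t")
        for est in effect_ci(fit, seed=1):
            assert est.ci_low <= est.mean <= est.ci_high

    def test_large_effect_declared_significant(self):
        truth = TraitGroundTruth(
            name="t", intercept=100.0, temperature_ratio=2.0, residual_sd=1.0
        )
        table, _, _ = _table([truth], seed=8)
        fit = fit_trait_model(table, "t")
        ests = {e.term: e for e in effect_ci(fit, seed=2)}
        assert ests["temperature"].significant
        assert not ests["intercept"].significant  # intercept never flagged


class TestCvScreen:
    def test_constant_trait_zero_cv(self):
        truth = TraitGroundTruth(name="t", intercept=5.0)
        table, _, _ = _table([truth])
        assert cv_screen(table, ["t"])["cv_percent"].iloc[0] == 0.0

    def test_hand_value(self):
        table = pd.DataFrame(
            {
                "temperature": [28.0] * 3,
                "pco2": [650.0] * 3,
                "group_id": ["g"] * 3,
                "t": [10.0, 20.0, 30.0],
            }
        )
        assert cv_screen(table, ["t"])["cv_percent"].iloc[0] == pytest.approx(50.0)

    def test_scale_invariance(self):
        truth = TraitGroundTruth(name="t", intercept=50.0, residual_sd=5.0)
        table, _, _ = _table([truth], seed=9)
        cv1 = cv_screen(table, ["t"])["cv_percent"].iloc[0]
        table["t"] *= 7.0
        cv2 = cv_screen(table, ["t"])["cv_percent"].iloc[0]
        assert cv1 == pytest.approx(cv2, rel=1e-12)


class TestCorrelationScreen:
    def test_fifteen_traits_yield_105_pairs(self):
        truths = [
            TraitGroundTruth(name=n, intercept=float(i + 1), residual_sd=1.0)
            for i, n in enumerate(TRAIT_NAMES)
        ]
        table, _, _ = _table(truths, seed=10)
        screen = correlation_screen(table)
        assert len(screen) == 105

    def test_exact_linear_relation_r_one(self):
        truth = TraitGroundTruth(name="a", intercept=10.0, residual_sd=2.0)
        table, _, _ = _table([truth], seed=11)
        table["b"] = 2.0 * table["a"]
        screen = correlation_screen(table, traits=["a", "b"])
        assert screen["r"].iloc[0] == pytest.approx(1.0)
        assert bool(screen["strong"].iloc[0])

    def test_independent_traits_rarely_significant(self):
        truths = [
            TraitGroundTruth(name=f"t{i}", intercept=0.0, residual_sd=1.0)
            for i in range(15)
        ]
        table, _, _ = _table(truths, seed=12)
        screen = correlation_screen(table, traits=[f"t{i}" for i in range(15)])
        # Bonferroni alpha 0.0005 over 105 independent tests: family-wise
        # error ~5%, so essentially always zero hits in one dataset
        assert screen["significant"].sum() <= 1


class TestLateralisationTests:
    def test_identical_cells_give_zero_d(self):
        table, _, _ = _table(
            [TraitGroundTruth(name="lateralisation_relative", intercept=10.0)],
            seed=13,
        )
        table["lateralisation_absolute"] = table["lateralisation_relative"].abs()
        res = lateralisation_tests(table)
        assert np.allclose(res["ks"]["D"], 0.0)
        assert len(res["ks"]) == 6  # all pairs of 4 cells

    def test_disjoint_supports_give_d_one(self):
        table, _, _ = _table(
            [
                TraitGroundTruth(
                    name="lateralisation_relative",
                    intercept=0.0,
                    temperature_ratio=1.0,
                    residual_sd=1.0,
                )
            ],
            seed=14,
        )
        # shift one cell far away
        hi = (table["temperature"] == 31.0) & (table["pco2"] == 1050.0)
        table.loc[hi, "lateralisation_relative"] += 1e6
        table["lateralisation_absolute"] = table["lateralisation_relative"].abs()
        res = lateralisation_tests(table)
        assert res["ks"]["D"].max() == pytest.approx(1.0)

    def test_vs_ambient_mode_gives_three_pairs(self):
        table, _, _ = _table(
            [TraitGroundTruth(name="lateralisation_relative", intercept=0.0,
                              residual_sd=5.0)],
            seed=15,
        )
        table["lateralisation_absolute"] = table["lateralisation_relative"].abs()
        res = lateralisation_tests(table, mode="vs_ambient")
        assert len(res["ks"]) == 3
        assert "lateralisation_relative" in res["bartlett"]
        assert res["bartlett"]["lateralisation_relative"]["K2"] >= 0.0


class TestFitAllTraits:
    def test_tidy_table_covers_all_traits_and_terms(self):
        from sharkstress.inference import fit_all_traits

        truths = [
            TraitGroundTruth(name=n, intercept=float(i + 1), residual_sd=0.5)
            for i, n in enumerate(TRAIT_NAMES[:4])
        ]
        table, _, _ = _table(truths, seed=20)
        tidy = fit_all_traits(table, n_sim=200, seed=0)
        assert set(tidy["trait"]) == set(TRAIT_NAMES[:4])
        assert set(tidy["term"]) == {"intercept", "temperature", "pco2", "interaction"}
        assert (tidy["ci_low"] <= tidy["mean"]).all()
        assert (tidy["mean"] <= tidy["ci_high"]).all()
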