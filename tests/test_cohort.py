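"""Cohort statistics: prevalence, statin adjustment, eGFR, associations,
prognosis screen and the joint AAC x LDL model."""

import numpy as np
import pandas as pd
import pytest

import aacquant as aq
from aacquant.cohort import (STATIN_MULTIPLIER, adjust_ldl_statin,
                             biomarker_association, egfr_from_cystatin,
                             fit_lipid_imputer, joint_mi_model,
                             prevalence_summary, prognosis_screen, significant)
from aacquant.synthetic import CohortParams, DiseaseSpec


class TestPrevalence:
    def test_all_zero(self):
        s = prevalence_summary([0, 0, 0, 0])
        assert s.mean == 0 and s.frac_above_3 == 0

    def test_hand_computed_moments(self):
        s = prevalence_summary([1, 3])
        assert s.mean == 2.0
        assert s.sd == pytest.approx(np.sqrt(2))  # sample sd, n-1
        assert s.threshold == pytest.approx(2.0 + np.sqrt(2))

    def test_default_cohort_matches_calibrated_regime(self, default_cohort):
        s = prevalence_summary(default_cohort["aac_score"],
                               default_cohort["age_imaging"],
                               default_cohort["sex_female"])
        assert 0.09 <= s.frac_above_3 <= 0.13
        assert s.stratified is not None

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            prevalence_summary([1.0])


class TestStatinAdjustment:
    def test_non_users_unchanged_under_every_model(self, default_cohort):
        imputer = fit_lipid_imputer(default_cohort)
        for model in (1, 2, 3):
            adj_l, adj_t = adjust_ldl_statin(
                [3.0, 2.0], [1.5, 1.0], [0, 0], model=model, imputer=imputer,
                cohort=default_cohort.iloc[:2])
            assert np.allclose(adj_l, [3.0, 2.0])
            assert np.allclose(adj_t, [1.5, 1.0])

    def test_model1_adds_absolute_reduction(self):
        adj_l, adj_t = adjust_ldl_statin([3.0], [1.5], [1], model=1)
        assert adj_l[0] == pytest.approx(4.25)
        assert adj_t[0] == pytest.approx(2.75)

    def test_model2_scales_by_54_percent_increase(self):
        adj_l, _ = adjust_ldl_statin([2.0], [1.5], [1], model=2)
        assert adj_l[0] == pytest.approx(2.0 * STATIN_MULTIPLIER)
        assert adj_l[0] == pytest.approx(3.08, abs=0.01)
        # the multiplier inverts a 35% on-treatment reduction (~54% increase)
        assert round((STATIN_MULTIPLIER - 1) * 100) == 54

    def test_model3_requires_fitted_imputer(self, default_cohort):
        with pytest.raises(ValueError):
            adjust_ldl_statin([3.0], [1.5], [1], model=3)

    def test_model3_imputes_users_only(self, default_cohort):
        imputer = fit_lipid_imputer(default_cohort)
        df = default_cohort.head(200)
        adj_l, _ = adjust_ldl_statin(df["ldl"], df["trig"], df["statin_user"],
                                     model=3, imputer=imputer, cohort=df)
        users = df["statin_user"].to_numpy(bool)
        assert not np.allclose(adj_l[users], df["ldl"][users])
        assert np.allclose(adj_l[~users], df["ldl"][~users])

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            adjust_ldl_statin([3.0], [1.5], [1], model=9)


class TestEgfr:
    def test_healthy_reference_in_normal_range(self):
        egfr = egfr_from_cystatin(0.8, age=50, sex_female=True)
        assert 85 <= egfr <= 105

    def test_strictly_decreasing_in_cystatin(self):
        lo = egfr_from_cystatin(0.8, 50, False)
        hi = egfr_from_cystatin(1.6, 50, False)
        assert hi < lo

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            egfr_from_cystatin(0.0, 50, True)


class TestBiomarkerAssociation:
    def test_self_association_is_unity_unadjusted(self, default_cohort):
        df = default_cohort.assign(self_marker=default_cohort["aac_score"])
        est = biomarker_association(df, "self_marker", model=0)
        assert est.beta_per_sd == pytest.approx(1.0, abs=1e-9)

    def test_null_biomarker_type_i_control(self):
        """With zero simulated effect, the association is non-significant at
        the screen-wide threshold in nearly all replicates."""
        params = CohortParams(biomarker_betas={"cystatin_c": 0.0})
        hits = 0
        for rep in range(40):
            df = aq.generate_cohort(1500, params, seed=3000 + rep)
            est = biomarker_association(df, "cystatin_c", model=1)
            hits += est.p < 1.2e-4
        assert hits <= 2

    def test_smoking_effect_recovered(self):
        """An ever-smoking shift of +0.12 score units is recovered within the
        95% CI (expressed per SD of the smoking indicator, in AAC SDs)."""
        params = CohortParams(aac_smoke_prev_beta=0.12,
                              aac_smoke_curr_beta=0.12)
        df = aq.generate_cohort(20000, params, seed=77)
        est = biomarker_association(df, "smoking", model=1)
        ever = (df["smoking"] != "never").to_numpy(float)
        truth = 0.12 * ever.std() / df["aac_score"].std()
        assert est.ci_low <= truth <= est.ci_high
        assert est.beta_per_sd > 0

    def test_constant_biomarker_rejected(self, default_cohort):
        df = default_cohort.assign(flat=1.0)
        with pytest.raises(ValueError):
            biomarker_association(df, "flat")


class TestPrognosisScreen:
    def test_event_filter_excludes_sparse_disease(self, default_cohort):
        res = prognosis_screen(default_cohort,
                               diseases=["precerebral_stenosis"],
                               min_events=10 ** 6)
        assert res == []

    def test_bonferroni_correction_properties(self, default_cohort):
        res = prognosis_screen(default_cohort, model=1, min_events=25)
        m = len(res)
        for e in res:
            assert e.p_bonf == pytest.approx(min(1.0, e.p * m))
            assert e.p_bonf >= e.p
            assert e.ci_low <= e.hr <= e.ci_high
        assert {x.disease for x in significant(res)} <= \
            {e.disease for e in res if e.p < 0.05}

    def test_prior_history_exclusion_matches_brute_force(self, default_cohort):
        df = default_cohort
        disease = "myocardial_infarction"
        res = prognosis_screen(df, diseases=[disease], model=1,
                               index="baseline")[0]
        expected_n = int((df[f"{disease}_prior"] == 0).sum())
        assert res.n == expected_n

    def test_model2_accepts_confounders(self, default_cohort):
        res = prognosis_screen(default_cohort,
                               diseases=["myocardial_infarction"], model=2,
                               index="baseline")
        assert len(res) == 1 and res[0].hr > 0


class TestJointMiModel:
    def test_zero_effect_simulation_recovers_null(self):
        params = CohortParams(diseases=[
            DiseaseSpec("myocardial_infarction", aac_hr=1.0, ldl_hr=1.0,
                        trig_hr=1.0, baseline_rate=0.01)])
        df = aq.generate_cohort(6000, params, seed=99)
        res = joint_mi_model(df, statin_model=1)
        for term in ("aac", "ldl", "trig"):
            assert res[term].ci_low <= 1.0 <= res[term].ci_high

    def test_statin_adjustment_deconfounds_ldl(self):
        """With statin-masked LDL, the model-1 adjusted LDL hazard is closer
        to the simulated truth (1.4) than the unadjusted-LDL hazard."""
        df = aq.generate_cohort(20000, seed=101)
        raw = joint_mi_model(df, statin_model=None, index="baseline")
        adj = joint_mi_model(df, statin_model=1, index="baseline")
        truth = np.log(1.4)
        assert abs(np.log(adj["ldl"].hr) - truth) < \
            abs(np.log(raw["ldl"].hr) - truth)

    def test_non_user_subset_uses_measured_lipids(self, default_cohort):
        res = joint_mi_model(default_cohort, statin_model=1,
                             subset="non_users", index="baseline")
        assert res["subset"] == "non_users"
        assert res["aac"].n <= (default_cohort["statin_user"] == 0).sum()

    def test_model3_without_imputer_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            joint_mi_model(default_cohort, statin_model=3)
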