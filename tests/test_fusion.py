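"""CA19-9 coding, OR/AND fusion, specificity-targeted calibration, frozen
external evaluation and covariate diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pdacmicro as pm


class TestEncodeCa199:
    def test_threshold_semantics(self):
        levels = pd.Series([50.0, 10.0, 37.0, np.nan])
        codes = pm.encode_ca199(levels)
        # above 37 -> 1; below -> 0; exactly 37 -> 0; missing -> 0
        assert codes.tolist() == [1, 0, 0, 0]

    def test_negative_level_is_a_data_error(self):
        with pytest.raises(ValueError, match="negative"):
            pm.encode_ca199(pd.Series([-1.0]))


class TestCombinations:
    @staticmethod
    def _scores(n=40, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        return pd.Series(rng.random(n), index=idx)

    def test_or_is_additive(self):
        s = pd.Series({"a": 0.3}, name="score")
        c = pd.Series({"a": 1})
        assert pm.combine_or(s, c)["a"] == pytest.approx(1.3)

    def test_and_is_multiplicative_and_zero_code_kills_score(self):
        s = pd.Series({"a": 0.3, "b": 0.9})
        c = pd.Series({"a": 0, "b": 1})
        out = pm.combine_and(s, c)
        assert out["a"] == 0.0 and out["b"] == pytest.approx(0.9)

    def test_uninformative_code_leaves_or_ranking_and_auroc_unchanged(self):
        s = self._scores()
        y = np.arange(len(s)) % 2 == 0
        for const in (0, 1):
            fused = pm.combine_or(s, pd.Series(const, index=s.index))
            assert pm.roc_evaluate(fused.to_numpy(), y).auroc == pytest.approx(
                pm.roc_evaluate(s.to_numpy(), y).auroc)

    def test_all_one_codes_leave_and_identical(self):
        s = self._scores()
        fused = pm.combine_and(s, pd.Series(1, index=s.index))
        assert np.array_equal(fused.to_numpy(), s.to_numpy())

    def test_misaligned_sample_sets_rejected(self):
        s = pd.Series({"a": 0.5})
        with pytest.raises(ValueError, match="sample sets"):
            pm.combine_or(s, pd.Series({"b": 1}))

    def test_or_fusion_with_complementary_marker_beats_each_component(self):
        """A complementary binary marker lifts the combined AUROC above both
        the microbiome-only and marker-only AUROCs in simulation."""
        rng = np.random.default_rng(3)
        n = 400
        y = np.array([True] * 200 + [False] * 200)
        idx = pd.Index([f"s{i}" for i in range(n)])
        weak = pd.Series(
            np.clip(rng.normal(0.45 + 0.2 * y, 0.25), 0, 1), index=idx)
        marker = pm.simulate_ca199(pd.Series(y, index=idx), seed=4)["code"]
        auc_mic = pm.roc_evaluate(weak.to_numpy(), y).auroc
        auc_mark = pm.roc_evaluate(marker.to_numpy(), y).auroc
        auc_or = pm.roc_evaluate(pm.combine_or(weak, marker).to_numpy(), y).auroc
        assert auc_or >= max(auc_mic, auc_mark)

    def test_perfect_code_lifts_and_combination(self):
        rng = np.random.default_rng(5)
        n = 300
        y = np.array([True] * 150 + [False] * 150)
        idx = pd.Index([f"s{i}" for i in range(n)])
        weak = pd.Series(np.clip(rng.normal(0.45 + 0.15 * y, 0.3), 0, 1), index=idx)
        perfect = pd.Series(y.astype(int), index=idx)
        auc_and = pm.roc_evaluate(pm.combine_and(weak, perfect).to_numpy(), y).auroc
        assert auc_and >= pm.roc_evaluate(weak.to_numpy(), y).auroc


class TestCalibrateThreshold:
    def test_ten_distinct_controls_flag_exactly_one(self):
        scores = np.arange(10) / 10
        calib = pm.calibrate_threshold(scores, target_specificity=0.90)
        assert (scores > calib.threshold).sum() == 1
        assert calib.achieved_fpr_train == pytest.approx(0.10)

    def test_all_zero_controls_give_zero_threshold(self):
        calib = pm.calibrate_threshold(np.zeros(20))
        assert calib.threshold == 0.0
        assert calib.achieved_fpr_train == 0.0

    def test_fifty_controls_flag_five(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        calib = pm.calibrate_threshold(scores, target_specificity=0.90)
        assert (scores > calib.threshold).sum() == 5
        assert calib.achieved_fpr_train == pytest.approx(0.10)

    def test_threshold_monotone_in_target_specificity(self):
        rng = np.random.default_rng(9)
        scores = rng.random(60)
        thresholds = [pm.calibrate_threshold(scores, t).threshold
                      for t in (0.80, 0.85, 0.90, 0.95, 1.0)]
        assert np.all(np.diff(thresholds) >= 0)

    def test_few_controls_warn(self):
        with pytest.warns(UserWarning, match="controls"):
            pm.calibrate_threshold(np.arange(5) / 5)


class TestEvaluateExternal:
    def test_training_controls_reproduce_calibrated_fpr(
            self, ensemble_m1, model_table, default_cohort, case_labels):
        """Consistency: calibrating on the ensemble scores of the training
        controls and re-evaluating those controls returns the same rate."""
        ctrl_cols = model_table.columns[~case_labels]
        ctrl_scores = pm.predict_ensemble(ensemble_m1, model_table[ctrl_cols])
        calib = pm.calibrate_threshold(ctrl_scores.to_numpy())
        res = pm.evaluate_external(
            ensemble_m1, calib, model_table[ctrl_cols],
            default_cohort.metadata.loc[ctrl_cols])
        ctr = res[res.status == "CTR"]
        assert ctr.rate.item() == pytest.approx(calib.achieved_fpr_train)

    def test_external_scoring_invariant_to_sample_order_and_extra_features(
            self, ensemble_m1, model_table):
        perm = np.random.default_rng(1).permutation(model_table.shape[1])
        s1 = pm.predict_ensemble(ensemble_m1, model_table)
        s2 = pm.predict_ensemble(ensemble_m1, model_table.iloc[:, perm])
        assert np.array_equal(s1.loc[s2.index].to_numpy(), s2.to_numpy())
        extra = pd.concat([model_table, pd.DataFrame(
            0.01, index=["novel_a", "novel_b"], columns=model_table.columns)])
        s3 = pm.predict_ensemble(ensemble_m1, extra)
        assert np.array_equal(s1.to_numpy(), s3.to_numpy())

    def test_scoring_twice_is_byte_identical(self, ensemble_m2, model_table):
        a = pm.predict_ensemble(ensemble_m2, model_table)
        b = pm.predict_ensemble(ensemble_m2, model_table)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_no_overlapping_features_is_an_error(self, ensemble_m1):
        alien = pd.DataFrame(0.5, index=["x", "y"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="no features"):
            pm.predict_ensemble(ensemble_m1, alien)

    def test_rates_include_pooled_non_pdac_grouping(self, ensemble_m2, model_table,
                                                    default_spec):
        panel = pm.generate_external_panel(
            default_spec, [("mix", "other_disease", 10, 31)])
        calib = pm.ThresholdCalibration(0.5, 0.90, 0.1, 60)
        res = pm.evaluate_external(ensemble_m2, calib, panel[0].profile,
                                   panel[0].metadata)
        assert {"OTHER:mix", "NON_PDAC"} <= set(res.status)
        assert ((res.n_flagged <= res.n) & (res.rate.between(0, 1))).all()


class TestCovariateDiagnostics:
    @staticmethod
    def _metadata(n, rng):
        return pd.DataFrame({
            "age": rng.integers(40, 80, n),
            "sex": rng.choice(["F", "M"], n),
            "depth": rng.integers(10**6, 10**7, n),
        }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))

    def test_score_equal_to_age_gives_perfect_spearman(self):
        rng = np.random.default_rng(2)
        md = self._metadata(30, rng)
        scores = pd.Series(md["age"].astype(float), index=md.index)
        res = pm.score_covariate_diagnostics(scores, md)
        rho = res.loc[res.covariate == "age", "statistic"].item()
        assert rho == pytest.approx(1.0)

    def test_independent_scores_give_small_correlations(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(50):
            md = self._metadata(60, rng)
            scores = pd.Series(rng.random(60), index=md.index)
            res = pm.score_covariate_diagnostics(scores, md)
            ps.append(res.loc[res.covariate == "age", "p"].item())
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_table_matches_pearson_on_ranks_oracle(self):
        rng = np.random.default_rng(4)
        md = self._metadata(6, rng)
        scores = pd.Series(rng.random(6), index=md.index)
        res = pm.score_covariate_diagnostics(scores, md)
        rho = res.loc[res.covariate == "age", "statistic"].item()
        oracle = np.corrcoef(stats.rankdata(scores), stats.rankdata(md["age"]))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_covariate_reported_as_nan(self):
        rng = np.random.default_rng(5)
        md = self._metadata(20, rng)
        md["age"] = 60
        res = pm.score_covariate_diagnostics(
            pd.Series(rng.random(20), index=md.index), md)
        assert np.isnan(res.loc[res.covariate == "age", "statistic"].item())
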