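"""Cross-validation scheme, enrichment filter, ensemble training, leakage
guard and ROC evaluation."""

import numpy as np
import pandas as pd
import pytest

import pdacmicro as pm
from pdacmicro.classifier import fit_fold, DEFAULT_LAMBDA_GRID
from pdacmicro.univariate import single_feature_auroc

from conftest import random_profile


class TestCvScheme:
    def test_folds_partition_every_repeat(self):
        y = np.array([True] * 40 + [False] * 60)
        scheme = pm.make_cv_scheme(y, n_repeats=10, n_folds=10, seed=3)
        for r in range(10):
            sizes = np.bincount(scheme.assignment[r], minlength=10)
            assert sizes.sum() == 100 and np.all(sizes == 10)
        # each sample is tested exactly once per repeat = 10 times overall
        assert scheme.assignment.shape == (10, 100)

    def test_same_seed_reproduces_assignment(self):
        y = np.array([True] * 30 + [False] * 30)
        a = pm.make_cv_scheme(y, seed=5).assignment
        b = pm.make_cv_scheme(y, seed=5).assignment
        assert np.array_equal(a, b)

    def test_stratification_keeps_class_ratio_within_one_sample(self):
        y = np.array([True] * 40 + [False] * 60)
        scheme = pm.make_cv_scheme(y, n_repeats=5, n_folds=10, seed=1)
        for r in range(5):
            for k in range(10):
                n_case = y[scheme.assignment[r] == k].sum()
                assert 3 <= n_case <= 5  # global ratio 4 per fold of 10

    def test_class_smaller_than_fold_count_fails_fast(self):
        y = np.array([True] * 7 + [False] * 60)
        with pytest.raises(ValueError, match="per class"):
            pm.make_cv_scheme(y, n_folds=10, seed=0)


class TestEnrichmentFilter:
    def test_auroc_boundary_rule(self):
        # one feature just below 0.5, one just above, one exactly at 0.5
        y = np.array([True, True, False, False])
        t = pd.DataFrame(
            {"s1": [1, 4, 5], "s2": [2, 3, 6], "s3": [3, 2, 5.5], "s4": [4, 1, 6.5]},
            index=["down", "up", "mixed"],
        )
        aurocs = {f: single_feature_auroc(t.loc[f], y) for f in t.index}
        kept = pm.enrichment_filter(t, y)
        for f in t.index:
            assert (f in kept) == (aurocs[f] >= 0.5)

    def test_matches_brute_force_on_random_matrix(self, rng):
        t = random_profile(rng, n_features=40, n_samples=30)
        y = np.array([True] * 15 + [False] * 15)
        kept = set(pm.enrichment_filter(t, y))
        oracle = {f for f in t.index if single_feature_auroc(t.loc[f], y) >= 0.5}
        assert kept == oracle

    def test_all_anti_associated_features_give_degenerate_fold(self):
        # clr rows sum to zero per sample, so uniformly depleting every
        # feature cannot produce an empty enriched set; ties can.  This frozen
        # table has single-feature AUROC 4/9 for every clr feature.
        y = np.array([True] * 3 + [False] * 3)
        t = pd.DataFrame(
            [[2.001e-3, 3.001e-3, 2.001e-3, 2.001e-3, 3.001e-3, 1.001e-3],
             [3.001e-3, 1.0e-6, 1.001e-3, 2.001e-3, 2.001e-3, 1.0e-6],
             [2.001e-3, 2.001e-3, 3.001e-3, 2.001e-3, 3.001e-3, 3.001e-3]],
            index=["f0", "f1", "f2"], columns=[f"s{j}" for j in range(6)])
        fold = fit_fold(t, y, np.arange(6), "enrichment_constrained",
                        DEFAULT_LAMBDA_GRID, 1e-5, 0)
        assert fold.degenerate
        assert fold.coefficients == {}
        z = pm.apply_frozen(fold.norm_params, t)
        assert np.all(fold.predict(z) == 0.5)


class TestTrainEnsemble:
    def test_signal_cohort_reaches_high_auroc(self, ensemble_m1, case_labels):
        roc = pm.roc_evaluate(ensemble_m1.cv_scores.to_numpy(), case_labels)
        assert roc.auroc >= 0.85

    def test_model2_constraint_holds_on_every_fold(self, ensemble_m2):
        """Every nonzero coefficient of the enrichment-constrained variant
        belongs to that fold's enriched feature set."""
        for fold in ensemble_m2.fold_models:
            assert fold.enrichment_features is not None
            assert set(fold.coefficients) <= set(fold.enrichment_features)

    def test_robustness_and_scores_are_fractions(self, ensemble_m1):
        assert ensemble_m1.robustness.between(0, 1).all()
        assert ensemble_m1.cv_scores.between(0, 1).all()

    def test_single_separating_feature_has_full_robustness(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.array([True] * 30 + [False] * 30)
        t = random_profile(rng, n_features=10, n_samples=n, sparsity=0.0)
        t.columns = [f"s{j}" for j in range(n)]
        sep = np.where(y, 1e-2, 1e-5) * (1 + 0.01 * rng.random(n))
        t.loc["sp0"] = sep
        t /= t.sum(axis=0)
        ens = pm.train_ensemble(t, y, seed=2)
        assert ens.robustness["sp0"] == 1.0

    def test_cv_scores_invariant_to_sample_order(self, model_table, case_labels):
        scheme = pm.make_cv_scheme(case_labels, n_repeats=1, n_folds=10, seed=9,
                                   sample_ids=tuple(model_table.columns))
        perm = np.random.default_rng(0).permutation(model_table.shape[1])
        a = pm.train_ensemble(model_table, case_labels, scheme)
        b = pm.train_ensemble(model_table.iloc[:, perm], case_labels[perm], scheme)
        common = a.cv_scores.index
        assert np.allclose(a.cv_scores, b.cv_scores.loc[common])

    def test_non_binary_labels_rejected(self, model_table):
        with pytest.raises(ValueError):
            pm.train_ensemble(model_table, np.ones(model_table.shape[1], bool))

    def test_ensemble_json_round_trip_scores_identically(self, ensemble_m1,
                                                         model_table, tmp_path):
        ensemble_m1.to_json(tmp_path / "m.json")
        back = pm.TrainedEnsemble.from_json(tmp_path / "m.json")
        s1 = pm.predict_ensemble(ensemble_m1, model_table)
        s2 = pm.predict_ensemble(back, model_table)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())


class TestLeakageGuard:
    def test_tampering_with_test_samples_leaves_fold_fit_unchanged(
            self, model_table, case_labels):
        """Perturbing held-out samples must not move the fold's fitted
        normalization, enrichment set or coefficients (20 random folds)."""
        rng = np.random.default_rng(12)
        scheme = pm.make_cv_scheme(case_labels, n_repeats=2, n_folds=10, seed=4,
                                   sample_ids=tuple(model_table.columns))
        for _ in range(20):
            r = rng.integers(0, 2)
            k = rng.integers(0, 10)
            test_mask = scheme.assignment[r] == k
            train_idx = np.flatnonzero(~test_mask)
            variant = ["unconstrained", "enrichment_constrained"][rng.integers(0, 2)]
            tampered = model_table.copy()
            cols = tampered.columns[test_mask]
            tampered.loc[:, cols] = rng.random((tampered.shape[0], len(cols)))
            f1 = fit_fold(model_table, case_labels, train_idx, variant,
                          DEFAULT_LAMBDA_GRID, 1e-5, 7)
            f2 = fit_fold(tampered, case_labels, train_idx, variant,
                          DEFAULT_LAMBDA_GRID, 1e-5, 7)
            assert np.array_equal(f1.norm_params.centre, f2.norm_params.centre)
            assert np.array_equal(f1.norm_params.scale, f2.norm_params.scale)
            assert f1.enrichment_features == f2.enrichment_features
            assert f1.coefficients == f2.coefficients
            assert f1.intercept == f2.intercept


class TestRocEvaluate:
    def test_scores_equal_to_labels_give_perfect_auroc(self):
        y = np.array([1, 0, 1, 0, 1], bool)
        roc = pm.roc_evaluate(y.astype(float), y)
        assert roc.auroc == 1.0

    def test_constant_scores_give_chance_auroc(self):
        y = np.array([1, 0, 1, 0], bool)
        roc = pm.roc_evaluate(np.full(4, 0.3), y)
        assert roc.auroc == 0.5

    def test_curve_monotone_nondecreasing(self, rng):
        y = rng.random(50) < 0.4
        s = rng.random(50)
        roc = pm.roc_evaluate(s, y)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_auroc_matches_pair_counting_oracle(self, rng):
        from test_univariate import auroc_pair_oracle
        for _ in range(200):
            n = rng.integers(6, 15)
            y = np.zeros(n, bool)
            y[: rng.integers(2, n - 1)] = True
            s = np.round(rng.random(n), 1)
            assert pm.roc_evaluate(s, y).auroc == pytest.approx(
                auroc_pair_oracle(s, y), abs=1e-12)

    def test_delong_ci_close_to_bootstrap(self, rng):
        """Two independent uncertainty routes agree on a six-point toy set
        and on larger random sets."""
        y = np.array([1, 1, 1, 0, 0, 0] * 10, bool)
        s = rng.normal(loc=y.astype(float), scale=1.0)
        roc = pm.roc_evaluate(s, y)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, len(y), len(y))
            if y[idx].all() or not y[idx].any():
                continue
            boots.append(pm.single_feature_auroc(s[idx], y[idx]))
        lo, hi = np.quantile(boots, [0.025, 0.975])
        assert roc.ci95[0] == pytest.approx(lo, abs=0.03)
        assert roc.ci95[1] == pytest.approx(hi, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pm.roc_evaluate([0.1, 0.2], [True, True])
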