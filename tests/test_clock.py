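"""Aging clock fitting, reduction, panel selection and classification."""

import numpy as np
import pandas as pd
import pytest

from lifespanomics.clock import (
    ClockModel,
    broken_stick_fit,
    clock_design,
    fit_clock,
    fit_panel_classifier,
    reduce_clock,
    select_panel,
)
from lifespanomics.core_tables import FeatureTable, FeatureTableError, SampleMeta
from lifespanomics.differential import DEComparison
from lifespanomics.synthetic import CohortConfig, TrajectorySpec, simulate_cohort

FAST = dict(alpha_grid=(0.5, 0.9), train_fractions=(0.7,), cv=5, n_lambda=10)


def _cohort_with_perfect_feature(seed=101, n_noise=499):
    cfg = CohortConfig(seed=seed, zero_inflation=0.0)
    t, m, _ = simulate_cohort(cfg, [TrajectorySpec("null", n_features=n_noise)])
    # one feature whose log10 abundance is exactly proportional to age
    t.data.loc["perfect"] = np.exp(0.05 * m.age.to_numpy())
    return FeatureTable(t.data), m


class TestFitClock:
    def test_perfect_predictor_recovered(self):
        t, m = _cohort_with_perfect_feature()
        model = fit_clock(t, m, seed=1, offset=0.0, **FAST)
        assert model.mae_test < 1.0
        assert model.r_test > 0.99
        assert "perfect" in model.nonzero_features

    def test_deterministic_given_seed(self):
        t, m = _cohort_with_perfect_feature(n_noise=50)
        m1 = fit_clock(t, m, seed=7, **FAST)
        m2 = fit_clock(t, m, seed=7, **FAST)
        pd.testing.assert_series_equal(m1.coefficients, m2.coefficients)
        assert m1.lam == m2.lam and m1.alpha == m2.alpha

    def test_mae_recomputable_from_stored_predictions(self):
        t, m = _cohort_with_perfect_feature(n_noise=50)
        model = fit_clock(t, m, seed=3, **FAST)
        te = model.predictions[model.predictions["split"] == "test"]
        mae = np.abs(te["predicted_age"] - te["age"]).mean()
        assert mae == pytest.approx(model.mae_test, abs=1e-10)

    def test_predictions_invariant_to_affine_feature_rescaling(self):
        t, m = _cohort_with_perfect_feature(n_noise=30)
        model1 = fit_clock(t, m, seed=5, offset=0.0, **FAST)
        # x -> c_f * x is an affine map of log10 x (offset 0), absorbed by
        # per-fit standardization
        rng = np.random.default_rng(0)
        scales = pd.Series(rng.uniform(0.5, 20, t.n_features), index=t.feature_ids)
        t2 = FeatureTable(t.data.mul(scales, axis=0))
        model2 = fit_clock(t2, m, seed=5, offset=0.0, **FAST)
        p1 = model1.predictions["predicted_age"]
        p2 = model2.predictions["predicted_age"]
        assert np.allclose(p1, p2, atol=1e-4)

    def test_all_null_features_no_spurious_accuracy(self):
        cfg = CohortConfig(seed=103, zero_inflation=0.0)
        t, m, _ = simulate_cohort(cfg, [TrajectorySpec("null", n_features=200)])
        model = fit_clock(t, m, seed=2, alpha_grid=(0.5,), train_fractions=(0.67,),
                          cv=5, n_lambda=10)
        assert not np.isfinite(model.r_test) or abs(model.r_test) < 0.3

    def test_invalid_grids_rejected(self, cohort_normalized):
        t, m, _ = cohort_normalized
        with pytest.raises(FeatureTableError):
            fit_clock(t, m, alpha_grid=(1.5,))
        with pytest.raises(FeatureTableError):
            fit_clock(t, m, train_fractions=(0.3,))


class TestBrokenStick:
    def test_exact_piecewise_curve_knot_recovered(self):
        x = np.arange(2, 31, dtype=float)
        knot_true = 9.4
        y = np.where(x <= knot_true, 0.2 + 0.08 * x,
                     0.2 + 0.08 * knot_true + 0.002 * (x - knot_true))
        knot, _, _, low_conf = broken_stick_fit(x, y)
        assert abs(knot - knot_true) <= 0.5
        assert not low_conf

    def test_flat_curve_flagged_low_confidence(self):
        x = np.arange(2, 20, dtype=float)
        y = np.full_like(x, 0.5)
        _, _, _, low_conf = broken_stick_fit(x, y)
        assert low_conf

    def test_too_few_points_error(self):
        with pytest.raises(FeatureTableError):
            broken_stick_fit([1, 2, 3], [1, 2, 3])


class TestReduceClock:
    def test_breakpoint_with_five_informative_features(self):
        cfg = CohortConfig(seed=107, noise_sigma=0.2, zero_inflation=0.0)
        specs = [TrajectorySpec("linear", n_features=5, beta=0.02, prefix="info"),
                 TrajectorySpec("null", n_features=95)]
        t, m, _ = simulate_cohort(cfg, specs)
        model = fit_clock(t, m, seed=13, **FAST)
        reduced = reduce_clock(model, t, m, alpha_grid=(0.5,), seed=13,
                               cv=5, n_lambda=8, max_features=20)
        assert 3 <= reduced.breakpoint <= 8
        assert reduced.final_model.r_test > 0.8

    def test_requires_three_nonzero_coefficients(self, cohort_normalized):
        t, m, _ = cohort_normalized
        dummy = _dummy_clock(["f1", "f2"], [1.0, 0.0])
        with pytest.raises(FeatureTableError, match="nonzero"):
            reduce_clock(dummy, t, m)


def _dummy_clock(features, coefs):
    s = pd.Series(coefs, index=features, dtype=float)
    return ClockModel(
        feature_ids=list(features), coefficients=s, intercept=0.0,
        scaler_mean=s * 0, scaler_scale=s * 0 + 1, alpha=0.5, lam=0.1,
        train_fraction=0.8, mae_test=1.0, r_test=0.9,
        predictions=pd.DataFrame(columns=["age", "predicted_age", "split"]),
        selection_trace=pd.DataFrame(),
    )


class TestSelectPanel:
    def _inputs(self, de_dirs, betas, qs, clock_coefs):
        feats = [f"f{i}" for i in range(len(de_dirs))]
        de_tab = pd.DataFrame(
            {"log2fc": 0.0, "t_stat": 0.0, "p": 0.01, "q": 0.01,
             "direction": de_dirs}, index=pd.Index(feats, name="feature_id"))
        de = DEComparison("elderly", "young", de_tab)
        am = pd.DataFrame({"beta_age": betas, "q_age": qs}, index=feats)
        clock = _dummy_clock(feats, clock_coefs)
        return de, am, clock

    def test_feature_in_all_three_sets_selected(self):
        de, am, clock = self._inputs(
            ["up", "up", "ns"], [0.1, -0.1, 0.1], [0.01, 0.01, 0.01],
            [0.5, 0.5, 0.5])
        sel = select_panel(de, am, clock)
        assert sel.intersection == ["f0"]
        assert sel.pairwise_counts["elderly_up&clock"] == 2

    def test_disjoint_sets_empty_intersection(self):
        de, am, clock = self._inputs(
            ["up", "ns", "ns"], [-0.1, 0.1, -0.1], [0.01, 0.01, 0.01],
            [0.0, 0.0, 0.7])
        sel = select_panel(de, am, clock)
        assert sel.intersection == []
        assert sel.pairwise_counts["elderly_up&age_increasing"] == 0

    def test_truth_recovery_of_engineered_panel_features(self):
        cfg = CohortConfig(seed=109, noise_sigma=0.2, zero_inflation=0.0)
        specs = [TrajectorySpec("linear", n_features=10, beta=0.03, prefix="panel"),
                 TrajectorySpec("null", n_features=90)]
        t, m, truth = simulate_cohort(cfg, specs)
        from lifespanomics.differential import de_two_groups
        from lifespanomics.trajectory import fit_linear_age
        ages = m.age
        elderly = list(ages.index[ages >= 65])
        young = list(ages.index[ages < 40])
        de = de_two_groups(t, m, elderly, young)
        am = fit_linear_age(t, m)
        model = fit_clock(t, m, seed=17, **FAST)
        sel = select_panel(de, am, model)
        engineered = set(truth.index[truth["kind"] == "linear"])
        assert len(engineered & set(sel.intersection)) >= 8


class TestPanelClassifier:
    def _separable(self, n_per=30, seed=0, scale=5.0):
        rng = np.random.default_rng(seed)
        ages = np.concatenate([rng.uniform(66, 84, n_per), rng.uniform(20, 39, n_per)])
        sexes = list(rng.choice(["F", "M"], 2 * n_per))
        from lifespanomics.core_tables import assign_group
        meta = SampleMeta(pd.DataFrame({
            "age": ages, "sex": sexes,
            "group": [assign_group(a) for a in ages],
        }, index=[f"s{i}" for i in range(2 * n_per)]))
        marker = np.concatenate([np.full(n_per, scale), np.ones(n_per)])
        noise = rng.uniform(1, 2, size=(3, 2 * n_per))
        data = pd.DataFrame(np.vstack([marker, noise]),
                            index=["marker", "n1", "n2", "n3"],
                            columns=meta.sample_ids)
        return FeatureTable(data), meta

    def test_separable_classes_perfect_auc(self):
        t, meta = self._separable()
        res = fit_panel_classifier(["marker", "n1"], t, meta, k_folds=10, seed=1)
        assert res.cv_auc_mean == pytest.approx(1.0)

    def test_permuted_labels_chance_auc(self):
        t, meta = self._separable(n_per=40)
        rng = np.random.default_rng(7)
        perm_ages = rng.permutation(meta.table["age"].to_numpy())
        from lifespanomics.core_tables import assign_group
        meta_perm = SampleMeta(meta.table.assign(
            age=perm_ages, group=[assign_group(a) for a in perm_ages]))
        res = fit_panel_classifier(["marker", "n1"], t, meta_perm, k_folds=10, seed=7)
        assert 0.35 <= res.cv_auc_mean <= 0.65

    def test_auc_equals_mann_whitney_pairwise_statistic(self):
        # tied 12-sample fixture: AUC from ROC equals the normalized
        # pairwise-comparison count (ties counted half)
        from sklearn.metrics import roc_auc_score
        scores = np.array([0.1, 0.4, 0.4, 0.8, 0.2, 0.4, 0.9, 0.3, 0.4, 0.7, 0.1, 0.6])
        labels = np.array([0, 0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = sum((1.0 if p > q else 0.5 if p == q else 0.0)
                    for p in pos for q in neg)
        oracle = pairs / (len(pos) * len(neg))
        assert roc_auc_score(labels, scores) == pytest.approx(oracle, abs=1e-12)

    def test_fold_reduction_warns_on_small_class(self):
        t, meta = self._separable(n_per=4)
        with pytest.warns(UserWarning, match="reducing folds"):
            res = fit_panel_classifier(["marker"], t, meta, k_folds=10, seed=0)
        assert res.n_folds == 4
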