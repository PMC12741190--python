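"""Linear age models, LOESS trajectories, clustering, DE-SWAN."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from lifespanomics import total_sum_normalize
from lifespanomics.core_tables import FeatureTable, FeatureTableError, SampleMeta
from lifespanomics.differential import bh_adjust
from lifespanomics.synthetic import CohortConfig, TrajectorySpec, simulate_cohort
from lifespanomics.trajectory import (
    cluster_trajectories,
    deswan,
    fit_linear_age,
    fit_loess_trajectories,
)


def _meta(ages, sexes=None):
    from lifespanomics.core_tables import assign_group
    sexes = sexes or ["F", "M"] * (len(ages) // 2 + 1)
    return SampleMeta(pd.DataFrame({
        "age": ages, "sex": sexes[: len(ages)],
        "group": [assign_group(a) for a in ages],
    }, index=[f"s{i}" for i in range(len(ages))]))


class TestLinearAgeModel:
    def test_noiseless_slope_recovered(self):
        ages = [0.0, 5, 10, 20, 30, 40, 50, 60, 70, 80]
        m = _meta(ages)
        # log10 abundance = 2 + 0.5 * age exactly -> abundance = 10**(...)
        y = 10.0 ** (2 + 0.5 * np.array(ages))
        t = FeatureTable(pd.DataFrame([y], index=["f"], columns=m.sample_ids))
        res = fit_linear_age(t, m, offset=0.0)
        assert res.loc["f", "beta_age"] == pytest.approx(0.5, abs=1e-8)

    def test_matches_normal_equations_on_12_sample_fixture(self):
        rng = np.random.default_rng(2)
        ages = list(rng.uniform(1, 80, 12))
        sexes = list(rng.choice(["F", "M"], 12))
        m = _meta(ages, sexes)
        data = pd.DataFrame(rng.uniform(1, 50, size=(5, 12)),
                            index=[f"f{i}" for i in range(5)],
                            columns=m.sample_ids)
        t = FeatureTable(data)
        res = fit_linear_age(t, m, offset=1.0)
        X = np.column_stack([np.ones(12), ages,
                             (np.array(sexes) == "M").astype(float)])
        for f in t.feature_ids:
            y = np.log10(data.loc[f].to_numpy() + 1.0)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert res.loc[f, "alpha_hat"] == pytest.approx(beta[0], abs=1e-9)
            assert res.loc[f, "beta_age"] == pytest.approx(beta[1], abs=1e-9)
            assert res.loc[f, "beta_sex"] == pytest.approx(beta[2], abs=1e-9)

    def test_type_one_error_calibrated_on_null(self, null_cohort):
        t, m, _ = null_cohort
        res = fit_linear_age(total_sum_normalize(t), m)
        reject = (res["p_age"] < 0.05).mean()
        assert 0.035 <= reject <= 0.065

    def test_slope_recovery_small_bias(self):
        betas = [0.005, -0.005, 0.01, -0.01, 0.02, -0.02]
        specs = [TrajectorySpec("linear", n_features=34, beta=b, prefix=f"b{i}")
                 for i, b in enumerate(betas)]
        cfg = CohortConfig(seed=41, noise_sigma=0.2, zero_inflation=0.0)
        t, m, truth = simulate_cohort(cfg, specs)
        res = fit_linear_age(t, m, offset=0.0)  # no zeros: exact log scale
        # model works on log10 scale; truth betas are natural log per year
        est = res["beta_age"] * np.log(10)
        for b in betas:
            members = truth.index[truth["beta"] == b]
            err = (est[members] - b).mean()
            assert abs(err) < 0.1 * abs(b)

    def test_single_sex_errors_when_covariate_requested(self):
        m = _meta([1, 5, 20, 40], ["F", "F", "F", "F"])
        t = FeatureTable(pd.DataFrame(np.ones((2, 4)) + np.arange(4),
                                      index=["a", "b"], columns=m.sample_ids))
        with pytest.raises(FeatureTableError, match="sex"):
            fit_linear_age(t, m)


class TestLoess:
    def test_linear_feature_reproduced(self):
        ages = np.linspace(0, 80, 40)
        m = _meta(list(ages))
        y = 10.0 ** (1 + 0.02 * ages)
        t = FeatureTable(pd.DataFrame([y], index=["f"], columns=m.sample_ids))
        res = fit_loess_trajectories(t, m, span=0.5, offset=0.0)
        expected = 1 + 0.02 * res.grid
        assert np.max(np.abs(res.curves.loc["f"].to_numpy() - expected)) < 1e-6

    def test_peak_location_recovered(self):
        cfg = CohortConfig(seed=43, noise_sigma=0.1, zero_inflation=0.0)
        specs = [TrajectorySpec("peak", n_features=5, peak_age=20, peak_width=6,
                                peak_height=1.0, prefix="pk"),
                 TrajectorySpec("null", n_features=100)]
        t, m, truth = simulate_cohort(cfg, specs)
        res = fit_loess_trajectories(total_sum_normalize(t), m, span=0.4)
        for f in truth.index[truth["kind"] == "peak"]:
            curve = res.curves.loc[f]
            argmax = float(curve.idxmax())
            assert abs(argmax - 20) <= 3

    def test_constant_feature_flagged(self):
        ages = list(np.linspace(1, 80, 20))
        m = _meta(ages)
        data = pd.DataFrame(
            [np.ones(20), 10.0 ** (0.01 * np.array(ages))],
            index=["flat", "rising"], columns=m.sample_ids,
        )
        res = fit_loess_trajectories(FeatureTable(data), m, offset=0.0)
        assert res.excluded == ["flat"]
        assert "flat" not in res.standardized.index

    def test_too_small_span_suggests_increase(self):
        ages = list(np.linspace(1, 80, 10))
        m = _meta(ages)
        t = FeatureTable(pd.DataFrame(np.ones((1, 10)) * 2, index=["f"],
                                      columns=m.sample_ids))
        with pytest.raises(FeatureTableError, match="span"):
            fit_loess_trajectories(t, m, span=0.05)


class TestClustering:
    def _antithetic_curves(self):
        cfg = CohortConfig(seed=47, noise_sigma=0.1, zero_inflation=0.0)
        specs = [
            TrajectorySpec("peak", n_features=20, peak_age=30, peak_width=8,
                           peak_height=1.0, prefix="up"),
            TrajectorySpec("peak", n_features=20, peak_age=30, peak_width=8,
                           peak_height=-1.0, prefix="down"),
        ]
        t, m, truth = simulate_cohort(cfg, specs)
        res = fit_loess_trajectories(total_sum_normalize(t), m, span=0.5)
        return res, truth

    def test_two_archetypes_perfect_rand_index(self):
        res, truth = self._antithetic_curves()
        clusters = cluster_trajectories(res.standardized, k=2)
        labels = {}
        for c in clusters:
            for f in c.member_features:
                labels[f] = c.cluster_id
        pred = [labels[f] for f in res.standardized.index]
        true = [truth.loc[f, "peak_height"] > 0 for f in res.standardized.index]
        assert adjusted_rand_score(true, pred) == 1.0

    def test_assignment_invariant_to_feature_order(self):
        res, _ = self._antithetic_curves()
        c1 = cluster_trajectories(res.standardized, k=2)
        shuffled = res.standardized.sample(frac=1, random_state=0)
        c2 = cluster_trajectories(shuffled, k=2)
        sets1 = sorted(frozenset(c.member_features) for c in c1)
        sets2 = sorted(frozenset(c.member_features) for c in c2)
        assert sets1 == sets2

    def test_identical_curves_error(self):
        curves = pd.DataFrame(np.ones((5, 10)), index=[f"f{i}" for i in range(5)])
        with pytest.raises(FeatureTableError, match="cluster"):
            cluster_trajectories(curves, k=3)

    def test_k_larger_than_n_error(self):
        curves = pd.DataFrame(np.eye(3))
        with pytest.raises(FeatureTableError, match="k"):
            cluster_trajectories(curves, k=5)


def deswan_oracle(t, m, centers, window, q_thresh):
    """Independent per-feature two-stratum regression count, feature by feature."""
    import statsmodels.api as sm
    from lifespanomics.core_tables import log_transform

    ages = m.age.to_numpy(dtype=float)
    male = (m.sex == "M").to_numpy(dtype=float)
    Y = log_transform(t).to_numpy()
    counts = {}
    for c in centers:
        young = (ages >= c - window / 2) & (ages < c)
        old = (ages > c) & (ages <= c + window / 2)
        if young.sum() < 3 or old.sum() < 3:
            continue
        sel = young | old
        cols = [np.ones(sel.sum()), old[sel].astype(float)]
        if len(np.unique(male[sel])) > 1:
            cols.append(male[sel])
        X = np.column_stack(cols)
        ps = []
        for i in range(Y.shape[0]):
            fit = sm.OLS(Y[i, sel], X).fit()
            ps.append(fit.pvalues[1])
        q = bh_adjust(np.array(ps))
        counts[c] = int((q < q_thresh).sum())
    return counts


class TestDeswan:
    def test_counts_equal_brute_force_oracle(self):
        cfg = CohortConfig(seed=53, zero_inflation=0.0)
        specs = [TrajectorySpec("step", n_features=30, step_age=40, step_delta=0.5),
                 TrajectorySpec("null", n_features=70)]
        t, m, _ = simulate_cohort(cfg, specs)
        tn = total_sum_normalize(t)
        centers = [20.0, 30.0, 40.0, 50.0, 60.0]
        curve = deswan(tn, m, centers=centers, window=20)
        oracle = deswan_oracle(tn, m, centers, 20, 0.05)
        got = dict(zip(curve.centers, curve.n_sig))
        assert got == oracle

    def test_step_features_peak_near_forty(self):
        cfg = CohortConfig(seed=59, noise_sigma=0.2, zero_inflation=0.0)
        specs = [TrajectorySpec("step", n_features=50, step_age=40, step_delta=0.5),
                 TrajectorySpec("null", n_features=100)]
        t, m, _ = simulate_cohort(cfg, specs)
        curve = deswan(total_sum_normalize(t), m, window=20)
        global_peak = curve.centers[np.argmax(curve.n_sig)]
        assert abs(global_peak - 40) <= 5
        assert any(abs(p - 40) <= 5 for p in curve.peaks)

    def test_null_features_flat_curve(self):
        cfg = CohortConfig(seed=61, zero_inflation=0.0)
        t, m, _ = simulate_cohort(cfg, [TrajectorySpec("null", n_features=200)])
        curve = deswan(total_sum_normalize(t), m, window=20)
        assert curve.n_sig.max() <= 2

    def test_single_center_type_one_calibration(self, null_cohort):
        t, m, _ = null_cohort
        tn = total_sum_normalize(t)
        curve = deswan(tn, m, centers=[40.0], window=20, keep_q=True)
        p = curve.per_center_p[40.0]
        reject = (p < 0.05).mean()
        assert 0.035 <= reject <= 0.065

    def test_center_age_excluded_from_both_strata(self):
        ages = [30, 32, 34, 36, 38, 40, 42, 44, 46, 48, 50]
        m = _meta([float(a) for a in ages])
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.uniform(1, 5, size=(10, len(ages))),
                            index=[f"f{i}" for i in range(10)],
                            columns=m.sample_ids)
        t = FeatureTable(data)
        full = deswan(t, m, centers=[40.0], window=20, min_side=3)
        # dropping the age-40 sample must not change the result
        keep = [s for s, a in zip(m.sample_ids, ages) if a != 40]
        t2 = t.subset_samples(keep)
        m2 = SampleMeta(m.table.loc[keep])
        reduced = deswan(t2, m2, centers=[40.0], window=20, min_side=3)
        assert full.n_sig.tolist() == reduced.n_sig.tolist()

    def test_signal_monotonicity_in_step_delta(self):
        def peak_count(delta):
            cfg = CohortConfig(seed=67, noise_sigma=0.2, zero_inflation=0.0)
            specs = [TrajectorySpec("step", n_features=40, step_age=40,
                                    step_delta=delta),
                     TrajectorySpec("null", n_features=60)]
            t, m, _ = simulate_cohort(cfg, specs)
            curve = deswan(total_sum_normalize(t), m, centers=[40.0], window=20)
            return curve.n_sig[0]

        assert peak_count(0.6) >= peak_count(0.3)

    def test_underpopulated_centers_recorded(self):
        cfg = CohortConfig(seed=71)
        t, m, _ = simulate_cohort(cfg, [TrajectorySpec("null", n_features=5)])
        with pytest.warns(UserWarning, match="skipped"):
            curve = deswan(total_sum_normalize(t), m, centers=[1.0, 40.0], window=4)
        skipped_centers = [c for c, _ in curve.skipped]
        assert len(skipped_centers) >= 1
        assert set(curve.centers).isdisjoint(skipped_centers)
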