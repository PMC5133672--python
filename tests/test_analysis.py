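"""Statistical stack: EMGM, clustering error, SVM, ROC, gating, LOD, projections."""

import numpy as np
import pandas as pd
import pytest

from defcyto import (
    GateSpec,
    apply_gate,
    backward_eliminate,
    clustering_error,
    deformability_size_ratio,
    emgm,
    fit_quantile_gate,
    fit_stiffness_calibration,
    lda_project,
    limit_of_detection,
    pca_project,
    predict_fractions,
    roc,
    similarity_matrix,
    spike_response,
    standardize,
    train_svm,
)


def two_gaussians(n_per, separation, p=2, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, sd, size=(n_per, p))
    x2 = rng.normal(0, sd, size=(n_per, p))
    x2[:, 0] += separation
    x = np.vstack([x1, x2])
    y = np.r_[np.zeros(n_per, int), np.ones(n_per, int)]
    return x, y


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(5, 3, size=(200, 4)),
                             columns=list("abcd"))
        std = standardize(table)
        assert np.allclose(std.values.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(std.values.std(axis=0), 1, atol=1e-9)

    def test_constant_column_excluded(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            std = standardize(table)
        assert std.feature_names == ["a"] and std.dropped == ["b"]

    def test_test_data_uses_train_stats(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame({"a": rng.normal(0, 1, 100)})
        test = pd.DataFrame({"a": rng.normal(5, 2, 50)})
        std = standardize(train)
        z = std.transform(test)
        own_z = (test["a"] - test["a"].mean()) / test["a"].std(ddof=0)
        # direct recomputation oracle: train-referenced z-scores differ
        # from the test table's own z-scores
        expected = (test["a"].to_numpy() - std.center[0]) / std.scale[0]
        assert np.allclose(z.ravel(), expected)
        assert not np.allclose(z.ravel(), own_z.to_numpy())


class TestEMGM:
    def test_separated_clusters_recovered(self):
        x, y = two_gaussians(1000, separation=10.0, seed=2)
        sol = emgm(x, k=2, seed=0)
        agreement = max(np.mean(sol.labels == y), np.mean(sol.labels != y))
        assert agreement >= 0.99
        means = sol.means[np.argsort(sol.means[:, 0])]
        se = 1.0 / np.sqrt(1000)
        assert abs(means[0, 0] - 0.0) < 3 * se
        assert abs(means[1, 0] - 10.0) < 3 * se

    def test_k1_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2, size=(500, 3))
        sol = emgm(x, k=1, seed=0)
        assert np.allclose(sol.means[0], x.mean(axis=0), atol=1e-8)
        expected = np.cov(x.T, bias=True) + 1e-6 * np.eye(3)  # + ridge
        assert np.allclose(sol.covariances[0], expected, atol=1e-8)

    def test_log_likelihood_monotone(self):
        x, _ = two_gaussians(300, separation=2.0, seed=4)
        sol = emgm(x, k=2, seed=1)
        ll = sol.log_likelihood_trace
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            emgm(np.zeros((5, 3)), k=2)


class TestClusteringError:
    def test_zero_within_scatter(self):
        x = np.array([[0.0, 0], [0, 0], [5, 0], [5, 0]])
        assert clustering_error(x, [0, 0, 1, 1]) == 0.0

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, size=(400, 6))
        y = rng.integers(0, 2, 400)
        # brute-force evaluation by an independent code path (plain loops)
        m = {c: x[y == c].mean(axis=0) for c in (0, 1)}
        within = sum(float(np.sum((xi - m[yi]) ** 2)) for xi, yi in zip(x, y))
        between = float(np.sum((m[0] - m[1]) ** 2))
        assert clustering_error(x, y) == pytest.approx(
            within / (400 * between), rel=1e-10)

    def test_scale_and_rotation_invariance(self):
        x, y = two_gaussians(200, separation=3.0, p=3, seed=6)
        e = clustering_error(x, y)
        assert clustering_error(7.3 * x, y) == pytest.approx(e, rel=1e-10)
        q, _ = np.linalg.qr(np.random.default_rng(7).normal(size=(3, 3)))
        assert clustering_error(x @ q, y) == pytest.approx(e, rel=1e-10)

    def test_decreasing_in_separation(self):
        errors = [clustering_error(*two_gaussians(500, s, seed=8))
                  for s in (1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(errors) < 0)

    def test_identical_means_undefined(self):
        x = np.array([[0.0, 1], [0, -1], [0, 1], [0, -1]])
        assert clustering_error(x, [0, 0, 1, 1]) == np.inf


class TestBackwardElimination:
    def test_minimal_two_features(self):
        x, y = two_gaussians(100, separation=5.0, p=2, seed=9)
        ranking = backward_eliminate(x, y, metric="clustering_error", floor=1)
        assert len(ranking.elimination_order) == 2
        assert len(ranking.trajectory) == 2
        # feature 0 carries the separation, so it survives
        assert ranking.surviving(1) == ["f0"]

    def test_informative_features_survive_svm_mode(self):
        rng = np.random.default_rng(10)
        n = 150
        x = rng.normal(0, 1, size=(2 * n, 6))
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        x[y == 1, :2] += 4.0  # features 0,1 informative; 2-5 noise
        ranking = backward_eliminate(x, y, metric="svm_cv_error", floor=2,
                                     seed=0)
        assert set(ranking.surviving(2)) == {"f0", "f1"}


class TestSVM:
    def test_separable_data_high_cv_accuracy(self):
        x, y = two_gaussians(200, separation=10.0, seed=11)
        bundle = train_svm(x, y, kernel="linear", seed=0)
        assert bundle.cv_accuracy >= 0.99

    def test_duplicated_feature_invariance(self):
        x, y = two_gaussians(200, separation=3.0, seed=12)
        b1 = train_svm(x, y, kernel="linear", seed=0)
        b2 = train_svm(np.hstack([x, x]), y, kernel="linear", seed=0)
        assert abs(b1.cv_accuracy - b2.cv_accuracy) < 0.03

    def test_small_class_raises(self):
        x = np.zeros((10, 2))
        y = [0] * 7 + [1] * 3
        with pytest.raises(ValueError):
            train_svm(x, y, folds=5)

    def test_gaussian_kernel_runs(self):
        x, y = two_gaussians(100, separation=6.0, seed=13)
        bundle = train_svm(x, y, kernel="gaussian", seed=0)
        assert bundle.cv_accuracy > 0.95
        assert bundle.gamma is not None and bundle.gamma > 0


class TestROC:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = scores > 0.5
        _, _, auc = roc(scores, labels)
        assert auc == 1.0

    def test_auc_equals_mannwhitney_with_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(14)
        for _ in range(20):
            n1, n0 = rng.integers(5, 100, 2)
            # ties guaranteed: scores drawn from a small integer set
            s = np.r_[rng.integers(0, 6, n1), rng.integers(0, 6, n0)].astype(float)
            y = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
            _, _, auc = roc(s, y)
            u = mannwhitneyu(s[y], s[~y], alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            roc([0.1, 0.9], [1, 1])


class TestGating:
    def _table(self, a, d3):
        return pd.DataFrame({"A": a, "D3": d3})

    def test_gate_thresholds_strict(self):
        table = self._table([14.0, 15.0], [1.5, 1.5])
        mask, _ = apply_gate(table, GateSpec(kind="diagonal"))
        assert mask.tolist() == [True, False]  # A = 15.0 excluded (strict)
        mask, _ = apply_gate(self._table([14.0, 14.0], [1.4, 1.41]),
                             GateSpec(kind="diagonal"))
        assert mask.tolist() == [False, True]  # D3 = 1.4 excluded (strict)

    def test_uniform_pass(self):
        _, frac = apply_gate(self._table([10.0] * 5, [2.0] * 5),
                             GateSpec(kind="size"))
        assert frac == 1.0

    def test_mask_matches_row_enumeration(self):
        rng = np.random.default_rng(15)
        table = self._table(rng.uniform(10, 20, 300), rng.uniform(1, 2, 300))
        for kind in ("size", "diagonal"):
            mask, _ = apply_gate(table, GateSpec(kind=kind))
            for i, row in table.iterrows():
                if kind == "size":
                    exp = row["A"] < 15.0
                else:
                    exp = (row["D3"] > 1.4) and (row["A"] < 15.0)
                assert mask[i] == exp

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            apply_gate(pd.DataFrame({"A": [1.0]}), GateSpec(kind="diagonal"))

    def test_quantile_gate_containment(self):
        rng = np.random.default_rng(16)
        cov = np.array([[2.25, -0.3 * 1.5 * 0.3], [-0.3 * 1.5 * 0.3, 0.09]])
        x = rng.multivariate_normal([15, 1.6], cov, size=5000)
        ref = self._table(x[:, 0], x[:, 1])
        gate = fit_quantile_gate(ref, containment=0.75)
        _, frac = apply_gate(ref, gate)
        assert frac == pytest.approx(0.75, abs=0.01)

    def test_full_containment(self):
        rng = np.random.default_rng(17)
        ref = self._table(rng.normal(15, 1, 100), rng.normal(1.6, 0.2, 100))
        gate = fit_quantile_gate(ref, containment=1.0)
        _, frac = apply_gate(ref, gate)
        assert frac == 1.0

    def test_shifted_population_less_contained(self):
        rng = np.random.default_rng(18)
        ref = self._table(rng.normal(15, 1, 2000), rng.normal(1.6, 0.2, 2000))
        shifted = self._table(rng.normal(20, 1, 2000), rng.normal(1.6, 0.2, 2000))
        gate = fit_quantile_gate(ref, containment=0.75)
        _, f_ref = apply_gate(ref, gate)
        _, f_shift = apply_gate(shifted, gate)
        assert f_shift < f_ref


class TestMixtureDeconvolution:
    def _separable(self, n_per, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=(2 * n_per, 3))
        x[n_per:, 0] += 12.0
        y = np.array(["a"] * n_per + ["b"] * n_per)
        return x, y

    def test_pure_population(self):
        x, y = self._separable(300, 19)
        bundle = train_svm(x, y, kernel="linear", seed=0)
        rng = np.random.default_rng(20)
        pure = rng.normal(0, 1, size=(500, 3))  # class "a" only
        frac = predict_fractions(bundle, pure)
        assert frac["a"] >= 0.98

    def test_fifty_fifty(self):
        x, y = self._separable(300, 21)
        bundle = train_svm(x, y, kernel="linear", seed=0)
        xt, yt = self._separable(400, 22)
        frac = predict_fractions(bundle, xt)
        assert frac["a"] == pytest.approx(0.5, abs=0.02)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_spike_response_identity_and_affine(self):
        s = [0.0, 0.25, 0.5, 0.75, 1.0]
        slope, intercept = spike_response(s, s)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        slope, intercept = spike_response(s, [0.5 * v + 0.1 for v in s])
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert intercept == pytest.approx(0.1, abs=1e-12)

    def test_spike_response_matches_normal_equations(self):
        rng = np.random.default_rng(23)
        s = np.linspace(0, 1, 6)
        p = 0.9 * s + 0.03 + rng.normal(0, 0.01, 6)
        slope, intercept = spike_response(s, p)
        # closed-form OLS oracle
        sx, sy = s.mean(), p.mean()
        beta = np.sum((s - sx) * (p - sy)) / np.sum((s - sx) ** 2)
        assert slope == pytest.approx(beta, abs=1e-10)
        assert intercept == pytest.approx(sy - beta * sx, abs=1e-10)

    def test_lod(self):
        assert limit_of_detection(1.0, 0.007) == pytest.approx(0.007)
        assert limit_of_detection(2.0, 0.007) == pytest.approx(0.0035)
        with pytest.raises(ValueError):
            limit_of_detection(0.0, 0.01)


class TestSimilarityMatrix:
    def test_basic_distances(self):
        d, _ = similarity_matrix(np.array([[0.0, 0], [3, 4], [0, 0]]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 2] == 0.0
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(24)
        x = rng.normal(size=(40, 5))
        d, order = similarity_matrix(x)
        for i in range(40):
            for j in range(40):
                assert d[i, j] == pytest.approx(
                    np.sqrt(np.sum((x[i] - x[j]) ** 2)), abs=1e-10)

    def test_block_structure(self):
        x, y = two_gaussians(100, separation=4.0, p=3, seed=25)
        d, order = similarity_matrix(x, labels=y)
        yo = y[order]
        within = d[np.ix_(yo == 0, yo == 0)].mean()
        between = d[np.ix_(yo == 0, yo == 1)].mean()
        assert within < between


class TestProjections:
    def test_pca_rank_one(self):
        rng = np.random.default_rng(26)
        t = rng.normal(size=200)
        x = np.column_stack([t, 2 * t]) + rng.normal(0, 1e-4, size=(200, 2))
        _, _, evr = pca_project(x, 2)
        assert evr[0] >= 0.999

    def test_pca_orthonormal_and_reconstruction(self):
        rng = np.random.default_rng(27)
        x = rng.normal(size=(100, 5))
        xc = x - x.mean(axis=0)
        scores, loadings, _ = pca_project(x, 5)
        assert np.allclose(loadings.T @ loadings, np.eye(5), atol=1e-9)
        assert np.allclose(scores @ loadings.T, xc, atol=1e-8)

    def test_lda_two_classes_one_direction(self):
        x, y = two_gaussians(200, separation=4.0, p=4, seed=28)
        scores, w = lda_project(x, y)
        assert w.shape == (4, 1)
        # separation lives in feature 0: leading direction aligns with it
        assert abs(w[0, 0]) / np.linalg.norm(w[:, 0]) >= 0.99

    def test_lda_beats_single_features_on_correlated_data(self):
        rng = np.random.default_rng(29)
        n = 400
        base = rng.normal(size=(2 * n, 2))
        mix = np.array([[1.0, 0.8], [0.8, 1.0]])
        x = base @ mix
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        x[y == 1] += [1.0, -1.0]
        scores, _ = lda_project(x, y)
        def sep(v):
            m0, m1 = v[y == 0], v[y == 1]
            pooled = np.sqrt(0.5 * (m0.var() + m1.var()))
            return abs(m0.mean() - m1.mean()) / pooled
        lda_sep = sep(scores[:, 0])
        assert lda_sep > max(sep(x[:, 0]), sep(x[:, 1]))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            lda_project(np.zeros((10, 2)), [0] * 10)


class TestSummariesAndCalibration:
    def test_constant_ratio(self):
        table = pd.DataFrame({"A": [16.0] * 7, "D3": [1.6] * 7})
        assert deformability_size_ratio(table) == pytest.approx(0.1)

    def test_median_is_sorted_middle(self):
        rng = np.random.default_rng(30)
        table = pd.DataFrame({"A": rng.uniform(10, 20, 31),
                              "D3": rng.uniform(1, 2, 31)})
        ratios = np.sort(table["D3"] / table["A"])
        assert deformability_size_ratio(table) == pytest.approx(ratios[15])

    def test_calibration_recovers_exact_line(self):
        d = np.linspace(1.0, 2.5, 6)
        e = 10 ** (2.0 - 1.5 * d)
        curve = fit_stiffness_calibration(d, e)
        assert curve.alpha == pytest.approx(2.0, abs=1e-9)
        assert curve.beta == pytest.approx(-1.5, abs=1e-9)

    def test_calibration_round_trip(self):
        d = np.array([1.1, 1.5, 2.0, 2.4])
        e = np.array([40.0, 8.0, 1.0, 0.2])  # spans the bead modulus range
        curve = fit_stiffness_calibration(d, e)
        assert curve.e_range == (0.2, 40.0)
        probe = np.array([1.2, 1.9])
        assert np.allclose(curve.inverse(curve.map(probe)), probe, atol=1e-9)

    def test_extrapolation_warns(self):
        d = np.array([1.1, 1.5, 2.0])
        curve = fit_stiffness_calibration(d, [30.0, 5.0, 0.5])
        with pytest.warns(UserWarning, match="extrapolat"):
            curve.map(3.0)
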