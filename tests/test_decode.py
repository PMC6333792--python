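import numpy as np
import pytest

from edlds.decode import (DecodabilityCurve, correctness_decodability,
                          decoder_similarity, fit_sparse_lda, onset_time,
                          poly2_kernel, previous_trial_decoding, project,
                          rt_correlation, trial_type_decodability, tune_lda,
                          window_average)


def _two_class(rng, n=60, p=6, sep=3.0, informative=None):
    informative = informative if informative is not None else list(range(p))
    X = rng.normal(0, 1, (2 * n, p))
    y = np.array(["contra"] * n + ["ipsi"] * n)
    for j in informative:
        X[:n, j] -= sep / 2 / len(informative) ** 0.5
        X[n:, j] += sep / 2 / len(informative) ** 0.5
    return X, y


class TestSparseLda:
    def test_matches_fisher_closed_form_without_penalties(self, rng):
        X, y = _two_class(rng)
        dec = fit_sparse_lda(X, y, gamma=0.0, delta=0.0)
        Xc = X - X.mean(axis=0)
        Sigma = Xc.T @ Xc / len(X)
        d = X[y == "contra"].mean(0) - X[y == "ipsi"].mean(0)
        fisher = np.linalg.solve(Sigma, d)
        fisher /= np.linalg.norm(fisher)
        cos = abs(dec.weights @ fisher)
        assert cos >= 0.999

    def test_large_l1_keeps_single_best_feature(self, rng):
        X, y = _two_class(rng, p=8, informative=[3])
        dec = fit_sparse_lda(X, y, gamma=0.1, delta=50.0)
        nz = np.flatnonzero(np.abs(dec.weights) > 1e-6)
        assert list(nz) == [3]

    def test_sign_convention_contra_negative(self, rng):
        X, y = _two_class(rng, p=5, informative=[0])
        dec = fit_sparse_lda(X, y, gamma=0.2, delta=0.0)
        assert dec.decision_value(X[y == "contra"]).mean() < 0
        assert dec.decision_value(X[y == "ipsi"]).mean() > 0

    def test_unit_norm(self, rng):
        X, y = _two_class(rng)
        for g, d in [(0.0, 0.0), (0.5, 0.0), (0.2, 0.5)]:
            dec = fit_sparse_lda(X, y, gamma=g, delta=d)
            assert np.linalg.norm(dec.weights) == pytest.approx(1.0)

    def test_weights_invariant_to_constant_feature_shift(self, rng):
        X, y = _two_class(rng)
        a = fit_sparse_lda(X, y, gamma=0.1, delta=0.1)
        b = fit_sparse_lda(X + 7.3, y, gamma=0.1, delta=0.1)
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-8)


class TestTuneLda:
    def test_separable_data_reaches_zero_error(self, rng):
        X, y = _two_class(rng, sep=8.0)
        dec, g, d = tune_lda(X, y, folds=4, seed=0)
        assert np.mean(dec.predict(X) == y) == 1.0

    def test_tie_break_prefers_small_delta_large_gamma(self, rng):
        # pure-noise labels: validation error ~ 0.5 everywhere; the
        # tie-break picks the smallest delta, then the largest gamma
        X = rng.normal(0, 1, (40, 4))
        y = np.array(["a", "b"] * 20)
        _, g, d = tune_lda(X, y, gammas=(0.1, 0.9), deltas=(0.0, 1.0),
                           folds=4, seed=1)
        assert d == 0.0

    def test_planted_sparsity_selects_positive_delta(self, rng):
        hits = 0
        for k in range(20):
            r = np.random.default_rng(k)
            X, y = _two_class(r, n=40, p=30, sep=2.5, informative=[1, 7, 20])
            _, g, d = tune_lda(X, y, gammas=(0.1, 0.5),
                               deltas=(0.0, 0.05, 0.2), folds=4, seed=k)
            hits += d > 0
        assert hits >= 10   # sparsity helps often on sparse truth


class TestProjection:
    def test_basis_vector_picks_coordinate(self, rng):
        X, y = _two_class(rng, p=4, informative=[0])
        dec = fit_sparse_lda(X, y, delta=50.0)
        act = np.array([3.0, 9.9, -2.1, 0.4])
        assert abs(project(dec, act)) == pytest.approx(3.0)

    def test_zero_activity_projects_to_zero(self, rng):
        X, y = _two_class(rng)
        dec = fit_sparse_lda(X, y)
        assert project(dec, np.zeros(X.shape[1])) == 0.0

    def test_linearity(self, rng):
        X, y = _two_class(rng)
        dec = fit_sparse_lda(X, y)
        v = rng.normal(0, 1, X.shape[1])
        assert project(dec, 2 * v) == pytest.approx(2 * project(dec, v))

    def test_dimension_mismatch(self, rng):
        X, y = _two_class(rng)
        dec = fit_sparse_lda(X, y)
        with pytest.raises(ValueError, match="mismatch"):
            project(dec, np.zeros(X.shape[1] + 1))


class TestTrialTypeDecodability:
    def _features(self, rng, sep, n=60, T=20, F=5):
        centers = np.linspace(-1.3, 0.03, T)
        X = rng.normal(0, 1, (2 * n, T, F))
        X[:n, :, 0] -= sep / 2
        X[n:, :, 0] += sep / 2
        y = np.array(["contra"] * n + ["ipsi"] * n)
        return X, y, centers

    def test_perfect_separation(self, rng):
        X, y, c = self._features(rng, sep=20.0)
        acc, sd = trial_type_decodability(X, y, c)
        assert acc == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        X, y, c = self._features(rng, sep=20.0)
        ys = rng.permutation(y)
        acc, _ = trial_type_decodability(X, ys, c, seed=0)
        # cross-validated accuracy on permuted labels is centered slightly
        # below 0.5 (anti-learning bias); allow for it plus binomial noise
        assert abs(acc - 0.5) < 0.2

    def test_window_outside_grid_rejected(self, rng):
        X, y, c = self._features(rng, sep=1.0)
        with pytest.raises(ValueError, match="window"):
            trial_type_decodability(X, y, c, at_ms=+5000)

    def test_window_average_selects_expected_bins(self):
        T = 10
        centers = np.linspace(-0.9, 0.0, T)
        feats = np.tile(np.arange(T, dtype=float)[None, :, None], (3, 1, 2))
        out = window_average(feats, centers, at_ms=-300, width_ms=150)
        sel = np.abs(centers * 1000 + 300) <= 75
        assert out[0, 0] == pytest.approx(np.arange(T)[sel].mean())


class TestRtCorrelation:
    def test_monotone_link_gives_unit_rho(self):
        s = np.linspace(-2, 2, 30)
        rho, p = rt_correlation(s, 300 - 50 * s)
        assert rho == pytest.approx(-1.0)

    def test_independent_near_zero(self, rng):
        s = rng.normal(0, 1, 500)
        rt = rng.uniform(150, 500, 500)
        rho, _ = rt_correlation(s, rt)
        assert abs(rho) < 0.1

    def test_slow_subset_filter(self):
        s = np.arange(20, dtype=float)
        rt = np.where(s < 10, 90.0, 200.0 + 10 * s)
        rho, _ = rt_correlation(s, rt, subset="slow_gt_100ms")
        assert rho == pytest.approx(1.0)

    def test_constant_projection_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            rho, p = rt_correlation(np.ones(10), np.linspace(200, 400, 10))
        assert np.isnan(rho)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            rt_correlation([1, 2, 3], [100, 200, 300])


class TestCorrectnessDecoding:
    def test_poly2_kernel_value(self):
        # inner-product average of 2 => G = (1 + 2)^2 = 9
        a = np.array([[2.0, 2.0]])
        b = np.array([[1.0, 1.0]])
        assert poly2_kernel(a, b)[0, 0] == pytest.approx(9.0)

    @pytest.mark.parametrize("family", ["SVM_poly2", "QDA"])
    def test_planted_offset_detected_late_not_early(self, rng, family):
        n, T, F = 40, 24, 4
        X = rng.normal(0, 1, (2 * n, T, F))
        labels = np.array(["correct"] * (2 * n - 12) + ["error"] * 12)
        X[labels == "error", T // 2:, 1] += 4.0
        centers = np.linspace(-1.5, 0.1, T)
        curve = correctness_decodability(X, labels, centers, family=family,
                                         folds=5, seed=0)
        assert curve.accuracy[: T // 2].mean() < 0.6
        assert curve.accuracy[T // 2 + 2:].mean() > 0.8

    def test_shuffled_labels_flat_at_chance(self, rng):
        X = rng.normal(0, 1, (60, 10, 3))
        labels = rng.permutation(np.array(["correct"] * 40 + ["error"] * 20))
        curve = correctness_decodability(X, labels, np.linspace(-1, 0, 10),
                                         folds=5, seed=0)
        assert abs(curve.accuracy.mean() - 0.5) < 0.15

    def test_too_few_errors_rejected(self, rng):
        X = rng.normal(0, 1, (30, 5, 3))
        labels = np.array(["correct"] * 27 + ["error"] * 3)
        with pytest.raises(ValueError, match="at least 5"):
            correctness_decodability(X, labels, np.linspace(-1, 0, 5))


class TestOnsetTime:
    def _curve(self, acc):
        return DecodabilityCurve(accuracy=np.asarray(acc, float),
                                 std=np.zeros(len(acc)),
                                 bin_centers_s=np.arange(len(acc), dtype=float),
                                 family="QDA", label_type="correctness")

    def test_always_above_threshold_onsets_at_first_bin(self, small_schedule):
        curve = self._curve(np.ones(12))
        assert onset_time(curve, small_schedule) == 0.0

    def test_chance_curve_never_onsets(self, small_schedule):
        assert onset_time(self._curve(np.full(12, 0.5)), small_schedule) is None

    def test_short_excursion_does_not_qualify(self, small_schedule):
        # shortest epoch of the fixture has 2 bins -> min run 2
        acc = np.full(12, 0.5)
        acc[4] = 0.9                       # single-bin run
        assert onset_time(self._curve(acc), small_schedule) is None
        acc[5] = 0.9                       # two-bin run qualifies
        assert onset_time(self._curve(acc), small_schedule) == 4.0


class TestPreviousTrialDecoding:
    def test_planted_history_effect_recovered(self, rng):
        n, T, F = 81, 16, 4
        X = rng.normal(0, 1, (n, T, F))
        prev = np.array(["none"] + ["rewarded", "unrewarded"] * ((n - 1) // 2))
        pre = np.zeros(T, bool); pre[:6] = True
        mask = prev == "rewarded"
        X[np.ix_(np.flatnonzero(mask), np.arange(6), [2])] += 2.5
        curve, avg = previous_trial_decoding(X, prev, np.linspace(-4, -3, T),
                                             pre, folds=5, seed=0)
        assert avg > 0.75
        assert len(curve.accuracy) == 6

    def test_no_effect_near_chance(self, rng):
        n, T = 81, 12
        X = rng.normal(0, 1, (n, T, 3))
        prev = np.array(["none"] + ["rewarded", "unrewarded"] * ((n - 1) // 2))
        pre = np.zeros(T, bool); pre[:5] = True
        _, avg = previous_trial_decoding(X, prev, np.linspace(-4, -3, T), pre,
                                         folds=5, seed=0)
        assert abs(avg - 0.5) < 0.15


class TestDecoderSimilarity:
    def test_identical_and_orthogonal(self, rng):
        X, y = _two_class(rng, p=4, informative=[0])
        d1 = fit_sparse_lda(X, y, delta=50.0)      # e0 only
        X2 = X.copy(); X2[:, [0, 1]] = X2[:, [1, 0]]
        d2 = fit_sparse_lda(X2, y, delta=50.0)     # e1 only
        G = decoder_similarity([d1, d1, d2])
        np.testing.assert_allclose(np.diag(G), 1.0)
        assert abs(G[0, 1]) == pytest.approx(1.0)
        assert abs(G[0, 2]) < 1e-6

    def test_mixed_feature_spaces_rejected(self, rng):
        X, y = _two_class(rng)
        a = fit_sparse_lda(X, y, feature_space="FNS")
        b = fit_sparse_lda(X, y, feature_space="SAS")
        with pytest.raises(ValueError, match="mixed"):
            decoder_similarity([a, b])
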