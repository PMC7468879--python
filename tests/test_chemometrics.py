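import numpy as np
import pytest
from scipy import stats

from avflux import chemometrics as cm


rng0 = np.random.default_rng(0)


def two_class_data(n_per=20, p=4, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0, 1, (n_per, p))
    X1 = rng.normal(0, 1, (n_per, p))
    X1[:, :2] += sep
    X = np.vstack([X0, X1])
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


class TestMultilevelSplit:
    def test_two_rows_one_variable(self):
        split = cm.multilevel_split(np.array([[1.0], [3.0]]), ["s", "s"])
        np.testing.assert_allclose(split.within, [[-1.0], [1.0]])
        np.testing.assert_allclose(split.between, [[0.0], [0.0]])

    def test_constant_matrix_gives_zero_parts(self):
        X = np.full((6, 3), 2.5)
        split = cm.multilevel_split(X, ["a", "a", "a", "b", "b", "b"])
        assert np.all(split.within == 0) and np.all(split.between == 0)

    def test_reconstruction_identity_random(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        subjects = np.repeat(["a", "b"], 5)
        split = cm.multilevel_split(X, subjects)
        np.testing.assert_allclose(split.reconstruct(), X, atol=1e-12)
        for s in ("a", "b"):
            np.testing.assert_allclose(
                split.within[subjects == s].sum(axis=0), 0.0, atol=1e-10
            )

    def test_single_row_subject_is_error(self):
        with pytest.raises(cm.ChemometricsError):
            cm.multilevel_split(np.ones((3, 2)), ["a", "a", "b"])


class TestOSC:
    def test_removed_scores_orthogonal_to_class_dummies(self):
        X, y = two_class_data(seed=1)
        Xc = X - X.mean(axis=0)
        Y, _ = cm._one_hot(y)
        Xf, scores = cm.osc_filter(Xc, Y, n_osc=2)
        Yc = Y - Y.mean(axis=0)
        for a in range(scores.shape[1]):
            t = scores[:, a]
            for j in range(Yc.shape[1]):
                cos = abs(t @ Yc[:, j]) / (np.linalg.norm(t) * np.linalg.norm(Yc[:, j]))
                assert cos < 1e-6

    def test_deflation_removes_variance(self):
        X, y = two_class_data(seed=2)
        Xc = X - X.mean(axis=0)
        Y, _ = cm._one_hot(y)
        Xf, _ = cm.osc_filter(Xc, Y, n_osc=1)
        assert np.sum(Xf**2) <= np.sum(Xc**2)

    def test_removes_structured_noise_orthogonal_to_class(self):
        # X = class signal + structured nuisance orthogonal to Y: after one OSC
        # component the nuisance subspace loses variance and Q2 does not drop.
        rng = np.random.default_rng(3)
        n = 40
        y = np.repeat(["a", "b"], n // 2)
        cls = np.where(y == "b", 1.0, -1.0)
        nuisance = rng.normal(size=n)
        nuisance -= nuisance @ cls / (cls @ cls) * cls  # orthogonal to class
        sig_dir = np.zeros(6); sig_dir[0] = 1
        nui_dir = np.zeros(6); nui_dir[1] = 1
        X = np.outer(cls, sig_dir) + 3 * np.outer(nuisance, nui_dir) + 0.1 * rng.normal(size=(n, 6))
        Xc = X - X.mean(axis=0)
        Y, _ = cm._one_hot(y)
        Xf, _ = cm.osc_filter(Xc, Y, n_osc=1)
        var_before = np.sum((Xc @ nui_dir) ** 2)
        var_after = np.sum((Xf @ nui_dir) ** 2)
        assert var_after < 0.2 * var_before
        q2_before = cm.cv_q2(Xc, y, folds=5, n_components_grid=(1,), seed=0).q2[1]
        q2_after = cm.cv_q2(Xf, y, folds=5, n_components_grid=(1,), seed=0).q2[1]
        assert q2_after >= q2_before - 1e-6


class TestScaling:
    def test_pareto_hand_value(self):
        out = cm.pareto_scale(np.array([[0.0], [2.0], [4.0]]))
        np.testing.assert_allclose(out[:, 0], np.array([-2, 0, 2]) / np.sqrt(2), atol=1e-12)

    def test_autoscale_hand_value_and_unit_sd(self):
        X = np.array([[0.0, 1.0], [2.0, 4.0], [4.0, 2.0]])
        out = cm.autoscale(X)
        np.testing.assert_allclose(out[:, 0], [-1, 0, 1], atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_autoscale_idempotent(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        np.testing.assert_allclose(cm.autoscale(cm.autoscale(X)), cm.autoscale(X), atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = cm.pareto_scale(X)
        assert out.shape == (5, 1)


class TestPCA:
    def test_rank_one_explains_everything(self):
        u = np.arange(1.0, 6.0)[:, None]
        v = np.array([[1.0, 2.0, -1.0]])
        with pytest.warns(UserWarning):
            res = cm.pca(u @ v, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 4))
        res = cm.pca(X, n_components=4)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(res.scores @ res.loadings.T, Xc, atol=1e-10)

    def test_matches_covariance_eigenvalues(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        res = cm.pca(X, n_components=5)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(res.explained_variance, eig, atol=1e-10)


class TestPLSDA:
    def test_separated_classes_classified_perfectly(self):
        X, y = two_class_data(sep=6.0, seed=8)
        model = cm.plsda_fit(cm.autoscale(X), y, n_components=2)
        assert np.all(model.predict(cm.autoscale(X)) == y)
        # independent oracle: LDA also separates this data perfectly
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        lda = LinearDiscriminantAnalysis().fit(X, y)
        assert np.all(lda.predict(X) == y)

    def test_shuffled_labels_reduce_r2y(self):
        X, y = two_class_data(sep=6.0, seed=9)
        Xs = cm.autoscale(X)
        true_r2 = cm.plsda_fit(Xs, y, n_components=2).r2y
        rng = np.random.default_rng(0)
        null_r2 = [
            cm.plsda_fit(Xs, y[rng.permutation(len(y))], n_components=2).r2y
            for _ in range(100)
        ]
        assert true_r2 > np.percentile(null_r2, 99)

    def test_duplicated_columns_get_identical_weights(self):
        X, y = two_class_data(p=3, seed=10)
        Xd = np.column_stack([X, X[:, 0]])
        model = cm.plsda_fit(cm.autoscale(Xd), y, n_components=1)
        assert model.weights[0, 0] == pytest.approx(model.weights[3, 0], abs=1e-8)

    def test_single_class_is_error(self):
        with pytest.raises(cm.ChemometricsError):
            cm.plsda_fit(np.random.default_rng(0).normal(size=(6, 2)), ["a"] * 6)


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        # symmetric two-variable, one-component model: VIP = (1, 1)
        y = np.repeat(["a", "b"], 10)
        sig = np.where(y == "b", 1.0, -1.0) + 0.01 * np.random.default_rng(1).normal(size=20)
        X = np.column_stack([sig, sig])
        model = cm.plsda_fit(X, y, n_components=1)
        np.testing.assert_allclose(model.vip, [1.0, 1.0], atol=1e-8)

    def test_sum_of_squares_equals_p(self):
        for seed in range(5):
            X, y = two_class_data(p=6, seed=seed)
            model = cm.plsda_fit(cm.autoscale(X), y, n_components=2)
            assert np.sum(model.vip**2) == pytest.approx(6.0, abs=1e-8)

    def test_noise_variable_scores_below_threshold(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.repeat(["a", "b"], 15)
            sig = np.where(y == "b", 1.0, -1.0)
            X = np.column_stack(
                [sig + 0.3 * rng.normal(size=30),
                 sig + 0.3 * rng.normal(size=30),
                 rng.normal(size=30)]
            )
            model = cm.plsda_fit(cm.autoscale(X), y, n_components=1)
            hits += model.vip[2] < 0.8
        assert hits >= 95


class TestSparsePLSDA:
    def test_keepx_p_equals_dense_fit(self):
        X, y = two_class_data(seed=11)
        Xs = cm.autoscale(X)
        dense = cm.plsda_fit(Xs, y, n_components=2)
        sparse = cm.splsda_fit(Xs, y, n_components=2, keepX=Xs.shape[1])
        np.testing.assert_allclose(sparse.weights, dense.weights, atol=1e-8)

    def test_nonzero_count_matches_keepx(self):
        X, y = two_class_data(p=8, seed=12)
        model = cm.splsda_fit(cm.autoscale(X), y, n_components=2, keepX=[3, 5])
        counts = np.sum(model.weights != 0, axis=0)
        np.testing.assert_array_equal(counts, [3, 5])

    def test_zero_keepx_is_error(self):
        X, y = two_class_data(seed=13)
        with pytest.raises(cm.ChemometricsError):
            cm.splsda_fit(X, y, n_components=1, keepX=0)

    def test_informative_variable_recovery(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.repeat(["a", "b"], n // 2)
            sig = np.where(y == "b", 1.0, -1.0)
            X = rng.normal(size=(n, 50))
            X[:, 0] += 2 * sig
            X[:, 1] += 2 * sig
            model = cm.splsda_fit(cm.autoscale(X), y, n_components=1, keepX=2)
            hits += set(np.flatnonzero(model.weights[:, 0])) == {0, 1}
        assert hits >= 95


class TestCrossValidation:
    def test_null_q2_rarely_positive(self):
        good = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 5))
            y = np.repeat(["a", "b"], 12)
            res = cm.cv_q2(X, y, folds=7, n_components_grid=(2,), seed=seed)
            good += res.q2[2] <= 0.05
        assert good >= 90

    def test_separated_classes_have_high_q2(self):
        X, y = two_class_data(sep=6.0, seed=14)
        res = cm.cv_q2(cm.autoscale(X), y, folds=7, n_components_grid=(1, 2), seed=0)
        assert res.q2[res.chosen_n_components] > 0.5

    def test_deterministic_given_seed(self):
        X, y = two_class_data(seed=15)
        a = cm.cv_q2(X, y, folds=7, seed=3)
        b = cm.cv_q2(X, y, folds=7, seed=3)
        assert a.q2 == b.q2

    def test_too_many_folds_is_error(self):
        X, y = two_class_data(n_per=3, seed=16)
        with pytest.raises(cm.ChemometricsError):
            cm.cv_q2(X, y, folds=10)

    def test_grouped_folds_keep_subjects_together(self):
        X, y = two_class_data(n_per=10, seed=17)
        groups = np.tile(np.repeat(["g1", "g2"], 5), 2)
        splits = cm._cv_splits(len(y), y, folds=7, groups=groups, seed=0)
        for train, test in splits:
            assert set(groups[train]).isdisjoint(set(groups[test]))


class TestPermutationTest:
    def test_observed_beats_all_nulls(self):
        y = np.arange(12)
        X = y[:, None].astype(float)
        stat = lambda Xm, ym: float(np.array_equal(ym, y))
        res = cm.permutation_test(X, y, stat, n_perm=200, seed=0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_null_p_values_roughly_uniform(self):
        frac = 0
        for rep in range(200):
            rng = np.random.default_rng(rep)
            X = rng.normal(size=(20, 1))
            y = np.repeat(["a", "b"], 10)
            stat = lambda Xm, ym: abs(np.corrcoef(Xm[:, 0], (ym == "b").astype(float))[0, 1])
            res = cm.permutation_test(X, y, stat, n_perm=99, seed=rep + 1)
            frac += res.p_value <= 0.05
        assert 0.01 <= frac / 200 <= 0.10

    def test_within_subject_permutation_preserves_block_multisets(self):
        y = np.array(["a", "a", "b", "b", "a", "b"])
        blocks = np.array(["s1", "s1", "s1", "s2", "s2", "s2"])
        seen = []

        def stat(Xm, ym):
            seen.append(ym.copy())
            return 0.0

        cm.permutation_test(np.zeros((6, 1)), y, stat, n_perm=20, seed=0, within_subject=blocks)
        for ym in seen[1:]:  # first call is the observed labelling
            for s in ("s1", "s2"):
                assert sorted(ym[blocks == s]) == sorted(y[blocks == s])

    def test_constant_labels_rejected(self):
        with pytest.raises(cm.ChemometricsError):
            cm.permutation_test(np.zeros((4, 1)), ["a"] * 4, lambda X, y: 0.0)


class TestKruskalWallisFdr:
    def test_hand_computed_h_statistic(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0], [7.0], [8.0], [9.0]])
        groups = np.repeat(["g1", "g2", "g3"], 3)
        res = cm.kruskal_wallis_fdr(X, groups)
        assert res["H"].iloc[0] == pytest.approx(7.2, abs=1e-12)

    def test_identical_values_give_h_zero_nonsignificant(self):
        X = np.ones((9, 2))
        res = cm.kruskal_wallis_fdr(X, np.repeat(["g1", "g2", "g3"], 3))
        assert np.all(res["H"] == 0) and np.all(res["p"] == 1) and not res["significant"].any()

    def test_empty_group_is_error(self):
        with pytest.raises(cm.ChemometricsError):
            cm.kruskal_wallis_fdr(np.ones((3, 1)), ["g1", "g1", "g1"])

    def test_bh_hand_example(self):
        q = cm.bh_fdr([0.01, 0.02, 0.05, 0.2])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.05 * 4 / 3, 0.2], atol=1e-12)

    def test_bh_controls_fdr_on_mixed_simulations(self):
        # 500 seeds, 20% true effects with strong signal: empirical FDR ≤ 0.07
        fdr = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            p_null = rng.uniform(size=40)
            p_alt = rng.uniform(size=10) * 1e-4
            q = cm.bh_fdr(np.concatenate([p_null, p_alt]))
            R = np.sum(q < 0.05)
            fdr.append(np.sum(q[:40] < 0.05) / max(R, 1))
        assert np.mean(fdr) <= 0.07
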