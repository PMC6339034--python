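import numpy as np
import pytest

from riemgait.errors import DegenerateBandwidthError
from riemgait.kernel_metric import (
    TrainConfig,
    _impostor_candidates,
    _target_neighbors,
    build_query_columns,
    classify_knn,
    cross_validate,
    estimate_bandwidth,
    fuse_kernels,
    kernel_columns,
    klmnn_gradient,
    klmnn_loss,
    lda_init,
    learned_distance,
    rbf_kernel,
    train_metric,
)

from .oracles import finite_difference_gradient


class TestBandwidth:
    def test_two_vectors(self):
        assert estimate_bandwidth(np.array([[0.0], [3.0]])) == pytest.approx(3.0)

    def test_three_collinear(self):
        bw = estimate_bandwidth(np.array([[0.0], [1.0], [2.0]]))
        assert bw == pytest.approx(4.0 / 3.0)

    def test_identical_raises(self):
        with pytest.raises(DegenerateBandwidthError):
            estimate_bandwidth(np.ones((4, 2)))

    def test_single_vector_raises(self):
        with pytest.raises(ValueError):
            estimate_bandwidth(np.ones((1, 2)))


class TestRbfKernel:
    def test_unit_diagonal(self, rng):
        k = rbf_kernel(rng.random((6, 3)), 1.5)
        assert np.allclose(np.diag(k.values), 1.0)

    def test_exponent_minus_one(self):
        delta = 0.8
        x = np.array([[0.0], [delta * np.sqrt(2)]])
        k = rbf_kernel(x, delta)
        assert k.values[0, 1] == pytest.approx(np.exp(-1), abs=1e-9)

    def test_distance_zero(self):
        k = rbf_kernel(np.zeros((2, 3)), 1.0)
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_psd(self, rng):
        k = rbf_kernel(rng.random((15, 4)), 0.7)
        assert np.linalg.eigvalsh(k.values).min() >= -1e-8

    def test_bad_bandwidth(self, rng):
        with pytest.raises(ValueError):
            rbf_kernel(rng.random((3, 2)), 0.0)


class TestFusion:
    def test_ones_identity(self, rng):
        kt = rbf_kernel(rng.random((5, 2)), 1.0)
        ks = rbf_kernel(np.zeros((5, 2)), 1.0)  # all-ones kernel
        assert np.allclose(ks.values, 1.0)
        assert np.allclose(fuse_kernels(ks, kt).values, kt.values)

    def test_entrywise(self):
        from riemgait.kernel_metric import KernelMatrix
        a = KernelMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), 1.0)
        b = KernelMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), 1.0)
        assert fuse_kernels(a, b).values[0, 1] == pytest.approx(0.2)

    def test_fused_psd_100_instances(self, rng):
        for _ in range(100):
            ks = rbf_kernel(rng.random((8, 3)), rng.uniform(0.3, 2.0))
            kt = rbf_kernel(rng.random((8, 5)), rng.uniform(0.3, 2.0))
            fused = fuse_kernels(ks, kt)
            assert np.linalg.eigvalsh(fused.values).min() >= -1e-8

    def test_size_mismatch(self, rng):
        with pytest.raises(ValueError):
            fuse_kernels(rbf_kernel(rng.random((4, 2)), 1.0),
                         rbf_kernel(rng.random((5, 2)), 1.0))


class TestLearnedDistance:
    def test_zero_for_equal(self):
        L = np.eye(3)
        v = np.array([1.0, 2.0, 3.0])
        assert learned_distance(L, v, v) == 0.0

    def test_identity_is_sq_euclid(self, rng):
        a, b = rng.random(4), rng.random(4)
        assert learned_distance(np.eye(4), a, b) == pytest.approx(
            float(np.sum((a - b) ** 2)))

    def test_quadratic_scaling(self, rng):
        a, b = rng.random(4), rng.random(4)
        assert learned_distance(2 * np.eye(4), a, b) == pytest.approx(
            4 * learned_distance(np.eye(4), a, b))


def _toy_instance(rng, n_per=4, classes=2, d=3, p=2):
    X = np.vstack([rng.standard_normal((n_per, d)) + 4 * c
                   for c in range(classes)])
    y = np.repeat([chr(97 + c) for c in range(classes)], n_per)
    targets = _target_neighbors(X, y, min(2, n_per - 1))
    impostors = _impostor_candidates(y)
    L = rng.standard_normal((p, d))
    return L, X, y, targets, impostors


class TestLoss:
    def test_coincident_zero(self):
        X = np.zeros((4, 4))
        y = np.array(["a", "a", "b", "b"])
        targets = [[1], [0], [3], [2]]
        impostors = _impostor_candidates(y)
        targets = [np.array(t) for t in targets]
        loss = klmnn_loss(np.eye(4), X, y, targets, impostors, 0.2, 0.0, 0.0)
        assert loss == 0.0

    def test_penalty_only(self, rng):
        X = rng.random((2, 3))
        y = np.array(["a", "b"])
        targets = [np.array([], dtype=int)] * 2
        impostors = _impostor_candidates(y)
        L = rng.standard_normal((2, 3))
        lam = 0.7
        loss = klmnn_loss(L, X, y, targets, impostors, 0.2, lam, 1.0)
        assert loss == pytest.approx(
            lam * np.linalg.norm(L.T @ L - np.eye(3)))

    def test_hand_example_1d(self):
        # samples at 0, 1, 10; target pair (0,1); impostor 10; mu=.2 zeta=1
        X = np.array([[0.0], [1.0], [10.0]])
        y = np.array(["a", "a", "b"])
        targets = [np.array([1]), np.array([0]), np.array([], dtype=int)]
        impostors = [np.array([2]), np.array([2]), np.array([], dtype=int)]
        L = np.array([[1.0]])
        loss = klmnn_loss(L, X, y, targets, impostors, 0.2, 0.0, 1.0)
        # pull = 0.8*(1+1); push hinges: (0): 1-100+1<0; (1): 1-81+1<0
        assert loss == pytest.approx(1.6)

    def test_invalid_mu(self, rng):
        L, X, y, t, i = _toy_instance(rng)
        with pytest.raises(ValueError):
            klmnn_loss(L, X, y, t, i, 1.5, 0.1, 1.0)


class TestGradient:
    def test_finite_difference_agreement(self, rng):
        # margin chosen so some hinges are active, none exactly at the kink
        L, X, y, targets, impostors = _toy_instance(rng, n_per=2, d=4, p=2)
        args = (X, y, targets, impostors, 0.2, 0.1, 5.0)
        grad = klmnn_gradient(L, *args)
        fd = finite_difference_gradient(
            lambda M: klmnn_loss(M, *args), L, h=1e-6)
        denom = np.maximum(np.abs(fd), 1e-3)
        assert np.max(np.abs(grad - fd) / denom) < 1e-5

    def test_random_instances_every_run(self):
        rng = np.random.default_rng()  # deliberately fresh each run
        for _ in range(3):
            L, X, y, targets, impostors = _toy_instance(rng, n_per=3, d=3, p=2)
            args = (X, y, targets, impostors, 0.3, 0.05, 2.0)
            grad = klmnn_gradient(L, *args)
            fd = finite_difference_gradient(
                lambda M: klmnn_loss(M, *args), L, h=1e-6)
            denom = np.maximum(np.abs(fd), 1e-2)
            assert np.max(np.abs(grad - fd) / denom) < 1e-4

    def test_coincident_zero_gradient(self):
        X = np.zeros((4, 4))
        y = np.array(["a", "a", "b", "b"])
        targets = [np.array([1]), np.array([0]), np.array([3]), np.array([2])]
        impostors = _impostor_candidates(y)
        g = klmnn_gradient(np.eye(4), X, y, targets, impostors, 0.2, 0.0, 0.0)
        assert np.allclose(g, 0.0)

    def test_pull_gradient_quadratic_in_scale(self, rng):
        L, X, y, targets, impostors = _toy_instance(rng, n_per=3, d=3, p=3)
        # mu=0 -> pure pull term; no hinge, no penalty
        g1 = klmnn_gradient(L, X, y, targets, impostors, 0.0, 0.0, 0.0)
        g2 = klmnn_gradient(L, 2 * X, y, targets, impostors, 0.0, 0.0, 0.0)
        assert np.allclose(g2, 4 * g1, rtol=1e-10)


class TestLdaInit:
    def test_two_class_direction(self, rng):
        n = 60
        X = np.vstack([
            rng.standard_normal((n, 2)) * [1.0, 0.2],
            rng.standard_normal((n, 2)) * [1.0, 0.2] + [6.0, 0.0],
        ])
        y = np.repeat(["a", "b"], n)
        L = lda_init(X, y, 1)
        # closed-form two-class LDA direction
        mu1, mu2 = X[:n].mean(0), X[n:].mean(0)
        sw = np.cov(X[:n].T) * (n - 1) + np.cov(X[n:].T) * (n - 1)
        w = np.linalg.solve(sw, mu2 - mu1)
        w /= np.linalg.norm(w)
        cos = abs(float(L[0] @ w))
        assert cos > np.cos(np.deg2rad(5))

    def test_rows_orthonormal(self, rng):
        X = rng.standard_normal((30, 6))
        y = np.repeat(["a", "b", "c"], 10)
        L = lda_init(X, y, 5)
        assert np.allclose(L @ L.T, np.eye(5), atol=1e-8)

    def test_pure_lda_when_p_is_c_minus_1(self, rng):
        X = rng.standard_normal((30, 6)) + np.repeat(
            np.arange(3)[:, None] * 3, 10, axis=0)
        y = np.repeat(["a", "b", "c"], 10)
        L = lda_init(X, y, 2)
        assert L.shape == (2, 6)

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            lda_init(rng.random((5, 3)), np.array(["a"] * 5), 1)


def _separable_columns(rng, classes=3, n_per=10, d=6, sep=30.0):
    X = np.vstack([rng.standard_normal((n_per, d)) + sep * c
                   for c in range(classes)])
    y = np.repeat([f"s{c}" for c in range(classes)], n_per)
    return X, y


class TestTrainMetric:
    def test_loss_monotone(self, rng):
        X, y = _separable_columns(rng, sep=3.0)
        model = train_metric(X, y, TrainConfig(p=4, max_epochs=15))
        h = model.loss_history
        assert all(b <= a + 1e-12 for a, b in zip(h[:-1], h[1:]))

    def test_monotone_20_random_instances(self, rng):
        for _ in range(20):
            X = rng.standard_normal((12, 4)) + np.repeat(
                rng.uniform(-2, 2, (3, 1)) * 2, 4, axis=0)
            y = np.repeat(["a", "b", "c"], 4)
            model = train_metric(X, y, TrainConfig(
                p=3, max_epochs=8, n_target_neighbors=2))
            h = model.loss_history
            assert all(b <= a + 1e-12 for a, b in zip(h[:-1], h[1:]))

    def test_separable_training_accuracy(self, rng):
        X, y = _separable_columns(rng)
        model = train_metric(X, y, TrainConfig(p=4))
        preds = classify_knn(model, X)
        assert np.mean(preds == y) == 1.0

    def test_zero_learning_rate_keeps_lda(self, rng):
        X, y = _separable_columns(rng, sep=2.0)
        cfg = TrainConfig(p=3, learning_rate=0.0, max_epochs=5)
        model = train_metric(X, y, cfg)
        assert np.allclose(model.L, lda_init(X, y, 3))

    def test_small_class_raises(self, rng):
        X = rng.random((4, 3))
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            train_metric(X, y, TrainConfig(n_target_neighbors=3))


class TestClassify:
    def test_training_column_k1(self, rng):
        X, y = _separable_columns(rng)
        model = train_metric(X, y, TrainConfig(p=4, k_classify=1))
        assert classify_knn(model, X[7])[0] == y[7]

    def test_tie_break_deterministic(self):
        X = np.array([[0.0], [0.0], [5.0]])
        y = np.array(["b", "a", "c"])
        from riemgait.kernel_metric import MetricModel
        model = MetricModel(L=np.eye(1), config=TrainConfig(k_classify=2),
                            train_columns=X[:2], train_labels=y[:2])
        # both voters at distance 0 -> tie on count and distance -> label order
        assert classify_knn(model, np.array([[0.0]]))[0] == "a"

    def test_chance_on_permuted_labels(self, rng):
        X, _ = _separable_columns(rng, classes=4, n_per=12, sep=10.0)
        y = np.array([f"s{i % 4}" for i in rng.permutation(48)])
        report = cross_validate(X, X.copy() + rng.random((48, 6)), y,
                                TrainConfig(p=6), mode="fused",
                                n_folds=4, n_repeats=2, seed=0)
        assert abs(report.mean_accuracy - 0.25) <= 0.12


class TestCrossValidate:
    def test_separable_perfect(self, rng):
        Xs, y = _separable_columns(rng, classes=3, n_per=10)
        Xt = Xs @ rng.standard_normal((6, 5))  # correlated temporal view
        report = cross_validate(Xs, Xt, y, TrainConfig(p=6), mode="fused",
                                n_folds=5, n_repeats=2, seed=1)
        assert report.mean_accuracy == 1.0

    def test_fold_counts_and_stratification(self, rng):
        from sklearn.model_selection import StratifiedKFold
        y = np.repeat(["a", "b"], 10)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.zeros(20, dtype=int)
        for _, test_idx in skf.split(np.zeros(20), y):
            seen[test_idx] += 1
            _, counts = np.unique(y[test_idx], return_counts=True)
            assert np.ptp(counts) <= 1
        assert np.all(seen == 1)

    def test_single_class_raises(self, rng):
        X = rng.random((10, 3))
        with pytest.raises(ValueError):
            cross_validate(X, X, np.array(["a"] * 10))

    def test_no_leakage_bandwidths(self, rng):
        # model trained on a fold must equal a model trained on the fold's
        # data alone (test rows physically removed)
        Xs, y = _separable_columns(rng, classes=2, n_per=8, sep=4.0)
        Xt = Xs + rng.random(Xs.shape)
        train_idx = np.arange(12)
        cols_a, da, ba = kernel_columns(Xs[train_idx], Xt[train_idx], "fused")
        cols_b, db, bb = kernel_columns(Xs[:12].copy(), Xt[:12].copy(), "fused")
        assert da == db and ba == bb
        assert np.allclose(cols_a, cols_b)
        ma = train_metric(cols_a, y[train_idx], TrainConfig(p=4, max_epochs=5))
        mb = train_metric(cols_b, y[:12], TrainConfig(p=4, max_epochs=5))
        assert np.allclose(ma.L, mb.L)


class TestQueryColumns:
    def test_query_equals_train_row(self, rng):
        Xs = rng.random((6, 3))
        Xt = rng.random((6, 4))
        cols, delta, beta = kernel_columns(Xs, Xt, "fused")
        q = build_query_columns(Xs, Xt, Xs[2:3], Xt[2:3], delta, beta, "fused")
        assert np.allclose(q[0], cols[2], atol=1e-12)
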