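"""GP regression and multiple kernel learning against closed forms and oracles."""

import numpy as np
import pytest

import lesiondecode as ld
from lesiondecode.features import CovarianceMatrix
from lesiondecode.gp import LOG2PI, mkl_weight_gradient
from oracles import primal_ridge_mean


def _cov(values):
    return CovarianceMatrix(np.asarray(values, float), True)


class TestLogMarginalLikelihood:
    def test_identity_kernel_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(2, 12)
            y = rng.normal(size=n)
            L = ld.log_marginal_likelihood(np.eye(n), y)
            assert L == pytest.approx(-0.5 * y @ y - 0.5 * n * LOG2PI, abs=1e-10)

    def test_scaled_identity_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(2, 10))
            c = float(rng.uniform(0.2, 5.0))
            y = rng.normal(size=n)
            L = ld.log_marginal_likelihood(c * np.eye(n), y)
            expect = -0.5 * n * np.log(c) - y @ y / (2 * c) - 0.5 * n * LOG2PI
            assert L == pytest.approx(expect, abs=1e-10)

    def test_shrinking_y_raises_likelihood(self):
        rng = np.random.default_rng(2)
        K = np.eye(5) * 2.0
        y = rng.normal(size=5)
        Ls = [ld.log_marginal_likelihood(K, y * t) for t in (1.0, 0.5, 0.1, 0.0)]
        assert all(a < b for a, b in zip(Ls, Ls[1:]))
        assert Ls[-1] == pytest.approx(-0.5 * 5 * np.log(2.0) - 0.5 * 5 * LOG2PI)


class TestGprFit:
    def test_low_noise_interpolation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        C = X @ X.T
        a = rng.normal(size=12)
        y = C @ a
        y /= y.std()
        model = ld.gpr_fit(_cov(C), y)
        assert model.noise_variance < 1e-3
        preds, _ = ld.gpr_predict(model, _cov(C))
        assert np.allclose(preds, y, atol=1e-2)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        C = X @ X.T
        perm = rng.permutation(8)
        m1 = ld.gpr_fit(_cov(C), y)
        m2 = ld.gpr_fit(_cov(C[np.ix_(perm, perm)]), y[perm])
        assert m1.signal_scale == pytest.approx(m2.signal_scale, rel=1e-5)
        assert m1.noise_variance == pytest.approx(m2.noise_variance, rel=1e-5)

    def test_optimizer_never_worse_than_init(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.normal(size=(10, 4))
            y = rng.normal(size=10)
            C = X @ X.T
            init = (0.7, 0.3)
            L0 = ld.log_marginal_likelihood(init[0] * C + init[1] * np.eye(10), y)
            model = ld.gpr_fit(_cov(C), y, init=init)
            assert model.log_marginal >= L0 - 1e-9

    def test_reported_l_consistent_with_direct_evaluation(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        C = X @ X.T
        model = ld.gpr_fit(_cov(C), y)
        K_y = model.signal_scale * C + model.noise_variance * np.eye(9)
        assert model.log_marginal == pytest.approx(
            ld.log_marginal_likelihood(K_y, y), abs=1e-8
        )
        # alpha solves K_y alpha = y
        assert np.linalg.norm(K_y @ model.alpha - y) <= 1e-8 * np.linalg.norm(y)


class TestGprPredict:
    def test_single_training_subject_closed_form(self):
        c, cstar, v = 2.0, 1.5, 0.3
        y = np.array([0.8])
        model = ld.GPModel(
            kind="gpr", noise_variance=v, alpha=np.array([y[0] / (c + v)]),
            log_marginal=0.0, signal_scale=1.0,
            train_kernel=np.array([[c]]),
            K_y_inv=np.array([[1.0 / (c + v)]]),
        )
        mean, var = ld.gpr_predict(model, np.array([[cstar]]),
                                   test_self_diag=np.array([cstar]))
        assert mean[0] == pytest.approx(cstar * y[0] / (c + v))
        assert var[0] == pytest.approx(cstar - cstar**2 / (c + v))

    def test_matches_primal_ridge_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n, d = int(rng.integers(3, 15)), int(rng.integers(2, 20))
            X = rng.normal(size=(n, d))
            Xs = rng.normal(size=(4, d))
            y = rng.normal(size=n)
            model = ld.gpr_fit(_cov(X @ X.T), y)
            mean, _ = ld.gpr_predict(model, Xs @ X.T)
            oracle = primal_ridge_mean(X, y, Xs, model.noise_variance,
                                       model.signal_scale)
            assert np.allclose(mean, oracle, atol=1e-8)

    def test_predictive_variances_nonnegative(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = ld.gpr_fit(_cov(X @ X.T), y)
        Xs = rng.normal(size=(6, 5))
        _, var = ld.gpr_predict(model, Xs @ X.T,
                                test_self_diag=np.einsum("ij,ij->i", Xs, Xs))
        assert (var >= -1e-8).all()

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 3))
        model = ld.gpr_fit(_cov(X @ X.T), rng.normal(size=5))
        with pytest.raises(ValueError):
            ld.gpr_predict(model, np.ones((2, 4)))


def _source_set(rng, n, M):
    kernels, names = [], []
    for i in range(M):
        X = rng.normal(size=(n, 3))
        kernels.append(_cov(X @ X.T))
        names.append(f"src{i}")
    return ld.SourceKernelSet(kernels, names)


class TestMklFit:
    def test_single_source_reduces_to_gpr(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        C = X @ X.T
        gpr = ld.gpr_fit(_cov(C), y)
        mkl = ld.mkl_fit(ld.SourceKernelSet([_cov(C)], ["only"]), y)
        assert mkl.log_marginal == pytest.approx(gpr.log_marginal, abs=1e-6)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n, M = 5, 3
            src = _source_set(rng, n, M)
            y = rng.normal(size=n)
            w = rng.uniform(0.3, 2.0, size=M)
            v = 0.4
            grad = mkl_weight_gradient(src, w, v, y)
            Cs = src.stacked()
            step = 1e-5
            for i in range(M):
                wp, wm = w.copy(), w.copy()
                wp[i] += step
                wm[i] -= step
                Kp = np.tensordot(wp, Cs, axes=1) + v * np.eye(n)
                Km = np.tensordot(wm, Cs, axes=1) + v * np.eye(n)
                fd = (
                    ld.log_marginal_likelihood(Kp, y)
                    - ld.log_marginal_likelihood(Km, y)
                ) / (2 * step)
                assert grad[i] == pytest.approx(fd, abs=1e-5)

    def test_informative_source_gets_top_weight(self):
        rng = np.random.default_rng(12)
        hits = 0
        for rep in range(10):
            n, M = 40, 5
            Xs = [rng.normal(size=(n, 6)) for _ in range(M)]
            y = Xs[1] @ rng.normal(size=6)
            y = (y - y.mean()) / y.std()
            src = ld.SourceKernelSet([_cov(X @ X.T) for X in Xs],
                                     [f"s{i}" for i in range(M)])
            model = ld.mkl_fit(src, y, seed=rep)
            if int(np.argmax(model.source_weights)) == 1:
                hits += 1
        assert hits >= 8

    def test_equal_sources_match_single_source_sum(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(9, 4))
        C = X @ X.T
        y = C @ rng.normal(size=9) + 0.3 * rng.normal(size=9)
        y = (y - y.mean()) / y.std()
        single = ld.gpr_fit(_cov(C), y)
        mkl = ld.mkl_fit(ld.SourceKernelSet([_cov(C)] * 3, list("abc")), y)
        # split among equal sources is non-identifiable; only the sum matters
        assert mkl.source_weights.sum() == pytest.approx(
            single.signal_scale, rel=1e-3
        )
        assert mkl.log_marginal == pytest.approx(single.log_marginal, abs=1e-6)

    def test_adding_noise_source_never_hurts_likelihood(self):
        rng = np.random.default_rng(14)
        n = 10
        X = rng.normal(size=(n, 4))
        y = rng.normal(size=n)
        base = ld.SourceKernelSet([_cov(X @ X.T)], ["a"])
        Z = rng.normal(size=(n, 4))
        extended = ld.SourceKernelSet([_cov(X @ X.T), _cov(Z @ Z.T)], ["a", "b"])
        L1 = ld.mkl_fit(base, y).log_marginal
        L2 = ld.mkl_fit(extended, y).log_marginal
        assert L2 >= L1 - 1e-6

    def test_fixed_noise_mode(self):
        rng = np.random.default_rng(15)
        src = _source_set(rng, 8, 2)
        y = rng.normal(size=8)
        model = ld.mkl_fit(src, y, noise_variance=0.5, optimize_noise=False)
        assert model.noise_variance == pytest.approx(0.5)

    def test_serialized_weights_sorted_descending(self):
        rng = np.random.default_rng(16)
        src = _source_set(rng, 8, 4)
        y = rng.normal(size=8)
        model = ld.mkl_fit(src, y)
        from lesiondecode.gp import serialize_model

        ws = [row["weight"] for row in serialize_model(model)["source_weights"]]
        assert ws == sorted(ws, reverse=True)
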