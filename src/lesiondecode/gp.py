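"""Gaussian-process regression on precomputed linear covariances, and
multiple kernel learning (MKL) by marginal-likelihood ascent.

The model is y = f(x) + eps with eps ~ N(0, sigma_n^2) and a GP prior on
f whose covariance between training examples is a precomputed dot-product
kernel.  The single-source model uses K_y = s * C + sigma_n^2 * I; the
multi-source model uses K_y = sum_i w_i * C_i + sigma_n^2 * I with one
kernel per information source (e.g. one anatomical region each).  All
hyperparameters (signal scale or source weights, and the noise variance)
maximize the standard multivariate Gaussian log marginal likelihood

    L = -1/2 log|K_y| - 1/2 y^T K_y^{-1} y - (n/2) log 2 pi,

with nonnegativity of the weights enforced through a log
parameterization and gradients computed analytically:

    dL/dw_i = 1/2 tr((alpha alpha^T - K_y^{-1}) C_i),  alpha = K_y^{-1} y.

Because the weights scale kernels built from identically standardized
features, they are interpretable as the relevance of each source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize

from .features import CovarianceMatrix

LOG2PI = float(np.log(2.0 * np.pi))


class GPNumericsError(RuntimeError):
    pass


class GPFitError(RuntimeError):
    def __init__(self, msg: str, trace=None):
        super().__init__(msg)
        self.trace = trace


@dataclass
class GPModel:
    """A fitted GP regressor over precomputed kernels."""

    kind: str  # "gpr" | "mkl"
    noise_variance: float
    alpha: np.ndarray  # K_y^{-1} y
    log_marginal: float
    signal_scale: float | None = None  # single-source
    source_weights: np.ndarray | None = None  # MKL
    source_names: list[str] | None = None
    train_kernel: np.ndarray | None = None  # combined signal kernel (no noise)
    K_y_inv: np.ndarray | None = None
    converged: bool = True

    @property
    def normalized_weights(self) -> np.ndarray | None:
        if self.source_weights is None:
            return None
        s = self.source_weights.sum()
        return self.source_weights / s if s > 0 else self.source_weights


@dataclass
class SourceKernelSet:
    """M training kernels over the same subjects, identically standardized."""

    kernels: list[CovarianceMatrix]
    source_names: list[str]

    def __post_init__(self):
        n = self.kernels[0].values.shape[0]
        for k in self.kernels:
            if k.values.shape != (n, n):
                raise ValueError("source kernels differ in shape")
        if len(self.source_names) != len(self.kernels):
            raise ValueError("one name per kernel required")

    def stacked(self) -> np.ndarray:
        return np.stack([k.values for k in self.kernels])


def _chol(K: np.ndarray):
    """Cholesky with a single jitter retry (1e-8 * trace / n)."""
    try:
        return cho_factor(K, lower=True)
    except LinAlgError:
        n = K.shape[0]
        jitter = 1e-8 * np.trace(K) / n + 1e-12
        try:
            return cho_factor(K + jitter * np.eye(n), lower=True)
        except LinAlgError as e:
            raise GPNumericsError(
                "covariance is not positive definite even after jitter"
            ) from e


def log_marginal_likelihood(K_y, y: np.ndarray) -> float:
    """L = -1/2 log|K_y| - 1/2 y^T K_y^{-1} y - (n/2) log 2 pi."""
    K = K_y.values if isinstance(K_y, CovarianceMatrix) else np.asarray(K_y)
    y = np.asarray(y, dtype=float)
    c, low = _chol(K)
    alpha = cho_solve((c, low), y)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * logdet - 0.5 * y @ alpha - 0.5 * len(y) * LOG2PI)


def _neg_L_and_grad(theta: np.ndarray, Cs: np.ndarray, y: np.ndarray):
    """Negative L and gradient in theta = log(w_1..w_M, sigma_n^2)."""
    w = np.exp(theta)
    n = len(y)
    K = np.tensordot(w[:-1], Cs, axes=1) + w[-1] * np.eye(n)
    c, low = _chol(K)
    alpha = cho_solve((c, low), y)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    L = -0.5 * logdet - 0.5 * y @ alpha - 0.5 * n * LOG2PI
    Kinv = cho_solve((c, low), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv
    grad = np.empty_like(theta)
    for i in range(Cs.shape[0]):
        grad[i] = 0.5 * np.sum(A * Cs[i]) * w[i]
    grad[-1] = 0.5 * np.trace(A) * w[-1]
    return -L, -grad


def mkl_weight_gradient(kernels, weights, noise_variance, y) -> np.ndarray:
    """Analytic dL/dw_i = 1/2 tr((alpha alpha^T - K_y^{-1}) C_i)."""
    Cs = (
        kernels.stacked()
        if isinstance(kernels, SourceKernelSet)
        else np.stack([k.values if isinstance(k, CovarianceMatrix) else k for k in kernels])
    )
    y = np.asarray(y, float)
    n = len(y)
    K = np.tensordot(np.asarray(weights, float), Cs, axes=1) + noise_variance * np.eye(n)
    c, low = _chol(K)
    alpha = cho_solve((c, low), y)
    Kinv = cho_solve((c, low), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv
    return np.array([0.5 * np.sum(A * Cs[i]) for i in range(Cs.shape[0])])


def _optimize(Cs: np.ndarray, y: np.ndarray, starts, max_iter: int, tol: float):
    best = None
    trace = []
    for x0 in starts:
        res = minimize(
            _neg_L_and_grad,
            x0=np.asarray(x0, dtype=float),
            args=(Cs, y),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-20.0, 20.0)] * len(x0),
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        trace.append((np.asarray(x0), res.fun, res.status))
        if best is None or res.fun < best.fun:
            best = res
    return best, trace


def _finalize(kind, Cs, y, theta, L, names=None, converged=True) -> GPModel:
    w = np.exp(theta)
    n = len(y)
    signal_K = np.tensordot(w[:-1], Cs, axes=1)
    K = signal_K + w[-1] * np.eye(n)
    c, low = _chol(K)
    alpha = cho_solve((c, low), y)
    Kinv = cho_solve((c, low), np.eye(n))
    return GPModel(
        kind=kind,
        noise_variance=float(w[-1]),
        alpha=alpha,
        log_marginal=float(L),
        signal_scale=float(w[0]) if kind == "gpr" else None,
        source_weights=w[:-1].copy() if kind == "mkl" else None,
        source_names=names,
        train_kernel=signal_K,
        K_y_inv=Kinv,
        converged=converged,
    )


def gpr_fit(
    C,
    y: np.ndarray,
    init: tuple[float, float] = (1.0, 0.1),
    max_iter: int = 200,
    tol: float = 1e-10,
) -> GPModel:
    """Fit signal scale s and noise variance by marginal-likelihood ascent.

    Optimization runs in (log s, log sigma_n^2) with L-BFGS-B from the
    supplied init plus fixed spread restarts; the best optimum wins, and
    the fitted L never falls below L at the initialization.
    """
    Cv = C.values if isinstance(C, CovarianceMatrix) else np.asarray(C)
    y = np.asarray(y, dtype=float)
    Cs = Cv[None]
    s0, v0 = init
    if s0 <= 0 or v0 <= 0:
        raise ValueError("init scale and noise variance must be positive")
    base = np.log([s0, v0])
    starts = [base, base + [2.0, 1.0], base + [-2.0, -2.0], np.array([0.0, -4.0])]
    best, trace = _optimize(Cs, y, starts, max_iter, tol)
    if best is None or not np.isfinite(best.fun):
        raise GPFitError("GPR hyperparameter optimization failed", trace)
    return _finalize("gpr", Cs, y, best.x, -best.fun)


def gpr_predict(
    model: GPModel,
    cross,
    test_self_diag: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Predictive means (and variances) for held-out subjects.

    ``cross`` is the raw test-by-train kernel (or the list of per-source
    cross kernels for MKL); the model applies its fitted scale/weights.
    Variances need ``test_self_diag``, the raw prior self-covariance
    diagonal of the test subjects (per source for MKL).
    """
    if model.kind == "mkl":
        crosses = [
            c.values if isinstance(c, CovarianceMatrix) else np.asarray(c)
            for c in cross
        ]
        Kstar = sum(w * c for w, c in zip(model.source_weights, crosses))
    else:
        c = cross.values if isinstance(cross, CovarianceMatrix) else np.asarray(cross)
        Kstar = model.signal_scale * c
    if Kstar.shape[1] != len(model.alpha):
        raise ValueError(
            f"cross kernel has {Kstar.shape[1]} training columns, "
            f"model has {len(model.alpha)} training subjects"
        )
    mean = Kstar @ model.alpha
    var = None
    if test_self_diag is not None:
        if model.kind == "mkl":
            prior = sum(
                w * np.asarray(d)
                for w, d in zip(model.source_weights, test_self_diag)
            )
        else:
            prior = model.signal_scale * np.asarray(test_self_diag)
        var = prior - np.einsum("ij,jk,ik->i", Kstar, model.K_y_inv, Kstar)
    return mean, var


def mkl_fit(
    sources: SourceKernelSet,
    y: np.ndarray,
    init_weights: np.ndarray | None = None,
    noise_variance: float | None = None,
    optimize_noise: bool = True,
    max_iter: int = 500,
    tol: float = 1e-10,
    n_restarts: int = 2,
    seed: int = 0,
) -> GPModel:
    """Learn nonnegative source weights by marginal-likelihood ascent.

    Weights are parameterized as w_i = exp(theta_i); the noise variance is
    jointly optimized by default (or held fixed when ``noise_variance`` is
    given with ``optimize_noise=False``).  Restarts: uniform weights plus
    ``n_restarts`` random log-weight draws.  On non-convergence the
    best-so-far model is returned with ``converged=False`` and a warning.
    """
    Cs = sources.stacked()
    y = np.asarray(y, dtype=float)
    M = Cs.shape[0]
    rng = np.random.default_rng(seed)
    w0 = np.full(M, 1.0 / M) if init_weights is None else np.asarray(init_weights, float)
    v0 = 0.1 if noise_variance is None else float(noise_variance)
    base = np.log(np.concatenate([w0, [v0]]))
    starts = [base]
    for _ in range(n_restarts):
        starts.append(
            np.concatenate([rng.normal(0.0, 1.5, size=M), [np.log(v0) + rng.normal()]])
        )

    if optimize_noise:
        best, trace = _optimize(Cs, y, starts, max_iter, tol)
        if best is None or not np.isfinite(best.fun):
            raise GPFitError("MKL optimization failed", trace)
        theta = best.x
        L = -best.fun
        # status 1 (iteration cap) still yields a usable optimum; only an
        # abnormal line-search failure counts as non-convergence
        converged = best.status != 2
    else:
        # optimize weights only, noise pinned
        logv = np.log(v0)

        def f(th):
            nl, ng = _neg_L_and_grad(np.concatenate([th, [logv]]), Cs, y)
            return nl, ng[:-1]

        best = None
        trace = []
        for x0 in starts:
            res = minimize(
                f,
                x0=x0[:-1],
                jac=True,
                method="L-BFGS-B",
                bounds=[(-20.0, 20.0)] * M,
                options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
            )
            trace.append((x0[:-1], res.fun, res.status))
            if best is None or res.fun < best.fun:
                best = res
        theta = np.concatenate([best.x, [logv]])
        L = -best.fun
        converged = best.status != 2

    if not converged:
        warnings.warn(
            "MKL weight optimization did not fully converge; returning the "
            "best parameters found",
            RuntimeWarning,
            stacklevel=2,
        )
    return _finalize(
        "mkl", Cs, y, theta, L, names=list(sources.source_names), converged=converged
    )


def serialize_model(model: GPModel) -> dict:
    """Structured-text form: parameters, L, weights sorted descending."""
    out = {
        "kind": model.kind,
        "noise_variance": model.noise_variance,
        "log_marginal_likelihood": model.log_marginal,
        "converged": model.converged,
    }
    if model.kind == "gpr":
        out["signal_scale"] = model.signal_scale
    else:
        names = model.source_names or [
            f"source{i}" for i in range(len(model.source_weights))
        ]
        order = np.argsort(model.source_weights)[::-1]
        nw = model.normalized_weights
        out["source_weights"] = [
            {
                "source": names[i],
                "weight": float(model.source_weights[i]),
                "weight_normalized": float(nw[i]),
            }
            for i in order
        ]
    return out
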