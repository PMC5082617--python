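"""Gaussian-process binary classification with approximate inference.

A zero-mean GP prior with a squared-exponential kernel (isotropic or ARD) is
placed on a latent function; class labels in {-1,+1} enter through a logistic
or probit likelihood.  The non-Gaussian posterior is approximated by Laplace's
method (Newton iterations on the latent posterior mode) or, optionally, by
Expectation Propagation with a probit likelihood.  Kernel hyperparameters are
chosen by maximizing the approximate log marginal likelihood.

The implementation follows the standard formulations of GP classification:
mode finding and marginal-likelihood evaluation use the numerically stable
B = I + W^1/2 K W^1/2 factorization, and predictive class probabilities
average the likelihood over the Gaussian latent predictive distribution
(Gauss-Hermite quadrature for logistic, closed form for probit).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, log_ndtr, ndtr

from gragp.data_io import LabelVector, ValidationError

logger = logging.getLogger(__name__)

_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(64)  # probabilists' Hermite
_GH_W = _GH_W / _GH_W.sum()


@dataclass
class GPConfig:
    """Kernel, likelihood and inference choices for the GP classifier."""

    kernel: str = "squared-exponential-ard"
    inference: str = "laplace"
    likelihood: str = "logistic"
    optimize_hypers: bool = True
    max_opt_iters: int = 100
    standardize: bool = True
    jitter_scale: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in {"squared-exponential-iso", "squared-exponential-ard"}:
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if self.inference not in {"laplace", "ep"}:
            raise ValidationError(f"unknown inference {self.inference!r}")
        if self.likelihood not in {"logistic", "probit"}:
            raise ValidationError(f"unknown likelihood {self.likelihood!r}")
        if self.inference == "ep" and self.likelihood != "probit":
            raise ValidationError("EP inference requires the probit likelihood")
        if self.max_opt_iters < 1:
            raise ValidationError("max_opt_iters must be >= 1")


@dataclass
class GPModel:
    """Fitted GP classifier: training data, hyperparameters and posterior state."""

    X: np.ndarray  # standardized training inputs, samples x genes
    y: np.ndarray  # targets in {-1, +1}
    cfg: GPConfig
    log_lengthscales: np.ndarray
    log_amplitude: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    log_marginal: float = 0.0
    # Laplace state
    f_hat: np.ndarray | None = None
    grad_loglik: np.ndarray | None = None
    sqrt_w: np.ndarray | None = None
    chol_b: np.ndarray | None = None
    # EP state
    nu_tilde: np.ndarray | None = None
    tau_tilde: np.ndarray | None = None


# ---------------------------------------------------------------- likelihoods


def _log_lik(y: np.ndarray, f: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return -np.logaddexp(0.0, -y * f)
    return log_ndtr(y * f)


def _grad_hess_loglik(y: np.ndarray, f: np.ndarray, kind: str):
    """Returns (gradient, W = -Hessian diagonal) of the log likelihood in f."""
    if kind == "logistic":
        pi = expit(f)
        grad = (y + 1) / 2.0 - pi
        w = pi * (1.0 - pi)
        return grad, np.maximum(w, 1e-12)
    z = y * f
    ratio = np.exp(_log_npdf(z) - log_ndtr(z))
    grad = y * ratio
    w = ratio * (ratio + z)
    return grad, np.maximum(w, 1e-12)


def _log_npdf(z: np.ndarray) -> np.ndarray:
    return -0.5 * z**2 - 0.5 * np.log(2.0 * np.pi)


def _mean_lik(mu: np.ndarray, var: np.ndarray, kind: str) -> np.ndarray:
    """E[p(y=+1|f*)] with f* ~ N(mu, var)."""
    if kind == "probit":
        return ndtr(mu / np.sqrt(1.0 + var))
    z = mu[:, None] + np.sqrt(np.maximum(var, 0.0))[:, None] * _GH_X[None, :]
    return expit(z) @ _GH_W


# -------------------------------------------------------------------- kernels


def se_kernel(
    xa: np.ndarray,
    xb: np.ndarray,
    log_lengthscales: np.ndarray,
    log_amplitude: float,
) -> np.ndarray:
    """Squared-exponential kernel sf^2 exp(-0.5 sum_d (xa_d - xb_d)^2 / l_d^2).

    A single length-scale broadcasts across dimensions (isotropic); one per
    dimension gives ARD.
    """
    ell = np.exp(np.asarray(log_lengthscales, dtype=float))
    sf2 = np.exp(2.0 * log_amplitude)
    a = np.asarray(xa, dtype=float) / ell
    b = np.asarray(xb, dtype=float) / ell
    sq = (
        (a**2).sum(axis=1)[:, None]
        + (b**2).sum(axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return sf2 * np.exp(-0.5 * np.maximum(sq, 0.0))


def _train_kernel(model_X: np.ndarray, log_ls, log_amp, jitter_scale: float) -> np.ndarray:
    k = se_kernel(model_X, model_X, log_ls, log_amp)
    n = k.shape[0]
    jitter = jitter_scale * np.trace(k) / n
    return k + jitter * np.eye(n)


# ----------------------------------------------------------- Laplace inference


def _laplace_mode(K: np.ndarray, y: np.ndarray, kind: str, tol: float = 1e-10):
    """Newton iteration for the posterior mode; stable B-matrix formulation.

    Returns (f_hat, grad, sqrt_w, L, log_marginal).
    """
    n = y.size
    f = np.zeros(n)
    obj_prev = -np.inf
    a = np.zeros(n)
    for _ in range(100):
        grad, w = _grad_hess_loglik(y, f, kind)
        sw = np.sqrt(w)
        B = np.eye(n) + sw[:, None] * K * sw[None, :]
        L = cholesky(B, lower=True)
        b = w * f + grad
        v = solve_triangular(L, sw * (K @ b), lower=True)
        a = b - sw * solve_triangular(L.T, v, lower=False)
        f = K @ a
        obj = -0.5 * a @ f + _log_lik(y, f, kind).sum()
        if abs(obj - obj_prev) < tol:
            break
        obj_prev = obj
    grad, w = _grad_hess_loglik(y, f, kind)
    sw = np.sqrt(w)
    B = np.eye(n) + sw[:, None] * K * sw[None, :]
    L = cholesky(B, lower=True)
    lml = -0.5 * a @ f + _log_lik(y, f, kind).sum() - np.log(np.diag(L)).sum()
    return f, grad, sw, L, float(lml)


# ---------------------------------------------------------------- EP inference


def _ep_posterior(K: np.ndarray, y: np.ndarray, max_sweeps: int = 60, tol: float = 1e-7):
    """Expectation propagation for the probit likelihood.

    Returns (nu_tilde, tau_tilde, log_marginal).
    """
    n = y.size
    nu = np.zeros(n)
    tau = np.zeros(n)
    sigma = K.copy()
    mu = np.zeros(n)
    for _ in range(max_sweeps):
        tau_old_sweep = tau.copy()
        for i in range(n):
            tau_cav = 1.0 / sigma[i, i] - tau[i]
            nu_cav = mu[i] / sigma[i, i] - nu[i]
            if tau_cav <= 0:
                continue
            mu_cav = nu_cav / tau_cav
            var_cav = 1.0 / tau_cav
            z = y[i] * mu_cav / np.sqrt(1.0 + var_cav)
            ratio = np.exp(_log_npdf(z) - log_ndtr(z))
            mu_hat = mu_cav + y[i] * var_cav * ratio / np.sqrt(1.0 + var_cav)
            var_hat = var_cav - var_cav**2 * ratio * (z + ratio) / (1.0 + var_cav)
            var_hat = max(var_hat, 1e-12)
            d_tau = 1.0 / var_hat - tau_cav - tau[i]
            tau[i] += d_tau
            nu[i] = mu_hat / var_hat - nu_cav
            si = sigma[:, i]
            sigma -= (d_tau / (1.0 + d_tau * sigma[i, i])) * np.outer(si, si)
            mu = sigma @ nu
        # full recompute for numerical hygiene
        s_sqrt = np.sqrt(np.maximum(tau, 0.0))
        B = np.eye(n) + s_sqrt[:, None] * K * s_sqrt[None, :]
        L = cholesky(B, lower=True)
        v = solve_triangular(L, s_sqrt[:, None] * K, lower=True)
        sigma = K - v.T @ v
        mu = sigma @ nu
        if np.max(np.abs(tau - tau_old_sweep)) < tol:
            break
    lml = _ep_log_marginal(K, y, nu, tau)
    return nu, tau, lml


def _ep_log_marginal(K, y, nu, tau) -> float:
    n = y.size
    s_sqrt = np.sqrt(np.maximum(tau, 1e-12))
    B = np.eye(n) + s_sqrt[:, None] * K * s_sqrt[None, :]
    L = cholesky(B, lower=True)
    v = solve_triangular(L, s_sqrt[:, None] * K, lower=True)
    sigma = K - v.T @ v
    mu = sigma @ nu
    tau_cav = 1.0 / np.maximum(np.diag(sigma), 1e-12) - tau
    nu_cav = mu / np.maximum(np.diag(sigma), 1e-12) - nu
    tau_cav = np.maximum(tau_cav, 1e-12)
    mu_cav = nu_cav / tau_cav
    var_cav = 1.0 / tau_cav
    z = y * mu_cav / np.sqrt(1.0 + var_cav)
    lz = log_ndtr(z).sum()
    term0 = -np.log(np.diag(L)).sum()
    term1 = 0.5 * np.log1p(tau / tau_cav).sum()
    w = solve_triangular(L, s_sqrt * (K @ nu), lower=True)
    term2 = 0.5 * nu @ (K @ nu) - 0.5 * w @ w
    term3 = -0.5 * (nu**2 / (tau + tau_cav)).sum()
    term4 = 0.5 * (
        (mu_cav * tau_cav - nu)
        * (nu / tau_cav - mu_cav * tau / tau_cav)
        / (1.0 + tau / tau_cav)
    ).sum()
    return float(lz + term0 + term1 + term2 + term3 + term4)


# ------------------------------------------------------------------- training


def _as_pm1(y) -> np.ndarray:
    if isinstance(y, LabelVector):
        y = y.labels
    y = np.asarray(y)
    uniq = set(np.unique(y).tolist())
    if uniq <= {0, 1}:
        return np.where(np.asarray(y) == 1, 1.0, -1.0)
    if uniq <= {-1, 1}:
        return np.asarray(y, dtype=float)
    raise ValidationError("targets must be coded 0/1 or -1/+1")


def gp_train(X: np.ndarray, y, cfg: GPConfig | None = None) -> GPModel:
    """Fit the GP classifier; hyperparameters maximize the approximate LML.

    ``X`` is samples x genes; ``y`` a LabelVector or 0/1 (or -1/+1) array.
    Training is deterministic for fixed inputs and configuration.
    """
    cfg = cfg or GPConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be samples x genes")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X must be finite")
    t = _as_pm1(y)
    if t.size != X.shape[0]:
        raise ValidationError("targets must align with rows of X")
    if np.sum(t > 0) < 2 or np.sum(t < 0) < 2:
        raise ValidationError("each class needs at least two training samples")

    if cfg.standardize:
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
    else:
        x_mean = np.zeros(X.shape[1])
        x_scale = np.ones(X.shape[1])
    Xs = (X - x_mean) / x_scale

    n_ls = X.shape[1] if cfg.kernel == "squared-exponential-ard" else 1
    theta0 = np.zeros(n_ls + 1)  # log lengthscales = 0, log amplitude = 0

    def neg_lml(theta: np.ndarray) -> float:
        K = _train_kernel(Xs, theta[:n_ls], theta[n_ls], cfg.jitter_scale)
        try:
            if cfg.inference == "laplace":
                *_, lml = _laplace_mode(K, t, cfg.likelihood)
            else:
                *_, lml = _ep_posterior(K, t)
        except np.linalg.LinAlgError:
            return 1e10
        if not np.isfinite(lml):
            return 1e10
        return -lml

    theta = theta0
    if cfg.optimize_hypers:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                neg_lml,
                theta0,
                method="L-BFGS-B",
                bounds=[(-5.0, 5.0)] * (n_ls + 1),
                options={"maxiter": cfg.max_opt_iters},
            )
        if np.isfinite(res.fun) and res.fun < neg_lml(theta0):
            theta = res.x
        else:
            logger.warning("hyperparameter optimization failed; keeping initial values")

    model = GPModel(
        X=Xs,
        y=t,
        cfg=cfg,
        log_lengthscales=theta[:n_ls].copy(),
        log_amplitude=float(theta[n_ls]),
        x_mean=x_mean,
        x_scale=x_scale,
    )
    K = _train_kernel(Xs, model.log_lengthscales, model.log_amplitude, cfg.jitter_scale)
    if cfg.inference == "laplace":
        f, grad, sw, L, lml = _laplace_mode(K, t, cfg.likelihood)
        model.f_hat, model.grad_loglik, model.sqrt_w, model.chol_b = f, grad, sw, L
        model.log_marginal = lml
    else:
        nu, tau, lml = _ep_posterior(K, t)
        model.nu_tilde, model.tau_tilde = nu, tau
        model.log_marginal = lml
    return model


def gp_predict(model: GPModel, Xstar: np.ndarray, return_latent: bool = False):
    """Predictive probability of class +1 at each row of ``Xstar``.

    Probabilities lie strictly inside (0,1); the hard decision is prob > 0.5.
    With ``return_latent=True`` also returns the latent mean and variance.
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != model.X.shape[1]:
        raise ValidationError(
            f"Xstar has {Xstar.shape[1]} columns; model expects {model.X.shape[1]}"
        )
    Xs = (Xstar - model.x_mean) / model.x_scale
    ks = se_kernel(model.X, Xs, model.log_lengthscales, model.log_amplitude)
    kss = np.exp(2.0 * model.log_amplitude) * np.ones(Xs.shape[0])

    if model.cfg.inference == "laplace":
        mu = ks.T @ model.grad_loglik
        v = solve_triangular(model.chol_b, model.sqrt_w[:, None] * ks, lower=True)
        var = kss - (v**2).sum(axis=0)
    else:
        n = model.y.size
        tau, nu = model.tau_tilde, model.nu_tilde
        s_sqrt = np.sqrt(np.maximum(tau, 1e-12))
        K = _train_kernel(
            model.X, model.log_lengthscales, model.log_amplitude, model.cfg.jitter_scale
        )
        B = np.eye(n) + s_sqrt[:, None] * K * s_sqrt[None, :]
        L = cholesky(B, lower=True)
        z = s_sqrt * solve_triangular(
            L.T, solve_triangular(L, s_sqrt * (K @ nu), lower=True), lower=False
        )
        mu = ks.T @ (nu - z)
        v = solve_triangular(L, s_sqrt[:, None] * ks, lower=True)
        var = kss - (v**2).sum(axis=0)

    var = np.maximum(var, 1e-12)
    prob = np.clip(_mean_lik(mu, var, model.cfg.likelihood), 1e-12, 1.0 - 1e-12)
    if return_latent:
        return prob, mu, var
    return prob
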