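"""Pooled linear fits and EM for mixtures of linear regressions.

The mixture model assumes each observation (z_i, y_i) is drawn from one of K
Gaussian linear regressions

    y | z, component k  ~  N(alpha_k + z' beta_k, sigma_k^2),

with unconstrained per-component residual variances and mixing weights pi on
the K-simplex. Fitting alternates an E-step (posterior responsibilities from
component densities times weights) and an M-step (responsibility-weighted
least squares plus weight updates), retaining the best of several random
restarts. Label switching is resolved only post hoc, by picking the component
with the largest mean absolute slope (the "informative" component).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .errors import DegenerateEMError, SingularDesignError

__all__ = [
    "LinearFit",
    "MixtureFit",
    "InformativeTieWarning",
    "fit_linear",
    "em_fit",
    "m_step",
    "bic",
    "relative_entropy",
    "identify_informative_component",
    "modal_assignment",
]

_LOG2PI = float(np.log(2.0 * np.pi))
#: relative variance floor: sigma_k^2 >= VARIANCE_FLOOR_REL * Var(y)
VARIANCE_FLOOR_REL = 1e-6


class InformativeTieWarning(UserWarning):
    """Two mixture components have (nearly) equal mean absolute slope."""


@dataclass
class LinearFit:
    """A (weighted) Gaussian linear regression fit."""

    coefficients: np.ndarray  # intercept first, then p slopes
    residual_sd: float
    n: int
    log_likelihood: float

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]


@dataclass
class MixtureFit:
    """A fitted K-component mixture of linear regressions."""

    K: int
    coefficients: np.ndarray  # K × (p+1), intercept first
    residual_sds: np.ndarray  # K
    mixing_weights: np.ndarray  # K-simplex
    posteriors: np.ndarray  # n × K
    log_likelihood: float
    bic: float
    relative_entropy: float
    n_iterations: int
    converged: bool
    n_starts_used: int
    seed: int
    n: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    loglik_paths: list = field(default_factory=list)  # one path per retained start

    @property
    def slopes(self) -> np.ndarray:
        """K × p slope matrix (intercept column dropped)."""
        return self.coefficients[:, 1:]


def _design(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return np.column_stack([np.ones(Z.shape[0]), Z])


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares. Returns (beta, residuals, weighted mean sq resid)."""
    if w is None:
        Xw = X
        yw = y
        wsum = float(len(y))
    else:
        Xw = X * w[:, None]
        yw = y * w
        wsum = float(np.sum(w))
    gram = X.T @ Xw
    rhs = X.T @ yw
    try:
        c, low = cho_factor(gram, check_finite=False)
        beta = cho_solve((c, low), rhs, check_finite=False)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise SingularDesignError(f"rank-deficient design: {exc}") from exc
    if not np.all(np.isfinite(beta)):
        raise SingularDesignError("non-finite WLS solution (collinear covariates?)")
    resid = y - X @ beta
    if w is None:
        msr = float(np.sum(resid**2) / wsum)
    else:
        msr = float(np.sum(w * resid**2) / wsum)
    return beta, resid, msr


def _gauss_loglik(resid: np.ndarray, sd: float, w: np.ndarray | None) -> float:
    z2 = (resid / sd) ** 2
    terms = -0.5 * (_LOG2PI + 2.0 * np.log(sd) + z2)
    return float(np.sum(terms if w is None else w * terms))


def fit_linear(Z: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> LinearFit:
    """Ordinary/weighted least squares with Gaussian log-likelihood.

    ``residual_sd`` is the maximum-likelihood estimate (weighted mean squared
    residual), floored at a tiny positive value so interpolating fits remain
    representable.
    """
    y = np.asarray(y, dtype=float)
    X = _design(Z)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.any(weights > 0):
            raise ValueError("weights must not be all zero")
    beta, resid, msr = _wls(X, y, weights)
    floor = 1e-12 * max(1.0, float(np.std(y)))
    sd = max(float(np.sqrt(msr)), floor)
    ll = _gauss_loglik(resid, sd, weights)
    return LinearFit(coefficients=beta, residual_sd=sd, n=len(y), log_likelihood=ll)


def m_step(
    Z: np.ndarray, y: np.ndarray, responsibilities: np.ndarray, variance_floor: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One M-step: per-component weighted least squares and weight update.

    Returns (coefficients K×(p+1), residual_sds K, mixing_weights K). With
    responsibilities frozen at 0/1 labels this reproduces per-label OLS
    exactly.
    """
    return _m_step_X(_design(Z), np.asarray(y, dtype=float),
                     np.asarray(responsibilities, dtype=float), variance_floor)


def _m_step_X(
    X: np.ndarray, y: np.ndarray, tau: np.ndarray, variance_floor: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, K = tau.shape
    p1 = X.shape[1]
    coefs = np.empty((K, p1))
    sds = np.empty(K)
    for k in range(K):
        beta, resid, msr = _wls(X, y, tau[:, k])
        coefs[k] = beta
        sds[k] = np.sqrt(max(msr, variance_floor))
    weights = tau.mean(axis=0)
    return coefs, sds, weights


def _e_step(
    X: np.ndarray, y: np.ndarray, coefs: np.ndarray, sds: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, float]:
    """Responsibilities and observed-data log-likelihood."""
    resid = y[:, None] - X @ coefs.T  # n × K
    logdens = -0.5 * (_LOG2PI + 2.0 * np.log(sds)[None, :] + (resid / sds[None, :]) ** 2)
    with np.errstate(divide="ignore"):
        logpost = logdens + np.log(weights)[None, :]
    norm = logsumexp(logpost, axis=1)
    tau = np.exp(logpost - norm[:, None])
    return tau, float(np.sum(norm))


def em_fit(
    Z: np.ndarray,
    y: np.ndarray,
    K: int = 2,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> MixtureFit:
    """Fit a K-component mixture of linear regressions by EM with restarts.

    Each start initializes responsibilities i.i.d. Dirichlet(1,...,1) per row,
    then alternates M- and E-steps until the relative change in observed-data
    log-likelihood drops below ``tol`` or ``max_iter`` is hit. A start is
    abandoned (and redrawn, up to 3×n_starts attempts total) when a component
    collapses: effective mass below p+2 subjects, a residual variance at the
    floor, or a singular weighted design. The best log-likelihood over
    successful starts is retained.
    """
    y = np.asarray(y, dtype=float)
    X = _design(Z)
    n, p1 = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K * (p1 + 1):
        raise DegenerateEMError(f"n={n} too small for K={K} components with {p1} coefficients")
    rng = np.random.default_rng(seed)
    var_floor = VARIANCE_FLOOR_REL * float(np.var(y))
    if var_floor == 0.0:
        var_floor = 1e-24

    best: dict | None = None
    paths: list[np.ndarray] = []
    successes = 0
    attempts = 0
    max_attempts = 3 * n_starts
    while successes < n_starts and attempts < max_attempts:
        attempts += 1
        tau = rng.dirichlet(np.ones(K), size=n) if K > 1 else np.ones((n, 1))
        path: list[float] = []
        ll_prev = -np.inf
        degenerate = False
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            mass = tau.sum(axis=0)
            if np.any(mass < p1 + 1):
                degenerate = True
                break
            try:
                coefs, sds, weights = _m_step_X(X, y, tau)
            except SingularDesignError:
                degenerate = True
                break
            if np.any(sds**2 < var_floor):
                degenerate = True
                break
            tau, ll = _e_step(X, y, coefs, sds, weights)
            path.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
                converged = True
                break
            ll_prev = ll
        if degenerate:
            continue
        successes += 1
        paths.append(np.asarray(path))
        if best is None or ll > best["ll"]:
            best = {
                "ll": ll,
                "coefs": coefs,
                "sds": sds,
                "weights": weights,
                "tau": tau,
                "iters": n_iter,
                "converged": converged,
                "path": np.asarray(path),
            }
    if best is None:
        raise DegenerateEMError(
            f"all {attempts} EM initializations degenerated (K={K}, n={n})"
        )

    fit = MixtureFit(
        K=K,
        coefficients=best["coefs"],
        residual_sds=best["sds"],
        mixing_weights=best["weights"],
        posteriors=best["tau"],
        log_likelihood=best["ll"],
        bic=np.nan,
        relative_entropy=relative_entropy(best["tau"]),
        n_iterations=best["iters"],
        converged=best["converged"],
        n_starts_used=successes,
        seed=seed,
        n=n,
        loglik_path=best["path"],
        loglik_paths=paths,
    )
    fit.bic = bic(fit)
    return fit


def bic(fit: LinearFit | MixtureFit) -> float:
    """Bayesian information criterion, −2·loglik + q·ln(n); lower is better.

    Free-parameter count q: for the linear model p+2 (p slopes, intercept,
    variance); for a K-component mixture K·(p+2) + K − 1 (per-component slopes,
    intercept and variance, plus K−1 mixing weights). At K=1 the two coincide.
    """
    if fit.n <= 1:
        raise ValueError("BIC undefined for n <= 1")
    if isinstance(fit, MixtureFit):
        p = fit.coefficients.shape[1] - 1
        q = fit.K * (p + 2) + fit.K - 1
    else:
        p = len(fit.coefficients) - 1
        q = p + 2
    return float(-2.0 * fit.log_likelihood + q * np.log(fit.n))


def relative_entropy(posteriors: np.ndarray) -> float:
    """Classification-sharpness summary in [0, 1].

    ``1 − Σ_ik (−τ_ik ln τ_ik) / (n ln K)`` with 0·ln 0 := 0. Equals 1 when
    every posterior row is degenerate (perfect separation) and 0 when every
    row is uniform. Defined as 1 for K=1.
    """
    tau = np.asarray(posteriors, dtype=float)
    if tau.ndim != 2:
        raise ValueError("posteriors must be a 2-D matrix")
    n, K = tau.shape
    if np.any(tau < -1e-12) or np.any(tau > 1 + 1e-12):
        raise ValueError("posterior entries must lie in [0, 1]")
    if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    if K == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(tau > 0, tau * np.log(tau), 0.0)
    ent = -float(np.sum(plogp))
    return float(1.0 - ent / (n * np.log(K)))


def identify_informative_component(fit: MixtureFit, tie_rel_tol: float = 0.10) -> int:
    """Index of the component with the largest mean absolute slope.

    On standardized covariates the informative (valid-subpopulation)
    component is the one whose coefficients are noticeably larger in absolute
    magnitude. Warns with :class:`InformativeTieWarning` when the top two
    components are within ``tie_rel_tol`` relative difference; exact ties go
    to the lowest index.
    """
    if fit.K < 2:
        return 0
    score = np.mean(np.abs(fit.slopes), axis=1)
    order = np.argsort(-score, kind="stable")
    top, second = score[order[0]], score[order[1]]
    if top == 0 or (top - second) < tie_rel_tol * top:
        warnings.warn(
            "informative-component choice is a near-tie: mean |slope| "
            f"{top:.4g} vs {second:.4g}",
            InformativeTieWarning,
            stacklevel=2,
        )
    # stable argsort already prefers the lowest index on exact ties
    return int(order[0])


def modal_assignment(posteriors: np.ndarray, informative: int | None = None) -> np.ndarray:
    """Per-row argmax labels; exact ties go to ``informative`` when given,
    else to the lowest index."""
    tau = np.asarray(posteriors, dtype=float)
    labels = tau.argmax(axis=1)
    if informative is not None:
        rowmax = tau.max(axis=1)
        labels = np.where(tau[:, informative] == rowmax, informative, labels)
    return labels
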