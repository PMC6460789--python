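"""Risk scores from fitted models and the surrogate-based score criteria.

A risk score R is a one-dimensional per-subject summary intended to order
subjects by disease disposition. Here R is a model's linear predictor: either
the pooled linear fit, or — for a mixture — the prediction of the single
component identified as the informative (valid-surrogate) subpopulation,
evaluated for *all* subjects.

The module also provides the three screening criteria for building risk
scores on a surrogate outcome:

* association of the covariates with the surrogate (``check_r1_r2``, R1),
* association of the covariates with the target outcome (R2),
* concordance of the score with the target, P(R_i < R_j | T_i < T_j) > 1/2
  (``r3_concordance``, R3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import kendalltau

from .errors import ConcordanceUndefinedError, InsufficientDataError
from .mixture_engine import LinearFit, MixtureFit, identify_informative_component

__all__ = [
    "RiskScoreSet",
    "AssociationScreen",
    "score_linear",
    "score_mixture_component",
    "build_risk_scores",
    "r3_concordance",
    "check_r1_r2",
]


@dataclass
class RiskScoreSet:
    """Named per-subject score vectors with provenance."""

    scores: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.scores.values()}
        if len(lengths) > 1:
            raise ValueError("all score vectors must share one length")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.scores[name]

    @property
    def names(self) -> list[str]:
        return list(self.scores)


def score_linear(fit: LinearFit, Z: np.ndarray) -> np.ndarray:
    """Linear-model risk score: the fitted linear predictor per subject."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[1] != len(fit.coefficients) - 1:
        raise ValueError(
            f"Z has {Z.shape[1]} columns but fit expects {len(fit.coefficients) - 1}"
        )
    return fit.intercept + Z @ fit.slopes


def score_mixture_component(fit: MixtureFit, k: int, Z: np.ndarray) -> np.ndarray:
    """Component-k linear predictor, evaluated for all subjects.

    Scoring does not condition on modal assignment: the informative
    component's model is applied uniformly, which is what lets the mixture
    generalize its subpopulation-V phenotype to the whole cohort.
    """
    if not 0 <= k < fit.K:
        raise ValueError(f"component index {k} outside [0, {fit.K})")
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    coef = fit.coefficients[k]
    if Z.shape[1] != len(coef) - 1:
        raise ValueError("Z not conformable with the mixture fit")
    return coef[0] + Z @ coef[1:]


def build_risk_scores(
    linear: LinearFit,
    mixture: MixtureFit,
    Z: np.ndarray,
    S: np.ndarray | None = None,
    component: int | None = None,
) -> RiskScoreSet:
    """Assemble the standard candidate set: raw surrogate, pooled linear
    prediction, and the mixture's informative-component prediction."""
    k = identify_informative_component(mixture) if component is None else component
    scores = {
        "linear": score_linear(linear, Z),
        "mixture_V": score_mixture_component(mixture, k, Z),
    }
    prov = {"linear": "pooled OLS", "mixture_V": f"mixture component {k}"}
    if S is not None:
        scores = {"raw_surrogate": np.asarray(S, dtype=float), **scores}
        prov["raw_surrogate"] = "observed surrogate"
    return RiskScoreSet(scores=scores, provenance=prov)


def _concordance_pairs(R: np.ndarray, T: np.ndarray) -> float:
    """Exhaustive pair enumeration, chunked to bound memory."""
    n = len(R)
    num = 0.0
    den = 0.0
    chunk = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, chunk):
        Ri = R[start : start + chunk, None]
        Ti = T[start : start + chunk, None]
        t_lt = Ti < T[None, :]
        num += np.sum(t_lt * ((Ri < R[None, :]) + 0.5 * (Ri == R[None, :])))
        den += np.sum(t_lt)
    if den == 0:
        raise ConcordanceUndefinedError("all target values tied; concordance undefined")
    return float(num / den)


def _tie_pairs(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2.0))


def _concordance_ranks(R: np.ndarray, T: np.ndarray) -> float:
    """O(n log n) path via Somers' D(R|T) recovered from Kendall's tau-b.

    concordance = (D + 1) / 2 with D = (C − D') / (#pairs with T distinct).
    Agrees with the pair-enumeration path to floating-point rounding.
    """
    n = len(R)
    n0 = n * (n - 1) / 2.0
    n1 = _tie_pairs(R)  # ties in R
    n2 = _tie_pairs(T)  # ties in T
    if n0 == n2:
        raise ConcordanceUndefinedError("all target values tied; concordance undefined")
    tau_b = kendalltau(R, T).statistic
    c_minus_d = tau_b * np.sqrt((n0 - n1) * (n0 - n2))
    somers_d = c_minus_d / (n0 - n2)
    return float((somers_d + 1.0) / 2.0)


def r3_concordance(R: np.ndarray, T: np.ndarray, method: str = "auto") -> float:
    """Concordance of a risk score with the target: over pairs with
    T_i < T_j, the fraction with R_i < R_j, counting ties in R as 1/2.

    ``method``: ``"pairs"`` (exhaustive O(n²)), ``"ranks"`` (O(n log n) via
    Kendall's tau-b), or ``"auto"`` (pairs below n=3000, ranks above). A value
    above 1/2 means the score shifts toward larger values as the target
    worsens.
    """
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    if len(R) != len(T):
        raise ValueError("R and T must be paired")
    if len(R) < 2:
        raise ValueError("need at least two subjects")
    if method == "auto":
        method = "pairs" if len(R) <= 3000 else "ranks"
    if method == "pairs":
        return _concordance_pairs(R, T)
    if method == "ranks":
        return _concordance_ranks(R, T)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class AssociationScreen:
    """Overall F-test of outcome-on-covariates plus marginal correlations."""

    f_statistic: float
    p_value: float
    marginal_correlations: np.ndarray
    n: int


def _screen(Z: np.ndarray, y: np.ndarray) -> AssociationScreen:
    X = sm.add_constant(Z)
    res = sm.OLS(y, X).fit()
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt(np.sum(Zc**2, axis=0) * np.sum(yc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, Zc.T @ yc / denom, np.nan)
    return AssociationScreen(
        f_statistic=float(res.fvalue),
        p_value=float(res.f_pvalue),
        marginal_correlations=corr,
        n=len(y),
    )


def check_r1_r2(
    Z: np.ndarray,
    S: np.ndarray,
    T: np.ndarray,
    observed_T: np.ndarray | None = None,
) -> dict[str, AssociationScreen]:
    """Screen the covariates for association with the surrogate (R1) and the
    target (R2).

    Returns ``{"R1": ..., "R2": ...}``. These are diagnostics, not gates: a
    small p-value says the covariates carry information about the outcome's
    distribution. The R2 screen uses only rows with an observed target.
    """
    Z = np.asarray(Z, dtype=float)
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    n, p = Z.shape
    if observed_T is None:
        observed_T = np.isfinite(T)
    observed_T = np.asarray(observed_T, dtype=bool)
    if n <= p + 1:
        raise InsufficientDataError("need n > p+1 rows for the surrogate screen")
    n_obs = int(observed_T.sum())
    if n_obs == 0:
        raise InsufficientDataError("target outcome entirely missing")
    if n_obs <= p + 1:
        raise InsufficientDataError(
            f"only {n_obs} observed target rows; need more than p+1={p + 1}"
        )
    return {
        "R1": _screen(Z, S),
        "R2": _screen(Z[observed_T], T[observed_T]),
    }
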