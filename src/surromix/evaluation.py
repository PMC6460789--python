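"""Discrimination metrics and paired comparisons for candidate risk scores.

Point metrics: the (optionally weighted) Mann–Whitney AUC against a binary
target event and Spearman's rank correlation against the continuous target.
Comparisons: a placement-value (structural-components) test for the
difference of two correlated AUCs, and a subject-level swap permutation test
for the difference of two dependent Spearman correlations. Missing-target
bias is addressed by inverse-probability-of-observation weights from a
logistic propensity model, and the weighted AUC comparison can be swept over
a grid of target cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm, rankdata, spearmanr

from .errors import InsufficientDataError, PerfectSeparationError, SurromixError

__all__ = [
    "DiscriminationReport",
    "SweepCurve",
    "PropensityModel",
    "roc_auc",
    "compare_auc_paired",
    "spearman_rho",
    "compare_spearman_permutation",
    "propensity_weights",
    "weighted_auc_sweep",
    "discrimination_report",
]


# ---------------------------------------------------------------------------
# AUC


def _validate_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(bool)
    if y.all() or not y.any():
        raise SurromixError("both outcome classes must be present")
    return y


def _weighted_auc(R: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Mann–Whitney statistic, ties counted half, via score grouping."""
    pos, neg = y, ~y
    wpos_tot = float(w[pos].sum())
    wneg_tot = float(w[neg].sum())
    if wpos_tot <= 0 or wneg_tot <= 0:
        raise SurromixError("both classes need positive weighted mass")
    uniq, inv = np.unique(R, return_inverse=True)
    wpos_at = np.bincount(inv[pos], weights=w[pos], minlength=len(uniq))
    wneg_at = np.bincount(inv[neg], weights=w[neg], minlength=len(uniq))
    cum_neg_below = np.concatenate([[0.0], np.cumsum(wneg_at)[:-1]])
    num = float(np.sum(wpos_at * (cum_neg_below + 0.5 * wneg_at)))
    return num / (wpos_tot * wneg_tot)


def _placement_values(R: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components.

    v10[i] for positives: fraction of negatives scored below R_i (ties half);
    v01[j] for negatives: fraction of positives scored above R_j (ties half).
    """
    pos_scores = R[y]
    neg_scores = R[~y]
    sn = np.sort(neg_scores)
    v10 = (
        np.searchsorted(sn, pos_scores, side="left")
        + np.searchsorted(sn, pos_scores, side="right")
    ) / (2.0 * len(sn))
    sp = np.sort(pos_scores)
    v01 = 1.0 - (
        np.searchsorted(sp, neg_scores, side="left")
        + np.searchsorted(sp, neg_scores, side="right")
    ) / (2.0 * len(sp))
    return v10, v01


def roc_auc(
    R: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AUC of score R against binary outcome y, with a confidence interval.

    Unweighted: the Mann–Whitney statistic with an asymptotic CI from the
    placement-value variance. Weighted: the weighted pair statistic with a
    stratified-bootstrap CI (resampling subjects within each class,
    ``n_boot`` resamples). The CI is clipped to [0, 1].
    """
    R = np.asarray(R, dtype=float)
    y = _validate_binary(y)
    z = norm.ppf(1.0 - alpha / 2.0)
    if weights is None:
        v10, v01 = _placement_values(R, y)
        auc = float(v10.mean())
        var = 0.0
        if len(v10) > 1:
            var += v10.var(ddof=1) / len(v10)
        if len(v01) > 1:
            var += v01.var(ddof=1) / len(v01)
        half = z * np.sqrt(var)
        return auc, (max(0.0, auc - half), min(1.0, auc + half))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    auc = _weighted_auc(R, y, w)
    rng = np.random.default_rng(seed)
    ipos = np.flatnonzero(y)
    ineg = np.flatnonzero(~y)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bi = np.concatenate(
            [rng.choice(ipos, size=len(ipos)), rng.choice(ineg, size=len(ineg))]
        )
        boots[b] = _weighted_auc(R[bi], y[bi], w[bi])
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(auc), (float(max(0.0, lo)), float(min(1.0, hi)))


def compare_auc_paired(
    R1: np.ndarray,
    R2: np.ndarray,
    y: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for equality of two correlated AUCs on one sample.

    Uses the placement-value variance of the AUC difference (the classic
    correlated-ROC construction). When that variance is exactly zero the test
    falls back to a paired subject-level bootstrap — except in the trivial
    case of an identically-zero difference, where p = 1.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if len(R1) != len(R2):
        raise ValueError("scores must be paired on the same subjects")
    y = _validate_binary(y)
    v10_1, v01_1 = _placement_values(R1, y)
    v10_2, v01_2 = _placement_values(R2, y)
    diff = float(v10_1.mean() - v10_2.mean())
    d10 = v10_1 - v10_2
    d01 = v01_1 - v01_2
    var = 0.0
    if len(d10) > 1:
        var += d10.var(ddof=1) / len(d10)
    if len(d01) > 1:
        var += d01.var(ddof=1) / len(d01)
    if var <= 0.0:
        if diff == 0.0:
            return 1.0
        rng = np.random.default_rng(seed)
        n = len(y)
        count = 0
        for _ in range(n_boot):
            bi = rng.integers(0, n, size=n)
            yb = y[bi]
            if yb.all() or not yb.any():
                continue
            a1, _ = _placement_values(R1[bi], yb)
            a2, _ = _placement_values(R2[bi], yb)
            if (a1.mean() - a2.mean()) * diff <= 0:
                count += 1
        return float(min(1.0, 2.0 * (count + 1) / (n_boot + 1)))
    zstat = diff / np.sqrt(var)
    return float(2.0 * norm.sf(abs(zstat)))


# ---------------------------------------------------------------------------
# Spearman


def spearman_rho(
    R: np.ndarray, T: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Spearman's rank correlation with a Fisher-z confidence interval
    (SE = 1/sqrt(n−3))."""
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    n = len(R)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(R) == 0 or np.ptp(T) == 0:
        raise ValueError("constant input vector; rank correlation undefined")
    rho = float(spearmanr(R, T).statistic)
    if n <= 3 or abs(rho) == 1.0:
        return rho, (rho, rho)
    z = np.arctanh(rho)
    half = norm.ppf(1.0 - alpha / 2.0) / np.sqrt(n - 3)
    return rho, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _rowwise_spearman(Rmat: np.ndarray, t_rank: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of Rmat with a fixed rank vector."""
    ranks = rankdata(Rmat, axis=1)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    tc = t_rank - t_rank.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (tc**2).sum())
    return (rc @ tc) / denom


def compare_spearman_permutation(
    R1: np.ndarray,
    R2: np.ndarray,
    T: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for rho(R1,T) = rho(R2,T) on paired data.

    The null of exchangeable scores is imposed by independently swapping the
    pair (R1_i, R2_i) with probability 1/2 per subject per permutation; this
    preserves each score's marginal and its coupling with T. Two-sided
    p = (1 + #{|d*| >= |d|}) / (n_perm + 1).
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    T = np.asarray(T, dtype=float)
    n = len(T)
    if not (len(R1) == len(R2) == n):
        raise ValueError("R1, R2, T must be paired")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if np.ptp(R1) == 0 or np.ptp(R2) == 0 or np.ptp(T) == 0:
        raise ValueError("constant input vector; rank correlation undefined")
    t_rank = rankdata(T)
    d_obs = float(
        _rowwise_spearman(R1[None, :], t_rank)[0]
        - _rowwise_spearman(R2[None, :], t_rank)[0]
    )
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, int(2e6 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        swap = rng.random((m, n)) < 0.5
        A = np.where(swap, R2[None, :], R1[None, :])
        B = np.where(swap, R1[None, :], R2[None, :])
        d = _rowwise_spearman(A, t_rank) - _rowwise_spearman(B, t_rank)
        count += int(np.sum(np.abs(d) >= abs(d_obs) - 1e-12))
        done += m
    return float((1 + count) / (n_perm + 1))


# ---------------------------------------------------------------------------
# Propensity weighting and the cutoff sweep


@dataclass
class PropensityModel:
    """Summary of the logistic observation-propensity fit."""

    coefficients: np.ndarray  # intercept first
    std_errors: np.ndarray
    converged: bool
    n_observed: int
    n_missing: int
    clip_value: float


def propensity_weights(
    Z: np.ndarray,
    observed: np.ndarray,
    mode: str = "ipw",
    clip_quantile: float = 0.99,
) -> tuple[np.ndarray, PropensityModel]:
    """Observation-propensity weights for evaluating with a missing target.

    Fits a logistic model of the observed-indicator on Z. ``mode="ipw"``
    (default) assigns observed subjects weight 1/p̂ (inverse probability of
    observation), clipped at the ``clip_quantile`` quantile and normalized to
    mean 1 over observed subjects; ``mode="propensity"`` uses p̂ itself as the
    weight. Missing subjects always get weight 0.
    """
    Z = np.asarray(Z, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    n, p = Z.shape
    if observed.all():
        raise InsufficientDataError("no missing subjects: nothing to weight for")
    if not observed.any():
        raise InsufficientDataError("no observed subjects")
    if n <= p + 1:
        raise InsufficientDataError("need n > p+1 for the propensity model")
    X = sm.add_constant(Z)
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(observed.astype(float), X, family=sm.families.Binomial()).fit()
        phat = np.asarray(res.predict(X))
    except Exception as exc:  # statsmodels raises various separation errors
        raise PerfectSeparationError(str(exc)) from exc
    eps = 1e-10
    if np.all((phat < eps) | (phat > 1.0 - eps)) or np.any(phat[observed] < eps):
        raise PerfectSeparationError("fitted propensities degenerate at 0/1")
    if mode == "ipw":
        raw = 1.0 / np.clip(phat, eps, 1.0)
    elif mode == "propensity":
        raw = phat.copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    w = np.zeros(n)
    obs_raw = raw[observed]
    clip = float(np.quantile(obs_raw, clip_quantile))
    obs_w = np.minimum(obs_raw, clip)
    obs_w = obs_w / obs_w.mean()
    w[observed] = obs_w
    model = PropensityModel(
        coefficients=np.asarray(res.params),
        std_errors=np.asarray(res.bse),
        converged=bool(getattr(res, "converged", True)),
        n_observed=int(observed.sum()),
        n_missing=int(n - observed.sum()),
        clip_value=clip,
    )
    return w, model


@dataclass
class SweepCurve:
    """Weighted-AUC comparison of two scores over a grid of target cutoffs."""

    cutoffs: np.ndarray
    auc_1: np.ndarray
    auc_2: np.ndarray
    auc_difference: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    undefined: np.ndarray  # bool per cutoff: a class had no weighted mass
    weights_summary: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "auc_1": self.auc_1,
                "auc_2": self.auc_2,
                "auc_difference": self.auc_difference,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "undefined": self.undefined,
            }
        )


def weighted_auc_sweep(
    R1: np.ndarray,
    R2: np.ndarray,
    T: np.ndarray,
    weights: np.ndarray | None = None,
    cutoffs: np.ndarray | None = None,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SweepCurve:
    """Weighted AUC of two scores at each target cutoff, with a
    stratified-bootstrap CI for the difference.

    At cutoff c the binary event is 1(T > c). Cutoffs where either class has
    no positive weighted mass are reported as undefined (NaN), not dropped.
    Subjects with zero weight (e.g. missing target) never contribute.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    T = np.asarray(T, dtype=float)
    n = len(T)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if cutoffs is None:
        cutoffs = np.arange(5.0, 26.0)
    cutoffs = np.asarray(cutoffs, dtype=float)
    if len(cutoffs) == 0:
        raise ValueError("cutoff grid must be nonempty")
    active = w > 0
    if cutoffs.min() > T[active].max() or cutoffs.max() < T[active].min():
        raise ValueError("cutoff grid entirely outside the observed target range")

    m = len(cutoffs)
    a1 = np.full(m, np.nan)
    a2 = np.full(m, np.nan)
    lo = np.full(m, np.nan)
    hi = np.full(m, np.nan)
    undef = np.zeros(m, dtype=bool)
    rng = np.random.default_rng(seed)
    idx_active = np.flatnonzero(active)
    Ra1, Ra2, Ta, wa = R1[idx_active], R2[idx_active], T[idx_active], w[idx_active]
    for i, c in enumerate(cutoffs):
        ya = Ta > c
        if not ya.any() or ya.all():
            undef[i] = True
            continue
        a1[i] = _weighted_auc(Ra1, ya, wa)
        a2[i] = _weighted_auc(Ra2, ya, wa)
        ipos = np.flatnonzero(ya)
        ineg = np.flatnonzero(~ya)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bi = np.concatenate(
                [rng.choice(ipos, size=len(ipos)), rng.choice(ineg, size=len(ineg))]
            )
            boots[b] = _weighted_auc(Ra1[bi], ya[bi], wa[bi]) - _weighted_auc(
                Ra2[bi], ya[bi], wa[bi]
            )
        lo[i], hi[i] = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return SweepCurve(
        cutoffs=cutoffs,
        auc_1=a1,
        auc_2=a2,
        auc_difference=a1 - a2,
        ci_lower=lo,
        ci_upper=hi,
        undefined=undef,
        weights_summary={
            "n_active": int(active.sum()),
            "mean": float(w[active].mean()) if active.any() else np.nan,
            "max": float(w[active].max()) if active.any() else np.nan,
        },
    )


# ---------------------------------------------------------------------------
# Combined report


@dataclass
class DiscriminationReport:
    """Per-score discrimination against one target, plus pairwise comparisons."""

    auc: dict[str, tuple[float, tuple[float, float]]]
    auc_p_values: dict[tuple[str, str], float]
    rho: dict[str, tuple[float, tuple[float, float]]]
    rho_p_values: dict[tuple[str, str], float]
    cutoff: float
    n_effective: int


def discrimination_report(
    scores: dict[str, np.ndarray],
    T: np.ndarray,
    cutoff: float = 20.0,
    observed_T: np.ndarray | None = None,
    direction: str = "greater",
    n_perm: int = 10_000,
    seed: int = 0,
) -> DiscriminationReport:
    """AUC at ``1(T > cutoff)`` (or ``<`` with ``direction="less"``) and
    Spearman's rho for each score, with all pairwise paired-AUC and
    permutation rho comparisons, restricted to observed-target subjects."""
    T = np.asarray(T, dtype=float)
    if observed_T is None:
        observed_T = np.isfinite(T)
    observed_T = np.asarray(observed_T, dtype=bool)
    Tm = T[observed_T]
    sub = {k: np.asarray(v, dtype=float)[observed_T] for k, v in scores.items()}
    y = Tm > cutoff if direction == "greater" else Tm < cutoff
    auc = {k: roc_auc(v, y) for k, v in sub.items()}
    rho = {k: spearman_rho(v, Tm) for k, v in sub.items()}
    names = list(sub)
    auc_p: dict[tuple[str, str], float] = {}
    rho_p: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            auc_p[(a, b)] = compare_auc_paired(sub[a], sub[b], y)
            rho_p[(a, b)] = compare_spearman_permutation(
                sub[a], sub[b], Tm, n_perm=n_perm, seed=seed
            )
    return DiscriminationReport(
        auc=auc,
        auc_p_values=auc_p,
        rho=rho,
        rho_p_values=rho_p,
        cutoff=cutoff,
        n_effective=int(observed_T.sum()),
    )
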