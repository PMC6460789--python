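"""Synthetic cohorts with a latent informative subpopulation.

Emulates the structure of a perioperative acute-kidney-injury cohort: ten
preoperative/intraoperative covariates, a continuous surrogate outcome S
(postoperative creatinine change, standardized model scale), and a continuous
target outcome T (90-day eGFR change, mean 0 / SD 50). Each subject carries a
latent membership label:

* ``V`` ("valid"): injury exceeded renal functional reserve, so the surrogate
  tracks the same covariate signal as the target,
* ``I`` ("invalid"): the surrogate is noise (or follows an unrelated model)
  and carries no information about the target.

Every generator is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .errors import InsufficientDataError

__all__ = [
    "CovariateSpec",
    "GenerativeParams",
    "Cohort",
    "BETA_V_DEFAULT",
    "BETA_I_DEFAULT",
    "COVARIATE_NAMES",
    "generate_covariates",
    "generate_membership",
    "generate_outcomes",
    "generate_cohort",
    "apply_missingness",
    "binned_conditional_mean",
    "load_config",
]

# Covariate order: 8 continuous (standardized) then 2 binary (0/1).
COVARIATE_NAMES: tuple[str, ...] = (
    "age",
    "bmi",
    "hemoglobin",
    "urine_output",
    "fluids_given",
    "baseline_egfr",
    "max_lactate",
    "surgery_length",
    "diabetes",
    "emergency",
)

# Informative-subpopulation slopes on standardized covariates (clinical fit,
# V column); the attenuated I column is kept for reference/tests.
BETA_V_DEFAULT = np.array(
    [0.213, 0.25, -0.253, -0.147, -0.134, 0.388, 0.206, 0.193, -0.109, 0.05]
)
BETA_I_DEFAULT = np.array(
    [0.063, 0.047, -0.063, -0.041, -0.015, 0.110, 0.060, 0.072, -0.002, 0.0]
)

#: modal share of the informative subpopulation in the clinical cohort, 728/4737
MIXING_PROP_DEFAULT = 728.0 / 4737.0

# Binary covariate prevalences: diabetes (567+1198)/4737, emergency (113+202)/4737.
_BINARY_PROPS_DEFAULT = ((567 + 1198) / 4737, (113 + 202) / 4737)


@dataclass(frozen=True)
class CovariateSpec:
    """Joint covariate model: exchangeable-correlation Gaussian copula.

    ``p_continuous`` standardized Gaussian columns followed by ``p_binary``
    0/1 columns obtained by thresholding latent Gaussians at the quantile of
    each prevalence in ``binary_props``.
    """

    p_continuous: int = 8
    p_binary: int = 2
    binary_props: tuple[float, ...] = _BINARY_PROPS_DEFAULT
    correlation: float = 0.2
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.p_continuous < 0 or self.p_binary < 0 or self.p == 0:
            raise ValueError("need at least one covariate")
        if len(self.binary_props) != self.p_binary:
            raise ValueError("binary_props length must equal p_binary")
        for q in self.binary_props:
            if not 0.0 < q < 1.0:
                raise ValueError(f"binary proportion {q} outside (0, 1)")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")

    @property
    def p(self) -> int:
        return self.p_continuous + self.p_binary


@dataclass(frozen=True)
class GenerativeParams:
    """Outcome-model parameters for the partial-surrogate generator.

    ``beta_V`` are the informative-component slopes (plus ``beta_V_intercept``)
    of the shared outcome model S|Z,V ~ N(int + Z·beta_V, sigma_V) and
    T|Z ~ N(int + Z·beta_V, sigma_V). ``sigma_I`` scales the invalid-component
    surrogate noise. ``mixing_prop`` is P(V). ``theory_noise_sd`` is the
    measurement-error SD of the idealized scenario where S|V = T + noise.
    """

    beta_V: np.ndarray = field(default_factory=lambda: BETA_V_DEFAULT.copy())
    beta_V_intercept: float = 0.0
    beta_I_intercept: float = 0.0
    # frozen output of with_default_sigmas() at R² = 0.9 (signal SD of Z·beta_V
    # under the default CovariateSpec) and the 2:1 noisy-subpopulation ratio;
    # this reproduces the separable regime of the clinical fit (classification
    # entropy ~0.6, BIC strongly favoring the mixture) — see docs/methods.md
    sigma_V: float = 0.2284
    sigma_I: float = 0.4568
    beta_T_intercept: float = 0.0
    beta_T_slopes: np.ndarray | None = None
    mixing_prop: float = MIXING_PROP_DEFAULT
    membership_mode: Literal["random", "covariate_dependent"] = "random"
    membership_slopes: np.ndarray | None = None
    beta_R_sd: float = 0.176
    target_mean: float = 0.0
    target_sd: float = 50.0
    theory_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_V", np.asarray(self.beta_V, dtype=float))
        if self.beta_T_slopes is not None:
            object.__setattr__(
                self, "beta_T_slopes", np.asarray(self.beta_T_slopes, dtype=float)
            )
        if self.membership_slopes is not None:
            object.__setattr__(
                self, "membership_slopes", np.asarray(self.membership_slopes, dtype=float)
            )
        if self.sigma_V <= 0 or self.sigma_I <= 0:
            raise ValueError("sigma_V and sigma_I must be strictly positive")
        if not 0.0 <= self.mixing_prop <= 1.0:
            raise ValueError("mixing_prop must lie in [0, 1]")
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")

    @classmethod
    def with_default_sigmas(
        cls, spec: CovariateSpec | None = None, r_squared: float = 0.9, **kwargs
    ) -> "GenerativeParams":
        """Construct params with sigma_V solving Var(Z·beta_V)·(1−R²)/R² = sigma_V².

        The signal variance is estimated once by a fixed-seed Monte-Carlo
        (n=200000), so the default is deterministic. sigma_I = 2·sigma_V.
        """
        spec = spec or CovariateSpec()
        params = cls(**kwargs)
        Z = generate_covariates(200_000, spec, seed=200_000)
        signal_var = float(np.var(Z @ params.beta_V))
        sigma_v = float(np.sqrt(signal_var * (1.0 - r_squared) / r_squared))
        return replace(params, sigma_V=sigma_v, sigma_I=2.0 * sigma_v)


@dataclass
class Cohort:
    """In-memory cohort: covariates, surrogate, target, observation mask, labels."""

    Z: np.ndarray
    S: np.ndarray
    T: np.ndarray
    observed_T: np.ndarray
    labels: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.Z.shape[0]
        for name in ("S", "T", "observed_T"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match Z rows")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match Z rows")
        if np.any(~np.isfinite(self.S)):
            raise ValueError("S must have no missing values")

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Z, columns=[f"z{j + 1}" for j in range(self.p)])
        df["S"] = self.S
        df["T"] = np.where(self.observed_T, self.T, np.nan)
        df["observed_T"] = self.observed_T.astype(int)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        df = pd.read_csv(path)
        zcols = [c for c in df.columns if c.startswith("z") and c[1:].isdigit()]
        zcols.sort(key=lambda c: int(c[1:]))
        observed = df["observed_T"].to_numpy().astype(bool)
        T = df["T"].to_numpy(dtype=float)
        T = np.where(observed, T, np.nan)
        labels = df["label"].to_numpy() if "label" in df.columns else None
        return cls(
            Z=df[zcols].to_numpy(dtype=float),
            S=df["S"].to_numpy(dtype=float),
            T=T,
            observed_T=observed,
            labels=labels,
        )


def generate_covariates(n: int, spec: CovariateSpec | None = None, seed: int = 0) -> np.ndarray:
    """Draw an n×p covariate matrix under ``spec``.

    Latent rows are exchangeably correlated Gaussians (one common factor);
    continuous columns are the latent values (sample-standardized when
    ``spec.standardize``), binary columns threshold the latent value at the
    normal quantile of their prevalence, giving 0/1 indicators.
    """
    spec = spec or CovariateSpec()
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    rho = spec.correlation
    common = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, spec.p))
    latent = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * idio
    Z = latent.copy()
    for j, q in enumerate(spec.binary_props):
        col = spec.p_continuous + j
        Z[:, col] = (latent[:, col] < ndtri(q)).astype(float)
    if spec.standardize and spec.p_continuous > 0 and n > 1:
        cont = Z[:, : spec.p_continuous]
        sd = cont.std(axis=0)
        sd[sd == 0] = 1.0
        Z[:, : spec.p_continuous] = (cont - cont.mean(axis=0)) / sd
    return Z


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + eta)) == target, by bisection."""
    if not 0.0 < target < 1.0:
        raise ValueError("target proportion must be interior to (0,1) to solve")

    def f(c: float) -> float:
        return float(np.mean(expit(c + eta))) - target

    return float(brentq(f, -40.0, 40.0, xtol=1e-12))


def generate_membership(
    Z: np.ndarray, params: GenerativeParams, seed: int = 0
) -> np.ndarray:
    """Draw latent V/I labels.

    ``random`` mode: i.i.d. Bernoulli(mixing_prop). ``covariate_dependent``
    mode: per-subject probability expit(c + Z·membership_slopes) with the
    intercept c solved numerically so the marginal P(V) equals mixing_prop.
    """
    n = Z.shape[0]
    rng = np.random.default_rng(seed)
    pv = params.mixing_prop
    if params.membership_mode == "random":
        prob = np.full(n, pv)
    elif params.membership_mode == "covariate_dependent":
        if params.membership_slopes is None:
            raise ValueError("membership_slopes required in covariate_dependent mode")
        if pv in (0.0, 1.0):
            prob = np.full(n, pv)
        else:
            eta = Z @ params.membership_slopes
            prob = expit(_solve_intercept(eta, pv) + eta)
    else:
        raise ValueError(f"unknown membership_mode {params.membership_mode!r}")
    return np.where(rng.random(n) < prob, "V", "I")


def generate_outcomes(
    Z: np.ndarray,
    labels: np.ndarray,
    params: GenerativeParams,
    scenario: Literal["theory", "sim1", "sim2"] = "sim2",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Draw the surrogate S and target T for one cohort.

    In every scenario T follows the informative outcome model for *all*
    subjects and is then affinely rescaled to sample mean ``target_mean`` and
    SD ``target_sd`` exactly. S for V-subjects comes from the same model
    (independent error); S for I-subjects is scenario-specific:

    * ``sim1``: a fresh random linear model ``[beta_I_intercept, beta_R]`` with
      slopes drawn N(0, beta_R_sd) once per call (returned as third element),
      residual SD ``sigma_I``;
    * ``sim2``: covariate-free noise N(0, sigma_I);
    * ``theory``: idealized measurement-error form — S|V = T + noise with SD
      ``theory_noise_sd``, S|I marginal-matched pure noise.
    """
    n, p = Z.shape
    if n == 0:
        raise ValueError("empty cohort")
    if len(labels) != n:
        raise ValueError("labels and Z not conformable")
    if scenario not in ("theory", "sim1", "sim2"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    is_v = np.asarray(labels) == "V"

    mean_v = params.beta_V_intercept + Z @ params.beta_V
    T_raw = mean_v + rng.normal(0.0, params.sigma_V, size=n)
    # exact affine normalization of the realized sample
    sd = T_raw.std()
    if sd == 0:
        sd = 1.0
    T = params.target_mean + params.target_sd * (T_raw - T_raw.mean()) / sd

    S = np.empty(n)
    beta_R: np.ndarray | None = None
    if scenario == "theory":
        S[is_v] = T[is_v] + rng.normal(0.0, params.theory_noise_sd, size=int(is_v.sum()))
        noise_sd = np.hypot(params.target_sd, params.theory_noise_sd)
        S[~is_v] = params.target_mean + rng.normal(0.0, noise_sd, size=int((~is_v).sum()))
    else:
        S[is_v] = mean_v[is_v] + rng.normal(0.0, params.sigma_V, size=int(is_v.sum()))
        n_i = int((~is_v).sum())
        if scenario == "sim1":
            beta_R = rng.normal(0.0, params.beta_R_sd, size=p)
            mean_i = params.beta_I_intercept + Z @ beta_R
            S[~is_v] = mean_i[~is_v] + rng.normal(0.0, params.sigma_I, size=n_i)
        else:  # sim2
            S[~is_v] = params.beta_I_intercept + rng.normal(0.0, params.sigma_I, size=n_i)
    return S, T, beta_R


def generate_cohort(
    n: int,
    scenario: Literal["theory", "sim1", "sim2"] = "sim2",
    spec: CovariateSpec | None = None,
    params: GenerativeParams | None = None,
    seed: int = 0,
) -> Cohort:
    """Convenience wrapper: covariates → membership → outcomes, one seed.

    Sub-seeds for the three stages are derived deterministically from ``seed``.
    """
    spec = spec or CovariateSpec()
    params = params or GenerativeParams()
    s_cov, s_mem, s_out = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    Z = generate_covariates(n, spec, seed=int(s_cov))
    labels = generate_membership(Z, params, seed=int(s_mem))
    S, T, _ = generate_outcomes(Z, labels, params, scenario=scenario, seed=int(s_out))
    return Cohort(Z=Z, S=S, T=T, observed_T=np.ones(n, dtype=bool), labels=labels, seed=seed)


def apply_missingness(
    cohort: Cohort,
    mechanism: Literal["mcar", "mar"] = "mcar",
    rate: float = 0.0,
    mar_slopes: Sequence[float] | None = None,
    seed: int = 0,
) -> Cohort:
    """Return a copy of ``cohort`` with target values masked.

    ``mcar`` masks i.i.d. with probability ``rate``; ``mar`` masks with
    probability expit(c + Z·mar_slopes), c solved so the marginal missing rate
    equals ``rate``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    n = cohort.n
    rng = np.random.default_rng(seed)
    if rate == 0.0:
        prob = np.zeros(n)
    elif rate == 1.0:
        prob = np.ones(n)
    elif mechanism == "mcar":
        prob = np.full(n, rate)
    elif mechanism == "mar":
        if mar_slopes is None:
            raise ValueError("mar_slopes required for mar mechanism")
        eta = cohort.Z @ np.asarray(mar_slopes, dtype=float)
        prob = expit(_solve_intercept(eta, rate) + eta)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    missing = rng.random(n) < prob
    observed = cohort.observed_T & ~missing
    T = np.where(observed, cohort.T, np.nan)
    return Cohort(
        Z=cohort.Z.copy(),
        S=cohort.S.copy(),
        T=T,
        observed_T=observed,
        labels=None if cohort.labels is None else cohort.labels.copy(),
        seed=cohort.seed,
    )


def binned_conditional_mean(
    S: np.ndarray, T: np.ndarray, n_bins: int = 20, trim: float = 0.02
) -> pd.DataFrame:
    """Local-average estimate of E[T|S] on equal-count S bins.

    Returns a frame with bin centers (mean S per bin), mean T, bin counts and
    the within-bin standard error of the mean. The extreme ``trim`` fraction
    on each side of S is discarded before binning.
    """
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    if len(S) < n_bins * 2:
        raise InsufficientDataError("too few points for the requested bins")
    lo, hi = np.quantile(S, [trim, 1.0 - trim])
    keep = (S >= lo) & (S <= hi)
    S, T = S[keep], T[keep]
    edges = np.quantile(S, np.linspace(0.0, 1.0, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, S, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        cnt = int(m.sum())
        if cnt == 0:
            continue
        rows.append(
            {
                "s_mean": float(S[m].mean()),
                "t_mean": float(T[m].mean()),
                "count": cnt,
                "t_sem": float(T[m].std(ddof=1) / np.sqrt(cnt)) if cnt > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def load_config(path_or_text) -> tuple[CovariateSpec, GenerativeParams]:
    """Read a YAML/JSON generator config with optional ``covariates`` and
    ``generative`` sections mirroring the two dataclasses."""
    if hasattr(path_or_text, "read"):
        raw = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            raw = fh.read()
    cfg = yaml.safe_load(io.StringIO(raw)) or {}
    spec = CovariateSpec(**{
        k: tuple(v) if k == "binary_props" else v
        for k, v in (cfg.get("covariates") or {}).items()
    })
    gen_kwargs = dict(cfg.get("generative") or {})
    for key in ("beta_V", "beta_T_slopes", "membership_slopes"):
        if key in gen_kwargs and gen_kwargs[key] is not None:
            gen_kwargs[key] = np.asarray(gen_kwargs[key], dtype=float)
    params = GenerativeParams(**gen_kwargs)
    return spec, params
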