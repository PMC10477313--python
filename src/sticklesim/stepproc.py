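"""Step-length marginal modelling and the autocorrelated gamma process.

A fish's step length (Euclidean displacement between positions 0.1 s apart,
in mm) is modelled with a gamma marginal whose consecutive values are rank
correlated.  The generator is a Gaussian copula: a latent standard-normal
AR(1) chain is pushed through the normal CDF and the gamma quantile
function, which preserves the gamma marginal exactly while imposing the
requested lag-1 Spearman correlation.  The AR(1) coefficient is obtained
from the target rank correlation via the exact bivariate-normal identity
``rho = 2*sin(rho_s * pi / 6)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, special, stats

from .errors import DegenerateDataError, InputError, ParameterError

__all__ = [
    "GammaParams",
    "AutocorrResult",
    "fit_gamma",
    "aic_model_comparison",
    "lag1_spearman",
    "autocorr_randomisation_test",
    "spearman_to_pearson",
    "sample_correlated_gamma",
    "CorrelatedGammaChain",
    "sample_two_point_steps",
    "TWO_POINT_MAX_STEP",
]

#: Upper support point (mm) of the "unnaturally stilted" two-point step draw.
TWO_POINT_MAX_STEP = 20.0


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class GammaParams:
    """Gamma marginal of the step-length process (shape a, rate b in 1/mm)."""

    shape: float
    rate: float

    def __post_init__(self):
        if not (
            np.isfinite(self.shape)
            and np.isfinite(self.rate)
            and self.shape > 0
            and self.rate > 0
        ):
            raise ParameterError(
                f"gamma shape and rate must be positive finite "
                f"(got shape={self.shape}, rate={self.rate})"
            )

    @property
    def mean(self) -> float:
        """Mean step length a/b in mm."""
        return self.shape / self.rate

    def to_dict(self) -> dict:
        return {"shape": float(self.shape), "rate": float(self.rate)}

    @classmethod
    def from_dict(cls, d: dict) -> "GammaParams":
        return cls(float(d["shape"]), float(d["rate"]))


@dataclass(frozen=True)
class AutocorrResult:
    """Lag-1 Spearman autocorrelation with its randomisation-test p value."""

    rho_s: float
    p_value: float
    n_permutations: int


def _validate_steps(steps, min_len: int, *, allow_constant: bool = False) -> np.ndarray:
    s = np.asarray(steps, dtype=float).ravel()
    if s.size < min_len:
        raise InputError(f"need at least {min_len} step values, got {s.size}")
    if not np.all(np.isfinite(s)):
        raise InputError("step series contains non-finite values")
    if np.any(s < 0):
        raise InputError("step lengths must be non-negative")
    if not allow_constant and float(np.ptp(s)) < 1e-12:
        raise DegenerateDataError("step series is constant")
    return s


def fit_gamma(steps, zero_floor: float = 1e-6) -> GammaParams:
    """Maximum-likelihood gamma fit to a step-length series.

    Exact zeros (and values below ``zero_floor`` mm) are floored before
    fitting, since the gamma density has no mass at zero but recorded series
    may contain rest frames.
    """
    s = _validate_steps(steps, min_len=50)
    s = np.maximum(s, zero_floor)
    shape, _, scale = stats.gamma.fit(s, floc=0.0)
    return GammaParams(float(shape), 1.0 / float(scale))


_AIC_CANDIDATES = ("gamma", "normal", "cauchy", "weibull", "logistic", "lognormal")


def _fit_candidate(name: str, s: np.ndarray) -> tuple[float, int]:
    """Return (max log-likelihood, n_params) for one candidate family."""
    if name == "gamma":
        a, loc, scale = stats.gamma.fit(s, floc=0.0)
        ll = stats.gamma.logpdf(s, a, loc, scale).sum()
        return float(ll), 2
    if name == "weibull":
        c, loc, scale = stats.weibull_min.fit(s, floc=0.0)
        ll = stats.weibull_min.logpdf(s, c, loc, scale).sum()
        return float(ll), 2
    if name == "lognormal":
        sg, loc, scale = stats.lognorm.fit(s, floc=0.0)
        ll = stats.lognorm.logpdf(s, sg, loc, scale).sum()
        return float(ll), 2
    dist = {"normal": stats.norm, "cauchy": stats.cauchy, "logistic": stats.logistic}[name]
    loc0, scale0 = float(np.median(s)), float(np.subtract(*np.percentile(s, [75, 25])) / 2)
    args = dist.fit(s, loc=loc0, scale=max(scale0, 1e-6))
    ll = dist.logpdf(s, *args).sum()
    return float(ll), 2


def aic_model_comparison(steps, zero_floor: float = 1e-6) -> pd.DataFrame:
    """Rank candidate step-length distributions by AIC (ascending).

    Candidates: gamma, normal, Cauchy, Weibull, logistic and log-normal,
    each fitted by maximum likelihood (positive-support families with the
    location pinned at zero).  A failed fit is recorded with NaN rather than
    raised.  Returns a DataFrame with columns ``distribution, n_params,
    log_likelihood, aic, delta_aic``.
    """
    s = _validate_steps(steps, min_len=50)
    s = np.maximum(s, zero_floor)
    rows = []
    for name in _AIC_CANDIDATES:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ll, k = _fit_candidate(name, s)
            if not np.isfinite(ll):
                raise FloatingPointError("non-finite log likelihood")
            aic = 2.0 * k - 2.0 * ll
        except Exception:
            ll, k, aic = np.nan, 2, np.nan
        rows.append({"distribution": name, "n_params": k, "log_likelihood": ll, "aic": aic})
    df = pd.DataFrame(rows).sort_values("aic", na_position="last", ignore_index=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


def lag1_spearman(steps) -> float:
    """Spearman rank correlation between the series and its one-step lag."""
    s = _validate_steps(steps, min_len=10)
    rho = stats.spearmanr(s[:-1], s[1:]).statistic
    if not np.isfinite(rho):
        raise DegenerateDataError("lag-1 Spearman correlation undefined")
    return float(rho)


def _lag1_pearson(x: np.ndarray) -> float:
    a, b = x[:-1], x[1:]
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        return 0.0
    return float(a @ b) / denom


def autocorr_randomisation_test(steps, n_perm: int = 999, rng=None) -> AutocorrResult:
    """Randomisation test of lag-1 rank autocorrelation against independence.

    The series order is permuted ``n_perm`` times; the two-sided p value is
    ``(1 + #{|rho*| >= |rho_hat|}) / (n_perm + 1)``, so the smallest
    attainable p is ``1/(n_perm + 1)``.
    """
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    rng = _as_rng(rng)
    rho = lag1_spearman(steps)
    s = np.asarray(steps, dtype=float).ravel()
    ranks = stats.rankdata(s)
    hits = 0
    for _ in range(n_perm):
        rp = ranks[rng.permutation(ranks.size)]
        if abs(_lag1_pearson(rp)) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AutocorrResult(rho_s=rho, p_value=p, n_permutations=n_perm)


def spearman_to_pearson(rho_s: float) -> float:
    """Map a Spearman rank correlation to the latent Pearson correlation.

    For a bivariate Gaussian copula the two are related exactly by
    ``rho = 2*sin(rho_s * pi / 6)``; the map is odd, monotone and fixes
    -1, 0 and 1.
    """
    if not np.isfinite(rho_s) or not -1.0 <= rho_s <= 1.0:
        raise InputError(f"rho_s must lie in [-1, 1], got {rho_s}")
    return 2.0 * math.sin(rho_s * math.pi / 6.0)


def _gamma_quantile(g: GammaParams, u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return special.gammaincinv(g.shape, u) / g.rate


def sample_correlated_gamma(g: GammaParams, rho_s: float, n: int, rng) -> np.ndarray:
    """Generate ``n`` gamma-marginal steps with lag-1 rank correlation ``rho_s``.

    The latent chain is a stationary standard-normal AR(1) with coefficient
    ``spearman_to_pearson(rho_s)``; each latent value is mapped through the
    normal CDF and the gamma quantile function, so every element is exactly
    Gamma(shape, rate) distributed regardless of the correlation.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if not 0.0 <= rho_s < 1.0:
        raise InputError(f"rho_s must lie in [0, 1), got {rho_s}")
    rng = _as_rng(rng)
    rho = spearman_to_pearson(rho_s)
    eps = rng.standard_normal(n)
    innov = eps * math.sqrt(1.0 - rho * rho)
    innov[0] = eps[0]  # stationary start: z_0 ~ N(0, 1)
    z = signal.lfilter([1.0], [1.0, -rho], innov)
    return _gamma_quantile(g, special.ndtr(z))


class CorrelatedGammaChain:
    """Stateful one-at-a-time version of :func:`sample_correlated_gamma`.

    Used by the simulator, where boundary handling may force repeated draws:
    every call to :meth:`draw` advances the latent AR(1) state, including
    draws that the caller later rejects.
    """

    def __init__(self, g: GammaParams, rho_s: float, rng):
        if not 0.0 <= rho_s < 1.0:
            raise InputError(f"rho_s must lie in [0, 1), got {rho_s}")
        self.g = g
        self.rho = spearman_to_pearson(rho_s)
        self._sq = math.sqrt(1.0 - self.rho * self.rho)
        self._rng = _as_rng(rng)
        self._z: float | None = None

    def draw(self) -> float:
        eps = float(self._rng.standard_normal())
        if self._z is None:
            z = eps
        else:
            z = self.rho * self._z + self._sq * eps
        self._z = z
        u = min(max(float(special.ndtr(z)), 1e-300), 1.0 - 1e-16)
        return float(special.gammaincinv(self.g.shape, u)) / self.g.rate


def sample_two_point_steps(mean_step: float, n: int, rng) -> np.ndarray:
    """Draw i.i.d. steps from the two-point distribution on {0, 20} mm.

    The probability of the 20 mm value is ``mean_step / 20``, so the mean
    matches ``mean_step`` exactly; this is the "unnaturally stilted"
    stimulus variant.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if not np.isfinite(mean_step) or mean_step < 0.0:
        raise InputError(f"mean_step must be >= 0, got {mean_step}")
    if mean_step > TWO_POINT_MAX_STEP:
        raise ParameterError(
            f"mean step {mean_step} mm infeasible for a two-point "
            f"distribution on [0, {TWO_POINT_MAX_STEP}]"
        )
    rng = _as_rng(rng)
    return TWO_POINT_MAX_STEP * (rng.random(n) < mean_step / TWO_POINT_MAX_STEP)
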