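"""Statistics for two-choice (Turing-type) preference trials.

A focal fish chooses between two animated stimuli; which stimulus its first
choice favoured and the latency to choose are recorded.  First-choice
counts are compared against chance with an exact two-sided binomial test,
latencies with a two-sample t-test, and the required sample size for a
given effect on a proportion comes from the arcsine-transform normal
approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InputError

__all__ = [
    "PreferenceTrial",
    "TTestResult",
    "binomial_first_choice_test",
    "latency_t_test",
    "min_sample_size_proportion",
]

#: Free-swimming phase of a trial, in seconds.
TRIAL_DURATION_S = 90.0

_CHOICES = ("modelled", "alternative")


@dataclass(frozen=True)
class PreferenceTrial:
    """One trial: which stimulus was approached first and after how long."""

    first_choice: str
    latency_s: float

    def __post_init__(self):
        if self.first_choice not in _CHOICES:
            raise InputError(f"first_choice must be one of {_CHOICES}")
        if not (0.0 < self.latency_s <= TRIAL_DURATION_S):
            raise InputError(
                f"latency must lie in (0, {TRIAL_DURATION_S}] s, got {self.latency_s}"
            )


def binomial_first_choice_test(k_modelled: int, n: int) -> float:
    """Exact two-sided binomial test of k successes in n trials against 0.5.

    The two-sided p value sums the probabilities of all outcomes no more
    likely than the observed count (the minimum-likelihood convention).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if not 0 <= k_modelled <= n:
        raise InputError(f"k must lie in [0, n] (got k={k_modelled}, n={n})")
    return float(stats.binomtest(k_modelled, n, p=0.5).pvalue)


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test: statistic, degrees of freedom, two-sided p."""

    t: float
    df: float
    p_value: float


def latency_t_test(latencies_a, latencies_b, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test for a latency difference between stimuli.

    Pooled-variance (classical) by default, with Welch's unequal-variance
    form available via ``equal_var=False``.
    """
    a = np.asarray(latencies_a, dtype=float).ravel()
    b = np.asarray(latencies_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InputError("need at least 2 latencies per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InputError("latencies must be finite")
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if va == 0.0 and vb == 0.0:
        if float(a.mean()) == float(b.mean()):
            # no variance, no difference: conventional t = 0, p = 1
            df = a.size + b.size - 2
            return TTestResult(t=0.0, df=float(df), p_value=1.0)
        raise DegenerateDataError("zero variance in both groups; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        na, nb = a.size, b.size
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    return TTestResult(t=float(res.statistic), df=float(df), p_value=float(res.pvalue))


def min_sample_size_proportion(
    effect_h: float, power: float = 0.8, alpha: float = 0.05
) -> int:
    """Smallest n detecting effect ``h`` in a two-sided one-proportion test.

    Uses the arcsine-transform normal approximation:
    ``n >= (z_{1-alpha/2} + z_{power})^2 / h^2``, rounded up.  Cohen's
    conventional "medium" effect is h = 0.5.
    """
    if not (np.isfinite(effect_h) and effect_h > 0):
        raise InputError(f"effect size h must be > 0, got {effect_h}")
    if not (0.0 < power < 1.0 and 0.0 < alpha < 1.0):
        raise InputError("power and alpha must lie in (0, 1)")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    z_power = stats.norm.ppf(power)
    n = (z_alpha + z_power) ** 2 / effect_h**2
    return max(1, int(math.ceil(n - 1e-9)))
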