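"""Power analysis for the paired t-test via the noncentral t distribution.

For a paired design with standardized effect size d (mean difference over
SD of differences) and n pairs, the test statistic follows a noncentral t
with df = n - 1 and noncentrality d * sqrt(n).  Power is the probability
mass of that distribution beyond the central-t critical value.  This is
the same model that standard power software uses for paired t-tests, so
sample sizes reproduce without external tools.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from scipy import stats as sps

__all__ = ["power_at_n", "required_n", "mc_power"]

Sided = Literal["one", "two"]


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")


def power_at_n(d: float, n: int, alpha: float = 0.05, sided: Sided = "one") -> float:
    """Exact power of the paired t-test at n pairs and true effect d."""
    _check_alpha(alpha)
    if n < 2:
        raise ValueError("need at least two pairs")
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    df = n - 1
    nc = d * math.sqrt(n)
    if sided == "one":
        t_crit = sps.t.ppf(1.0 - alpha, df)
        return float(sps.nct.sf(t_crit, df, nc))
    if sided == "two":
        t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))
    raise ValueError("sided must be 'one' or 'two'")


def required_n(d: float, target_power: float = 0.80, alpha: float = 0.05,
               sided: Sided = "one", n_max: int = 1_000_000) -> int:
    """Smallest n with power_at_n(d, n) >= target_power.

    Power is strictly increasing in n for d > 0, so an exponential bracket
    plus bisection finds the minimum exactly.
    """
    _check_alpha(alpha)
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must lie in (0, 1)")
    if d <= 0:
        raise ValueError("no finite n reaches the target power for d <= 0")
    lo, hi = 2, 2
    while power_at_n(d, hi, alpha, sided) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError(f"required n exceeds {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at_n(d, mid, alpha, sided) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def mc_power(d: float, n: int, alpha: float = 0.05, sided: Sided = "one",
             reps: int = 100_000, seed: int | np.random.Generator | None = None) -> float:
    """Monte-Carlo power estimate: fraction of simulated cohorts of paired
    differences ~ Normal(d, 1) whose t-test rejects at alpha."""
    if reps < 1000:
        raise ValueError("reps must be at least 1000")
    _check_alpha(alpha)
    rng = np.random.default_rng(seed)
    diffs = rng.normal(d, 1.0, size=(reps, n))
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    if sided == "one":
        t_crit = sps.t.ppf(1.0 - alpha, df)
        reject = t > t_crit
    else:
        t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
        reject = np.abs(t) > t_crit
    return float(reject.mean())
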