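"""Within-subject inferential statistics.

Implements the classical univariate repeated-measures ANOVA for fully
crossed, balanced within-subject designs (up to three factors): every
effect is tested against its own subject-by-effect interaction mean
square, with Greenhouse-Geisser sphericity correction for effects with
more than one numerator degree of freedom and generalized eta squared
(Olejnik-Algina / Bakeman) as the effect size, which keeps all error
variance — including between-subject variance — in the denominator.

Also provides the paired t-test with Cohen's d for paired data
(d = mean(diff)/sd(diff), hence d = t/sqrt(n)), and Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "TTestResult",
    "rm_anova",
    "gg_epsilon",
    "paired_t",
    "bonferroni",
]


@dataclass(frozen=True)
class AnovaEffect:
    """One tested within-subject effect."""

    effect: str
    F: float
    df_num: int
    df_den: int
    gg_epsilon: float
    p_uncorrected: float
    p_gg_corrected: float
    ges: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    n_pairs: int
    sided: str
    correction: str = "none"


def _subsets(items: Sequence[int]) -> list[tuple[int, ...]]:
    return list(chain.from_iterable(combinations(items, k)
                                    for k in range(len(items) + 1)))


def _mobius_deviation(arr: np.ndarray, effect_axes: tuple[int, ...]) -> np.ndarray:
    """Inclusion-exclusion deviation table for an effect.

    ``arr`` holds cell means with one axis per factor in the effect (other
    factors already averaged out).  The returned table, indexed by the
    effect's axes, sums marginal means over all subsets of the effect's
    factors with alternating signs — the classical balanced-design effect
    estimate.
    """
    dev = np.zeros_like(arr, dtype=float)
    for sub in _subsets(effect_axes):
        drop = tuple(ax for ax in effect_axes if ax not in sub)
        sign = (-1.0) ** len(drop)
        dev += sign * arr.mean(axis=drop, keepdims=True) if drop else sign * arr
    return dev


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal basis of the contrast space (rows sum to 0)."""
    a = np.ones((k, 1))
    q, _ = np.linalg.qr(np.hstack([a, np.eye(k)]))
    return q[:, 1:k].T


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k cell covariance matrix.

    Box's correction factor: with C the centering matrix and S the
    covariance of within-subject cell scores,
    eps = tr(CSC)^2 / ((k-1) tr((CSC)^2)), bounded by (1/(k-1), 1].
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need at least two cells")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if k == 2:
        return 1.0
    C = np.eye(k) - np.full((k, k), 1.0 / k)
    M = C @ cov @ C
    denom = (k - 1) * float(np.trace(M @ M))
    if denom <= 0:
        raise ValueError("degenerate covariance")
    eps = float(np.trace(M)) ** 2 / denom
    return min(1.0, max(eps, 1.0 / (k - 1)))


def _effect_epsilon(scores: np.ndarray, level_counts: Sequence[int]) -> float:
    """GG epsilon for a (possibly interaction) effect.

    ``scores``: subjects x cells matrix of the effect's marginal means,
    cells ordered as the flattened cross of the effect's factors.  The
    effect's contrast space is the Kronecker product of each factor's
    orthonormal contrasts.
    """
    C = np.array([[1.0]])
    for k in level_counts:
        C = np.kron(C, _orthonormal_contrasts(k))
    z = scores @ C.T
    if z.shape[1] == 1:
        return 1.0
    S = np.cov(z, rowvar=False, ddof=1)
    q = z.shape[1]
    denom = q * float(np.trace(S @ S))
    if denom <= 0:
        return 1.0
    return min(1.0, max(float(np.trace(S)) ** 2 / denom, 1.0 / q))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject",
) -> list[AnovaEffect]:
    """Repeated-measures ANOVA for a balanced, fully within-subject design.

    ``data`` must contain exactly one observation per subject x cell (use
    :func:`pitkit.metrics.summarize` first).  Returns one
    :class:`AnovaEffect` per main effect and interaction, each tested
    against its own subject-by-effect error term.
    """
    within = list(within)
    if not 1 <= len(within) <= 3:
        raise ValueError("between one and three within factors supported")
    counts = data.groupby([subject] + within, observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError("need exactly one observation per subject x cell")
    wide = data.pivot_table(index=subject, columns=within, values=dv, observed=True)
    if wide.isna().any().any():
        raise ValueError("missing cells in the within design")
    if len(within) == 1:
        level_values = [list(wide.columns)]
    else:
        level_values = [list(lv) for lv in wide.columns.levels]
    levels = [len(lv) for lv in level_values]
    n_subj = wide.shape[0]
    if n_subj < 2:
        raise ValueError("need at least two subjects")
    arr = wide.to_numpy().reshape([n_subj] + levels)  # axis 0 = subject

    total_cells = int(np.prod(levels))
    factor_axes = tuple(range(1, len(levels) + 1))

    # subject SS (between-subject error stratum)
    subj_means = arr.mean(axis=factor_axes)
    ss_subject = total_cells * float(np.sum((subj_means - subj_means.mean()) ** 2))

    effects: list[AnovaEffect] = []
    raw: list[dict] = []
    for axes in _subsets(factor_axes):
        if not axes:
            continue
        keep = (0,) + axes
        marr = arr.mean(axis=tuple(ax for ax in factor_axes if ax not in axes))
        # marr axes: subject + effect factors (in order)
        cell_means = marr.mean(axis=0)
        mult = total_cells / np.prod([levels[ax - 1] for ax in axes])
        eff_axes_local = tuple(range(cell_means.ndim))
        dev = _mobius_deviation(cell_means, eff_axes_local)
        ss_eff = n_subj * mult * float(np.sum(dev ** 2))
        # subject x effect interaction (error term)
        dev_err = _mobius_deviation(marr, tuple(range(marr.ndim)))
        ss_err = mult * float(np.sum(dev_err ** 2))
        df_num = int(np.prod([levels[ax - 1] - 1 for ax in axes]))
        df_den = (n_subj - 1) * df_num
        ms_eff = ss_eff / df_num
        ms_err = ss_err / df_den
        if ms_eff == 0.0:
            F = 0.0
        elif ms_err == 0.0:
            F = math.inf
        else:
            F = ms_eff / ms_err
        scores = marr.reshape(n_subj, -1)
        eps = _effect_epsilon(scores, [levels[ax - 1] for ax in axes]) \
            if df_num > 1 else 1.0
        p_unc = float(sps.f.sf(F, df_num, df_den))
        p_gg = float(sps.f.sf(F, eps * df_num, eps * df_den)) if df_num > 1 else p_unc
        name = ":".join(within[ax - 1] for ax in axes)
        raw.append(dict(name=name, F=F, df_num=df_num, df_den=df_den, eps=eps,
                        p_unc=p_unc, p_gg=p_gg, ss_eff=ss_eff, ss_err=ss_err))

    ss_all_error = ss_subject + sum(r["ss_err"] for r in raw)
    for r in raw:
        ges = r["ss_eff"] / (r["ss_eff"] + ss_all_error)
        effects.append(AnovaEffect(
            effect=r["name"], F=r["F"], df_num=r["df_num"], df_den=r["df_den"],
            gg_epsilon=r["eps"], p_uncorrected=r["p_unc"],
            p_gg_corrected=r["p_gg"], ges=ges,
            ss_effect=r["ss_eff"], ss_error=r["ss_err"]))
    return effects


def paired_t(
    x_plus: Sequence[float],
    x_minus: Sequence[float],
    sided: Literal["one", "two"] = "two",
) -> TTestResult:
    """Paired t-test with Cohen's d for paired data.

    d = mean(diff) / sd(diff), so d = t / sqrt(n) identically.  One-sided
    tests the alternative mean(x_plus - x_minus) > 0.
    """
    x_plus = np.asarray(x_plus, dtype=float)
    x_minus = np.asarray(x_minus, dtype=float)
    if x_plus.shape != x_minus.shape or x_plus.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = x_plus.size
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = x_plus - x_minus
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t = float(diff.mean() / (sd / math.sqrt(n)))
    df = n - 1
    if sided == "one":
        p = float(sps.t.sf(t, df))
    elif sided == "two":
        p = float(2 * sps.t.sf(abs(t), df))
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return TTestResult(t=t, df=df, p=p, cohens_d=float(diff.mean() / sd),
                       n_pairs=n, sided=sided)


def bonferroni(p_values: Iterable[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m * p) per test."""
    p = [float(v) for v in p_values]
    if any(not 0.0 <= v <= 1.0 for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of tests")
    return [min(1.0, m * v) for v in p]
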