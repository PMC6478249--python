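"""Predictive-validity model comparison across threat-learning measures.

Each measure (the behavioral PIT response-rate contrast, SCR, pupil size,
heart period) yields one estimate per subject per CS level.  Its predictive
validity is quantified as the evidence for a model in which CS type differs
by measure value: CS type (coded +1/-1) is regressed on the measure plus
per-subject intercepts — a setup formally equivalent to a paired t-test.
The residual sum of squares maps to an information criterion,

    AIC = n log(RSS / n) + 2 (r + 1)        (natural log),

with n observations and r regressors, and AIC differences to log Bayes
factors, LBF = (AIC - AIC_ref) / 2, the PIT measure serving as reference.
Smaller LBF means a better model; |LBF| > 3 is treated as decisive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelFit",
    "EvidenceComparison",
    "fit_reversed_regression",
    "aic_from_rss",
    "lbf",
    "compare_measures",
    "cross_measure_correlations",
    "CorrelationResults",
]

DECISIVE_LBF = 3.0


@dataclass(frozen=True)
class ModelFit:
    """Reversed-regression fit for one measure."""

    measure: str
    n: int
    r: int
    rss: float
    aic: float


@dataclass(frozen=True)
class EvidenceComparison:
    reference: str
    fits: Mapping[str, ModelFit]
    lbf: Mapping[str, float]
    decisive: Mapping[str, bool]

    def ranking(self) -> list[str]:
        """Measures from best (lowest AIC) to worst."""
        return sorted(self.fits, key=lambda m: self.fits[m].aic)


def _cs_table(values: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Validate and pivot a (subject, cs, value) table to subjects x 2."""
    required = {"subject", "cs", value_col}
    if not required <= set(values.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wide = values.pivot_table(index="subject", columns="cs", values=value_col,
                              observed=True)
    if set(wide.columns) != {"cs+", "cs-"}:
        raise ValueError("exactly the two CS levels 'cs+' and 'cs-' are required")
    if wide.isna().any().any():
        raise ValueError("every subject needs one value per CS level")
    return wide[["cs+", "cs-"]]


def fit_reversed_regression(values: pd.DataFrame, measure: str = "measure",
                            value_col: str = "value") -> ModelFit:
    """OLS of the CS indicator on the measure with per-subject intercepts.

    ``values``: long table with columns ``subject``, ``cs`` ('cs+'/'cs-')
    and ``value_col``; exactly one row per subject per CS level.  Returns
    n = 2 * n_subjects observations and r = n_subjects + 1 regressors.
    A measure carrying no CS information degenerates gracefully: the fit
    reduces to the subject intercepts.
    """
    wide = _cs_table(values, value_col)
    S = wide.shape[0]
    if S < 3:
        raise ValueError("need at least three subjects")
    y = np.tile([1.0, -1.0], S)                      # CS+ -> +1, CS- -> -1
    x = wide.to_numpy().reshape(-1)                   # subject-major, cs+ then cs-
    X = np.zeros((2 * S, S + 1))
    X[np.arange(2 * S), np.repeat(np.arange(S), 2)] = 1.0
    X[:, S] = x
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n, r = 2 * S, S + 1
    if rss < n * 1e-12:  # numerically perfect separation
        rss = 0.0
    return ModelFit(measure=measure, n=n, r=r, rss=rss,
                    aic=aic_from_rss(rss, n, r))


def aic_from_rss(rss: float, n: int, r: int) -> float:
    """AIC = n log(RSS/n) + 2(r+1); -inf (with a warning) for a perfect fit."""
    if n <= 0 or r < 0:
        raise ValueError("need n > 0 and r >= 0")
    if rss < 0:
        raise ValueError("RSS cannot be negative")
    if rss == 0.0:
        warnings.warn("zero RSS: AIC is -infinity (perfect fit)", RuntimeWarning)
        return -math.inf
    return n * math.log(rss / n) + 2.0 * (r + 1)


def lbf(aic: float, aic_ref: float) -> float:
    """Log Bayes factor relative to a reference model: (AIC - AIC_ref)/2."""
    return (aic - aic_ref) / 2.0


def compare_measures(
    tables: Mapping[str, pd.DataFrame],
    reference: str = "pit",
    value_col: str = "value",
) -> EvidenceComparison:
    """Fit every measure and compute LBF against the reference measure.

    All measures must come from the same subjects so that every model has
    identical n and r and AIC differences reduce to RSS ratios.
    """
    if reference not in tables:
        raise ValueError(f"reference measure {reference!r} not among tables")
    subjects = None
    fits: dict[str, ModelFit] = {}
    for name, tab in tables.items():
        wide = _cs_table(tab, value_col)
        if subjects is None:
            subjects = set(wide.index)
        elif set(wide.index) != subjects:
            raise ValueError(f"measure {name!r} has a different subject set")
        fits[name] = fit_reversed_regression(tab, measure=name, value_col=value_col)
    ref_aic = fits[reference].aic
    lbfs = {name: lbf(f.aic, ref_aic) for name, f in fits.items()}
    decisive = {name: abs(v) > DECISIVE_LBF for name, v in lbfs.items()}
    return EvidenceComparison(reference=reference, fits=fits, lbf=lbfs,
                              decisive=decisive)


@dataclass(frozen=True)
class CorrelationResults:
    """Pairwise Pearson correlations between measures."""

    diff_r: pd.DataFrame
    diff_p: pd.DataFrame
    residual_r: pd.DataFrame
    residual_p: pd.DataFrame


def cross_measure_correlations(
    tables: Mapping[str, pd.DataFrame],
    value_col: str = "value",
) -> CorrelationResults:
    """Correlations of CS+ - CS- differences between measures, plus
    residual correlations after removing each CS level's grand mean
    (pooled over subject x CS rows)."""
    names = list(tables)
    wides = {}
    subjects = None
    for name in names:
        wide = _cs_table(tables[name], value_col)
        if subjects is None:
            subjects = wide.index
        wide = wide.loc[subjects]
        wides[name] = wide
    if len(subjects) < 4:
        raise ValueError("need at least four subjects")

    diffs = pd.DataFrame({n: w["cs+"] - w["cs-"] for n, w in wides.items()})
    resids = pd.DataFrame({n: np.concatenate([w["cs+"] - w["cs+"].mean(),
                                              w["cs-"] - w["cs-"].mean()])
                           for n, w in wides.items()})

    def corr_with_p(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
        for i, a in enumerate(names):
            if df[a].std(ddof=1) == 0:
                raise ValueError(f"zero-variance column {a!r}")
            for b in names[i + 1:]:
                res = sps.pearsonr(df[a], df[b])
                r.loc[a, b] = r.loc[b, a] = res.statistic
                p.loc[a, b] = p.loc[b, a] = res.pvalue
        return r, p

    dr, dp = corr_with_p(diffs)
    rr, rp = corr_with_p(resids)
    return CorrelationResults(diff_r=dr, diff_p=dp, residual_r=rr, residual_p=rp)
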