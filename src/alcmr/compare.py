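"""Analyses run alongside the core MR estimators.

Observational dose-category regressions (reference: current non-drinkers)
with a rule-based dose-response classifier, stratified MR with Cochran's Q
heterogeneity across strata, and Holm / Bonferroni multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import MREstimate
from .exposure import DOSE_CATEGORIES
from .instruments import _covariate_matrix

__all__ = [
    "CategoryEffects",
    "StrataComparison",
    "observational_assoc",
    "classify_dose_response",
    "stratified_mr",
    "cochran_q_strata",
    "holm_adjust",
]

#: Covariate sets for observational models, as cohort-column names
#: ("smoking_current" encodes the current-smoker indicator).
ADJUSTMENT_SETS = {
    "minimal": ("sex", "age"),
    "full": ("sex", "age", "smoking_current", "ses", "bmi"),
}


@dataclass
class CategoryEffects:
    """Per-dose-category estimates against the non-drinker reference.

    The reference category carries estimate 0 (log scale); ``table`` rows are
    ordered by dose. Estimates are identity-scale for linear models and
    log-OR for logistic models.
    """

    table: pd.DataFrame
    outcome: str
    family: str
    adjustment: str

    @property
    def estimates(self) -> np.ndarray:
        return self.table["estimate"].to_numpy()


@dataclass
class StrataComparison:
    """Per-stratum MR estimates with a heterogeneity test across strata."""

    strata: tuple
    estimates: dict
    q_statistic: float
    df: int
    p_heterogeneity: float
    excluded: list = field(default_factory=list)


def _nondrinker_mask(cohort: pd.DataFrame, reference: str) -> np.ndarray:
    """Rows forming the reference group, and rows retained in the model.

    ``reference='all_zero'`` treats everyone with zero current intake
    (never, former, and zero-reporting current drinkers) as the reference;
    ``reference='never_only'`` drops former drinkers from the analysis so the
    reference is never-drinkers plus zero-reporting current drinkers.
    """
    zero = cohort["exposure_glasses_week"].to_numpy() == 0
    if reference == "all_zero":
        keep = np.ones(len(cohort), dtype=bool)
    elif reference == "never_only":
        keep = (cohort["drinker_status"] != "former").to_numpy()
    else:
        raise ValueError(f"unknown reference definition {reference!r}")
    return zero, keep


def observational_assoc(
    cohort: pd.DataFrame,
    outcome: str,
    family: str = "linear",
    adjustment: str = "minimal",
    reference: str = "all_zero",
) -> CategoryEffects:
    """Dose-category regression of an outcome against non-drinkers.

    Fits linear (continuous outcome) or logistic (binary) regression with
    indicator variables for each populated non-reference dose category plus
    the named adjustment set. Returns per-category estimates (identity or
    log-OR scale), standard errors and 95% CIs, with the reference pinned
    at 0.
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    if adjustment not in ADJUSTMENT_SETS:
        raise ValueError(f"unknown adjustment set {adjustment!r}")
    zero, keep = _nondrinker_mask(cohort, reference)
    sub = cohort[keep]
    zero = zero[keep]
    if not zero.any():
        raise ValueError("reference group (non-drinkers) is empty")
    cats = np.array([_categorize(d) for d in sub["drinks_day"].to_numpy()])
    cats[zero] = DOSE_CATEGORIES[0]
    populated = [c for c in DOSE_CATEGORIES[1:] if (cats == c).any()]
    if not populated:
        raise ValueError("no non-reference dose categories are populated")

    covs = [c for c in ADJUSTMENT_SETS[adjustment] if c == "smoking_current" or c in sub]
    C = _covariate_matrix(sub, covs)
    dummies = np.column_stack([(cats == c).astype(float) for c in populated])
    X = np.hstack([np.ones((len(sub), 1)), dummies] + ([C] if C is not None else []))
    y = sub[outcome].to_numpy(dtype=float)
    if family == "linear":
        res = sm.OLS(y, X).fit()
    else:
        res = sm.Logit(y, X).fit(disp=0)

    rows = [
        {"category": DOSE_CATEGORIES[0], "estimate": 0.0, "se": np.nan,
         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
         "n": int(zero.sum())}
    ]
    for j, c in enumerate(populated, start=1):
        est, se = float(res.params[j]), float(res.bse[j])
        rows.append(
            {
                "category": c,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.959963984540054 * se,
                "ci_high": est + 1.959963984540054 * se,
                "p": float(res.pvalues[j]),
                "n": int((cats == c).sum()),
            }
        )
    return CategoryEffects(
        table=pd.DataFrame(rows), outcome=outcome, family=family, adjustment=adjustment
    )


def _categorize(drinks_day: float) -> str:
    from .exposure import categorize_daily

    return categorize_daily(drinks_day)


def classify_dose_response(effects, eps: float = 0.01) -> str:
    """Rule-based label for a dose-response curve (reference first, at 0).

    Labels: ``flat`` (all |estimate| < eps), ``monotonic-increasing`` /
    ``monotonic-decreasing`` (ordered including the reference),
    ``J-shape`` (some moderate category at or below the reference while the
    top category exceeds every moderate one), ``J-shape-below-reference``
    (J-shape whose top category still sits below the reference), otherwise
    ``unclassified``.
    """
    if isinstance(effects, CategoryEffects):
        est = effects.estimates
    else:
        est = np.asarray(effects, dtype=float)
    if est.size < 3:
        raise ValueError("need at least 3 dose categories to classify")
    if abs(est[0]) > 1e-12:
        raise ValueError("first (reference) estimate must be 0")
    moderate = est[1:-1]
    top = est[-1]
    if np.all(np.abs(est) < eps):
        return "flat"
    diffs = np.diff(est)
    if np.all(diffs >= 0):
        return "monotonic-increasing"
    if np.all(diffs <= 0):
        return "monotonic-decreasing"
    if moderate.min() <= 0 and top > moderate.max():
        if top < 0:
            return "J-shape-below-reference"
        return "J-shape"
    return "unclassified"


def cochran_q_strata(betas, ses):
    """Cochran's Q heterogeneity test across stratum estimates.

    Uses the precision-weighted mean; Q is chi-square with S-1 degrees of
    freedom under homogeneity. Binary-outcome estimates must be on the
    log-OR scale.
    """
    b = np.atleast_1d(np.asarray(betas, dtype=float))
    s = np.atleast_1d(np.asarray(ses, dtype=float))
    if b.size < 2:
        raise ValueError("heterogeneity test needs at least 2 strata")
    if (s <= 0).any():
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / s**2
    mean = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - mean) ** 2))
    df = b.size - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def stratified_mr(
    cohort: pd.DataFrame,
    geno,
    stratum: str,
    estimator: Callable[..., MREstimate],
    outcome: str,
    instrument_columns=None,
    covariates=("sex", "age"),
    min_n: int = 500,
) -> StrataComparison:
    """Run an MR estimator independently within each stratum.

    ``estimator`` is one of the one-sample estimators (signature
    ``(outcome, exposure, instrument, covariates)``); strata smaller than
    ``min_n`` are excluded with a logged warning. Heterogeneity across the
    per-stratum estimates comes from :func:`cochran_q_strata`.
    """
    if instrument_columns is None:
        instrument_columns = geno.coded()
    instrument_columns = np.asarray(instrument_columns, dtype=float).reshape(
        len(cohort), -1
    )
    levels = pd.unique(cohort[stratum])
    estimates, excluded = {}, []
    for lev in levels:
        mask = (cohort[stratum] == lev).to_numpy()
        if mask.sum() < min_n:
            excluded.append(f"{stratum}={lev}: n={int(mask.sum())} < {min_n}")
            continue
        sub = cohort[mask]
        covs = [c for c in (covariates or ()) if c != stratum]
        C = _covariate_matrix(sub, covs) if covs else None
        estimates[lev] = estimator(
            sub[outcome].to_numpy(),
            sub["drinks_day"].to_numpy(),
            instrument_columns[mask],
            C,
        )
    if len(estimates) < 2:
        raise ValueError(
            f"need at least 2 usable strata, got {len(estimates)} (excluded: {excluded})"
        )
    q, df, p = cochran_q_strata(
        [e.beta for e in estimates.values()], [e.se for e in estimates.values()]
    )
    return StrataComparison(
        strata=tuple(estimates),
        estimates=estimates,
        q_statistic=q,
        df=df,
        p_heterogeneity=p,
        excluded=excluded,
    )


def holm_adjust(pvalues, method: str = "holm") -> np.ndarray:
    """Step-down Holm (default) or Bonferroni adjusted p-values.

    Holm: sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity by a running maximum, cap at 1; returned in input order.
    """
    p = np.atleast_1d(np.asarray(pvalues, dtype=float))
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "holm":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
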