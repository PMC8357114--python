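"""Causal-effect estimators for Mendelian randomization.

All estimators return an :class:`MREstimate` whose ``beta`` is the causal
effect per one additional drink per day: on the identity scale for
continuous outcomes, on the log-odds-ratio scale for binary outcomes.

* :func:`wald_ratio` — single-SNP ratio of outcome to exposure coefficient.
* :func:`ivw` — fixed-effect inverse-variance-weighted pooling of per-SNP
  ratios, with Cochran's Q heterogeneity across SNPs.
* :func:`tsls_continuous` — one-sample two-stage least squares.
* :func:`two_stage_binary` — one-sample two-stage estimator with a logistic
  second stage (predictor substitution).
* :func:`mvmr` — multivariable MR: weighted regression of outcome betas on
  several exposures' betas, giving each exposure's direct effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._regress import add_intercept, ols, two_sided_p
from .instruments import first_stage

__all__ = [
    "MREstimate",
    "MVMRResult",
    "wald_ratio",
    "ivw",
    "tsls_continuous",
    "two_stage_binary",
    "mvmr",
]

Z95 = 1.959963984540054  # standard-normal 97.5% quantile

#: First-stage F below which a weak-instrument warning is recorded.
WEAK_F_FLOOR = 10.0


@dataclass
class MREstimate:
    """A causal-effect estimate per additional drink/day."""

    beta: float
    se: float
    method: str
    scale: str = "identity"  # 'identity' or 'log_or'
    n_snps: int = 1
    q_statistic: Optional[float] = None
    q_pvalue: Optional[float] = None
    warnings: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"se must be positive and finite, got {self.se!r}")
        if self.q_statistic is not None and self.q_statistic < -1e-12:
            raise ValueError("q_statistic must be >= 0")

    @property
    def ci95_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci95_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def pvalue(self) -> float:
        return float(two_sided_p(np.array(self.beta / self.se)))

    @property
    def odds_ratio(self) -> Optional[float]:
        return math.exp(self.beta) if self.scale == "log_or" else None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "scale": self.scale,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci95_low,
            "ci_high": self.ci95_high,
            "p": self.pvalue,
            "n_snps": self.n_snps,
            "q": self.q_statistic,
            "q_p": self.q_pvalue,
            "or": self.odds_ratio,
            "warnings": ";".join(self.warnings),
        }
        return d


@dataclass
class MVMRResult:
    """Direct effects of several exposures from multivariable MR."""

    exposures: tuple
    betas: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    n_snps: int

    def estimate(self, exposure: str) -> MREstimate:
        i = self.exposures.index(exposure)
        return MREstimate(
            beta=float(self.betas[i]),
            se=float(self.ses[i]),
            method="mvmr",
            n_snps=self.n_snps,
        )


def wald_ratio(
    beta_GY: float,
    se_GY: float,
    beta_GX: float,
    se_GX: float,
    se_method: str = "first_order",
    scale: str = "identity",
) -> MREstimate:
    """Ratio estimator: SNP-outcome coefficient over SNP-exposure coefficient.

    First-order se is ``se_GY / |beta_GX|``; the second-order (delta-method)
    se adds ``beta_GY^2 * se_GX^2 / beta_GX^4`` under the square root.
    """
    if beta_GX == 0:
        raise ZeroDivisionError(
            "beta_GX is zero: the instrument has no exposure effect (weak instrument)"
        )
    if se_GY <= 0 or se_GX <= 0:
        raise ValueError("standard errors must be > 0")
    beta = beta_GY / beta_GX
    if se_method == "first_order":
        se = se_GY / abs(beta_GX)
    elif se_method == "second_order":
        se = math.sqrt(se_GY**2 / beta_GX**2 + beta_GY**2 * se_GX**2 / beta_GX**4)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return MREstimate(beta=beta, se=se, method="wald", scale=scale, n_snps=1)


def ivw(
    beta_GX,
    se_GX,
    beta_GY,
    se_GY,
    random_effects: bool = False,
    scale: str = "identity",
) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate over per-SNP ratios.

    Weights are ``beta_GX_j^2 / se_GY_j^2``; the pooled estimate equals a
    zero-intercept weighted regression of outcome betas on exposure betas.
    Cochran's Q over the per-SNP ratios (df = n_snps - 1) quantifies
    heterogeneity; with ``random_effects`` the se is inflated by
    ``max(1, sqrt(Q/df))`` (multiplicative random effects).
    """
    bGX = np.atleast_1d(np.asarray(beta_GX, dtype=float))
    sGX = np.atleast_1d(np.asarray(se_GX, dtype=float))
    bGY = np.atleast_1d(np.asarray(beta_GY, dtype=float))
    sGY = np.atleast_1d(np.asarray(se_GY, dtype=float))
    if bGX.size == 0:
        raise ValueError("ivw requires at least one SNP")
    if not (bGX.size == sGX.size == bGY.size == sGY.size):
        raise ValueError("per-SNP inputs must have equal length")
    if (sGX <= 0).any() or (sGY <= 0).any():
        raise ValueError("all standard errors must be > 0")
    if (bGX == 0).any():
        raise ZeroDivisionError("beta_GX contains zeros (weak instrument)")
    ratios = bGY / bGX
    w = bGX**2 / sGY**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    m = bGX.size
    q = float(np.sum(w * (ratios - beta) ** 2))
    if m > 1:
        q_p = float(stats.chi2.sf(q, m - 1))
        if random_effects:
            se *= max(1.0, math.sqrt(q / (m - 1)))
    else:
        q_p = None
        q = None if m == 1 else q
    return MREstimate(
        beta=beta,
        se=se,
        method="ivw",
        scale=scale,
        n_snps=m,
        q_statistic=q,
        q_pvalue=q_p,
        diagnostics={"random_effects": random_effects},
    )


def _prepare_iv_design(outcome, exposure, instrument, covariates):
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    Z = np.asarray(instrument, dtype=float).reshape(len(y), -1)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float).reshape(len(y), -1)
    return y, x, Z, C


def tsls_continuous(
    outcome,
    exposure_drinks_day,
    instrument,
    covariates=None,
    weak_f_floor: float = WEAK_F_FLOOR,
) -> MREstimate:
    """One-sample two-stage least squares for a continuous outcome.

    Stage 1 regresses exposure on instrument(s) and covariates; stage 2
    regresses the outcome on the fitted exposure and the same covariates.
    Standard errors use the conventional 2SLS correction: residuals are
    recomputed with the observed exposure, not the fitted values.
    """
    y, x, Z, C = _prepare_iv_design(outcome, exposure_drinks_day, instrument, covariates)
    n = len(y)
    k = Z.shape[1]
    fs = first_stage(x, Z, C)

    X_stage1 = add_intercept(C, Z)
    b1, _, _, _, _ = ols(x, X_stage1, names=None)
    xhat = X_stage1 @ b1

    D = add_intercept(C, xhat)  # second-stage design, exposure column last
    p = D.shape[1]
    b2, _, _, _, dtd_inv = ols(y, D)
    X_struct = add_intercept(C, x)
    resid = y - X_struct @ b2
    sigma2 = float(resid @ resid) / (n - p)
    se = float(np.sqrt(sigma2 * dtd_inv[-1, -1]))

    warnings = []
    if fs.f_statistic < weak_f_floor:
        warnings.append(
            f"weak instrument: first-stage F={fs.f_statistic:.2f} < {weak_f_floor:g}"
        )
    return MREstimate(
        beta=float(b2[-1]),
        se=se,
        method="tsls",
        scale="identity",
        n_snps=k,
        warnings=warnings,
        diagnostics={"first_stage": fs},
    )


def two_stage_binary(
    outcome,
    exposure_drinks_day,
    instrument,
    covariates=None,
    weak_f_floor: float = WEAK_F_FLOOR,
) -> MREstimate:
    """One-sample two-stage estimator for a binary outcome (log-OR scale).

    Predictor substitution: a linear first stage for the exposure, then a
    logistic regression of the outcome on the fitted exposure and
    covariates. The procedure choice is recorded in the diagnostics.
    """
    y, x, Z, C = _prepare_iv_design(outcome, exposure_drinks_day, instrument, covariates)
    classes = np.unique(y)
    if not set(classes.tolist()) <= {0.0, 1.0}:
        raise ValueError("binary outcome must be coded 0/1")
    if classes.size < 2:
        raise ValueError("binary outcome has a single class")
    fs = first_stage(x, Z, C)

    X_stage1 = add_intercept(C, Z)
    b1, _, _, _, _ = ols(x, X_stage1)
    xhat = X_stage1 @ b1

    D = add_intercept(C, xhat)
    model = sm.Logit(y, D)
    try:
        res = model.fit(disp=0, maxiter=100)
    except Exception as exc:  # perfect separation etc.
        raise RuntimeError(f"second-stage logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            f"second-stage logistic did not converge: {res.mle_retvals}"
        )
    warnings = []
    if fs.f_statistic < weak_f_floor:
        warnings.append(
            f"weak instrument: first-stage F={fs.f_statistic:.2f} < {weak_f_floor:g}"
        )
    return MREstimate(
        beta=float(res.params[-1]),
        se=float(res.bse[-1]),
        method="two_stage_binary",
        scale="log_or",
        n_snps=Z.shape[1],
        warnings=warnings,
        diagnostics={"first_stage": fs, "procedure": "predictor_substitution"},
    )


def mvmr(
    exposure_betas,
    beta_GY,
    se_GY,
    exposure_labels: Sequence[str] = (),
) -> MVMRResult:
    """Multivariable MR: per-exposure direct effects from summary statistics.

    Zero-intercept weighted least squares of per-SNP outcome betas on the
    (n_snps x n_exposures) exposure-beta matrix, weights ``1 / se_GY^2``.
    """
    B = np.asarray(exposure_betas, dtype=float)
    if B.ndim == 1:
        B = B.reshape(-1, 1)
    y = np.asarray(beta_GY, dtype=float)
    s = np.asarray(se_GY, dtype=float)
    m, k = B.shape
    if m < k:
        raise ValueError(f"need at least as many SNPs ({m}) as exposures ({k})")
    if (s <= 0).any():
        raise ValueError("all outcome standard errors must be > 0")
    labels = tuple(exposure_labels) or tuple(f"exposure_{i + 1}" for i in range(k))
    if np.linalg.matrix_rank(B) < k:
        norms = np.linalg.norm(B, axis=0)
        degenerate = [labels[i] for i in range(k) if norms[i] < 1e-12]
        pairs = []
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(B, rowvar=False)
        for i in range(k):
            for j in range(i + 1, k):
                if np.isfinite(corr[i, j]) and abs(corr[i, j]) > 0.999:
                    pairs.append((labels[i], labels[j]))
        raise ValueError(
            "exposure beta matrix is rank deficient; "
            f"zero columns: {degenerate}; collinear pairs: {pairs}"
        )
    w = 1.0 / s**2
    Bw = B * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    xtx_inv = np.linalg.inv(Bw.T @ Bw)
    betas = xtx_inv @ Bw.T @ yw
    ses = np.sqrt(np.diag(xtx_inv))  # fixed-effect (known per-SNP variances)
    pvals = two_sided_p(betas / ses)
    return MVMRResult(
        exposures=labels, betas=betas, ses=ses, pvalues=np.asarray(pvals), n_snps=m
    )
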