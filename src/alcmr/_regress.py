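"""Internal least-squares and per-SNP association helpers.

Simulation studies run the same small regressions tens of thousands of
times, so the hot paths here use plain normal-equation linear algebra rather
than a full model-fitting framework. Correctness against statsmodels is
pinned in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = ["add_intercept", "ols", "per_snp_linear", "per_snp_logistic"]


def add_intercept(*columns) -> np.ndarray:
    """Stack 1-D/2-D arrays into a design matrix with a leading intercept."""
    real = [c for c in columns if c is not None]
    if not real:
        raise ValueError("add_intercept needs at least one non-None column")
    n = len(np.atleast_1d(real[0]))
    parts = [np.ones((n, 1))]
    for c in columns:
        if c is None:
            continue
        c = np.asarray(c, dtype=float)
        parts.append(c.reshape(n, -1))
    return np.hstack(parts)


def _check_rank(X: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if names is None:
            names = [f"col{j}" for j in range(X.shape[1])]
        # identify columns involved in the deficiency via QR pivots
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(X.shape[1]) if diag[j] <= tol]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def ols(y: np.ndarray, X: np.ndarray, names=None):
    """OLS fit returning (beta, se, rss, sigma2, XtX_inv).

    Raises on rank-deficient designs, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    return beta, se, rss, sigma2, xtx_inv


def per_snp_linear(coded: np.ndarray, y: np.ndarray):
    """Simple regression of y on each SNP column separately (with intercept).

    Vectorised across SNPs; returns (beta, se) arrays of length n_snps.
    """
    coded = np.asarray(coded, dtype=float)
    y = np.asarray(y, dtype=float)
    n = coded.shape[0]
    gc = coded - coded.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    beta = sxy / sxx
    # residual variance per SNP: SS_y - beta * S_xy, df = n - 2
    rss = yc @ yc - beta * sxy
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def per_snp_logistic(coded: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Logistic regression of a binary y on each SNP column separately.

    Fits all single-SNP models (intercept + genotype) simultaneously by
    Newton-Raphson on the 2-parameter score equations, vectorised across
    SNPs. Returns (beta, se) for the genotype coefficient (log-OR per coded
    unit).
    """
    G = np.asarray(coded, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        raise ValueError("outcome has a single class")
    a = np.full(m, np.log(pbar / (1 - pbar)))  # intercepts
    b = np.zeros(m)  # genotype slopes
    for _ in range(max_iter):
        eta = a + G * b  # (n, m)
        mu = expit(eta)
        w = mu * (1 - mu)
        r = y[:, None] - mu
        # score vector per SNP
        s0 = r.sum(axis=0)
        s1 = np.einsum("ij,ij->j", G, r)
        # Hessian entries per SNP
        h00 = w.sum(axis=0)
        h01 = np.einsum("ij,ij->j", G, w)
        h11 = np.einsum("ij,ij,ij->j", G, G, w)
        det = h00 * h11 - h01 * h01
        da = (h11 * s0 - h01 * s1) / det
        db = (h00 * s1 - h01 * s0) / det
        a += da
        b += db
        if max(np.abs(da).max(initial=0.0), np.abs(db).max(initial=0.0)) < tol:
            break
    else:
        raise RuntimeError("per-SNP logistic Newton iteration did not converge")
    eta = a + G * b
    mu = expit(eta)
    w = mu * (1 - mu)
    h00 = w.sum(axis=0)
    h01 = np.einsum("ij,ij->j", G, w)
    h11 = np.einsum("ij,ij,ij->j", G, G, w)
    det = h00 * h11 - h01 * h01
    se = np.sqrt(h00 / det)
    return b, se


def two_sided_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value for a z statistic."""
    return 2.0 * stats.norm.sf(np.abs(z))
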