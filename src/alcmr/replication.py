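"""Replicate studies: bias, coverage, type-I error of the MR estimators.

Runs a scenario many times and applies the estimators to each draw. The
hot path skips measured covariates: the instruments are independent of them
by construction, so the IV estimators remain consistent, and dropping the
covariate columns keeps large replicate studies fast.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._regress import ols, add_intercept, per_snp_linear, per_snp_logistic
from .compare import cochran_q_strata
from .config import ScenarioConfig
from .estimators import ivw, tsls_continuous, two_stage_binary
from .simulate import simulate_cohort

__all__ = ["replicate_study", "summarize_replicates"]

ESTIMATORS = ("tsls", "ivw", "two_stage_binary", "ols", "q_strata")


def _one_replicate(config: ScenarioConfig, seed, estimators) -> list:
    cohort, geno = simulate_cohort(config, seed)
    dd = cohort["drinks_day"].to_numpy()
    y = cohort[config.continuous_label].to_numpy()
    yb = cohort[config.binary_label].to_numpy()
    coded = geno.coded()
    rows = []

    if "tsls" in estimators:
        est = tsls_continuous(y, dd, coded[:, :1])
        rows.append(("tsls", config.continuous_label, est.beta, est.se))
    if "ivw" in estimators:
        bgx, sgx = per_snp_linear(coded, dd)
        bgy, sgy = per_snp_linear(coded, y)
        est = ivw(bgx, sgx, bgy, sgy)
        rows.append(("ivw", config.continuous_label, est.beta, est.se))
    if "ivw_binary" in estimators:
        bgx, sgx = per_snp_linear(coded, dd)
        bgy, sgy = per_snp_logistic(coded, yb)
        est = ivw(bgx, sgx, bgy, sgy, scale="log_or")
        rows.append(("ivw_binary", config.binary_label, est.beta, est.se))
    if "two_stage_binary" in estimators:
        est = two_stage_binary(yb, dd, coded[:, :1])
        rows.append(("two_stage_binary", config.binary_label, est.beta, est.se))
    if "ols" in estimators:
        beta, se, _, _, _ = ols(y, add_intercept(dd))
        rows.append(("ols", config.continuous_label, float(beta[-1]), float(se[-1])))
    if "q_strata" in estimators:
        male = cohort["sex"].to_numpy() == 1
        betas, ses = [], []
        for mask in (male, ~male):
            est = tsls_continuous(y[mask], dd[mask], coded[mask, :1])
            betas.append(est.beta)
            ses.append(est.se)
        q, df, p = cochran_q_strata(betas, ses)
        rows.append(("q_strata", "p_heterogeneity", p, np.nan))
    return rows


def replicate_study(
    config: ScenarioConfig,
    reps: int,
    seed: int = 0,
    estimators: Iterable[str] = ("tsls", "ivw", "two_stage_binary", "ols"),
) -> pd.DataFrame:
    """Run ``reps`` independent replicates; one row per estimator per rep."""
    estimators = tuple(estimators)
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    records = []
    for r, s in enumerate(child_seeds):
        for method, outcome, beta, se in _one_replicate(config, s, estimators):
            records.append(
                {"rep": r, "method": method, "outcome": outcome, "beta": beta, "se": se}
            )
    return pd.DataFrame(records)


def summarize_replicates(results: pd.DataFrame, truths: Optional[dict] = None) -> pd.DataFrame:
    """Per-estimator bias / coverage / rejection summary of a replicate study.

    ``truths`` maps method name to the true effect; coverage and bias are
    reported only for methods with a stated truth. Rejection is a two-sided
    test of zero at the 5% level (for ``q_strata`` rows, of homogeneity).
    """
    truths = truths or {}
    rows = []
    for method, grp in results.groupby("method", sort=False):
        beta = grp["beta"].to_numpy()
        se = grp["se"].to_numpy()
        row = {
            "method": method,
            "reps": len(grp),
            "mean_beta": beta.mean(),
            "sd_beta": beta.std(ddof=1),
            "replicate_se": beta.std(ddof=1) / np.sqrt(len(grp)),
        }
        if method == "q_strata":
            row["rejection_rate"] = float((beta < 0.05).mean())  # beta column holds p
        else:
            row["rejection_rate"] = float((np.abs(beta / se) > 1.959963984540054).mean())
            if method in truths:
                t = truths[method]
                row["truth"] = t
                row["bias"] = beta.mean() - t
                lo = beta - 1.959963984540054 * se
                hi = beta + 1.959963984540054 * se
                row["coverage"] = float(((lo <= t) & (t <= hi)).mean())
        rows.append(row)
    return pd.DataFrame(rows)
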