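"""Genetic instruments: coding, first-stage fits, strength diagnostics.

The two instrument styles mirror common MR practice for alcohol intake: a
single large-effect coding variant analysed under a dominant model (carriers
vs wildtype), and a multi-SNP set analysed additively, either per SNP (for
IVW) or collapsed into a weighted allele score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._regress import add_intercept, ols, per_snp_linear, per_snp_logistic, two_sided_p
from .simulate import GenotypeMatrix

__all__ = [
    "InstrumentSpec",
    "FirstStageFit",
    "code_dominant",
    "build_allele_score",
    "first_stage",
    "genotype_group_difference",
    "snp_exposure_associations",
    "snp_outcome_associations",
    "orient_to_exposure_increasing",
]

#: Default measured-covariate set for one-sample fits.
DEFAULT_COVARIATES = ("sex", "age", "smoking_current", "ses")


@dataclass(frozen=True)
class InstrumentSpec:
    """Which SNPs form the instrument and how each is coded."""

    snp_ids: tuple
    coding: tuple  # 'additive' or 'dominant' per SNP
    weights: Optional[tuple] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        object.__setattr__(self, "coding", tuple(self.coding))
        if len(self.coding) != len(self.snp_ids):
            raise ValueError("coding must match snp_ids in length")
        bad = [c for c in self.coding if c not in ("additive", "dominant")]
        if bad:
            raise ValueError(f"coding must be 'additive' or 'dominant', got {bad}")
        if self.weights is not None:
            object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
            if len(self.weights) != len(self.snp_ids):
                raise ValueError("weights must match snp_ids in length")

    def to_file(self, path) -> None:
        w = self.weights or (1.0,) * len(self.snp_ids)
        pd.DataFrame(
            {"snp_id": self.snp_ids, "coding": self.coding, "weight": w}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path) -> "InstrumentSpec":
        df = pd.read_csv(path, sep="\t")
        return cls(
            snp_ids=tuple(df["snp_id"]),
            coding=tuple(df["coding"]),
            weights=tuple(df["weight"]) if "weight" in df else None,
        )


@dataclass(frozen=True)
class FirstStageFit:
    """Instrument-on-exposure regression summary.

    ``beta_GX`` is the exposure change (drinks/day) per coded-instrument
    unit; ``f_statistic`` is the ANOVA F for the instrument block given any
    covariates.
    """

    beta_GX: float
    se_GX: float
    r_squared: float
    f_statistic: float
    n: int
    n_instruments: int = 1

    def __post_init__(self) -> None:
        if self.se_GX <= 0:
            raise ValueError("se_GX must be > 0")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must be in [0, 1]")
        if self.f_statistic < 0:
            raise ValueError("f_statistic must be >= 0")


def code_dominant(allele_counts) -> np.ndarray:
    """Collapse heterozygous and homozygous carriers: 0 -> 0, {1, 2} -> 1."""
    counts = np.asarray(allele_counts)
    if not np.isin(counts, (0, 1, 2)).all():
        raise ValueError("allele counts must be in {0, 1, 2}")
    return (counts > 0).astype(int)


def _coded_columns(geno: GenotypeMatrix, spec: InstrumentSpec) -> np.ndarray:
    missing = [s for s in spec.snp_ids if s not in geno.snp_ids]
    extra = [s for s in geno.snp_ids if s not in spec.snp_ids]
    if missing:
        raise KeyError(
            f"instrument SNPs absent from genotype matrix: {missing}"
            + (f" (genotype-only SNPs: {extra})" if extra else "")
        )
    idx = [list(geno.snp_ids).index(s) for s in spec.snp_ids]
    cols = geno.allele_counts[:, idx].astype(float)
    for j, coding in enumerate(spec.coding):
        if coding == "dominant":
            cols[:, j] = code_dominant(cols[:, j])
    return cols


def build_allele_score(geno: GenotypeMatrix, spec: InstrumentSpec) -> np.ndarray:
    """Weighted allele score sum_j w_j * code_j(g_j) per individual."""
    if spec.weights is None:
        raise ValueError("InstrumentSpec.weights required to build an allele score")
    coded = _coded_columns(geno, spec)
    return coded @ np.asarray(spec.weights, dtype=float)


def _covariate_matrix(cohort: pd.DataFrame, covariates) -> Optional[np.ndarray]:
    """Assemble a numeric covariate matrix from cohort columns.

    The smoking category is encoded as a current-smoker indicator under the
    pseudo-column name ``smoking_current``.
    """
    if covariates is None:
        return None
    cols = []
    for c in covariates:
        if c == "smoking_current":
            cols.append((cohort["smoking"] == "current").astype(float).to_numpy())
        else:
            cols.append(cohort[c].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else None


def first_stage(
    exposure_drinks_day,
    instrument,
    covariates=None,
    covariate_names: Sequence[str] = (),
) -> FirstStageFit:
    """OLS of exposure (drinks/day) on the instrument(s) plus covariates.

    The F statistic is the ANOVA F for the instrument block,
    ``F = ((RSS0 - RSS1)/k) / (RSS1/(n - p))`` with RSS0 from the
    covariate-only model. ``beta_GX`` is reported for a single instrument
    column (NaN when several columns are passed).
    """
    y = np.asarray(exposure_drinks_day, dtype=float)
    Z = np.asarray(instrument, dtype=float).reshape(len(y), -1)
    k = Z.shape[1]
    names = ["intercept"] + [f"cov:{c}" for c in covariate_names] + [
        f"iv{j}" for j in range(k)
    ]
    X1 = add_intercept(covariates, Z)
    n, p = X1.shape
    if n <= p:
        raise ValueError("not enough observations for the first-stage fit")
    beta1, se1, rss1, _, _ = ols(y, X1, names)
    X0 = add_intercept(covariates) if covariates is not None else np.ones((n, 1))
    if covariates is None:
        rss0 = float(np.sum((y - y.mean()) ** 2))
    else:
        _, _, rss0, _, _ = ols(y, X0)
    f_stat = max(((rss0 - rss1) / k) / (rss1 / (n - p)), 0.0)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss1 / tss if tss > 0 else 0.0
    return FirstStageFit(
        beta_GX=float(beta1[-1]) if k == 1 else float("nan"),
        se_GX=float(se1[-1]) if k == 1 else float(se1[-k:].mean()),
        r_squared=min(max(r2, 0.0), 1.0),
        f_statistic=float(f_stat),
        n=n,
        n_instruments=k,
    )


def genotype_group_difference(trait, carrier, covariates=None, covariate_names=()):
    """Covariate-adjusted mean trait difference between carriers and wildtype.

    Returns ``(difference, se, p)`` where the difference is the carrier-
    indicator coefficient from least squares and p is the two-sided normal
    p-value.
    """
    carrier = np.asarray(carrier)
    if len(np.unique(carrier)) < 2:
        raise ValueError("both genotype groups must be non-empty")
    X = add_intercept(covariates, carrier.astype(float))
    names = ["intercept"] + [f"cov:{c}" for c in covariate_names] + ["carrier"]
    trait = np.asarray(trait, dtype=float)
    beta, se, _, sigma2, _ = ols(trait, X, names)
    diff, diff_se = float(beta[-1]), float(se[-1])
    scale = max(float(np.mean(trait**2)), 1.0)
    if sigma2 < 1e-20 * scale:  # degenerate: trait exactly explained
        p = 1.0 if abs(diff) < 1e-10 * np.sqrt(scale) else 0.0
    else:
        p = float(two_sided_p(np.array(diff / diff_se)))
    return diff, diff_se, p


def snp_exposure_associations(
    geno: GenotypeMatrix, exposure_drinks_day, trait: str = "alcohol"
) -> pd.DataFrame:
    """Per-SNP regressions of exposure on coded genotype (SumStats layout)."""
    beta, se = per_snp_linear(geno.coded(), np.asarray(exposure_drinks_day, float))
    return pd.DataFrame(
        {
            "snp_id": list(geno.snp_ids),
            "effect_allele": list(geno.effect_allele),
            "other_allele": list(geno.other_allele),
            "eaf": geno.eaf,
            "beta": beta,
            "se": se,
            "n": geno.n_individuals,
            "trait": trait,
        }
    )


def snp_outcome_associations(
    geno: GenotypeMatrix, outcome, family: str = "linear", trait: str = "outcome"
) -> pd.DataFrame:
    """Per-SNP outcome associations: linear beta or logistic log-OR."""
    y = np.asarray(outcome, dtype=float)
    if family == "linear":
        beta, se = per_snp_linear(geno.coded(), y)
    elif family == "logistic":
        beta, se = per_snp_logistic(geno.coded(), y)
    else:
        raise ValueError(f"unknown family {family!r}")
    return pd.DataFrame(
        {
            "snp_id": list(geno.snp_ids),
            "effect_allele": list(geno.effect_allele),
            "other_allele": list(geno.other_allele),
            "eaf": geno.eaf,
            "beta": beta,
            "se": se,
            "n": geno.n_individuals,
            "trait": trait,
        }
    )


def orient_to_exposure_increasing(
    exposure_stats: pd.DataFrame, *outcome_stats: pd.DataFrame
):
    """Re-orient every SNP so the effect allele increases the exposure.

    SNPs with a negative exposure beta have alleles swapped, betas
    sign-flipped and frequencies complemented, in the exposure table and in
    each aligned outcome table. Returns the new tables plus a boolean Series
    of flips (indexed by snp_id).
    """
    exp = exposure_stats.copy()
    flips = exp["beta"] < 0
    out_frames = []
    for df in outcome_stats:
        df = df.set_index("snp_id").loc[exp["snp_id"]].reset_index()
        out_frames.append(df)

    def _flip(df: pd.DataFrame, mask) -> pd.DataFrame:
        df = df.copy()
        ea = df.loc[mask, "effect_allele"].copy()
        df.loc[mask, "effect_allele"] = df.loc[mask, "other_allele"]
        df.loc[mask, "other_allele"] = ea
        df.loc[mask, "beta"] = -df.loc[mask, "beta"]
        if "eaf" in df:
            df.loc[mask, "eaf"] = 1.0 - df.loc[mask, "eaf"]
        return df

    mask = flips.to_numpy()
    exp = _flip(exp, mask)
    out_frames = [_flip(df, mask) for df in out_frames]
    flip_series = pd.Series(mask, index=exposure_stats["snp_id"].to_numpy(), name="flipped")
    return (exp, *out_frames, flip_series)
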