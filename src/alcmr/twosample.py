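"""Two-sample MR from GWAS summary statistics.

Summary statistics travel as tab-separated text with the canonical columns
``snp_id, effect_allele, other_allele, eaf, beta, se, n``; a dialect mapping
adapts arbitrary header names. Before estimation, outcome records are
harmonized to the exposure instrument's effect alleles: matching by SNP id,
sign-flipping swapped orientations (directly or via strand complement), and
resolving palindromic A/T and C/G variants by allele frequency or dropping
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw, wald_ratio

__all__ = [
    "SUMSTATS_COLUMNS",
    "SumStats",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "two_sample_mr",
    "split_sample_sumstats",
]

SUMSTATS_COLUMNS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "n")
_MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})

HARMONIZE_ACTIONS = ("kept", "flipped", "dropped_palindromic", "dropped_missing")


@dataclass
class SumStats:
    """Validated per-SNP association records for one trait."""

    table: pd.DataFrame
    trait: str = ""
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        dups = self.table["snp_id"][self.table["snp_id"].duplicated()]
        if len(dups):
            raise ValueError(f"duplicate snp_id in summary statistics: {sorted(set(dups))}")

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __len__(self) -> int:
        return len(self.table)


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in _PALINDROMIC


def read_sumstats(path, dialect: Optional[dict] = None, trait: str = "", sep: str = "\t") -> SumStats:
    """Read and validate a summary-statistics file.

    ``dialect`` maps canonical roles to the file's column names, e.g.
    ``{"snp_id": "SNP", "beta": "Effect"}``; unmapped roles default to the
    canonical names. Malformed rows (non-finite beta, se <= 0, bad alleles)
    are rejected with their 1-based line number and a reason, not silently
    dropped. Allele case is normalised to upper.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    mapping = {role: role for role in SUMSTATS_COLUMNS}
    if dialect:
        unknown = set(dialect) - set(SUMSTATS_COLUMNS)
        if unknown:
            raise ValueError(f"dialect maps unknown roles: {sorted(unknown)}")
        mapping.update(dialect)
    missing = [role for role in _MANDATORY if mapping[role] not in raw.columns]
    if missing:
        raise ValueError(
            f"missing mandatory column(s) {missing} in {path} "
            f"(available: {list(raw.columns)})"
        )
    df = pd.DataFrame(index=raw.index)
    for role in SUMSTATS_COLUMNS:
        col = mapping[role]
        df[role] = raw[col] if col in raw.columns else np.nan

    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reasons = pd.Series("", index=df.index)
    reasons[~np.isfinite(df["beta"])] = "non-finite beta"
    reasons[~(df["se"] > 0)] = "se not > 0"
    bad_alleles = (
        ~df["effect_allele"].isin(list("ACGT"))
        | ~df["other_allele"].isin(list("ACGT"))
        | (df["effect_allele"] == df["other_allele"])
    )
    reasons[bad_alleles] = "invalid alleles"
    eaf_bad = df["eaf"].notna() & ~df["eaf"].between(0.0, 1.0)
    reasons[eaf_bad] = "eaf outside [0, 1]"

    ok = reasons == ""
    rejected = pd.DataFrame(
        {"line": df.index[~ok] + 2, "reason": reasons[~ok]}  # +2: header + 1-based
    ).reset_index(drop=True)
    return SumStats(table=df[ok].reset_index(drop=True), trait=trait, rejected=rejected)


def write_sumstats(stats: SumStats | pd.DataFrame, path) -> None:
    df = stats.table if isinstance(stats, SumStats) else stats
    df.to_csv(path, sep="\t", index=False, columns=[c for c in SUMSTATS_COLUMNS if c in df])


def _as_table(x) -> pd.DataFrame:
    return x.table if isinstance(x, SumStats) else pd.DataFrame(x)


def harmonize(
    exposure,
    outcome,
    palindrome_policy: str = "frequency",
    eaf_window: tuple = (0.42, 0.58),
) -> pd.DataFrame:
    """Align outcome records to the exposure's effect alleles.

    For every exposure SNP the result carries one row with columns
    ``snp_id, beta_GX, se_GX, beta_GY, se_GY, action``. Orientation logic:

    * same alleles -> ``kept``; swapped alleles -> ``flipped`` (outcome beta
      sign inverted, eaf complemented); the same two cases are recognised
      through strand complements for non-palindromic SNPs.
    * palindromic SNPs (A/T, C/G): under ``frequency`` policy the strand is
      inferred from allele frequencies when both eafs lie outside the
      ambiguity window, otherwise ``dropped_palindromic``; under ``drop``
      they are always dropped.
    * SNPs absent from the outcome (or with incompatible alleles) ->
      ``dropped_missing``.
    """
    if palindrome_policy not in ("frequency", "drop"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    exp = _as_table(exposure)
    out = _as_table(outcome)
    for name, df in (("exposure", exp), ("outcome", out)):
        dups = df["snp_id"][df["snp_id"].duplicated()]
        if len(dups):
            raise ValueError(f"duplicate snp_id in {name} file: {sorted(set(dups))}")
    if exp.empty or out.empty:
        raise ValueError("exposure and outcome summary statistics must be non-empty")
    out_by_id = out.set_index("snp_id")

    lo, hi = eaf_window
    rows = []
    for rec in exp.itertuples(index=False):
        row = {
            "snp_id": rec.snp_id,
            "beta_GX": rec.beta,
            "se_GX": rec.se,
            "beta_GY": np.nan,
            "se_GY": np.nan,
            "action": "dropped_missing",
        }
        if rec.snp_id in out_by_id.index:
            o = out_by_id.loc[rec.snp_id]
            ea, oa = rec.effect_allele, rec.other_allele
            oea, ooa = o["effect_allele"], o["other_allele"]
            if _is_palindromic(ea, oa):
                if {oea, ooa} != {ea, oa}:
                    pass  # incompatible alleles -> dropped_missing
                elif palindrome_policy == "drop":
                    row["action"] = "dropped_palindromic"
                else:
                    eaf_x, eaf_y = rec.eaf, o["eaf"]
                    usable = (
                        pd.notna(eaf_x)
                        and pd.notna(eaf_y)
                        and not lo <= eaf_x <= hi
                        and not lo <= eaf_y <= hi
                    )
                    if not usable:
                        row["action"] = "dropped_palindromic"
                    else:
                        # For a palindromic SNP the label cannot identify the
                        # strand; the frequency alone does. The outcome's
                        # labelled effect allele is the exposure's effect
                        # allele exactly when both frequencies fall on the
                        # same side of 0.5.
                        flip = (eaf_x < 0.5) != (eaf_y < 0.5)
                        row["action"] = "flipped" if flip else "kept"
                        row["beta_GY"] = -o["beta"] if flip else o["beta"]
                        row["se_GY"] = o["se"]
            else:
                comp = (_COMPLEMENT[oea], _COMPLEMENT[ooa])
                if (oea, ooa) == (ea, oa) or comp == (ea, oa):
                    row.update(action="kept", beta_GY=o["beta"], se_GY=o["se"])
                elif (oea, ooa) == (oa, ea) or comp == (oa, ea):
                    row.update(action="flipped", beta_GY=-o["beta"], se_GY=o["se"])
                # else: allele mismatch -> dropped_missing
        rows.append(row)
    return pd.DataFrame(rows)


def two_sample_mr(pairs: pd.DataFrame, scale: str = "identity"):
    """Per-SNP Wald ratios and a pooled IVW estimate from harmonized pairs.

    Only rows with action ``kept`` or ``flipped`` enter the estimates; the
    pooled estimate records how many SNPs were actually used.

    Returns ``(per_snp DataFrame, pooled MREstimate)``.
    """
    used = pairs[pairs["action"].isin(("kept", "flipped"))]
    if used.empty:
        raise ValueError("no overlapping instruments after harmonization")
    per_snp = []
    for rec in used.itertuples(index=False):
        est = wald_ratio(rec.beta_GY, rec.se_GY, rec.beta_GX, rec.se_GX, scale=scale)
        per_snp.append(
            {"snp_id": rec.snp_id, "beta": est.beta, "se": est.se, "p": est.pvalue}
        )
    pooled = ivw(
        used["beta_GX"].to_numpy(),
        used["se_GX"].to_numpy(),
        used["beta_GY"].to_numpy(),
        used["se_GY"].to_numpy(),
        scale=scale,
    )
    return pd.DataFrame(per_snp), pooled


def split_sample_sumstats(cohort, geno, outcome_col: str, family: str = "linear", seed=0):
    """Build non-overlapping exposure and outcome summary statistics.

    Randomly halves a simulated cohort: per-SNP exposure associations come
    from one half and per-SNP outcome associations from the other, emulating
    the two-sample setting where exposure and outcome GWAS share no samples.
    """
    from .instruments import snp_exposure_associations, snp_outcome_associations
    from .simulate import GenotypeMatrix

    n = len(cohort)
    rng = np.random.default_rng(seed)
    half_a = np.zeros(n, dtype=bool)
    half_a[rng.permutation(n)[: n // 2]] = True

    def subset(mask):
        return GenotypeMatrix(
            allele_counts=geno.allele_counts[mask],
            snp_ids=list(geno.snp_ids),
            effect_allele=list(geno.effect_allele),
            other_allele=list(geno.other_allele),
            eaf=geno.eaf,
            dominant=geno.dominant,
        )

    exp = snp_exposure_associations(
        subset(half_a), cohort.loc[half_a, "drinks_day"].to_numpy(), trait="alcohol"
    )
    out = snp_outcome_associations(
        subset(~half_a), cohort.loc[~half_a, outcome_col].to_numpy(), family=family,
        trait=outcome_col,
    )
    return SumStats(exp, trait="alcohol"), SumStats(out, trait=outcome_col)
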