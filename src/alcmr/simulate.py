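"""Synthetic individual-level cohorts with a known causal structure.

The generator draws genotypes under Hardy-Weinberg equilibrium, builds an
alcohol-intake exposure with a non-drinker point mass, and produces mediator,
continuous and binary outcomes through explicit structural equations with a
shared latent confounder. Because every causal path (instrument strength,
confounding, mediation, pleiotropy) is a scenario parameter, the cohorts act
as ground truth for validating instrumental-variable estimators end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ScenarioConfig
from .exposure import WEEKS_PER_YEAR, ConversionTable

__all__ = [
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_outcomes",
    "simulate_cohort",
    "simulate_drink_records",
]

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass
class GenotypeMatrix:
    """Per-individual effect-allele counts at the instrument SNPs.

    ``allele_counts[i, j]`` counts copies (0/1/2) of SNP j's effect allele in
    individual i. The effect allele here is the minor allele whose frequency
    is the scenario MAF; analysis code may re-orient alleles afterwards.
    """

    allele_counts: np.ndarray
    snp_ids: list
    effect_allele: list
    other_allele: list
    eaf: np.ndarray
    dominant: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.allele_counts = np.asarray(self.allele_counts, dtype=np.int8)
        if self.allele_counts.ndim != 2:
            raise ValueError("allele_counts must be 2-D (individuals x SNPs)")
        bad = ~np.isin(self.allele_counts, (0, 1, 2))
        if bad.any():
            raise ValueError("allele counts must be in {0, 1, 2}")
        if self.dominant is None:
            self.dominant = np.zeros(self.n_snps, dtype=bool)
        self.dominant = np.asarray(self.dominant, dtype=bool)
        self.eaf = np.asarray(self.eaf, dtype=float)
        for sid, ea, oa in zip(self.snp_ids, self.effect_allele, self.other_allele):
            if ea == oa:
                raise ValueError(f"effect and other allele identical for {sid}")

    @property
    def n_individuals(self) -> int:
        return self.allele_counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.allele_counts.shape[1]

    def coded(self) -> np.ndarray:
        """Analysis coding: carrier indicator for dominant SNPs, else count."""
        out = self.allele_counts.astype(float)
        if self.dominant.any():
            out[:, self.dominant] = (out[:, self.dominant] > 0).astype(float)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.allele_counts, columns=list(self.snp_ids))


def simulate_genotypes(
    maf,
    n: int,
    seed,
    snp_ids=None,
    dominant=None,
) -> GenotypeMatrix:
    """Draw unlinked genotypes under Hardy-Weinberg equilibrium.

    Each SNP's effect-allele count is Binomial(2, maf), independent across
    SNPs and individuals; reproducible for a fixed seed.
    """
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    if n < 1:
        raise ValueError("n must be >= 1")
    if snp_ids is None:
        snp_ids = [f"snp_{j + 1}" for j in range(maf.size)]
    for sid, q in zip(snp_ids, maf):
        if not np.isfinite(q) or not (0.0 < q <= 0.5):
            raise ValueError(f"MAF for {sid} must be finite and in (0, 0.5], got {q!r}")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(2, maf, size=(int(n), maf.size)).astype(np.int8)
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(maf.size)]
    return GenotypeMatrix(
        allele_counts=counts,
        snp_ids=list(snp_ids),
        effect_allele=[p[0] for p in pairs],
        other_allele=[p[1] for p in pairs],
        eaf=maf.copy(),
        dominant=dominant,
    )


def simulate_exposure(geno: GenotypeMatrix, config: ScenarioConfig, seed) -> pd.DataFrame:
    """Simulate covariates, the latent confounder and alcohol intake.

    Latent intake is linear in coded genotype, sex, current smoking and the
    confounder, with normal noise; observed intake is the latent value
    truncated at zero and forced to zero for never/former drinkers, giving
    the zero-inflated, right-truncated mixture seen in questionnaire data.
    """
    if geno.n_snps != config.n_snps:
        raise ValueError(
            f"genotype matrix has {geno.n_snps} SNPs but config specifies "
            f"{config.n_snps} gamma entries"
        )
    n = geno.n_individuals
    rng = np.random.default_rng(seed)

    male = rng.random(n) < config.p_male
    age = rng.normal(config.age_mean, config.age_sd, n)
    smoking = rng.choice(
        np.array(["never", "former", "current"]), size=n, p=list(config.p_smoking)
    )
    ses = rng.normal(0.0, 1.0, n)  # Townsend-like, standardised
    u = rng.normal(0.0, 1.0, n)

    coded = geno.coded()
    latent = (
        config.exposure_intercept
        + config.sex_effect_exposure * male
        + config.smoking_effect_exposure * (smoking == "current")
        + coded @ np.asarray(config.gamma)
        + config.kappa_exposure * u
        + rng.normal(0.0, config.sigma_exposure, n)
    )
    exposure = np.maximum(latent, 0.0)

    status_draw = rng.random(n)
    status = np.where(
        status_draw < config.p_never,
        "never",
        np.where(status_draw < config.p_never + config.p_former, "former", "current"),
    )
    exposure[status != "current"] = 0.0

    return pd.DataFrame(
        {
            "exposure_glasses_week": exposure,
            "drinks_day": exposure / 7.0,
            "drinker_status": status,
            "sex": male.astype(int),
            "age": age,
            "smoking": smoking,
            "ses": ses,
            "confounder_u": u,
        }
    )


def simulate_outcomes(
    cohort: pd.DataFrame, geno: GenotypeMatrix, config: ScenarioConfig, seed
) -> pd.DataFrame:
    """Add mediator, continuous and binary outcome columns to a cohort.

    All exposure effects are per drink/day. The binary outcome uses a logit
    link whose intercept is solved (by centring the linear predictor) so the
    marginal prevalence matches ``baseline_prevalence``; with all effect
    paths zero this reduces to an intercept-only Bernoulli draw.
    """
    if "drinks_day" not in cohort.columns:
        raise ValueError("cohort lacks exposure columns; run simulate_exposure first")
    if not 0.0 < config.baseline_prevalence < 1.0:
        raise ValueError("baseline_prevalence must be in (0, 1)")
    n = len(cohort)
    rng = np.random.default_rng(seed)
    coded = geno.coded()
    dd = cohort["drinks_day"].to_numpy()
    u = cohort["confounder_u"].to_numpy()
    male = cohort["sex"].to_numpy()

    mediator = (
        config.mediator_intercept
        + config.a_exposure_mediator * dd
        + coded @ np.asarray(config.gamma_mediator)
        + rng.normal(0.0, config.sigma_mediator, n)
    )
    med_c = mediator - config.mediator_intercept

    y_cont = (
        config.outcome_intercept_continuous
        + config.theta_continuous * dd
        + config.theta_continuous_sex_interaction * dd * male
        + config.b_mediator_continuous * med_c
        + config.kappa_outcome_continuous * u
        + coded @ np.asarray(config.pleiotropy_continuous)
        + config.age_effect_continuous * (cohort["age"].to_numpy() - config.age_mean)
        + config.sex_effect_continuous * male
        + rng.normal(0.0, config.sigma_outcome, n)
    )

    eta = (
        config.theta_binary * dd
        + config.b_mediator_binary * med_c
        + config.kappa_outcome_binary * u
        + coded @ np.asarray(config.pleiotropy_binary)
        + config.sex_effect_binary * male
    )
    eta = eta - eta.mean() + logit(config.baseline_prevalence)
    y_bin = (rng.random(n) < expit(eta)).astype(int)

    out = cohort.copy()
    out[config.mediator_label] = mediator
    out[config.continuous_label] = y_cont
    out[config.binary_label] = y_bin
    return out


def simulate_cohort(config: ScenarioConfig, seed=None):
    """Generate a full cohort: genotypes, exposure, outcomes.

    One seed drives three independent substreams (genotypes, exposure,
    outcomes), so the draw is bit-reproducible for a given config and seed.
    Returns ``(cohort DataFrame, GenotypeMatrix)``.
    """
    if seed is None:
        seed = config.seed
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_geno, ss_expo, ss_out = root.spawn(3)
    geno = simulate_genotypes(
        config.maf,
        config.n_individuals,
        ss_geno,
        snp_ids=config.snp_ids,
        dominant=config.dominant,
    )
    cohort = simulate_exposure(geno, config, ss_expo)
    cohort = simulate_outcomes(cohort, geno, config, ss_out)
    return cohort, geno


def simulate_drink_records(
    target_grams_year,
    table: ConversionTable | None = None,
    seed=0,
):
    """Invert annual gram targets into integer weekly drink counts.

    For each individual a random subset of beverage types receives integer
    weekly counts whose implied grams/year approximate the target; exact
    inversion is impossible in general with integer counts, so the achieved
    value and a ``nearest_only`` flag are returned alongside the counts.

    Returns ``(counts DataFrame, achieved grams/year array, nearest_only
    boolean array)``.
    """
    if table is None:
        table = ConversionTable()
    targets = np.atleast_1d(np.asarray(target_grams_year, dtype=float))
    if (targets < 0).any() or not np.isfinite(targets).all():
        raise ValueError("targets must be finite and >= 0")
    bevs = list(table.grams_per_serving)
    if not bevs:
        raise ValueError("conversion table is empty")
    grams = np.array([table.grams_per_serving[b] for b in bevs])
    rng = np.random.default_rng(seed)

    counts = np.zeros((targets.size, len(bevs)), dtype=int)
    nearest = np.zeros(targets.size, dtype=bool)
    for i, t in enumerate(targets):
        weekly_target = t / WEEKS_PER_YEAR
        order = rng.permutation(len(bevs))
        remaining = weekly_target
        for rank, j in enumerate(order):
            if rank < len(order) - 1:
                c = int(remaining // grams[j]) if grams[j] <= remaining else 0
                # spread across types: keep at most half the remainder here
                c = int(rng.integers(0, c + 1)) if c > 0 else 0
            else:
                c = int(round(remaining / grams[j]))
            counts[i, j] = c
            remaining -= c * grams[j]
        if abs(remaining) > 1e-9:
            nearest[i] = True
    achieved = counts @ grams * WEEKS_PER_YEAR
    return pd.DataFrame(counts, columns=bevs), achieved, nearest
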