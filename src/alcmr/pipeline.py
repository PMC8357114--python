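"""Config-driven orchestration of the full analysis.

A run config names a scenario and an ordered list of analysis stages; the
pipeline simulates the cohort, executes each stage, and collects results in
a :class:`RunReport` with provenance (config hash, seed, package version,
timestamp) sufficient to reproduce the run. One global seed feeds
deterministic per-stage substreams, so adding a stage never perturbs the
draws of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import classify_dose_response, observational_assoc, stratified_mr
from .config import ScenarioConfig, default_scenario
from .estimators import ivw, mvmr, tsls_continuous, two_stage_binary
from .instruments import (
    DEFAULT_COVARIATES,
    _covariate_matrix,
    first_stage,
    snp_exposure_associations,
    snp_outcome_associations,
)
from .simulate import simulate_cohort
from .twosample import harmonize, split_sample_sumstats, two_sample_mr

__all__ = [
    "KNOWN_STAGES",
    "RunConfig",
    "RunReport",
    "validate_config",
    "run_pipeline",
    "write_report",
    "format_estimate",
]

KNOWN_STAGES = (
    "first_stage",
    "tsls",
    "two_stage_binary",
    "ivw",
    "mvmr",
    "two_sample",
    "stratified",
    "observational",
)

DEFAULT_STAGES = ("first_stage", "tsls", "two_stage_binary", "ivw", "mvmr",
                  "two_sample", "stratified", "observational")


@dataclass
class RunConfig:
    scenario: ScenarioConfig
    analyses: tuple = DEFAULT_STAGES
    output_dir: str = "alcmr_run"
    seed: int = 0
    options: dict = field(default_factory=dict)  # per-stage option dicts

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "scenario": self.scenario.to_dict(),
                "analyses": list(self.analyses),
                "output_dir": self.output_dir,
                "seed": self.seed,
                "options": self.options,
            },
            sort_keys=True,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    tables: dict
    provenance: dict
    warnings: list = field(default_factory=list)
    failed: dict = field(default_factory=dict)  # stage -> error message

    @property
    def success(self) -> bool:
        return not self.failed


def validate_config(path) -> RunConfig:
    """Parse and validate a run config, aggregating every violation.

    Raises ``ValueError`` listing all problems found, not just the first.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors = []
    known_keys = {"scenario", "scenario_file", "analyses", "output_dir", "seed", "options"}
    for k in set(raw) - known_keys:
        errors.append(f"unknown config key: {k!r}")

    scenario = None
    if "scenario_file" in raw:
        sf = Path(raw["scenario_file"])
        if not sf.exists():
            errors.append(f"scenario_file does not exist: {sf}")
        else:
            try:
                scenario = ScenarioConfig.from_yaml(sf)
            except Exception as exc:
                errors.append(f"invalid scenario_file: {exc}")
    elif isinstance(raw.get("scenario"), dict):
        try:
            scenario = ScenarioConfig.from_dict(raw["scenario"])
        except Exception as exc:
            errors.append(f"invalid scenario: {exc}")
    else:
        scenario = default_scenario()

    analyses = raw.get("analyses", list(DEFAULT_STAGES))
    if not isinstance(analyses, (list, tuple)):
        errors.append("analyses must be a list of stage names")
        analyses = []
    for stage in analyses:
        if stage not in KNOWN_STAGES:
            errors.append(f"unknown analysis stage: {stage!r} (known: {KNOWN_STAGES})")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")

    options = raw.get("options", {}) or {}
    if not isinstance(options, dict):
        errors.append("options must be a mapping of stage name to option dict")
        options = {}
    else:
        for stage, opts in options.items():
            if stage not in KNOWN_STAGES:
                errors.append(f"options given for unknown stage: {stage!r}")
            estimator = (opts or {}).get("estimator")
            if estimator is not None and estimator not in ("tsls", "two_stage_binary"):
                errors.append(f"unknown estimator name for {stage}: {estimator!r}")

    if errors:
        raise ValueError("invalid run config:\n  - " + "\n  - ".join(errors))
    return RunConfig(
        scenario=scenario,
        analyses=tuple(analyses),
        output_dir=raw.get("output_dir", "alcmr_run"),
        seed=seed,
        options=options,
    )


def _est_row(est, outcome: str, stratum: str = "all", method: Optional[str] = None) -> dict:
    d = est.to_dict()
    d["method"] = method or d["method"]
    d["outcome"] = outcome
    d["stratum"] = stratum
    return d


def run_pipeline(config: RunConfig) -> RunReport:
    """Simulate the scenario cohort and execute the configured stages.

    Identical config and seed produce identical report tables. A stage that
    raises is marked failed; remaining stages still run (they share only the
    simulated cohort), and the report's ``success`` flag turns false.
    """
    sc = config.scenario
    seeds = np.random.SeedSequence(config.seed).spawn(len(KNOWN_STAGES) + 1)
    stage_seed = dict(zip(("simulate",) + KNOWN_STAGES, seeds))

    t0 = time.time()
    cohort, geno = simulate_cohort(sc, stage_seed["simulate"])
    coded = geno.coded()
    single_iv = coded[:, :1]  # first SNP: the large-effect variant
    covs = _covariate_matrix(cohort, DEFAULT_COVARIATES)
    dd = cohort["drinks_day"].to_numpy()

    tables: dict = {}
    warnings: list = []
    failed: dict = {}

    def run_stage(name, fn):
        if name not in config.analyses:
            return
        try:
            tables[name] = fn()
        except Exception as exc:
            failed[name] = f"{type(exc).__name__}: {exc}"

    def _first_stage():
        rows = []
        for label, inst in (("single_snp", single_iv), ("allele_score", coded.sum(axis=1))):
            fs = first_stage(dd, inst, covs, DEFAULT_COVARIATES)
            rows.append(
                {
                    "instrument": label,
                    "beta_GX": fs.beta_GX,
                    "se_GX": fs.se_GX,
                    "r_squared": fs.r_squared,
                    "f_statistic": fs.f_statistic,
                    "n": fs.n,
                }
            )
        return pd.DataFrame(rows)

    def _tsls():
        est = tsls_continuous(cohort[sc.continuous_label].to_numpy(), dd, single_iv, covs)
        warnings.extend(est.warnings)
        return pd.DataFrame([_est_row(est, sc.continuous_label)])

    def _binary():
        est = two_stage_binary(cohort[sc.binary_label].to_numpy(), dd, single_iv, covs)
        warnings.extend(est.warnings)
        return pd.DataFrame([_est_row(est, sc.binary_label)])

    def _ivw():
        exp = snp_exposure_associations(geno, dd)
        rows = []
        for outcome, family, scale in (
            (sc.continuous_label, "linear", "identity"),
            (sc.binary_label, "logistic", "log_or"),
        ):
            out = snp_outcome_associations(geno, cohort[outcome].to_numpy(), family)
            est = ivw(exp["beta"], exp["se"], out["beta"], out["se"], scale=scale)
            rows.append(_est_row(est, outcome))
        return pd.DataFrame(rows)

    def _mvmr():
        exp_alc = snp_exposure_associations(geno, dd)
        exp_med = snp_outcome_associations(
            geno, cohort[sc.mediator_label].to_numpy(), "linear"
        )
        out = snp_outcome_associations(geno, cohort[sc.binary_label].to_numpy(), "logistic")
        res = mvmr(
            np.column_stack([exp_alc["beta"], exp_med["beta"]]),
            out["beta"].to_numpy(),
            out["se"].to_numpy(),
            exposure_labels=("alcohol", sc.mediator_label),
        )
        return pd.DataFrame(
            {
                "exposure": res.exposures,
                "beta": res.betas,
                "se": res.ses,
                "p": res.pvalues,
                "outcome": sc.binary_label,
                "n_snps": res.n_snps,
            }
        )

    def _two_sample():
        opts = config.options.get("two_sample", {})
        exp, out = split_sample_sumstats(
            cohort, geno, sc.continuous_label, "linear",
            seed=stage_seed["two_sample"],
        )
        pairs = harmonize(exp, out, opts.get("palindrome_policy", "frequency"))
        per_snp, pooled = two_sample_mr(pairs)
        n_dropped = int((~pairs["action"].isin(("kept", "flipped"))).sum())
        if n_dropped:
            warnings.append(f"two_sample: {n_dropped} SNPs dropped in harmonization")
        return pd.DataFrame([_est_row(pooled, sc.continuous_label, method="ivw_two_sample")])

    def _stratified():
        rows = []
        for stratum in ("sex", "smoking"):
            comp = stratified_mr(
                cohort, geno, stratum, tsls_continuous, sc.continuous_label,
                instrument_columns=single_iv,
            )
            warnings.extend(comp.excluded)
            for lev, est in comp.estimates.items():
                row = _est_row(est, sc.continuous_label, stratum=f"{stratum}={lev}")
                row["q_strata"] = comp.q_statistic
                row["p_heterogeneity"] = comp.p_heterogeneity
                rows.append(row)
        return pd.DataFrame(rows)

    def _observational():
        rows = []
        for outcome, family in (
            (sc.continuous_label, "linear"),
            (sc.binary_label, "logistic"),
        ):
            for adjustment in ("minimal",):
                eff = observational_assoc(cohort, outcome, family, adjustment)
                shape = classify_dose_response(eff)
                t = eff.table.copy()
                t.insert(0, "outcome", outcome)
                t["family"] = family
                t["adjustment"] = adjustment
                t["dose_response"] = shape
                rows.append(t)
        return pd.concat(rows, ignore_index=True)

    run_stage("first_stage", _first_stage)
    run_stage("tsls", _tsls)
    run_stage("two_stage_binary", _binary)
    run_stage("ivw", _ivw)
    run_stage("mvmr", _mvmr)
    run_stage("two_sample", _two_sample)
    run_stage("stratified", _stratified)
    run_stage("observational", _observational)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "n_individuals": sc.n_individuals,
        "n_snps": sc.n_snps,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_s": round(time.time() - t0, 3),
    }
    return RunReport(tables=tables, provenance=provenance, warnings=warnings, failed=failed)


def format_estimate(beta: float, ci_low: float, ci_high: float, digits: int = 2) -> str:
    """Render an estimate as ``beta [low, high]``, e.g. ``2.65 [1.40, 3.89]``."""
    return f"{beta:.{digits}f} [{ci_low:.{digits}f}, {ci_high:.{digits}f}]"


def write_report(report: RunReport, out_dir, formats=("tsv", "json")) -> list:
    """Write stage tables, a JSON report and a human-readable summary.

    Fails before any partial write if the directory cannot be created.
    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc

    written = []
    if "tsv" in formats:
        for stage, table in report.tables.items():
            p = out / f"{stage}.tsv"
            table.to_csv(p, sep="\t", index=False)
            written.append(p)
    if "json" in formats:
        payload = {
            "provenance": report.provenance,
            "warnings": report.warnings,
            "failed": report.failed,
            "tables": {
                stage: json.loads(t.to_json(orient="records"))
                for stage, t in report.tables.items()
            },
        }
        p = out / "report.json"
        p.write_text(json.dumps(payload, indent=2, default=str))
        written.append(p)

    lines = [f"alcmr run {report.provenance['config_hash']} "
             f"(seed={report.provenance['seed']}, n={report.provenance['n_individuals']})"]
    for stage, table in report.tables.items():
        if {"beta", "ci_low", "ci_high", "outcome"} <= set(table.columns):
            for _, r in table.iterrows():
                label = f"{r['outcome']} {r.get('method', stage)}"
                if r.get("stratum", "all") != "all":
                    label += f" [{r['stratum']}]"
                if r.get("or") and not pd.isna(r.get("or")):
                    txt = format_estimate(
                        np.exp(r["beta"]), np.exp(r["ci_low"]), np.exp(r["ci_high"])
                    ) + " (OR)"
                else:
                    txt = format_estimate(r["beta"], r["ci_low"], r["ci_high"])
                lines.append(f"{label}: {txt}")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    for stage, msg in report.failed.items():
        lines.append(f"FAILED {stage}: {msg}")
    p = out / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
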