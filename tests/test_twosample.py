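"""Summary-statistic IO, allele harmonization, two-sample MR."""

import numpy as np
import pandas as pd
import pytest

from alcmr.config import default_scenario
from alcmr.simulate import simulate_cohort
from alcmr.twosample import (
    SUMSTATS_COLUMNS,
    harmonize,
    read_sumstats,
    split_sample_sumstats,
    two_sample_mr,
    write_sumstats,
)


def _stats(rows):
    return pd.DataFrame(rows, columns=list(SUMSTATS_COLUMNS))


@pytest.fixture
def exposure_stats():
    return _stats(
        [
            ("rs1", "A", "G", 0.20, 0.30, 0.05, 1000),
            ("rs2", "C", "T", 0.40, 0.25, 0.04, 1000),
            ("rs3", "A", "T", 0.10, 0.20, 0.05, 1000),  # palindromic
        ]
    )


class TestReadSumstats:
    def _write(self, tmp_path, text, name="ss.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_well_formed(self, tmp_path):
        p = self._write(
            tmp_path,
            "snp_id\teffect_allele\tother_allele\teaf\tbeta\tse\tn\n"
            "rs1\ta\tg\t0.2\t0.3\t0.05\t1000\n"
            "rs2\tC\tT\t0.4\t-0.1\t0.04\t1000\n"
            "rs3\tG\tA\t0.3\t0.0\t0.02\t1000\n",
        )
        ss = read_sumstats(p, trait="alcohol")
        assert len(ss) == 3
        assert ss.n_rejected == 0
        assert ss.table.loc[0, "effect_allele"] == "A"  # case normalised

    def test_zero_se_row_rejected_with_line(self, tmp_path):
        p = self._write(
            tmp_path,
            "snp_id\teffect_allele\tother_allele\teaf\tbeta\tse\tn\n"
            "rs1\tA\tG\t0.2\t0.3\t0.05\t1000\n"
            "rs2\tC\tT\t0.4\t0.1\t0\t1000\n",
        )
        ss = read_sumstats(p)
        assert len(ss) == 1
        assert ss.n_rejected == 1
        assert ss.rejected.loc[0, "line"] == 3
        assert "se" in ss.rejected.loc[0, "reason"]

    def test_dialect_mapping_round_trip(self, tmp_path):
        canonical = self._write(
            tmp_path,
            "snp_id\teffect_allele\tother_allele\teaf\tbeta\tse\tn\n"
            "rs1\tA\tG\t0.2\t0.3\t0.05\t1000\n",
        )
        shuffled = self._write(
            tmp_path,
            "STDERR\tEffect\tFREQ\tN\tSNP\tEA\tOA\n"
            "0.05\t0.3\t0.2\t1000\trs1\tA\tG\n",
            name="shuffled.tsv",
        )
        dialect = {
            "snp_id": "SNP",
            "effect_allele": "EA",
            "other_allele": "OA",
            "eaf": "FREQ",
            "beta": "Effect",
            "se": "STDERR",
            "n": "N",
        }
        a = read_sumstats(canonical).table
        b = read_sumstats(shuffled, dialect=dialect).table
        pd.testing.assert_frame_equal(a, b)

    def test_missing_mandatory_column_named(self, tmp_path):
        p = self._write(tmp_path, "snp_id\tbeta\tse\nrs1\t0.3\t0.05\n")
        with pytest.raises(ValueError, match="effect_allele"):
            read_sumstats(p)

    def test_write_read_round_trip(self, tmp_path, exposure_stats):
        p = tmp_path / "out.tsv"
        write_sumstats(exposure_stats, p)
        back = read_sumstats(p).table
        np.testing.assert_allclose(back["beta"], exposure_stats["beta"])


class TestHarmonize:
    def test_identical_orientation_all_kept(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome["beta"] = [0.1, 0.2, 0.05]
        pairs = harmonize(exposure_stats, outcome)
        assert (pairs["action"] == "kept").all()
        np.testing.assert_allclose(pairs["beta_GY"], outcome["beta"])

    def test_swapped_alleles_flipped(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome["beta"] = [0.1, 0.2, 0.05]
        outcome.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        outcome.loc[0, "eaf"] = 0.80
        pairs = harmonize(exposure_stats, outcome)
        assert pairs.loc[0, "action"] == "flipped"
        assert pairs.loc[0, "beta_GY"] == pytest.approx(-0.1)
        assert pairs.loc[1, "action"] == "kept"

    def test_strand_complement_recognised(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome["beta"] = [0.1, 0.2, 0.05]
        # rs1 reported on the other strand: A/G -> T/C
        outcome.loc[0, ["effect_allele", "other_allele"]] = ["T", "C"]
        pairs = harmonize(exposure_stats, outcome)
        assert pairs.loc[0, "action"] == "kept"
        assert pairs.loc[0, "beta_GY"] == pytest.approx(0.1)

    def test_palindromic_ambiguous_eaf_dropped(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome.loc[2, "eaf"] = 0.50  # inside the ambiguity window
        pairs = harmonize(exposure_stats, outcome)
        assert pairs.loc[2, "action"] == "dropped_palindromic"

    def test_palindromic_resolved_by_frequency(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome["beta"] = [0.1, 0.2, 0.05]
        outcome.loc[2, "eaf"] = 0.12  # same minor side, same label -> kept
        pairs = harmonize(exposure_stats, outcome)
        assert pairs.loc[2, "action"] == "kept"
        # opposite side: physically the other allele -> flipped
        outcome.loc[2, "eaf"] = 0.88
        pairs = harmonize(exposure_stats, outcome)
        assert pairs.loc[2, "action"] == "flipped"
        assert pairs.loc[2, "beta_GY"] == pytest.approx(-0.05)

    def test_drop_policy_always_drops_palindromic(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome.loc[2, "eaf"] = 0.12
        pairs = harmonize(exposure_stats, outcome, palindrome_policy="drop")
        assert pairs.loc[2, "action"] == "dropped_palindromic"

    def test_missing_snp_dropped(self, exposure_stats):
        outcome = exposure_stats.iloc[:2].copy()
        pairs = harmonize(exposure_stats, outcome)
        assert pairs.loc[2, "action"] == "dropped_missing"

    def test_allele_mismatch_dropped(self, exposure_stats):
        outcome = exposure_stats.copy()
        # A/C cannot be reconciled with C/T on either strand
        outcome.loc[1, ["effect_allele", "other_allele"]] = ["A", "C"]
        pairs = harmonize(exposure_stats, outcome)
        assert pairs.loc[1, "action"] == "dropped_missing"

    def test_complement_swap_is_flip(self, exposure_stats):
        # A/G read on the other strand with swapped order (C/T vs exposure's
        # C/T... here rs2 C/T vs outcome A/G) resolves to a sign flip
        outcome = exposure_stats.copy()
        outcome["beta"] = [0.1, 0.2, 0.05]
        outcome.loc[1, ["effect_allele", "other_allele"]] = ["A", "G"]
        pairs = harmonize(exposure_stats, outcome)
        assert pairs.loc[1, "action"] == "flipped"
        assert pairs.loc[1, "beta_GY"] == pytest.approx(-0.2)

    def test_duplicate_snp_rejected(self, exposure_stats):
        dup = pd.concat([exposure_stats, exposure_stats.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(exposure_stats, dup)

    def test_actions_partition_input(self, exposure_stats):
        rng = np.random.default_rng(11)
        outcome = exposure_stats.copy()
        outcome = outcome.sample(frac=0.7, random_state=3)  # drop some SNPs
        pairs = harmonize(exposure_stats, outcome)
        assert len(pairs) == len(exposure_stats)
        assert pairs["snp_id"].is_unique
        assert pairs["action"].isin(
            ("kept", "flipped", "dropped_palindromic", "dropped_missing")
        ).all()

    def test_idempotent_on_aligned_data(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome["beta"] = [0.1, 0.2, 0.05]
        outcome.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        outcome.loc[0, "eaf"] = 0.80
        first = harmonize(exposure_stats, outcome)
        # re-express the outcome in the harmonized orientation and repeat
        aligned = exposure_stats.copy()
        aligned["beta"] = first["beta_GY"]
        aligned["se"] = first["se_GY"]
        second = harmonize(exposure_stats, aligned)
        assert (second["action"] == "kept").all()
        np.testing.assert_allclose(second["beta_GY"], first["beta_GY"])


class TestTwoSampleMR:
    def test_single_pair_equals_wald(self, exposure_stats):
        outcome = exposure_stats.iloc[:1].copy()
        outcome["beta"] = [0.15]
        pairs = harmonize(exposure_stats.iloc[:1], outcome)
        per_snp, pooled = two_sample_mr(pairs)
        assert pooled.beta == pytest.approx(0.15 / 0.30)
        assert pooled.n_snps == 1

    def test_zero_outcome_betas(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome["beta"] = 0.0
        outcome["se"] = 0.05
        pairs = harmonize(exposure_stats, outcome)
        _, pooled = two_sample_mr(pairs)
        assert pooled.beta == pytest.approx(0.0)
        assert pooled.q_statistic == pytest.approx(0.0)

    def test_no_overlap_is_error(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome["snp_id"] = ["zz1", "zz2", "zz3"]
        pairs = harmonize(exposure_stats, outcome)
        with pytest.raises(ValueError, match="no overlapping"):
            two_sample_mr(pairs)

    def test_full_outcome_flip_leaves_ivw_unchanged(self, exposure_stats):
        outcome = exposure_stats.copy()
        outcome["beta"] = [0.12, 0.18, 0.06]
        _, pooled = two_sample_mr(harmonize(exposure_stats, outcome))
        flipped = outcome.copy()
        flipped["effect_allele"] = outcome["other_allele"]
        flipped["other_allele"] = outcome["effect_allele"]
        flipped["beta"] = -outcome["beta"]
        flipped["eaf"] = 1 - outcome["eaf"]
        _, pooled_f = two_sample_mr(harmonize(exposure_stats, flipped))
        assert pooled_f.beta == pytest.approx(pooled.beta, abs=1e-12)
        assert pooled_f.se == pytest.approx(pooled.se, abs=1e-12)

    def test_split_sample_recovery(self):
        """Exposure betas from one half-cohort, outcome betas from the other:
        pooled IVW recovers the simulated causal effect. Uses the
        strong-instrument scenario so per-SNP weak-instrument attenuation is
        negligible at half-cohort size."""
        from dataclasses import replace

        from alcmr.config import mediation_scenario

        theta = 0.4
        sc = replace(
            mediation_scenario(n_individuals=30_000), theta_continuous=theta
        )
        betas = []
        for i, s in enumerate(np.random.SeedSequence(21).spawn(10)):
            cohort, geno = simulate_cohort(sc, s)
            exp, out = split_sample_sumstats(cohort, geno, "sbp", "linear", seed=i)
            pairs = harmonize(exp, out)
            _, pooled = two_sample_mr(pairs)
            assert pooled.n_snps == sc.n_snps
            betas.append(pooled.beta)
        betas = np.array(betas)
        rep_se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - theta) < 3 * rep_se
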