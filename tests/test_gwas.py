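import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from specphos.gwas import (
    GwasError, bonferroni_log_threshold, call_significant, group_loci,
    group_loci_oracle, ld_candidate_window, loci_table, maf_filter,
    manhattan_data, naive_assoc, qq_data, read_assoc, validate_assoc,
)
from specphos.simulate import SyntheticGwasConfig, generate_gwas


def _assoc(rows):
    return pd.DataFrame(rows, columns=["chr", "rs", "ps", "af", "p_wald"])


class TestMafFilter:
    def test_boundary_kept_below_removed(self):
        df = _assoc([(1, "a", 100, 0.049, 0.5), (1, "b", 200, 0.05, 0.5),
                     (1, "c", 300, 0.30, 0.5)])
        out = maf_filter(df)
        assert list(out["rs"]) == ["b", "c"]

    def test_empty_input(self):
        assert len(maf_filter(_assoc([]))) == 0

    def test_idempotent(self):
        df = _assoc([(1, "a", 100, 0.04, 0.5), (1, "b", 200, 0.2, 0.5)])
        once = maf_filter(df)
        pd.testing.assert_frame_equal(once, maf_filter(once))


class TestBonferroni:
    def test_paper_scale_threshold(self):
        assert bonferroni_log_threshold(113114, 0.05) == pytest.approx(6.35, abs=0.005)

    @pytest.mark.parametrize("n,expected", [(1, 1.3010), (20, 2.6021)])
    def test_small_cases(self, n, expected):
        assert bonferroni_log_threshold(n) == pytest.approx(expected, abs=1e-4)

    def test_invalid_n(self):
        with pytest.raises(GwasError):
            bonferroni_log_threshold(0)


class TestCallSignificant:
    def test_boundary_is_significant(self):
        df = _assoc([(1, "a", 100, 0.2, 10**-6.35), (1, "b", 200, 0.2, 0.05)])
        out = call_significant(df, 6.35)
        assert list(out["rs"]) == ["a"]

    def test_invalid_p_rejected(self):
        df = _assoc([(1, "a", 100, 0.2, 0.0)])
        with pytest.raises(GwasError):
            call_significant(df, 6.35)

    def test_uniform_null_rarely_crosses(self):
        rng = np.random.default_rng(0)
        df = _assoc([(1, f"s{i}", i + 1, 0.2, p)
                     for i, p in enumerate(rng.uniform(size=10_000))])
        # expected survivors: 1e4 * 10^-6.35 ~ 0.004
        assert len(call_significant(df, 6.35)) == 0


class TestGroupLoci:
    def test_within_window_one_locus(self):
        df = _assoc([(1, "a", 1_000, 0.2, 1e-8), (1, "b", 200_000, 0.2, 1e-7)])
        loci = group_loci(df, trait="Pi")
        assert len(loci) == 1
        assert loci[0].lead_snp == "a"
        assert loci[0].name == "qPi1"

    def test_gap_beyond_window_splits(self):
        df = _assoc([(1, "a", 1_000, 0.2, 1e-8), (1, "b", 200_000, 0.2, 1e-7),
                     (1, "c", 600_000, 0.2, 1e-9)])
        loci = group_loci(df, trait="Pi")
        assert len(loci) == 2
        assert [l.name for l in loci] == ["qPi1-1", "qPi1-2"]
        assert loci[1].lead_snp == "c"

    def test_single_snp_is_its_own_lead(self):
        df = _assoc([(5, "x", 42, 0.1, 1e-7)])
        (locus,) = group_loci(df, trait="SR")
        assert locus.lead_snp == "x" and locus.name == "qSR5"
        assert locus.span == (42, 42)

    def test_lead_tie_breaks_to_lower_position(self):
        df = _assoc([(1, "b", 2_000, 0.2, 1e-8), (1, "a", 1_000, 0.2, 1e-8)])
        (locus,) = group_loci(df)
        assert locus.lead_snp == "a"

    @given(st.lists(
        st.tuples(st.integers(1, 3), st.integers(1, 2_000_000)),
        min_size=1, max_size=100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_transitive_closure_oracle(self, snps):
        rng = np.random.default_rng(0)
        df = _assoc([(c, f"s{i}", p, 0.2, float(rng.uniform(1e-12, 1e-7)))
                     for i, (c, p) in enumerate(snps)])
        df = df.drop_duplicates(subset=["chr", "ps"])
        loci = group_loci(df, window=300_000)
        got = sorted(tuple(sorted(l.snp_ids)) for l in loci)
        expected = sorted(tuple(sorted(g))
                          for g in group_loci_oracle(df, window=300_000))
        assert got == expected

    def test_loci_table_columns(self):
        df = _assoc([(1, "a", 1_000, 0.2, 1e-8)])
        table = loci_table(group_loci(df, trait="Pi"))
        assert table.iloc[0]["minus_log10_p"] == pytest.approx(8.0)
        assert table.iloc[0]["n_significant_snps"] == 1


class TestLdCandidateWindow:
    def setup_method(self):
        self.all_snps = _assoc([
            (1, "lead", 1_000_000, 0.2, 1e-8),
            (1, "near_strong", 1_050_000, 0.2, 0.5),
            (1, "near_exact_half", 1_060_000, 0.2, 0.5),
            (1, "too_far", 1_100_001, 0.2, 0.5),
            (1, "near_no_ld", 1_020_000, 0.2, 0.5),
        ])
        self.ld = pd.DataFrame({
            "snp_a": ["lead", "lead", "lead"],
            "snp_b": ["near_strong", "near_exact_half", "too_far"],
            "r2": [0.9, 0.50, 0.95],
        })
        self.lead = {"rs": "lead", "chr": 1, "ps": 1_000_000}

    def test_strict_r2_and_distance_boundaries(self):
        out = ld_candidate_window(self.lead, self.all_snps, self.ld)
        assert "near_strong" in out          # r2 = 0.9 at 50 kb
        assert "near_exact_half" not in out  # r2 == 0.50 excluded (strict >)
        assert "too_far" not in out          # 100,001 bp away
        assert "near_no_ld" not in out       # missing pair -> below threshold
        assert "lead" in out


class TestQqManhattan:
    def test_single_p_value(self):
        out = qq_data(np.array([0.5]))
        assert out["expected"].iloc[0] == pytest.approx(0.3010, abs=1e-4)
        assert out["observed"].iloc[0] == pytest.approx(0.3010, abs=1e-4)

    def test_length_preserved_and_sorted(self):
        p = np.random.default_rng(0).uniform(size=100)
        out = qq_data(p)
        assert len(out) == 100
        assert (np.diff(out["observed"]) <= 1e-12).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_uniform_draws_track_expectation(self, seed):
        p = np.random.default_rng(seed).uniform(size=10_000)
        out = qq_data(p)
        # exclude the extreme tail where order statistics are noisy
        body = out.iloc[100:]
        assert (body["observed"] - body["expected"]).abs().max() < 0.25

    def test_manhattan_offsets(self):
        df = _assoc([(1, "a", 500_000, 0.2, 0.5), (1, "b", 1_000_000, 0.2, 0.5),
                     (2, "c", 1, 0.2, 0.5)])
        out = manhattan_data(df, chrom_lengths={1: 1_000_000, 2: 1_000_000})
        assert out.loc[out["rs"] == "c", "cum_pos"].iloc[0] == 1_000_001
        assert list(out["rs"]) == ["a", "b", "c"]  # order preserved


class TestNaiveAssoc:
    def _fixture(self, seed=0, planted=()):
        cfg = SyntheticGwasConfig(n_snps=300, n_chromosomes=2,
                                  n_accessions=120,
                                  planted_loci=list(planted), seed=seed)
        return generate_gwas(cfg)

    def test_constant_trait_gives_p_one(self):
        snp_info, genotypes, _, _ = self._fixture()
        assoc = naive_assoc(genotypes, np.zeros(len(genotypes)), snp_info)
        assert (assoc["p_wald"] == 1.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_null_p_values_pass_ks(self, seed):
        snp_info, genotypes, trait, _ = self._fixture(seed=seed)
        assoc = naive_assoc(genotypes, trait, snp_info)
        # thin to one SNP per LD block to approximate independence
        p = assoc["p_wald"].to_numpy()[::10]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_effect_is_top_hit(self):
        snp_info, genotypes, trait, _ = self._fixture(
            seed=1, planted=[(1, 10_000_000, 2.0)])
        assoc = naive_assoc(genotypes, trait, snp_info)
        planted = snp_info.attrs["planted_snps"][0]
        top = assoc.loc[assoc["p_wald"].idxmin()]
        planted_ps = assoc.loc[assoc["rs"] == planted, "ps"].iloc[0]
        assert abs(top["ps"] - planted_ps) <= 300_000 and top["chr"] == 1


class TestEndToEndRecovery:
    def test_planted_loci_called_and_no_spurious_chromosomes(self):
        cfg = SyntheticGwasConfig(
            n_snps=2_000, n_chromosomes=5, n_accessions=172,
            planted_loci=[(1, 10_000_000, 1.2), (3, 20_000_000, 1.2)],
            maf_range=(0.15, 0.5), trait_noise_sd=0.8, seed=5,
        )
        snp_info, genotypes, trait, _ = generate_gwas(cfg)
        assoc = maf_filter(naive_assoc(genotypes, trait, snp_info))
        thr = bonferroni_log_threshold(len(assoc))
        sig = call_significant(assoc, thr)
        loci = group_loci(sig, trait="T")
        chroms_hit = {l.chromosome for l in loci}
        assert 1 in chroms_hit and 3 in chroms_hit
        for l in loci:
            if l.chromosome == 1:
                assert abs(l.lead_position - 10_000_000) <= 400_000
            if l.chromosome == 3:
                assert abs(l.lead_position - 20_000_000) <= 400_000
        assert not chroms_hit - {1, 3}

    def test_read_assoc_requires_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"chr": [1], "rs": ["a"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(GwasError, match="missing"):
            read_assoc(path)

    def test_validate_rejects_bad_positions(self):
        with pytest.raises(GwasError):
            validate_assoc(_assoc([(1, "a", 0, 0.2, 0.5)]))
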