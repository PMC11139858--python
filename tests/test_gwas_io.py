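"""Summary-statistics IO, allele harmonization, marginal GWAS and meta-subtraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_panel, make_sumstats, meta_oracle
from multiprs import gwas_io


# ------------------------------------------------------------------ parsing

class TestReadSummaryStats:
    def test_well_formed_tsv(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "CHR\tPOS\tEA\tOA\tBETA\tSE\tP\tN\n"
            "1\t100\tA\tG\t0.5\t0.1\t1e-4\t5000\n"
            "1\t200\tC\tT\t-0.2\t0.2\t0.3\t5000\n"
            "2\t300\tG\tA\t0.1\t0.05\t5e-08\t5000\n"
        )
        stats = gwas_io.read_summary_stats(path)
        assert len(stats) == 3
        assert stats["P"].iloc[2] == pytest.approx(5e-8)
        assert stats.attrs["n_rejected"] == 0

    def test_custom_dialect(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("chrom\tbp\ta1\ta2\teff\tstderr\tpval\n1\t100\tA\tG\t0.5\t0.1\t0.01\n")
        stats = gwas_io.read_summary_stats(
            path,
            dialect={"CHR": "chrom", "POS": "bp", "EA": "a1", "OA": "a2",
                     "BETA": "eff", "SE": "stderr", "P": "pval"},
        )
        assert stats["BETA"].iloc[0] == 0.5

    def test_missing_se_column_is_named(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("CHR\tPOS\tEA\tOA\tBETA\tP\tN\n1\t100\tA\tG\t0.5\t0.1\t100\n")
        with pytest.raises(ValueError, match="SE"):
            gwas_io.read_summary_stats(path)

    def test_invalid_records_rejected_and_counted(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "CHR\tPOS\tEA\tOA\tBETA\tSE\tP\tN\n"
            "1\t100\tA\tG\t0.5\t0.1\t0.01\t100\n"
            "1\t200\tA\tG\t0.5\t-0.1\t0.01\t100\n"   # bad SE
            "1\t300\tA\tG\t0.5\t0.1\t1.5\t100\n"     # bad P
        )
        stats = gwas_io.read_summary_stats(path)
        assert len(stats) == 1
        assert stats.attrs["n_rejected"] == 2

    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        stats = make_sumstats(
            beta=rng.standard_normal(20), se=rng.uniform(0.01, 1, 20),
            p=rng.uniform(1e-300, 1, 20),
        )
        path = tmp_path / "rt.tsv"
        gwas_io.write_summary_stats(stats, path)
        back = gwas_io.read_summary_stats(path, source_id="test")
        for col in ("CHR", "POS", "EA", "OA", "BETA", "SE", "P", "N"):
            assert (back[col].to_numpy() == stats[col].to_numpy()).all(), col


# ------------------------------------------------------------- harmonization

class TestHarmonizeAlleles:
    panel_variants = pd.DataFrame(
        {"CHR": ["1", "1", "1"], "POS": [100, 200, 300],
         "EA": ["G", "A", "A"], "OA": ["A", "G", "C"]}
    )

    def test_swapped_alleles_flip_beta(self):
        stats = make_sumstats(pos=[100], ea=["A"], oa=["G"], beta=[0.3])
        out = gwas_io.harmonize_alleles(stats, self.panel_variants)
        assert out["BETA"].iloc[0] == pytest.approx(-0.3)
        assert out["EA"].iloc[0] == "G" and out["OA"].iloc[0] == "A"

    def test_exact_match_passes_through(self):
        stats = make_sumstats(pos=[200], ea=["A"], oa=["G"], beta=[0.3])
        out = gwas_io.harmonize_alleles(stats, self.panel_variants)
        assert out["BETA"].iloc[0] == pytest.approx(0.3)

    def test_unresolvable_pair_dropped_and_counted(self):
        stats = make_sumstats(pos=[100, 200], ea=["A", "A"], oa=["C", "G"],
                              beta=[0.1, 0.2])
        out = gwas_io.harmonize_alleles(stats, self.panel_variants)
        assert len(out) == 1
        assert out.attrs["n_dropped_mismatch"] == 1

    def test_strand_ambiguous_dropped_by_default(self):
        panel = pd.DataFrame({"CHR": ["1"], "POS": [100], "EA": ["A"], "OA": ["T"]})
        stats = make_sumstats(pos=[100], ea=["A"], oa=["T"], beta=[0.1])
        assert len(gwas_io.harmonize_alleles(stats, panel)) == 0
        assert len(gwas_io.harmonize_alleles(stats, panel, keep_ambiguous=True)) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        stats = make_sumstats(
            pos=[100, 200, 300], ea=["A", "G", "A"], oa=["G", "A", "C"],
            beta=rng.standard_normal(3),
        )
        once = gwas_io.harmonize_alleles(stats, self.panel_variants)
        twice = gwas_io.harmonize_alleles(once, self.panel_variants)
        pd.testing.assert_frame_equal(once, twice)


# ------------------------------------------------------------ marginal GWAS

class TestRunMarginalGwas:
    def test_noiseless_slope_recovered(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(200, 3)).astype(float)
        panel = make_panel(dos)
        y = 2.0 * dos[:, 1]
        stats = gwas_io.run_marginal_gwas(panel, y)
        assert stats["BETA"].iloc[1] == pytest.approx(2.0, abs=1e-10)
        assert stats["P"].iloc[1] <= np.finfo(float).tiny * 10

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(300, 1000)).astype(float)
        panel = make_panel(dos)
        y = rng.standard_normal(300)
        stats = gwas_io.run_marginal_gwas(panel, y)
        ks = sps.kstest(stats["P"], "uniform")
        assert ks.pvalue > 0.01

    def test_sampling_distribution(self):
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, 0.3, size=(10000, 1)).astype(float)
        panel = make_panel(dos)
        y = 0.5 * dos[:, 0] + rng.standard_normal(10000)
        stats = gwas_io.run_marginal_gwas(panel, y)
        assert abs(stats["BETA"].iloc[0] - 0.5) < 3 * stats["SE"].iloc[0]

    def test_covariate_adjustment(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(30, 80, 2000)
        dos = rng.binomial(2, 0.4, size=(2000, 1)).astype(float)
        panel = make_panel(dos)
        y = 0.8 * age + 0.5 * dos[:, 0] + rng.standard_normal(2000)
        stats = gwas_io.run_marginal_gwas(
            panel, y, covariates=pd.DataFrame({"age": age})
        )
        assert abs(stats["BETA"].iloc[0] - 0.5) < 3 * stats["SE"].iloc[0]

    def test_zero_variance_dosage_flagged(self):
        dos = np.column_stack([np.ones(50), np.random.default_rng(0).integers(0, 3, 50)])
        panel = make_panel(dos.astype(float))
        stats = gwas_io.run_marginal_gwas(panel, np.random.default_rng(1).standard_normal(50))
        assert np.isnan(stats["BETA"].iloc[0])
        assert stats.attrs["n_monomorphic"] == 1


# --------------------------------------------------------- meta subtraction

class TestSubtractGwas:
    def test_exact_two_study_inversion(self):
        s1 = make_sumstats(pos=[100], beta=[1.0], se=[0.5], source="s1")
        s2 = make_sumstats(pos=[100], beta=[0.2], se=[1.0], source="s2")
        meta = gwas_io.meta_analyze([s1, s2])
        assert meta["BETA"].iloc[0] == pytest.approx(0.84)
        assert meta["SE"].iloc[0] == pytest.approx(1 / np.sqrt(5))
        rem = gwas_io.subtract_gwas(meta, s2)
        assert rem["BETA"].iloc[0] == pytest.approx(1.0)
        assert rem["SE"].iloc[0] == pytest.approx(0.5)

    def test_zero_weight_placeholder_is_identity(self):
        meta = make_sumstats(pos=[100, 200], beta=[0.3, -0.1], se=[0.1, 0.2])
        ghost = make_sumstats(pos=[100, 200], beta=[0.0, 0.0], se=[1e9, 1e9])
        rem = gwas_io.subtract_gwas(meta, ghost)
        np.testing.assert_allclose(rem["BETA"], meta["BETA"], rtol=1e-6)
        np.testing.assert_allclose(rem["SE"], meta["SE"], rtol=1e-6)

    def test_three_study_round_trip_matches_oracle(self):
        rng = np.random.default_rng(6)
        m = 50
        pos = np.arange(1, m + 1) * 137
        studies = [
            make_sumstats(pos=pos, beta=rng.standard_normal(m),
                          se=rng.uniform(0.05, 0.5, m), source=f"s{k}")
            for k in range(3)
        ]
        meta = gwas_io.meta_analyze(studies)
        rem = gwas_io.subtract_gwas(meta, studies[2])
        beta12, se12 = meta_oracle(studies[:2])
        np.testing.assert_allclose(rem["BETA"], beta12, rtol=1e-10)
        np.testing.assert_allclose(rem["SE"], se12, rtol=1e-10)

    def test_overweight_sub_variant_dropped(self):
        meta = make_sumstats(pos=[100], beta=[0.3], se=[0.5])
        sub = make_sumstats(pos=[100], beta=[0.3], se=[0.4])  # heavier than meta
        rem = gwas_io.subtract_gwas(meta, sub)
        assert len(rem) == 0
        assert rem.attrs["n_dropped_weight"] == 1

    def test_unshared_variants_pass_through(self):
        meta = make_sumstats(pos=[100, 200], beta=[0.3, 0.7], se=[0.5, 0.5])
        sub = make_sumstats(pos=[100], beta=[0.1], se=[1.0])
        rem = gwas_io.subtract_gwas(meta, sub)
        row = rem[rem["POS"] == 200].iloc[0]
        assert row["BETA"] == 0.7 and row["SE"] == 0.5


# ---------------------------------------------------------------- LD regions

class TestLdRegions:
    def test_parse_basic(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t1000000\n")
        regions = gwas_io.read_ld_regions(bed)
        assert len(regions) == 1
        assert regions.loc[0, "START"] == 0 and regions.loc[0, "END"] == 1000000
        assert regions.loc[0, "REGION_ID"] == "chr1:0-1000000"

    def test_abutting_regions_half_open(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("1\t0\t10\tr1\n1\t10\t20\tr2\n")
        regions = gwas_io.read_ld_regions(bed)
        variants = pd.DataFrame({"CHR": ["1", "1"], "POS": [10, 11]})  # 0-based 9, 10
        assigned = gwas_io.assign_regions(variants, regions)
        assert list(assigned) == ["r1", "r2"]

    def test_overlap_raises(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("1\t0\t15\n1\t10\t20\n")
        with pytest.raises(ValueError, match="overlap"):
            gwas_io.read_ld_regions(bed)
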