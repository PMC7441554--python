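"""Genomic STR association statistics and the synthetic genome fixture."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strstall import genome as gen

MOTIF_SIGMA = {"AAG": 0.1, "AT": 0.2, "ACG": 0.3, "AC": 0.5, "AGG": 0.6, "ACC": 0.8}


@pytest.fixture(scope="module")
def fixture_small():
    cfg = gen.FixtureConfig(motif_sigma=MOTIF_SIGMA, n_loci=2000)
    return gen.generate_genome_fixture(cfg, seed=9)


class TestLocusModel:
    def test_basic_fields(self):
        locus = gen.GenomicLocus("chr1", 100, 124, "ACG")
        assert locus.length_nt == 24
        assert locus.ds_class == "ACG"
        assert not locus.mononucleotide

    def test_mono_flagged(self):
        assert gen.GenomicLocus("chr1", 5, 25, "A").mononucleotide

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            gen.GenomicLocus("chr1", 10, 10, "AC")

    def test_strand_collapse(self):
        fwd = gen.GenomicLocus("chr1", 0, 24, "CAG")
        rev = gen.GenomicLocus("chr1", 0, 24, "CTG")
        assert fwd.ds_class == rev.ds_class


class TestLoaders:
    def test_round_trip(self, fixture_small, tmp_path):
        loci, _, _, _ = fixture_small
        path = tmp_path / "loci.tsv"
        gen.write_loci(loci[:100], str(path))
        back, errors = gen.load_str_loci(str(path))
        assert not errors
        assert [(l.chrom, l.start, l.end, l.motif) for l in back] == [
            (l.chrom, l.start, l.end, l.motif) for l in loci[:100]
        ]

    def test_one_based_conversion_preserves_length(self, tmp_path):
        path = tmp_path / "msdb.tsv"
        pd.DataFrame(
            [{"chrom": "chr1", "start": 101, "end": 124, "motif": "ACG"}]
        ).to_csv(path, sep="\t", index=False)
        loci, _ = gen.load_str_loci(str(path), one_based=True)
        assert loci[0].start == 100 and loci[0].length_nt == 24

    def test_malformed_rows_skipped(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chrom\tstart\tend\tmotif\nchr1\t10\t30\tAC\nchr1\t50\t40\tAC\n"
            + "\n".join(f"chr1\t{i * 100}\t{i * 100 + 20}\tAC" for i in range(2, 30))
        )
        loci, errors = gen.load_str_loci(str(path))
        assert len(errors) == 1 and len(loci) == 29

    def test_vcf_reader_skips_non_snps(self, tmp_path):
        path = tmp_path / "v.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t11\t.\tA\tG\t.\tPASS\t.\n"
            "chr1\t20\t.\tAT\tA\t.\tPASS\t.\n"
        )
        snps = gen.read_snp_vcf(str(path))
        assert snps == [("chr1", 10)]


class TestAbundanceAndMutability:
    def test_binned_counts(self):
        loci = [gen.GenomicLocus("c", i * 100, i * 100 + 24, "AAG") for i in range(6)]
        loci += [gen.GenomicLocus("c", 10_000 + i * 100, 10_000 + i * 100 + 24, "ACC") for i in range(4)]
        out = gen.abundance_and_length_by_score(
            loci, {"AAG": 0.1, "ACC": 0.9}, bins=[0, 0.5, 1.0]
        )
        assert out["n_loci"].tolist() == [6, 4]

    def test_top_n_restriction(self):
        loci = [gen.GenomicLocus("c", i * 100, i * 100 + 12 + i % 7, "AAG") for i in range(50)]
        out = gen.abundance_and_length_by_score(
            loci, {"AAG": 0.1}, bins=[0, 1.0], top_n_lengths=10
        )
        lengths = sorted(l.length_nt for l in loci)[-10:]
        assert out["median_top_length"].iloc[0] == pytest.approx(np.median(lengths))

    def test_abundance_anticorrelates_with_planted_sigma(self, fixture_small):
        loci, _, _, _ = fixture_small
        out = gen.abundance_and_length_by_score(
            loci, MOTIF_SIGMA, bins=[0, 0.25, 0.5, 0.75, 1.0]
        )
        rho = stats.spearmanr(range(len(out)), out["n_loci"]).statistic
        assert rho < 0

    def test_join_filters(self):
        loci = [
            gen.GenomicLocus("c", 0, 10, "AC"),  # too short
            gen.GenomicLocus("c", 100, 124, "AC"),  # kept
            gen.GenomicLocus("c", 200, 224, "A"),  # mononucleotide
            gen.GenomicLocus("c", 300, 324, "AC"),  # mu below floor
        ]
        params = pd.DataFrame(
            [
                {"chrom": "c", "start": 0, "end": 10, "mu": 1e-5, "beta": 0.3, "p": 0.8},
                {"chrom": "c", "start": 100, "end": 124, "mu": 1e-5, "beta": 0.3, "p": 0.8},
                {"chrom": "c", "start": 200, "end": 224, "mu": 1e-5, "beta": 0.3, "p": 0.8},
                {"chrom": "c", "start": 300, "end": 324, "mu": 1e-8, "beta": 0.3, "p": 0.8},
            ]
        )
        kept = gen.join_mutability(loci, params)
        assert [(l.start) for l in kept] == [100]

    def test_mu_ordering_recovered(self, fixture_small):
        loci, _, _, _ = fixture_small
        lo = [l.mu for l in loci if MOTIF_SIGMA[l.ds_class] <= 0.3]
        hi = [l.mu for l in loci if MOTIF_SIGMA[l.ds_class] >= 0.6]
        assert np.median(lo) > np.median(hi)


class TestSnpDensity:
    def test_single_snp_at_minus_one(self):
        locus = gen.GenomicLocus("c", 100, 124, "ACG")
        prof = gen.snp_density_profile([locus], [("c", 99)], flank=5)
        d = prof.set_index(["anchor", "offset"])["density"]
        assert d[("start", -1)] == 1.0
        assert d[("start", -2)] == 0.0

    def test_no_snps_zero_everywhere(self):
        locus = gen.GenomicLocus("c", 100, 124, "ACG")
        prof = gen.snp_density_profile([locus], [], flank=5)
        assert (prof["density"] == 0).all()

    def test_densities_bounded_and_order_invariant(self, fixture_small):
        loci, snps, _, _ = fixture_small
        a = gen.snp_density_profile(loci[:500], snps, flank=5)
        b = gen.snp_density_profile(list(reversed(loci[:500])), snps, flank=5)
        assert ((a["density"] >= 0) & (a["density"] <= 1)).all()
        pd.testing.assert_frame_equal(a, b)


class TestBoundaryEnrichment:
    def test_balanced_table(self):
        # directly exercise the 2x2 construction with synthetic marking
        loci_a = [gen.GenomicLocus("c", i * 1000, i * 1000 + 24, "AC") for i in range(100)]
        loci_b = [gen.GenomicLocus("c", 500_000 + i * 1000, 500_000 + i * 1000 + 24, "AC") for i in range(100)]
        snps = [("c", l.start - 1) for l in loci_a[:50]] + [
            ("c", l.start - 1) for l in loci_b[:50]
        ]
        res = gen.boundary_enrichment(loci_a, loci_b, snps)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.contingency.tolist() == [[50, 50], [50, 50]]

    def test_or_nine_table(self):
        p_scipy = stats.fisher_exact([[30, 10], [10, 30]])[1]
        p_enum = gen.fisher_exact_enumeration(np.array([[30, 10], [10, 30]]))
        assert p_enum == pytest.approx(p_scipy, rel=1e-9)
        assert (30 * 30) / (10 * 10) == 9.0

    def test_null_fixture_or_near_one(self):
        cfg = gen.FixtureConfig(
            motif_sigma=MOTIF_SIGMA, n_loci=4000, boundary_odds_ratio=1.0
        )
        loci, snps, _, _ = gen.generate_genome_fixture(cfg, seed=2)
        unstable = [l for l in loci if l.mu > gen.MU_QUANTIFICATION_FLOOR]
        stable = [l for l in loci if l.mu <= gen.MU_QUANTIFICATION_FLOOR]
        res = gen.boundary_enrichment(unstable, stable, snps)
        assert res.p_value > 0.01

    def test_fixture_determinism(self):
        cfg = gen.FixtureConfig(motif_sigma=MOTIF_SIGMA, n_loci=300)
        a = gen.generate_genome_fixture(cfg, seed=4)
        b = gen.generate_genome_fixture(cfg, seed=4)
        assert a[1] == b[1]
        assert [(l.start, l.end, l.motif, l.mu) for l in a[0]] == [
            (l.start, l.end, l.motif, l.mu) for l in b[0]
        ]

    def test_fixture_files_round_trip(self, fixture_small, tmp_path):
        loci, snps, params, truth = fixture_small
        prefix = str(tmp_path / "fx")
        gen.write_fixture(loci[:50], snps[:50], params.head(50), truth, prefix)
        back, _ = gen.load_str_loci(prefix + "_loci.tsv")
        assert len(back) == 50
        snps_back = gen.read_snp_vcf(prefix + "_snps.vcf")
        assert snps_back == list(snps[:50])


class TestFisherOracle:
    def test_matches_scipy_on_small_tables(self):
        for a, b, c, d in itertools.product(range(8), repeat=4):
            if a + b + c + d == 0:
                continue
            table = np.array([[a, b], [c, d]])
            assert gen.fisher_exact_enumeration(table) == pytest.approx(
                stats.fisher_exact(table)[1], rel=1e-9, abs=1e-12
            )
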