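"""Synthetic assay generator: determinism, conservation, convergence."""

import numpy as np
import pytest

from strstall.library import LibraryEntry
from strstall import simulate as sim


@pytest.fixture(scope="module")
def one_entry():
    return LibraryEntry("STR_ACG_72", "STR", "ACG" * 24, 72, motif="ACG")


class TestGroundTruth:
    def test_class_ranges_and_signs(self, control_library):
        truths = sim.sample_ground_truth(control_library, seed=1)
        for t in truths:
            lo, hi, llo, lhi = sim.DEFAULT_CLASS_RANGES[t.true_class]
            assert lo <= t.sigma0 <= hi
            assert llo <= t.lam <= lhi
            if t.true_class == "HAIRP":
                assert t.lam < 0
            elif t.true_class in ("QUAD", "IMOT"):
                assert t.lam > 0
            else:
                assert abs(t.lam) <= 0.01

    def test_class_mean_lambda_ordering(self, control_library):
        truths = sim.sample_ground_truth(control_library, seed=1)
        means = {
            c: np.mean([t.lam for t in truths if t.true_class == c])
            for c in ("HAIRP", "UNF", "IMOT", "QUAD")
        }
        assert means["HAIRP"] < means["UNF"] < means["IMOT"] <= means["QUAD"]

    def test_determinism_and_order_independence(self, control_library):
        a = sim.sample_ground_truth(control_library, seed=4)
        b = sim.sample_ground_truth(list(reversed(control_library)), seed=4)
        by_id = {t.entry_id: t for t in b}
        assert all(by_id[t.entry_id] == t for t in a)

    def test_unknown_category(self):
        bad = LibraryEntry("X", "WEIRD", "ACGT", 4)
        with pytest.raises(KeyError):
            sim.sample_ground_truth(
                [bad], class_map=lambda e: e.category, seed=0
            )


class TestCounts:
    def test_read_conservation_and_determinism(self, control_library):
        truths = sim.sample_ground_truth(control_library[:10], seed=2)
        counts = sim.simulate_counts(truths, depth=500, seed=2)
        assert (counts["stalled_reads"] >= 0).all()
        assert (counts["extended_reads"] >= 0).all()
        again = sim.simulate_counts(truths, depth=500, seed=2)
        assert counts.equals(again)

    def test_binomial_mean_at_high_depth(self):
        truth = sim.GroundTruth("E", "UNF", 0.5, 0.0, 5, 0, 0.001, 0.1, 0.7)
        counts = sim.simulate_counts(
            [truth], depth=100_000, replicates=1, times=[1.0], seed=3,
            replicate_noise_sd=0.0,
        )
        frac = counts["stalled_reads"] / (
            counts["stalled_reads"] + counts["extended_reads"]
        )
        se = np.sqrt(0.25 / 100_000)
        assert abs(frac.iloc[0] - 0.5) < 3 * se

    def test_sigma_closed_form(self):
        truth = sim.GroundTruth("E", "QUAD", 0.4, np.log(2), 5, 0, 0.001, 0.1, 0.7)
        assert truth.sigma(1.0) == pytest.approx(0.8)
        assert truth.sigma(100.0) == 1.0  # clamped

    def test_saturated_entries_stall_only(self):
        truth = sim.GroundTruth("E", "QUAD", 0.9, 0.5, 5, 0, 0.001, 0.1, 0.7)
        counts = sim.simulate_counts([truth], depth=10_000, times=[30.0], seed=4)
        assert (counts["extended_reads"] == 0).all()


class TestCoverage:
    def test_transition_at_stall_site(self):
        truth = sim.GroundTruth("E", "QUAD", 0.5, 0.0, 20.0, 0.0, 0, 0, 0.7)
        cov = sim.simulate_coverage(truth, 72, times=[0.5], read_depth=5000, noise_sd=0.0, seed=5)
        prof = cov.sort_values("position")["count"].to_numpy()
        rel = prof / prof.max()
        assert rel[0] == 1.0
        assert rel[19] == 1.0 and rel[21] == 0.0  # step at the stall site
        assert (np.diff(rel) <= 0).all()  # monotone non-increasing

    def test_drift_moves_midpoint(self):
        truth = sim.GroundTruth("E", "HAIRP", 0.5, -0.05, 10.0, 1.0, 0, 0, 0.7)
        cov = sim.simulate_coverage(truth, 72, times=[0.5, 30.0], read_depth=8000, seed=6)
        from strstall.coverage import profiles_from_table

        prof = {p.time_min: p.stall_position for p in profiles_from_table(cov)}
        assert prof[30.0] - prof[0.5] == pytest.approx(29.5, abs=1.0)

    def test_zero_drift_constant_midpoint(self):
        truth = sim.GroundTruth("E", "QUAD", 0.5, 0.0, 15.0, 0.0, 0, 0, 0.7)
        cov = sim.simulate_coverage(truth, 72, times=[0.5, 30.0], read_depth=8000, seed=7)
        from strstall.coverage import profiles_from_table

        prof = {p.time_min: p.stall_position for p in profiles_from_table(cov)}
        assert prof[30.0] == pytest.approx(prof[0.5], abs=0.5)


class TestReads:
    def test_error_free_reads_match_reference(self, one_entry):
        truth = sim.GroundTruth(one_entry.entry_id, "UNF", 0.1, 0.0, 5, 0, 0.0, 0.0, 1.0)
        reads, parental = sim.simulate_reads_with_variants(
            truth, one_entry, n_reads=50, seed=8, bs_rate=0.0, ec_rate=0.0
        )
        assert parental == []
        assert all(r.seq == one_entry.insert and r.cigar == "72M" for r in reads)

    def test_step_p_one_slips_single_unit(self, one_entry):
        truth = sim.GroundTruth(one_entry.entry_id, "UNF", 0.1, 0.0, 5, 0, 0.0, 1.0, 1.0)
        reads, _ = sim.simulate_reads_with_variants(
            truth, one_entry, n_reads=100, seed=9, bs_rate=0.0, ec_rate=1.0
        )
        for r in reads:
            assert abs(len(r.seq) - 72) == 3  # exactly one 3-nt unit

    def test_non_str_rejected(self):
        entry = LibraryEntry("R", "RANDOM", "ACGT" * 18, 72)
        truth = sim.GroundTruth("R", "UNF", 0.1, 0.0, 5, 0, 0.001, 0.1, 0.7)
        with pytest.raises(ValueError):
            sim.simulate_reads_with_variants(truth, entry, n_reads=1, seed=0)

    def test_sam_round_trip(self, one_entry, tmp_path):
        truth = sim.GroundTruth(one_entry.entry_id, "UNF", 0.1, 0.0, 5, 0, 0.01, 0.3, 0.7)
        reads, _ = sim.simulate_reads_with_variants(truth, one_entry, n_reads=30, seed=10)
        path = str(tmp_path / "reads.sam")
        sim.write_sam(reads, {one_entry.entry_id: one_entry.insert}, path)
        back = sim.read_sam(path)
        assert len(back) == len(reads)
        assert all(
            (a.qname, a.pos, a.cigar, a.seq) == (b.qname, b.pos, b.cigar, b.seq)
            for a, b in zip(reads, back)
        )
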