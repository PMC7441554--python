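"""Variant calling, filtering and BS/EC classification at STR inserts."""

import numpy as np
import pytest

from strstall.library import LibraryEntry
from strstall.simulate import AlignedRead, GroundTruth, ParentalVariant, simulate_reads_with_variants
from strstall import variants as var

REF = "ACG" * 8  # 24-nt (ACG) repeat


def _read(seq, cigar, qual=None, pos=0, name="r1"):
    return AlignedRead(
        qname=name, rname="E", pos=pos, cigar=cigar, seq=seq,
        qual=qual or chr(35 + 33) * len(seq),
    )


class TestRawCalling:
    def test_reference_read_yields_nothing(self):
        assert var.call_raw_variants([_read(REF, "24M")], REF, "E") == []

    def test_single_mismatch_counts(self):
        reads = [_read(REF, "24M", name=f"m{i}") for i in range(90)]
        mutant = REF[:7] + "G" + REF[8:]
        reads += [_read(mutant, "24M", name=f"x{i}") for i in range(10)]
        cands = var.call_raw_variants(reads, REF, "E")
        assert len(cands) == 1
        c = cands[0]
        assert (c.position, c.ref_allele, c.alt_allele) == (7, REF[7], "G")
        assert (c.supporting_reads, c.covering_reads) == (10, 100)

    def test_insertion_left_aligned(self):
        # ACG inserted after 4 units == inserted at the repeat start
        seq = REF[:12] + "ACG" + REF[12:]
        cands = var.call_raw_variants([_read(seq, "12M3I12M")], REF, "E")
        assert len(cands) == 1
        assert cands[0].position == 0
        assert cands[0].alt_allele == "ACG"

    def test_all_in_register_placements_collapse(self):
        reads = []
        for i, boundary in enumerate((3, 9, 18)):
            seq = REF[:boundary] + "ACG" + REF[boundary:]
            reads.append(_read(seq, f"{boundary}M3I{24 - boundary}M", name=f"r{i}"))
        cands = var.call_raw_variants(reads, REF, "E")
        assert len(cands) == 1
        assert cands[0].supporting_reads == 3


class TestLeftAlign:
    def test_shifts_within_repeat(self):
        pos, seq = var.left_align_indel(REF, 12, "ACG")
        assert (pos, seq) == (0, "ACG")

    def test_non_repeat_context_stays(self):
        ref = "TTTTACGTTT"
        pos, seq = var.left_align_indel(ref, 4, "ACG")
        assert (pos, seq) == (4, "ACG")


class TestFilters:
    def test_quality_threshold(self):
        low = _read(REF[:7] + "G" + REF[8:], "24M", qual=chr(10 + 33) * 24)
        cands = var.call_raw_variants([low], REF, "E")
        assert var.filter_variants(cands, "ACG") == []
        assert len(var.filter_variants(cands, "ACG", min_quality=5)) == 1

    def test_parental_excluded(self):
        mutant = _read(REF[:7] + "G" + REF[8:], "24M")
        cands = var.call_raw_variants([mutant], REF, "E")
        parental = [ParentalVariant("E", 7, REF[7], "G")]
        assert var.filter_variants(cands, "ACG", parental) == []

    def test_non_unit_multiple_rejected(self):
        seq = REF[:12] + "ACGA" + REF[12:]
        cands = var.call_raw_variants([_read(seq, "12M4I12M")], REF, "E")
        assert var.filter_variants(cands, "ACG") == []

    def test_two_unit_expansion_arithmetic(self):
        seq = REF[:12] + "ACGACG" + REF[12:]
        cands = var.call_raw_variants([_read(seq, "12M6I12M")], REF, "E")
        calls = var.filter_variants(cands, "ACG")
        assert len(calls) == 1
        assert calls[0].var_type == "EC"
        assert calls[0].n_units == 2
        assert calls[0].unit_size == 3

    def test_contraction_negative_units(self):
        seq = REF[:12] + REF[15:]
        cands = var.call_raw_variants([_read(seq, "12M3D9M")], REF, "E")
        calls = var.filter_variants(cands, "ACG")
        assert calls[0].var_type == "EC" and calls[0].n_units == -1

    def test_repeat_region_restriction(self):
        mutant = _read(REF[:7] + "G" + REF[8:], "24M")
        cands = var.call_raw_variants([mutant], REF, "E")
        assert var.filter_variants(cands, "ACG", repeat_region=(10, 24)) == []
        assert len(var.filter_variants(cands, "ACG", repeat_region=(0, 24))) == 1


class TestFrequencyAndMatrices:
    def test_frequency(self):
        assert var.variant_frequency(5, 50) == pytest.approx(0.1)
        assert var.variant_frequency(7, 7) == 1.0
        with pytest.raises(ZeroDivisionError):
            var.variant_frequency(1, 0)

    def test_substitution_matrix_rows_normalized(self):
        calls = [
            var.VariantCall("E", 1, "BS", "A", "G", 30, 3, 10),
            var.VariantCall("E", 4, "BS", "A", "C", 30, 1, 10),
            var.VariantCall("E", 2, "BS", "C", "T", 30, 2, 10),
        ]
        mats = var.substitution_matrix(calls)
        m = mats["ALL"]
        assert m.loc["A"].sum() == pytest.approx(1.0)
        assert m.loc["A", "G"] == pytest.approx(0.5)
        assert np.allclose(np.diag(m.to_numpy()), 0.0)

    def test_per_class_grouping(self):
        calls = [
            var.VariantCall("E1", 1, "BS", "A", "G", 30, 1, 10),
            var.VariantCall("E2", 1, "BS", "C", "A", 30, 1, 10),
        ]
        mats = var.substitution_matrix(calls, {"E1": "QUAD", "E2": "HAIRP"})
        assert set(mats) == {"QUAD", "HAIRP"}


@pytest.fixture(scope="module")
def entry():
    return LibraryEntry("STR_ACG_72", "STR", "ACG" * 24, 72, motif="ACG")


class TestSimulatorRoundTrip:
    def test_injected_expansion_round_trip(self, entry):
        truth = GroundTruth(entry.entry_id, "UNF", 0.1, 0.0, 5, 0, 0.0, 1.0, 1.0)
        reads, _ = simulate_reads_with_variants(
            truth, entry, n_reads=50, seed=1, bs_rate=0.0, ec_rate=1.0
        )
        cands = var.call_raw_variants(reads, entry.insert, entry.entry_id)
        calls = var.filter_variants(cands, "ACG")
        assert calls and all(c.var_type == "EC" for c in calls)
        assert all(abs(c.n_units) == 1 for c in calls)  # step_p = 1

    def test_bs_rate_recovered(self, entry):
        bs_rate = 0.002
        truth = GroundTruth(entry.entry_id, "UNF", 0.1, 0.0, 5, 0, bs_rate, 0.0, 1.0)
        reads, _ = simulate_reads_with_variants(
            truth, entry, n_reads=2000, seed=2, ec_rate=0.0
        )
        cands = var.call_raw_variants(reads, entry.insert, entry.entry_id)
        calls = var.filter_variants(cands, "ACG")
        n_events = sum(c.supporting_reads for c in calls if c.var_type == "BS")
        total_bases = 2000 * 72
        se = np.sqrt(bs_rate * total_bases)
        assert abs(n_events - bs_rate * total_bases) < 4 * se

    def test_parental_variants_never_called(self, entry):
        truth = GroundTruth(entry.entry_id, "UNF", 0.1, 0.0, 5, 0, 0.001, 0.2, 0.7)
        reads, parental = simulate_reads_with_variants(
            truth, entry, n_reads=400, parental_fraction=0.5, seed=3
        )
        cands = var.call_raw_variants(reads, entry.insert, entry.entry_id)
        calls = var.filter_variants(cands, "ACG", parental)
        keys = {(c.position, c.ref_allele, c.alt_allele) for c in calls}
        for pv in parental:
            assert (pv.position, pv.ref, pv.alt) not in keys


class TestVcfOutput:
    def test_records_written(self, tmp_path):
        calls = [
            var.VariantCall("E", 7, "BS", "A", "G", 30, 3, 10),
            var.VariantCall("E", 0, "EC", "", "ACG", 30, 2, 10, unit_size=3, n_units=1),
        ]
        path = tmp_path / "calls.vcf"
        var.write_vcf(calls, {"E": REF}, str(path))
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 2
        assert "TYPE=BS" in lines[0] and "UNITS=1" in lines[1]
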