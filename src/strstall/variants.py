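"""De novo variant calling and classification at STR inserts.

Extended-product reads are compared against the designed insert with a
per-read pileup: mismatches become base-substitution (BS) candidates
and indels become expansion/contraction (EC) candidates after
left-alignment within the repeat (all in-register placements of a
slippage event collapse to one locus). Candidates are filtered on
phred-scaled base quality (> 20 by default), membership in the parental
variant set (anything present before extension is not de novo), and —
for EC — the requirement that the length change is an exact multiple of
the repeat unit size and that the inserted/deleted sequence tiles the
unit. Variant frequency is supporting reads over covering (spanning)
reads.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import AlignedRead, ParentalVariant

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

DEFAULT_MIN_QUALITY = 20.0


@dataclass(frozen=True)
class CandidateVariant:
    entry_id: str
    position: int  # 0-based offset in the insert
    ref_allele: str
    alt_allele: str
    quality: float
    supporting_reads: int
    covering_reads: int


@dataclass(frozen=True)
class VariantCall:
    entry_id: str
    position: int
    var_type: str  # "BS" or "EC"
    ref_allele: str
    alt_allele: str
    quality: float
    supporting_reads: int
    covering_reads: int
    unit_size: int | None = None
    n_units: int | None = None

    @property
    def frequency(self) -> float:
        return variant_frequency(self.supporting_reads, self.covering_reads)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if not ops or sum(n for n, _ in ops) == 0:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    return ops


def left_align_indel(reference: str, position: int, inserted_or_deleted: str) -> tuple[int, str]:
    """Shift an indel left while the flanking base matches its last base.

    Standard left normalization: within a repeat, all in-register
    placements of the same insertion/deletion are equivalent; the
    leftmost placement is the canonical one.
    """
    seq = inserted_or_deleted
    pos = position
    while pos > 0 and seq and reference[pos - 1] == seq[-1]:
        seq = reference[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def _mean_phred(qual: str, start: int, length: int) -> float:
    sub = qual[start : start + length] or qual[max(start - 1, 0) : start + 1]
    if not sub:
        return 0.0
    return float(np.mean([ord(c) - 33 for c in sub]))


def call_raw_variants(
    reads: list[AlignedRead], reference: str, entry_id: str
) -> list[CandidateVariant]:
    """Collect per-read mismatches and indels against the insert.

    Candidate quality is the mean phred base quality over supporting
    bases; covering reads are those spanning the variant locus.
    """
    support: dict[tuple[int, str, str], list[float]] = defaultdict(list)
    coverage = np.zeros(len(reference) + 1, dtype=int)

    for read in reads:
        if read.rname != entry_id:
            raise ValueError(f"read {read.qname} aligned to {read.rname}, not {entry_id}")
        rpos, qpos = read.pos, 0
        coverage[rpos : rpos + _reference_span(read.cigar)] += 1
        for n, op in parse_cigar(read.cigar):
            if op in ("M", "=", "X"):
                for k in range(n):
                    ref_base = reference[rpos + k]
                    alt_base = read.seq[qpos + k]
                    if alt_base != ref_base:
                        q = ord(read.qual[qpos + k]) - 33
                        support[(rpos + k, ref_base, alt_base)].append(float(q))
                rpos += n
                qpos += n
            elif op == "I":
                ins = read.seq[qpos : qpos + n]
                q = _mean_phred(read.qual, qpos, n)
                apos, aseq = left_align_indel(reference, rpos, ins)
                support[(apos, "", aseq)].append(q)
                qpos += n
            elif op == "D":
                deleted = reference[rpos : rpos + n]
                q = _mean_phred(read.qual, max(qpos - 1, 0), 2)
                apos, aseq = left_align_indel(reference, rpos, deleted)
                support[(apos, aseq, "")].append(q)
                rpos += n
            elif op in ("S", "H"):
                if op == "S":
                    qpos += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    candidates = []
    for (pos, ref_allele, alt_allele), quals in support.items():
        span = max(len(ref_allele), 1)
        covering = int(coverage[pos : pos + span].min()) if pos < len(coverage) else 0
        candidates.append(
            CandidateVariant(
                entry_id=entry_id,
                position=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                quality=float(np.mean(quals)),
                supporting_reads=len(quals),
                covering_reads=max(covering, len(quals)),
            )
        )
    candidates.sort(key=lambda c: (c.position, c.ref_allele, c.alt_allele))
    return candidates


def _reference_span(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in ("M", "=", "X", "D", "N"))


def tiles_unit(seq: str, unit: str) -> bool:
    """True when *seq* is a head-to-tail tiling of a rotation of *unit*.

    Slippage copies whatever register the polymerase slipped at, so any
    rotation of the repeat unit is an admissible tile.
    """
    if len(seq) % len(unit) != 0:
        return False
    rotations = {unit[i:] + unit[:i] for i in range(len(unit))}
    k = len(seq) // len(unit)
    return any(seq == rot * k for rot in rotations)


def classify_candidate(
    cand: CandidateVariant, unit: str
) -> VariantCall | None:
    """BS for single-base mismatches; EC for unit-multiple tiling indels;
    None for indels that are not clean slippage events."""
    if len(cand.ref_allele) == 1 and len(cand.alt_allele) == 1:
        return VariantCall(
            entry_id=cand.entry_id,
            position=cand.position,
            var_type="BS",
            ref_allele=cand.ref_allele,
            alt_allele=cand.alt_allele,
            quality=cand.quality,
            supporting_reads=cand.supporting_reads,
            covering_reads=cand.covering_reads,
        )
    changed = cand.alt_allele if len(cand.alt_allele) > len(cand.ref_allele) else cand.ref_allele
    if not tiles_unit(changed, unit):
        return None
    n_units = (len(cand.alt_allele) - len(cand.ref_allele)) // len(unit)
    return VariantCall(
        entry_id=cand.entry_id,
        position=cand.position,
        var_type="EC",
        ref_allele=cand.ref_allele,
        alt_allele=cand.alt_allele,
        quality=cand.quality,
        supporting_reads=cand.supporting_reads,
        covering_reads=cand.covering_reads,
        unit_size=len(unit),
        n_units=n_units,
    )


def filter_variants(
    candidates: list[CandidateVariant],
    unit: str,
    parental_variants: list[ParentalVariant] | None = None,
    min_quality: float = DEFAULT_MIN_QUALITY,
    repeat_region: tuple[int, int] | None = None,
) -> list[VariantCall]:
    """Quality, de novo and unit-arithmetic filters; returns retained calls.

    Candidates at loci present in the parental set (same position and
    alleles) are excluded as pre-existing; EC candidates must change the
    length by an exact multiple of the unit size with a unit-tiling
    sequence; BS/EC outside the repeat region (when given) are dropped.
    """
    parental = {
        (v.position, v.ref, v.alt) for v in (parental_variants or [])
    }
    calls = []
    for cand in candidates:
        if cand.quality <= min_quality:
            continue
        if (cand.position, cand.ref_allele, cand.alt_allele) in parental:
            continue
        if repeat_region is not None and not (
            repeat_region[0] <= cand.position < repeat_region[1]
        ):
            continue
        call = classify_candidate(cand, unit)
        if call is not None:
            calls.append(call)
    return calls


def variant_frequency(supporting: int, covering: int) -> float:
    if covering == 0:
        raise ZeroDivisionError("variant frequency undefined with zero coverage")
    if not 0 < supporting <= covering:
        raise ValueError("need 1 <= supporting <= covering")
    return supporting / covering


BASES = "ACGT"


def substitution_matrix(
    calls: list[VariantCall], entry_class: dict[str, str] | None = None
) -> dict[str, pd.DataFrame]:
    """Per-class 4x4 ref->alt substitution frequency matrices.

    Counts of BS events are accumulated per structural class (single
    key "ALL" when no grouping is given) and each row is normalized to
    sum to 1 where nonzero; the diagonal is zero by construction.
    """
    counts: dict[str, np.ndarray] = defaultdict(lambda: np.zeros((4, 4)))
    for call in calls:
        if call.var_type != "BS":
            continue
        group = entry_class.get(call.entry_id, "ALL") if entry_class else "ALL"
        counts[group][BASES.index(call.ref_allele), BASES.index(call.alt_allele)] += 1
    matrices = {}
    for group, mat in counts.items():
        norm = mat.copy()
        row_sums = norm.sum(axis=1, keepdims=True)
        np.divide(norm, row_sums, out=norm, where=row_sums > 0)
        matrices[group] = pd.DataFrame(norm, index=list(BASES), columns=list(BASES))
    return matrices


def calls_dataframe(calls: list[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "entry_id": c.entry_id,
                "position": c.position,
                "var_type": c.var_type,
                "ref": c.ref_allele,
                "alt": c.alt_allele,
                "quality": c.quality,
                "supporting": c.supporting_reads,
                "covering": c.covering_reads,
                "frequency": c.frequency,
                "unit_size": c.unit_size if c.unit_size is not None else "",
                "n_units": c.n_units if c.n_units is not None else "",
            }
            for c in calls
        ]
    )


def write_vcf(calls: list[VariantCall], references: dict[str, str], path: str) -> None:
    """Retained calls as VCF with TYPE/UNITS/FREQ INFO fields.

    Indel records follow VCF convention (anchored on the preceding
    base); internal call coordinates stay 0-based allele-only.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="BS or EC">\n')
        fh.write('##INFO=<ID=UNITS,Number=1,Type=Integer,Description="Signed unit count for EC">\n')
        fh.write('##INFO=<ID=FREQ,Number=1,Type=Float,Description="Supporting/covering">\n')
        for name, seq in references.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            ref_seq = references[c.entry_id]
            if c.var_type == "BS":
                pos, ref, alt = c.position + 1, c.ref_allele, c.alt_allele
            else:
                anchor_i = max(c.position - 1, 0)
                anchor = ref_seq[anchor_i]
                pos = anchor_i + 1
                ref = anchor + c.ref_allele
                alt = anchor + c.alt_allele
            info = f"TYPE={c.var_type};FREQ={c.frequency:.6g}"
            if c.var_type == "EC":
                info += f";UNITS={c.n_units}"
            fh.write(
                f"{c.entry_id}\t{pos}\t.\t{ref}\t{alt}\t{c.quality:.1f}\tPASS\t{info}\n"
            )
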