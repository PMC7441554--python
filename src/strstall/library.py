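"""Design of the 20,000-entry pooled oligonucleotide library.

The library holds every primitive STR motif of period 1-6 tiled to three
insert lengths (24, 48 and 72 nt; 16,068 entries), plus structured
positive controls — hairpins (stem + TTTT loop + reverse-complement
stem), G-quadruplexes (four G-tracts of 2-5 nt separated by three 1-9 nt
loops) and i-motifs (the C-tract analogue) — and random negative
controls of 72 nt spanning 20-80% GC. Each entry carries a unique 12-nt
barcode (pairwise Hamming distance >= 3, no homopolymer run >= 3 nt) and
is assembled into a 150-nt oligo between fixed priming/restriction
flanks (HindIII upstream, BamHI downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .motifs import (
    MotifRecord,
    _check_dna,
    reverse_complement,
    sequence_features,
)

# flanks: forward priming site (contains HindIII AAGCTT) and the reverse
# complement of the reverse primer (contains BamHI GGATCC)
P1_FLANK = "GGGGAAGCTTGCCGTAAG"
P2_PRIMER = "TGATCGCGGATCCATCGC"
P2_FLANK = reverse_complement(P2_PRIMER)  # GCGATGGATCCGCGATCA

OLIGO_LENGTH = 150
BARCODE_LENGTH = 12
#: nt available for insert + spacer between the flanks and the barcode
PAYLOAD = OLIGO_LENGTH - len(P1_FLANK) - len(P2_FLANK) - BARCODE_LENGTH

# constant neutral spacer (no AAGCTT/GGATCC, no homopolymer >= 3); being
# identical across entries it cannot confound per-entry comparisons
_SPACER = (
    "TCAGTACTGACTGATCAGTCATGACTAGTCAGTACTGACTGATCAGTCATGACTAGTCAGTACTGACTGATCAGTCAT"
    "GACTAGTCAGTACTGACTGATC"
)

CATEGORIES = ("STR", "HAIRPIN", "G4", "IMOT", "RANDOM")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """Constrained sampling failed within the retry budget."""


@dataclass
class LibraryEntry:
    entry_id: str
    category: str
    insert: str
    insert_length: int
    barcode: str = ""
    oligo: str = ""
    motif: str | None = None
    design_gc: float | None = None


def tile_motif(motif: str, length: int) -> str:
    """Tile a motif head-to-tail and truncate at exactly *length* nt."""
    _check_dna(motif)
    if length < len(motif):
        raise ValueError(f"target length {length} shorter than period {len(motif)}")
    return (motif * (length // len(motif) + 1))[:length]


def design_str_inserts(
    catalog: Sequence[MotifRecord], lengths: Iterable[int] = (24, 48, 72)
) -> list[LibraryEntry]:
    """One entry per (primitive motif, insert length)."""
    entries = []
    for rec in catalog:
        for length in lengths:
            entries.append(
                LibraryEntry(
                    entry_id=f"STR_{rec.motif}_{length}",
                    category="STR",
                    insert=tile_motif(rec.motif, length),
                    insert_length=length,
                    motif=rec.ss_class,
                )
            )
    return entries


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    n_gc = int(round(length * gc))
    bases = [rng.choice(["G", "C"]) for _ in range(n_gc)]
    bases += [rng.choice(["A", "T"]) for _ in range(length - n_gc)]
    rng.shuffle(bases)
    return "".join(bases)


def _sample_tetrad(rng: np.random.Generator, tract_base: str) -> str:
    """Four 2-5 nt tracts of one base separated by three 1-9 nt loops.

    Loop termini avoid the tract base so tract lengths stay as drawn.
    """
    other = [b for b in "ACGT" if b != tract_base]
    parts = []
    for i in range(4):
        parts.append(tract_base * rng.integers(2, 6))
        if i < 3:
            loop_len = int(rng.integers(1, 10))
            loop = [str(rng.choice(other))]
            for _ in range(loop_len - 2):
                loop.append(str(rng.choice(list("ACGT"))))
            if loop_len > 1:
                loop.append(str(rng.choice(other)))
            parts.append("".join(loop))
    return "".join(parts)


def _sample_hairpin(rng: np.random.Generator) -> tuple[str, float]:
    for _ in range(10_000):
        stem_len = int(rng.integers(7, 23))
        gc = float(rng.uniform(0.20, 0.80))
        stem = _random_seq(rng, stem_len, gc)
        actual_gc = sequence_features(stem)[0]
        if 0.20 <= actual_gc <= 0.80:
            return stem + "TTTT" + reverse_complement(stem), actual_gc
    raise GenerationError("could not sample a hairpin stem in the GC window")


def design_controls(
    n_hairpin: int = 960,
    n_g4: int = 1500,
    n_imot: int = 472,
    n_random: int = 1000,
    seed: int = 0,
) -> list[LibraryEntry]:
    """Structured positive controls and random-GC negative controls.

    Defaults give the 3,932 control entries that complete the 20,000-
    sequence library alongside the 16,068 STR inserts.
    """
    rng = np.random.default_rng(seed)
    entries: list[LibraryEntry] = []
    for i in range(n_hairpin):
        insert, gc = _sample_hairpin(rng)
        entries.append(
            LibraryEntry(f"HAIRPIN_{i:04d}", "HAIRPIN", insert, len(insert), design_gc=gc)
        )
    for i in range(n_g4):
        insert = _sample_tetrad(rng, "G")
        entries.append(LibraryEntry(f"G4_{i:04d}", "G4", insert, len(insert)))
    for i in range(n_imot):
        insert = _sample_tetrad(rng, "C")
        entries.append(LibraryEntry(f"IMOT_{i:04d}", "IMOT", insert, len(insert)))
    for i in range(n_random):
        gc = float(rng.uniform(0.20, 0.80))
        insert = _random_seq(rng, 72, gc)
        entries.append(
            LibraryEntry(f"RANDOM_{i:04d}", "RANDOM", insert, 72, design_gc=gc)
        )
    return entries


def _no_homopolymer_run(codes: np.ndarray, max_run: int = 2) -> bool:
    run = 1
    for i in range(1, len(codes)):
        run = run + 1 if codes[i] == codes[i - 1] else 1
        if run > max_run:
            return False
    return True


def assign_barcodes(
    n: int, length: int = BARCODE_LENGTH, min_dist: int = 3, seed: int = 0
) -> list[str]:
    """Greedy seeded barcode accumulation.

    Candidates are drawn base-by-base forbidding any homopolymer run of
    3 nt and accepted only if their Hamming distance to every accepted
    barcode is >= *min_dist* (Gilbert-Varshamov-style construction; the
    12-nt/4-letter code space vastly exceeds 20,000 words at distance 3).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, length), dtype=np.uint8)
    count = 0
    attempts = 0
    max_attempts = 200 * n + 10_000
    while count < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(f"barcode space exhausted after {count} barcodes")
        cand = np.empty(length, dtype=np.uint8)
        cand[0] = rng.integers(4)
        for i in range(1, length):
            if i >= 2 and cand[i - 1] == cand[i - 2]:
                choices = np.delete(np.arange(4), cand[i - 1])
                cand[i] = choices[rng.integers(3)]
            else:
                cand[i] = rng.integers(4)
        if count and int((accepted[:count] != cand).sum(axis=1).min()) < min_dist:
            continue
        accepted[count] = cand
        count += 1
    return ["".join("ACGT"[c] for c in row) for row in accepted]


def assemble_oligo(insert: str, barcode: str) -> str:
    """P1 flank + insert + spacer + barcode + P2 flank, exactly 150 nt.

    The barcode sits at the 3' edge of the designed payload so that it is
    always read, and the constant spacer absorbs the length difference
    between 24/48/72-nt inserts.
    """
    _check_dna(insert)
    if len(barcode) != BARCODE_LENGTH:
        raise ValueError(f"barcode must be {BARCODE_LENGTH} nt, got {len(barcode)}")
    spacer_len = PAYLOAD - len(insert)
    if spacer_len < 0:
        raise ValueError(
            f"insert of {len(insert)} nt exceeds payload of {PAYLOAD} nt"
        )
    oligo = P1_FLANK + insert + _SPACER[:spacer_len] + barcode + P2_FLANK
    assert len(oligo) == OLIGO_LENGTH
    return oligo


def build_library(
    catalog: Sequence[MotifRecord],
    n_hairpin: int = 960,
    n_g4: int = 1500,
    n_imot: int = 472,
    n_random: int = 1000,
    seed: int = 0,
) -> list[LibraryEntry]:
    """Full barcoded library: STR inserts plus all control classes."""
    entries = design_str_inserts(catalog) + design_controls(
        n_hairpin, n_g4, n_imot, n_random, seed=seed
    )
    barcodes = assign_barcodes(len(entries), seed=seed + 1)
    for entry, barcode in zip(entries, barcodes):
        entry.barcode = barcode
        entry.oligo = assemble_oligo(entry.insert, barcode)
    return entries


def pairwise_min_hamming(barcodes: Sequence[str], chunk: int = 512) -> int:
    """Minimum pairwise Hamming distance across a barcode set (vectorized)."""
    arr = np.array([[ord(c) for c in b] for b in barcodes], dtype=np.uint8)
    n = len(arr)
    best = arr.shape[1]
    for start in range(0, n, chunk):
        block = arr[start : start + chunk]
        d = (block[:, None, :] != arr[None, start:, :]).sum(axis=2)
        iu = np.triu_indices(block.shape[0], k=1, m=d.shape[1])
        mask = np.ones_like(d, dtype=bool)
        for i in range(block.shape[0]):
            mask[i, : i + 1] = False
        if mask.any():
            best = min(best, int(d[mask].min()))
    return best


def write_fasta(entries: Sequence[LibraryEntry], path, what: str = "oligo") -> None:
    """FASTA of oligos or inserts via Biopython."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(getattr(e, what)), id=e.entry_id, description="")
        for e in entries
    ]
    SeqIO.write(records, path, "fasta")


def manifest_dataframe(entries: Sequence[LibraryEntry]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "entry_id": e.entry_id,
                "category": e.category,
                "motif": e.motif or "",
                "insert_length": e.insert_length,
                "barcode": e.barcode,
            }
            for e in entries
        ]
    )
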