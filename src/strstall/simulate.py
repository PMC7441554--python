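"""Synthetic pooled primer-extension assay.

This module replaces the wet-lab experiment with a generative model so
that the entire analysis pipeline can be exercised and validated
end-to-end. Each library entry receives a ground-truth structural class
(HAIRP, IMOT, QUAD or UNF) and stalling kinetics sigma(t) =
min(1, sigma0 * exp(lam * t)): hairpins resolve over time (lam < 0),
tetrahelical structures stall persistently (lam > 0), unfolded
sequences barely stall (small sigma0, |lam| ~ 0). Reads are then
partitioned binomially between the stalled and extended fractions at
each time point, stalled-read 3' ends drift into the repeat at a
class-dependent rate, and extended reads acquire base substitutions
(more frequent at high sigma) and unit-multiple slippage indels with
geometric step sizes (less frequent at high sigma).

Everything is seeded; per-entry substreams are derived by stable
hashing of the entry id so that the simulation is reproducible and
independent of entry order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library import LibraryEntry

TIME_POINTS = (0.5, 1.0, 2.0, 4.0, 30.0)
CLASSES = ("HAIRP", "IMOT", "QUAD", "UNF")

#: default ground-truth parameter ranges per structural class:
#: (sigma0 low/high, lambda low/high [1/min])
DEFAULT_CLASS_RANGES: dict[str, tuple[float, float, float, float]] = {
    "UNF": (0.05, 0.15, -0.01, 0.01),
    "HAIRP": (0.30, 0.60, -0.15, -0.03),
    "QUAD": (0.40, 0.70, 0.03, 0.10),
    "IMOT": (0.25, 0.50, 0.02, 0.08),
}

#: probability that a designed control actually folds under assay
#: conditions; a substantial fraction of rationally designed structures
#: stay unfolded (roughly 4/9 of hairpins, 2/3 of G4s, 2/9 of i-motifs
#: retain their designed structure), so unfolded truths appear in every
#: designed category. Entries that fail to fold become UNF.
DEFAULT_FOLD_PROBABILITY: dict[str, float] = {
    "HAIRPIN": 427 / 960,
    "G4": 983 / 1500,
    "IMOT": 105 / 472,
}


def entry_rng(seed: int, entry_id: str, stream: int = 0) -> np.random.Generator:
    """Per-entry substream via CRC32 of the entry id (order independent)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(entry_id.encode()), stream])
    )


@dataclass
class GroundTruth:
    entry_id: str
    true_class: str
    sigma0: float
    lam: float
    stall_site: float
    drift_rate: float
    bs_rate: float
    ec_rate: float
    step_p: float

    def sigma(self, t: float) -> float:
        return min(1.0, self.sigma0 * np.exp(self.lam * t))


def default_class_map(entry: LibraryEntry) -> str:
    """Map a designed category to a ground-truth structural class.

    Controls follow their design. STR inserts are assigned from their
    G-quadruplex propensity: strongly G-skewed motifs fold into G4s,
    strongly C-skewed ones into i-motifs, GC-balanced high-entropy
    motifs into hairpins, the rest stay unfolded.
    """
    if entry.category == "HAIRPIN":
        return "HAIRP"
    if entry.category == "G4":
        return "QUAD"
    if entry.category == "IMOT":
        return "IMOT"
    if entry.category == "RANDOM":
        return "UNF"
    from .motifs import sequence_features

    gc, entropy, g4h = sequence_features(entry.insert)
    if g4h >= 0.8:
        return "QUAD"
    if g4h <= -0.8:
        return "IMOT"
    if gc >= 0.5 and entropy >= 0.9 and abs(g4h) < 0.3:
        return "HAIRP"
    return "UNF"


def sample_ground_truth(
    entries: Sequence[LibraryEntry],
    class_map=default_class_map,
    seed: int = 0,
    class_ranges: Mapping[str, tuple[float, float, float, float]] | None = None,
    fold_probability: Mapping[str, float] | None = None,
) -> list[GroundTruth]:
    """Draw per-entry kinetic and mutational parameters.

    Designed controls fold with the category's *fold_probability* and
    otherwise become UNF. Substitution rates increase, and slippage
    rates decrease, linearly with sigma0 (the simulator's knob for
    structure-coupled fidelity).
    """
    ranges = dict(DEFAULT_CLASS_RANGES if class_ranges is None else class_ranges)
    fold_p = dict(DEFAULT_FOLD_PROBABILITY if fold_probability is None else fold_probability)
    truths = []
    for entry in entries:
        cls = class_map(entry)
        if cls not in ranges:
            raise KeyError(f"no parameter range for class {cls!r}")
        rng = entry_rng(seed, entry.entry_id)
        if entry.category in fold_p and rng.random() > fold_p[entry.category]:
            cls = "UNF"
        s_lo, s_hi, l_lo, l_hi = ranges[cls]
        sigma0 = float(rng.uniform(s_lo, s_hi))
        lam = float(rng.uniform(l_lo, l_hi))
        truths.append(
            GroundTruth(
                entry_id=entry.entry_id,
                true_class=cls,
                sigma0=sigma0,
                lam=lam,
                stall_site=float(rng.uniform(2.0, max(entry.insert_length / 3.0, 3.0))),
                drift_rate=float(rng.uniform(0.5, 1.5)) if lam < 0 else float(rng.uniform(0.0, 0.2)),
                bs_rate=0.001 + 0.02 * sigma0,
                ec_rate=max(0.3 * (1.0 - sigma0), 0.01),
                step_p=0.7,
            )
        )
    return truths


#: multiplicative log-normal dispersion of sigma between replicate
#: measurements; emulates independent template preparations, whose
#: variability dominates counting noise in pooled assays (real
#: replicate rank correlations are substantially below 1)
DEFAULT_REPLICATE_NOISE_SD = 0.35


def simulate_counts(
    truths: Sequence[GroundTruth],
    depth: int = 10_000,
    replicates: int = 2,
    times: Sequence[float] = TIME_POINTS,
    seed: int = 0,
    replicate_noise_sd: float = DEFAULT_REPLICATE_NOISE_SD,
) -> pd.DataFrame:
    """Stalled/extended read counts per entry, time point and replicate.

    Per entry the sequenced total is Poisson around *depth* (pooled-
    library abundance dispersion); the stalled count is binomial with
    probability sigma(t) jittered by log-normal replicate dispersion.
    Returns a long-format table with one row per (entry, time,
    replicate) and raw counts for both fractions.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rows = []
    for truth in truths:
        rng = entry_rng(seed, truth.entry_id, stream=1)
        for rep in range(1, replicates + 1):
            for t in times:
                n = int(rng.poisson(depth))
                # dispersion perturbs the kinetic amplitude inside the
                # clamp: saturated entries stay stalled-fraction-only
                jitter = float(np.exp(rng.normal(0.0, replicate_noise_sd)))
                p = min(truth.sigma0 * jitter * float(np.exp(truth.lam * t)), 1.0)
                stalled = int(rng.binomial(n, p)) if n else 0
                rows.append(
                    {
                        "entry_id": truth.entry_id,
                        "time_min": t,
                        "replicate": rep,
                        "stalled_reads": stalled,
                        "extended_reads": n - stalled,
                    }
                )
    return pd.DataFrame(rows)


def simulate_coverage(
    truth: GroundTruth,
    insert_length: int,
    times: Sequence[float] = TIME_POINTS,
    read_depth: int = 2000,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-position stalled-product coverage over the insert.

    Stalled-read 3' ends sit at stall_site + drift_rate*(t - 0.5) with
    Gaussian noise (sd 2 nt), truncated to the insert. Coverage at
    position p counts reads whose synthesis extended past p, so each
    profile is monotone non-increasing with a sigmoidal transition whose
    midpoint advances with time when the polymerase travels.
    """
    rng = entry_rng(seed, truth.entry_id, stream=2)
    rows = []
    for t in times:
        center = truth.stall_site + truth.drift_rate * (t - 0.5)
        ends = rng.normal(center, noise_sd, size=read_depth)
        ends = np.clip(ends, 0.0, float(insert_length))
        positions = np.arange(insert_length + 1)
        coverage = (ends[None, :] >= positions[:, None]).sum(axis=1)
        for pos, cov in enumerate(coverage):
            rows.append(
                {
                    "entry_id": truth.entry_id,
                    "time_min": t,
                    "position": pos,
                    "count": int(cov),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AlignedRead:
    """Minimal aligned-read record (SAM-representable)."""

    qname: str
    rname: str
    pos: int  # 0-based leftmost reference position
    cigar: str
    seq: str
    qual: str
    flag: int = 0


@dataclass
class ParentalVariant:
    entry_id: str
    position: int
    ref: str
    alt: str


def _apply_substitutions(seq: list[str], rng: np.random.Generator, rate: float) -> None:
    for i in range(len(seq)):
        if rng.random() < rate:
            seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))


def simulate_reads_with_variants(
    truth: GroundTruth,
    entry: LibraryEntry,
    n_reads: int = 200,
    parental_fraction: float = 0.0,
    base_quality: int = 35,
    seed: int = 0,
    bs_rate: float | None = None,
    ec_rate: float | None = None,
) -> tuple[list[AlignedRead], list[ParentalVariant]]:
    """Extended-product reads over an STR insert with mutations.

    Each read spans the whole insert. With probability ec_rate it slips
    by k repeat units (k geometric with parameter step_p, sign chosen at
    random, in-register insertion or deletion); each base then mutates
    with probability bs_rate. If parental_fraction > 0 one fixed
    substitution is injected both into the parental variant set and into
    that fraction of reads, providing material for the de-novo filter.
    """
    if entry.category != "STR":
        raise ValueError(f"entry {entry.entry_id} is not an STR")
    rng = entry_rng(seed, entry.entry_id, stream=3)
    ref = entry.insert
    unit = entry.motif if entry.motif else ref
    unit_size = len(unit)
    bs = truth.bs_rate if bs_rate is None else bs_rate
    ec = truth.ec_rate if ec_rate is None else ec_rate

    parental: list[ParentalVariant] = []
    if parental_fraction > 0:
        p_pos = int(rng.integers(0, len(ref)))
        p_alt = str(rng.choice([b for b in "ACGT" if b != ref[p_pos]]))
        parental.append(ParentalVariant(entry.entry_id, p_pos, ref[p_pos], p_alt))

    reads = []
    for i in range(n_reads):
        seq = list(ref)
        cigar_ops: list[tuple[int, str]] = [(len(ref), "M")]
        if rng.random() < ec:
            k = int(rng.geometric(truth.step_p))
            sign = 1 if rng.random() < 0.5 else -1
            max_units = len(ref) // unit_size
            if sign < 0:
                k = min(k, max_units - 1)
            if k >= 1:
                # slip at an in-register unit boundary; contractions only
                # where k whole units remain downstream
                if sign > 0:
                    boundary = int(rng.integers(1, max_units)) * unit_size
                    block = ref[boundary - unit_size : boundary] * k
                    seq = list(ref[:boundary]) + list(block) + list(ref[boundary:])
                    cigar_ops = [
                        (boundary, "M"),
                        (len(block), "I"),
                        (len(ref) - boundary, "M"),
                    ]
                else:
                    boundary = int(rng.integers(1, max_units - k + 1)) * unit_size
                    del_len = k * unit_size
                    seq = list(ref[:boundary]) + list(ref[boundary + del_len :])
                    cigar_ops = [
                        (boundary, "M"),
                        (del_len, "D"),
                        (len(ref) - boundary - del_len, "M"),
                    ]
        _apply_substitutions(seq, rng, bs)
        for pv in parental:
            if parental_fraction > 0 and rng.random() < parental_fraction:
                if cigar_ops == [(len(ref), "M")] and len(seq) == len(ref):
                    seq[pv.position] = pv.alt
        cigar = "".join(f"{n}{op}" for n, op in cigar_ops if n > 0)
        read_seq = "".join(seq)
        reads.append(
            AlignedRead(
                qname=f"{entry.entry_id}_r{i}",
                rname=entry.entry_id,
                pos=0,
                cigar=cigar,
                seq=read_seq,
                qual=chr(base_quality + 33) * len(read_seq),
            )
        )
    return reads, parental


def write_sam(
    reads: Iterable[AlignedRead], references: Mapping[str, str], path: str
) -> None:
    """Minimal SAM writer (QNAME/FLAG/RNAME/POS/CIGAR/SEQ/QUAL)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in reads:
            fh.write(
                f"{r.qname}\t{r.flag}\t{r.rname}\t{r.pos + 1}\t60\t{r.cigar}\t"
                f"*\t0\t0\t{r.seq}\t{r.qual}\n"
            )


def read_sam(path: str) -> list[AlignedRead]:
    """Load aligned reads from a SAM file via pysam."""
    import pysam

    reads = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            reads.append(
                AlignedRead(
                    qname=rec.query_name,
                    rname=rec.reference_name,
                    pos=rec.reference_start,
                    cigar=rec.cigarstring,
                    seq=rec.query_sequence,
                    qual="".join(chr(q + 33) for q in rec.query_qualities)
                    if rec.query_qualities is not None
                    else "I" * len(rec.query_sequence),
                    flag=rec.flag,
                )
            )
    return reads


def write_parental_vcf(
    variants: Sequence[ParentalVariant], references: Mapping[str, str], path: str
) -> None:
    """Parental variant set as a minimal VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in references.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.entry_id}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n"
            )


def counts_dataframe_to_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index=False)
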