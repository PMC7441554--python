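"""Genomic behaviour of STRs: abundance, length, mutability and SNP density.

Per-motif stall scores measured in vitro are joined to genomic STR
annotations to ask whether structure-prone repeats are rarer, shorter,
more length-stable and more often interrupted by point mutations.
Loci are grouped by the canonical double-stranded class of their repeat
unit (reverse-strand annotations collapse onto the same class) and
binned by the class mean stall score. Mutability parameters are the
per-generation length mutation rate mu, the length-constraint strength
beta and the single-step probability p of the geometric step-size
model; loci shorter than 12 nt, mononucleotide repeats and loci with
mu <= 10^-7.5 (the quantification floor) are excluded from mutability
analyses.

SNP density around repeat boundaries is the fraction of loci carrying a
SNP at a given position relative to the repeat start or end. Boundary
enrichment between two locus subsets is a two-sided Fisher exact test
on the 2x2 table of boundary-marked versus unmarked loci.

A seeded genome-fixture generator emits loci/SNP/parameter files with
planted effect sizes so every statistic here is testable without any
genome download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import canonical_ds_class

MU_QUANTIFICATION_FLOOR = 10 ** -7.5
MIN_LOCUS_LENGTH = 12

#: positions tested for boundary enrichment, as (anchor, offset) pairs:
#: one base either side of the first and last repeat base
BOUNDARY_OFFSETS = (("start", -1), ("start", 1), ("end", -1), ("end", 1))


@dataclass
class GenomicLocus:
    chrom: str
    start: int  # 0-based half-open
    end: int
    motif: str
    ds_class: str = ""
    mu: float | None = None
    beta: float | None = None
    step_p: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end {self.end} <= start {self.start}")
        if not self.ds_class:
            self.ds_class = canonical_ds_class(self.motif)

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def mononucleotide(self) -> bool:
        return len(set(self.motif)) == 1


def load_str_loci(
    path: str, one_based: bool = False, max_skip_fraction: float = 0.10
) -> tuple[list[GenomicLocus], list[str]]:
    """Read a BED-like/MSDB-style locus table (chrom, start, end, motif).

    MSDB-style 1-based inclusive coordinates are converted to 0-based
    half-open. Malformed rows are skipped with a logged message; more
    than *max_skip_fraction* skipped rows aborts the load. Returns
    (loci, skipped-row messages); mononucleotide repeats are kept but
    flagged via :attr:`GenomicLocus.mononucleotide` for exclusion.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "motif"}
    if not required.issubset(table.columns):
        raise ValueError(f"locus table must have columns {sorted(required)}")
    loci, errors = [], []
    for i, row in table.iterrows():
        try:
            start = int(row["start"]) - (1 if one_based else 0)
            end = int(row["end"])
            loci.append(GenomicLocus(str(row["chrom"]), start, end, str(row["motif"])))
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i}: {exc}")
    if len(errors) > max_skip_fraction * max(len(table), 1):
        raise ValueError(f"{len(errors)}/{len(table)} rows malformed")
    return loci, errors


def write_loci(loci: Sequence[GenomicLocus], path: str) -> None:
    pd.DataFrame(
        [
            {"chrom": l.chrom, "start": l.start, "end": l.end, "motif": l.motif}
            for l in loci
        ]
    ).to_csv(path, sep="\t", index=False)


def abundance_and_length_by_score(
    loci: Sequence[GenomicLocus],
    motif_scores: Mapping[str, float],
    bins: Sequence[float],
    top_n_lengths: int = 1000,
) -> pd.DataFrame:
    """Bin loci by class mean stall score; per-bin counts and lengths.

    Mononucleotide repeats and loci of unscored classes are excluded.
    The per-bin length distribution keeps only the *top_n_lengths*
    longest instances, so extreme achievable length is compared rather
    than the bulk (dominated by short loci in every bin).
    """
    rows = []
    for locus in loci:
        if locus.mononucleotide or locus.ds_class not in motif_scores:
            continue
        rows.append(
            {"sigma": motif_scores[locus.ds_class], "length": locus.length_nt}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no scorable loci")
    df["bin"] = pd.cut(df["sigma"], bins=list(bins), include_lowest=True)
    out = []
    for interval, grp in df.groupby("bin", observed=False):
        lengths = grp["length"].nlargest(top_n_lengths)
        out.append(
            {
                "bin": interval,
                "n_loci": len(grp),
                "median_top_length": float(lengths.median()) if len(lengths) else np.nan,
                "max_length": int(grp["length"].max()) if len(grp) else 0,
            }
        )
    return pd.DataFrame(out)


def join_mutability(
    loci: Sequence[GenomicLocus], params: pd.DataFrame
) -> list[GenomicLocus]:
    """Attach (mu, beta, p) keyed by locus interval and apply exclusions:
    mononucleotides, loci < 12 nt, and mu <= 10^-7.5 (below the
    quantification floor of the mutation-rate model)."""
    keyed = params.set_index(["chrom", "start", "end"])
    joined = []
    misses = 0
    for locus in loci:
        key = (locus.chrom, locus.start, locus.end)
        if key not in keyed.index:
            misses += 1
            continue
        row = keyed.loc[key]
        locus.mu = float(row["mu"])
        locus.beta = float(row["beta"])
        locus.step_p = float(row["p"])
        joined.append(locus)
    if misses > 0.5 * len(loci):
        raise ValueError(f"{misses}/{len(loci)} loci missing from parameter table")
    return [
        l
        for l in joined
        if not l.mononucleotide
        and l.length_nt >= MIN_LOCUS_LENGTH
        and l.mu > MU_QUANTIFICATION_FLOOR
    ]


def _snp_positions_by_chrom(snp_positions: Iterable[tuple[str, int]]):
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in snp_positions:
        by_chrom.setdefault(chrom, []).append(pos)
    return {c: np.unique(p) for c, p in by_chrom.items()}


def read_snp_vcf(path: str) -> list[tuple[str, int]]:
    """SNP (chrom, 0-based pos) pairs from a VCF; non-SNP records skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            ref, alt = fields[3], fields[4]
            if len(ref) == 1 and all(len(a) == 1 for a in alt.split(",")):
                out.append((fields[0], int(fields[1]) - 1))
    return out


def boundary_positions(locus: GenomicLocus) -> list[int]:
    """Genomic positions tested for boundary SNPs.

    Anchors are the first repeat base (start) and the last repeat base
    (end - 1); offsets of -1/+1 from each anchor give one flanking and
    one just-internal base per boundary.
    """
    anchors = {"start": locus.start, "end": locus.end - 1}
    return sorted({anchors[a] + off for a, off in BOUNDARY_OFFSETS})


def snp_density_profile(
    loci: Sequence[GenomicLocus],
    snp_positions: Iterable[tuple[str, int]],
    flank: int = 10,
) -> pd.DataFrame:
    """Fraction of loci with a SNP at each position relative to the
    repeat start and end anchors, offsets in [-flank, +flank]."""
    snps = _snp_positions_by_chrom(snp_positions)
    offsets = np.arange(-flank, flank + 1)
    counts = {("start", int(o)): 0 for o in offsets}
    counts.update({("end", int(o)): 0 for o in offsets})
    n = 0
    for locus in loci:
        positions = snps.get(locus.chrom)
        n += 1
        if positions is None or len(positions) == 0:
            continue
        for anchor, base in (("start", locus.start), ("end", locus.end - 1)):
            window = base + offsets
            hits = positions[np.searchsorted(positions, window[0]) : np.searchsorted(positions, window[-1], side="right")]
            for h in hits:
                counts[(anchor, int(h - base))] += 1
    if n == 0:
        raise ValueError("no loci")
    rows = [
        {"anchor": a, "offset": o, "density": c / n}
        for (a, o), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    contingency: np.ndarray  # [[A marked, A unmarked], [B marked, B unmarked]]
    comparison: str


def _locus_marked(locus: GenomicLocus, snps: Mapping[str, np.ndarray]) -> bool:
    positions = snps.get(locus.chrom)
    if positions is None:
        return False
    return any(
        positions[np.searchsorted(positions, p)] == p
        if np.searchsorted(positions, p) < len(positions)
        else False
        for p in boundary_positions(locus)
    )


def boundary_enrichment(
    loci_a: Sequence[GenomicLocus],
    loci_b: Sequence[GenomicLocus],
    snp_positions: Iterable[tuple[str, int]],
    comparison: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of boundary-SNP marking, A versus B.

    The 2x2 table counts loci with/without a SNP at any of the four
    boundary-adjacent positions. The odds ratio uses a 0.5 continuity
    correction when any cell is empty (the P value stays exact).
    """
    snps = _snp_positions_by_chrom(snp_positions)
    a_marked = sum(_locus_marked(l, snps) for l in loci_a)
    b_marked = sum(_locus_marked(l, snps) for l in loci_b)
    table = np.array(
        [
            [a_marked, len(loci_a) - a_marked],
            [b_marked, len(loci_b) - b_marked],
        ]
    )
    p_value = float(stats.fisher_exact(table, alternative="two-sided")[1])
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    odds_ratio = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    return EnrichmentResult(
        odds_ratio=odds_ratio,
        p_value=p_value,
        contingency=table,
        comparison=comparison or f"A(n={len(loci_a)}) vs B(n={len(loci_b)}) at boundary +/-1",
    )


def fisher_exact_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher P by exhaustive hypergeometric enumeration.

    Independent oracle for the exact test: sums P(X=k) over every table
    with the observed margins whose probability does not exceed the
    observed table's (with a tiny relative tolerance for float ties).
    """
    table = np.asarray(table, dtype=int)
    r1 = table[0].sum()
    c1 = table[:, 0].sum()
    n = table.sum()
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(table[0, 0], n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


# ---------------------------------------------------------------------------
# synthetic genome fixture


@dataclass
class FixtureConfig:
    """Planted effect sizes for the synthetic genome fixture.

    The fixture emulates a genome-scale STR annotation: per-class
    abundance decreasing with stall score, locus length decreasing with
    stall score, log-normal mutation rates decreasing (and length
    constraints increasing) with stall score, and a boundary SNP
    enrichment of configurable odds ratio at length-unstable loci.
    """

    motif_sigma: dict[str, float]  # ds_class -> mean stall score
    n_loci: int = 10_000
    chrom: str = "chrSim"
    locus_spacing: int = 100
    abundance_coupling: float = 2.0  # weight ~ exp(-coupling * sigma)
    base_length: float = 40.0  # mean extra length at sigma = 0
    length_coupling: float = 2.0  # mean length ~ base * exp(-coupling * sigma)
    mu_log10_intercept: float = -7.0
    mu_log10_slope: float = -1.5  # log10 mu ~ intercept + slope * sigma
    mu_log10_sd: float = 0.4
    beta_intercept: float = 0.2
    beta_slope: float = 0.5
    step_p: float = 0.8
    snp_background: float = 0.01  # per-position SNP probability in flanks
    boundary_snp_stable: float = 0.05  # per boundary-position, stable loci
    boundary_odds_ratio: float = 2.5  # planted enrichment at unstable loci
    flank: int = 10


def generate_genome_fixture(
    config: FixtureConfig, seed: int = 0
) -> tuple[list[GenomicLocus], list[tuple[str, int]], pd.DataFrame, dict]:
    """Emit (loci, SNPs, mutability parameters, truth sidecar).

    All randomness flows from *seed*; the truth dict records every
    planted effect size for recovery tests.
    """
    if not config.motif_sigma:
        raise ValueError("motif_sigma must be non-empty")
    rng = np.random.default_rng(seed)
    motifs = sorted(config.motif_sigma)
    sigmas = np.array([config.motif_sigma[m] for m in motifs])
    weights = np.exp(-config.abundance_coupling * sigmas)
    weights /= weights.sum()

    # per-locus boundary marking probability: odds-scaled for unstable loci
    p_stable = config.boundary_snp_stable
    odds_unstable = config.boundary_odds_ratio * p_stable / (1 - p_stable)
    p_unstable = odds_unstable / (1 + odds_unstable)

    loci: list[GenomicLocus] = []
    snps: set[tuple[str, int]] = set()
    params_rows = []
    cursor = 200
    for _ in range(config.n_loci):
        idx = int(rng.choice(len(motifs), p=weights))
        motif, sigma = motifs[idx], float(sigmas[idx])
        period = len(motif)
        mean_units = max(config.base_length * np.exp(-config.length_coupling * sigma) / period, 2.0)
        n_units = 2 + int(rng.geometric(1.0 / max(mean_units - 1.0, 1.0)))
        length = n_units * period
        start = cursor
        end = start + length
        locus = GenomicLocus(config.chrom, start, end, motif)
        log10_mu = rng.normal(
            config.mu_log10_intercept + config.mu_log10_slope * sigma,
            config.mu_log10_sd,
        )
        locus.mu = float(10**log10_mu)
        locus.beta = float(max(config.beta_intercept + config.beta_slope * sigma + rng.normal(0, 0.05), 0.01))
        locus.step_p = config.step_p
        loci.append(locus)
        params_rows.append(
            {
                "chrom": locus.chrom,
                "start": start,
                "end": end,
                "mu": locus.mu,
                "beta": locus.beta,
                "p": locus.step_p,
            }
        )
        # background SNPs in the flanks, sparing the tested boundary
        # positions so the planted odds ratio is not diluted
        tested = set(boundary_positions(locus))
        for pos in range(start - config.flank, start):
            if pos not in tested and rng.random() < config.snp_background:
                snps.add((config.chrom, pos))
        for pos in range(end, end + config.flank):
            if pos not in tested and rng.random() < config.snp_background:
                snps.add((config.chrom, pos))
        # planted boundary enrichment, stability defined by the mu floor
        p_mark = p_unstable if locus.mu > MU_QUANTIFICATION_FLOOR else p_stable
        if rng.random() < p_mark:
            snps.add((config.chrom, int(rng.choice(boundary_positions(locus)))))
        cursor = end + config.locus_spacing

    truth = {
        "boundary_odds_ratio": config.boundary_odds_ratio,
        "p_boundary_stable": p_stable,
        "p_boundary_unstable": p_unstable,
        "abundance_coupling": config.abundance_coupling,
        "length_coupling": config.length_coupling,
        "mu_log10_slope": config.mu_log10_slope,
        "seed": seed,
    }
    return loci, sorted(snps), pd.DataFrame(params_rows), truth


def write_fixture(
    loci: Sequence[GenomicLocus],
    snps: Sequence[tuple[str, int]],
    params: pd.DataFrame,
    truth: dict,
    prefix: str,
) -> None:
    """Write loci TSV, SNP VCF, params TSV and truth JSON under *prefix*."""
    write_loci(loci, f"{prefix}_loci.tsv")
    params.to_csv(f"{prefix}_params.tsv", sep="\t", index=False)
    with open(f"{prefix}_snps.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in snps:
            fh.write(f"{chrom}\t{pos + 1}\t.\tA\tG\t.\tPASS\t.\n")
    with open(f"{prefix}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
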