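"""Short tandem repeat (STR) motif enumeration, canonicalization and features.

An STR motif is a 1-6 nt DNA unit repeated head-to-tail. Motifs are
*primitive* when they are not a whole-number power of a shorter unit
(``ACAC`` is not primitive, ``AC`` is). Two motifs describe the same
single-stranded repeat when they are cyclic rotations of each other
(``GAA`` and ``AAG``), and the same double-stranded genomic repeat when
additionally one is a rotation of the other's reverse complement
(``CAG`` and ``CTG``). The canonical representative of either
equivalence class is the lexicographically smallest member, which makes
class assignment deterministic and order-free.

Per-motif sequence features are the GC fraction, the Shannon entropy of
the base composition (bits), and a G-quadruplex propensity score in
[-4, 4] computed G4Hunter-style from runs of G (positive) and C
(negative). Pairwise motif similarity is the cosine of circular-bigram
count vectors, which is rotation invariant and therefore well defined on
single-stranded classes.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from sympy import divisors, mobius

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: all 16 dinucleotides in lexicographic order; index base for bigram vectors
BIGRAMS = ["".join(p) for p in itertools.product(DNA_ALPHABET, repeat=2)]
_BIGRAM_INDEX = {b: i for i, b in enumerate(BIGRAMS)}


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


def _check_dna(seq: str) -> str:
    if not seq:
        raise ValueError("empty DNA sequence")
    if any(c not in "ACGT" for c in seq):
        raise AlphabetError(f"non-ACGT character in {seq!r}")
    return seq


def reverse_complement(seq: str) -> str:
    return _check_dna(seq).translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if *motif* is not a whole-number power of a shorter string."""
    _check_dna(motif)
    n = len(motif)
    for d in divisors(n)[:-1]:
        if motif == motif[:d] * (n // d):
            return False
    return True


def rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def canonical_ss_class(motif: str) -> str:
    """Lexicographically smallest rotation: the single-stranded class label."""
    _check_dna(motif)
    return min(rotations(motif))


def canonical_ds_class(motif: str) -> str:
    """Smallest string over rotations of the motif and of its reverse
    complement: the double-stranded (strand-symmetric) class label."""
    _check_dna(motif)
    return min(min(rotations(motif)), min(rotations(reverse_complement(motif))))


def sequence_features(seq: str) -> tuple[float, float, float]:
    """Return ``(gc_fraction, entropy_bits, g4h_score)`` for a DNA string.

    entropy is the Shannon entropy of the base composition; g4h_score is
    the mean of per-position run scores: a base in a run of k G scores
    +min(k, 4), in a run of k C scores -min(k, 4), A/T score 0.
    """
    _check_dna(seq)
    n = len(seq)
    counts = Counter(seq)
    gc = (counts["G"] + counts["C"]) / n
    freqs = np.array([c / n for c in counts.values()])
    entropy = float(-(freqs * np.log2(freqs)).sum())
    score = 0.0
    for base, run in itertools.groupby(seq):
        k = len(list(run))
        if base == "G":
            score += k * min(k, 4)
        elif base == "C":
            score -= k * min(k, 4)
    return gc, max(entropy, 0.0), score / n


def hairpin_tm(stem_length: int, gc_fraction: float) -> float:
    """Wallace-rule hairpin stem melting temperature, Tm = L*(2*%GC + 2).

    Equivalent to 4 degC per G:C pair and 2 degC per A:T pair over a stem
    of L pairs with the given GC fraction.
    """
    if stem_length < 1:
        raise ValueError(f"stem_length must be >= 1, got {stem_length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction outside [0, 1]: {gc_fraction}")
    return stem_length * (2.0 * gc_fraction + 2.0)


def is_palindromic(motif: str) -> bool:
    return motif == reverse_complement(motif)


@dataclass(frozen=True)
class MotifRecord:
    """One STR motif with its equivalence classes and sequence features."""

    motif: str
    period: int
    primitive: bool
    ss_class: str
    ds_class: str
    gc_fraction: float
    entropy_bits: float
    g4h_score: float
    palindromic: bool

    @classmethod
    def from_motif(cls, motif: str) -> "MotifRecord":
        gc, h, g4h = sequence_features(motif)
        return cls(
            motif=motif,
            period=len(motif),
            primitive=is_primitive(motif),
            ss_class=canonical_ss_class(motif),
            ds_class=canonical_ds_class(motif),
            gc_fraction=gc,
            entropy_bits=h,
            g4h_score=g4h,
            palindromic=is_palindromic(motif),
        )


def enumerate_primitive_motifs(max_period: int) -> list[MotifRecord]:
    """All primitive motifs of period 1..max_period, lexicographic order.

    With max_period=6 this yields the 5356 possible STR repeat units.
    """
    if not 1 <= max_period <= 8:
        raise ValueError(f"max_period must be in [1, 8], got {max_period}")
    records = []
    for n in range(1, max_period + 1):
        for letters in itertools.product(DNA_ALPHABET, repeat=n):
            motif = "".join(letters)
            if is_primitive(motif):
                records.append(MotifRecord.from_motif(motif))
    return records


def count_primitive_closed_form(period: int) -> int:
    """Mobius closed form for the number of primitive strings of a period."""
    return int(sum(mobius(period // d) * 4**d for d in divisors(period)))


def count_ss_classes_closed_form(period: int) -> int:
    """Number of rotation classes of primitive motifs of a period
    (primitive necklaces): count_primitive(period) / period."""
    return count_primitive_closed_form(period) // period


def bigram_vector(motif: str) -> np.ndarray:
    """16-component circular (wrap-around) bigram count vector.

    Circularity gives period-1 motifs a defined vector and makes the
    vector, hence any similarity built on it, rotation invariant.
    """
    _check_dna(motif)
    vec = np.zeros(16, dtype=int)
    n = len(motif)
    for i in range(n):
        vec[_BIGRAM_INDEX[motif[i] + motif[(i + 1) % n]]] += 1
    return vec


def cosine_similarity(motif_a: str, motif_b: str) -> float:
    a, b = bigram_vector(motif_a), bigram_vector(motif_b)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


@dataclass
class SimilarityMatrix:
    motif_ids: list[str]
    values: np.ndarray
    bigram_vectors: np.ndarray  # (n_motifs, 16) counts

    def __post_init__(self) -> None:
        n = len(self.motif_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")


def similarity_matrix(motifs: Sequence[str]) -> SimilarityMatrix:
    """Pairwise cosine similarity over circular-bigram vectors."""
    vecs = np.array([bigram_vector(m) for m in motifs], dtype=float)
    norms = np.linalg.norm(vecs, axis=1)
    values = (vecs @ vecs.T) / np.outer(norms, norms)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(motifs), np.clip(values, 0.0, 1.0), vecs.astype(int))


def cluster_motifs(similarity: SimilarityMatrix) -> np.ndarray:
    """Average-linkage agglomerative clustering on distance = 1 - similarity.

    Returns a scipy linkage matrix; leaves are the motif_ids in their
    input order (sort the input lexicographically for a deterministic
    tie-break).
    """
    dist = 1.0 - similarity.values
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least two motifs to cluster")
    condensed = dist[np.triu_indices(n, k=1)]
    return hierarchy.average(condensed)


def dendrogram_to_newick(linkage: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


def catalog_dataframe(records: Iterable[MotifRecord]):
    """Motif catalog as a pandas DataFrame (TSV-writable)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "motif": r.motif,
                "period": r.period,
                "ss_class": r.ss_class,
                "ds_class": r.ds_class,
                "gc": r.gc_fraction,
                "entropy": r.entropy_bits,
                "g4h": r.g4h_score,
                "palindromic": r.palindromic,
            }
            for r in records
        ]
    )
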