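# Methods

## Motif combinatorics

A repeat unit is *primitive* when it is not a whole-number power of a
shorter string; there are `Σ_{d|n} μ(n/d)·4^d` primitive units of
period n (Möbius inversion), totalling 5,356 for n ≤ 6. The
single-stranded class of a unit is its orbit under cyclic rotation
(964 classes for n ≤ 6, equal to the primitive-necklace count
`(1/n) Σ_{d|n} μ(n/d)·4^d` summed over n); the double-stranded class
additionally merges the reverse-complement orbit (501 classes). The
canonical representative of either class is the lexicographic minimum
of the orbit — deterministic and independent of input order.

Sequence features per motif: GC fraction; Shannon entropy of the base
*composition* in bits (the positional-frequency form of the entropy is
degenerate for a single sequence, so composition frequencies are used);
and a G4Hunter-style score in [−4, 4] where a base in a run of k G
(resp. C) scores +min(k, 4) (resp. −min(k, 4)) and the score is the
*mean* over positions, matching the convention of the score's original
definition. Hairpin stem stability uses the Wallace rule,
Tm = L·(2·%GC + 2) °C for a stem of L pairs.

Motif similarity is the cosine of 16-component *circular* bigram count
vectors. Circularity gives period-1 motifs a defined vector and makes
similarity rotation-invariant, consistent with single-stranded class
semantics. Clustering is average-linkage agglomerative on
distance = 1 − similarity; ties are broken by presenting leaves in
lexicographic order. The linkage choice is ours — nothing in the
analysis depends on intra-cluster geometry beyond the grouping.

## Library design

16,068 STR inserts (5,356 units × 24/48/72 nt). Units whose period does
not divide the target length (period 5) are tiled and truncated at the
exact target length; the partial final unit is intentional, keeping all
inserts of a length column strictly comparable.

Controls: hairpins are `S + TTTT + revcomp(S)` with stems of 7–22 nt
and 20–80% GC (rejection-sampled, retry cap 10,000); G4s are four
G-tracts of 2–5 nt separated by three 1–9 nt loops whose terminal bases
avoid G so tract lengths are exactly as drawn; i-motifs are the C-tract
analogue; negative controls are 1,000 random 72-mers spanning 20–80%
GC. Defaults (960/1,500/472/1,000) complete a 20,000-entry library.

Barcodes: 12 nt, pairwise Hamming distance ≥ 3, no homopolymer run of
3+. Generation is greedy (Gilbert–Varshamov style): candidates are
drawn base-by-base with runs forbidden by construction and accepted
against the running set with a vectorized Hamming check; the code space
vastly exceeds 20,000 words at distance 3, so the greedy construction
terminates comfortably.

Oligos are exactly 150 nt: `P1-flank + insert + spacer + barcode +
P2-flank`, with the HindIII site in the upstream flank and BamHI in the
downstream flank. The spacer is one fixed neutral sequence (no
restriction sites, no homopolymer runs) truncated per insert length; a
constant spacer cannot confound per-entry comparisons. Its content is
otherwise arbitrary.

## Synthetic assay

The generator replaces the wet-lab experiment. Each entry gets a
ground-truth class and kinetics σ(t) = min(1, σ₀·e^{λt}):

| class | σ₀ | λ (min⁻¹) |
|-------|----|-----------|
| UNF   | 0.05–0.15 | −0.01–0.01 |
| HAIRP | 0.30–0.60 | −0.15–−0.03 |
| QUAD  | 0.40–0.70 | 0.03–0.10 |
| IMOT  | 0.25–0.50 | 0.02–0.08 |

Designed controls fold with probability 427/960 (hairpins), 983/1500
(G4s) and 105/472 (i-motifs) — the fractions of designed controls that
retain their designed label in a real pooled assay — and otherwise
become UNF. STR entries are classed deterministically from sequence:
G4Hunter score ≥ 0.8 → QUAD, ≤ −0.8 → IMOT, GC-balanced high-entropy →
HAIRP, else UNF.

Counts: per (entry, time, replicate) the sequenced total is Poisson
around the configured depth (pooled-library abundance dispersion; the
real dispersion of the pool is unknown, Poisson is a stand-in), and the
stalled count is Binomial with probability
min(1, σ₀·e^ε·e^{λt}), ε ~ N(0, 0.35²). The log-normal jitter models
replicate-preparation variability, which dominates counting noise in
pooled assays and keeps simulated replicate rank correlations
substantially below 1, as in real data; it perturbs the kinetic
amplitude *inside* the clamp so saturated entries remain
stalled-fraction-only. All randomness derives per-entry substreams from
one seed by hashing the entry id, so results are independent of entry
order.

Coverage: stalled-read 3′ ends sit at `stall_site + drift·(t − 0.5)`
with Gaussian noise (sd 2 nt) truncated to the insert; coverage counts
reads extending past each position, so profiles are monotone
non-increasing with a sigmoidal transition that advances with time when
the polymerase travels.

Reads: each extended read spans the insert; with probability `ec_rate`
it slips by k units (k geometric with parameter `step_p`, default 0.7;
expansion or contraction with equal probability, placed at an
in-register unit boundary), and each base substitutes with probability
`bs_rate`. The default coupling `bs_rate = 0.001 + 0.02·σ₀`,
`ec_rate = max(0.3·(1 − σ₀), 0.01)` encodes the qualitative
observation that structure-prone (high-σ) repeats suffer more point
mutations and fewer slippage events. An optional parental variant is
injected into both the parental set and a configurable fraction of
reads, to exercise the de-novo filter.

What the generator does **not** emulate: sequencer error models, PCR
duplicates, adapter/tail artifacts, alignment ambiguity, multiple stall
sites per insert, or real pool abundance dispersion. Tests passing on
this generator therefore validate the *analysis* (estimators, filters,
statistics) under a faithful generative model of the assay's design —
not the robustness of the pipeline to raw-sequencing artifacts.

## Stall scores and kinetics

CPM normalization is per (fraction, time, replicate); an entry absent
from a library receives a substitute raw count of 1 (CPM = 10⁶/total)
before normalization, keeping σ strictly inside (0, 1). The literal
alternative (raw count 1/total) yields CPM = 10⁶/total², which is
numerically indistinguishable from the 0/1 endpoints; the substitute
count is the usable reading.

σ = stalled_CPM/(stalled_CPM + extended_CPM). σ is scale-free in the
raw counts, and *relative*: it depends on the library composition
through the per-fraction totals, so σ values are comparable within a
run, not across differently composed pools.

Replicates: per-entry per-time mean and sd; entries whose mean sd
across time points exceeds the 95th percentile of that statistic are
flagged outliers and excluded downstream (exactly 5% on a continuous sd
distribution).

Kinetics: ln σ is regressed on t by ordinary least squares; λ is the
slope, σ₀ = exp(intercept), R² is the log-space coefficient of
determination clipped to [0, 1]. The log-linear fit is exact for the
exponential model, deterministic, and needs no initialization — the
reason it is preferred over nonlinear least squares. Fits need ≥ 3
positive σ values; failed fits are flagged and imputed with 0 in
classifier features. Known limitation: once σ saturates at 1 the model
is censored and λ is biased toward 0 for strongly stalling entries;
sign recovery is unaffected because the early time points and the
saturated plateau still pin the slope's sign.

Significance: per time point a one-sided (greater) Mann–Whitney U test
of the entry's replicate σs against the pooled replicate σs of the
random-GC controls — one-sided because structure can only elevate
stalling relative to unstructured sequence; pooling (rather than
per-entry averaging) keeps the control sample large for the exact
test. The per-time P values are combined by Fisher's method,
χ² = −2Σln Pᵢ with 2k df. Fisher's method assumes independent Pᵢ; for
entries whose σ₀ sits persistently in the upper tail of the control
range the per-time P values are correlated and the combined Q is
anticonservative. This is a property of the published procedure itself
(the same template preparations are measured at every time point), and
its consequence for training labels is discussed below.

## Structure classification

Eleven features per entry: σ at the five time points, Q, λ, R², GC,
G4Hunter score, entropy; centred and scaled with training statistics
inside a scikit-learn pipeline. Training labels: a designed structured
control keeps its designed class when Q ≤ 0.1 and becomes UNF
otherwise; the label universe is the structured controls only, and the
Q rule applies to *training labels* only — at prediction time the
classifier output is authoritative. The model is a 500-tree random
forest chosen by 10-fold cross-validation (grid over `max_features`) on
a stratified 70/30 split; held-out accuracy and per-class confusion are
reported. Classes with < 10 members fall back to an unstratified split.

Known limitation: because labels are a deterministic function of Q and
the designed category, entries whose true behaviour is unfolded but
whose persistent σ₀ lies in the control upper tail are labelled (and
hence predicted) as their designed class. Held-out label accuracy is
near-perfect on separable synthetic classes, while recovery of the
simulator's latent class is capped near the rate at which the Q rule
itself flags truly-unfolded entries.

## Stall mapping

Replicate coverage profiles are each normalized by their own maximum
and averaged position-wise. The stall position is the first downward
crossing of relative coverage 0.5, linearly interpolated between
flanking integer positions; the first crossing is used because the
earliest stall site dominates the stalled fraction when several exist.
Travel distance at time t is position(t) − position(0.5 min).
Coordinates are 0-based offsets from the first repeat base.

## Variant calling

A per-read pileup caller against the designed insert replaces a
haplotype caller: synthetic reads are unambiguous and the scientific
content lies in the filters, not caller internals. Indels are
left-aligned (all in-register placements of a slippage event collapse
to one locus); candidate quality is the mean phred quality of
supporting bases. Filters: quality > 20; any candidate present in the
parental set (same position and alleles) is excluded as pre-existing;
EC candidates must change length by an exact multiple of the unit size
*and* the changed sequence must tile a rotation of the unit (any
rotation is admissible because slippage copies whatever register the
polymerase slipped at). Variant frequency is supporting / covering
(spanning) reads. BS events accumulate into per-class 4×4 ref→alt
matrices, row-normalized, zero diagonal.

## Genome associations

Loci are keyed by canonical double-stranded class, so reverse-strand
annotations collapse correctly. Exclusions for mutability analyses:
mononucleotide repeats, loci < 12 nt (two full hexamer units), and
μ ≤ 10^−7.5 per generation (strictly-greater, the model's
quantification floor). Abundance/length analyses bin loci by class mean
stall score; length comparisons use the top 1,000 longest instances per
bin so the comparison is about achievable extreme length rather than
the short-locus bulk.

SNP density at a relative position is the fraction of loci carrying a
SNP there, anchored at the first and last repeat base. Boundary
enrichment compares two locus subsets on a 2×2 table of loci
with/without a SNP at the four boundary-adjacent positions (offsets
−1/+1 from each anchor); the test is two-sided Fisher exact, the odds
ratio uses a 0.5 continuity correction only when a cell is empty, and
every result stores its contingency table and a description of the
comparison so each odds ratio is auditable. The exact test is verified
against exhaustive hypergeometric enumeration.

The genome fixture plants: per-class abundance ∝ exp(−2σ), mean locus
length decaying with σ, log-normal μ with median 10^(−7−1.5σ) (sd 0.4
dex; the intercept puts the stable/unstable split near balance so
boundary comparisons are well powered), β rising with σ, background
flank SNPs at 1%/position (sparing the tested boundary positions so
the planted odds ratio is not diluted), and a boundary SNP marking
whose odds ratio between μ-unstable and μ-stable loci is configurable
(default 2.5). All planted effect sizes are recorded in a truth sidecar.

## Problem sizes and runtimes

Test and validation runs use: full 20,000-entry library for
combinatorial checks; 320–640 simulated entries at depth 10⁴, five time
points, two replicates for parameter-recovery and classifier runs;
1,000 null entries for Q calibration; 10⁴ reads for slippage step-size
recovery; 10⁴ fixture loci for the planted odds ratio; all 2×2 tables
with n ≤ 50 for the exact-test oracle. These sizes were chosen so each
property is tested with adequate statistical power while the whole
suite runs in minutes on one CPU.
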