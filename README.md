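# strstall

Analysis pipeline for high-throughput primer-extension measurements of
DNA polymerase stalling at short tandem repeats (STRs) and structured
DNA controls — with a seeded synthetic-assay module that stands in for
the wet-lab experiment, so every stage is testable end to end.

## The problem

STRs (1–6 nt units repeated head-to-tail) are the most mutable elements
of eukaryotic genomes. Their low-complexity sequences can fold into
intrastrand secondary structures — hairpins, G-quadruplexes (G4),
i-motifs — that impede a replicative DNA polymerase. A pooled primer
extension assay measures, for every possible repeat unit at several
lengths plus rationally designed structured controls, how strongly and
how persistently the polymerase stalls. Those measurements can then be
related to the abundance, length, mutability and boundary SNP density of
STR loci in genomes.

`strstall` implements the computational side of that experiment for
researchers in genome stability and repeat biology:

- **Motif combinatorics** — there are 5,356 primitive repeat units of
  period 1–6 over {A,C,G,T}; grouping them by cyclic rotation gives 964
  single-stranded motif classes, and additionally by reverse
  complementation gives 501 double-stranded classes (verified against
  the necklace closed form `(1/n) Σ_{d|n} μ(n/d) 4^d`).
- **Library design** — the 20,000-entry oligo pool: 16,068 STR inserts
  (all units × lengths 24/48/72 nt), 960 hairpins, 1,500 G4s, 472
  i-motifs, 1,000 random GC-gradient controls; unique 12-nt barcodes at
  pairwise Hamming distance ≥ 3 with no homopolymer runs; 150-nt oligo
  assembly between priming/restriction flanks.
- **Stall-score kinetics** — per entry, the stall score
  `σ(t) = stalled_CPM / (stalled_CPM + extended_CPM)` at five time
  points, and the kinetic constant λ of the exponential model
  `σ(t) = σ₀·e^{λt}` (λ > 0: persistent stalling, G4-like; λ < 0:
  transient, hairpin-like), plus a Fisher-combined Mann–Whitney Q value
  against the random-GC controls.
- **Structure classification** — a random forest over 11 features
  (σ at 5 time points, Q, λ, R², GC, G4Hunter-style score, entropy),
  trained on the designed controls with a 70/30 stratified split and
  10-fold cross-validation.
- **Stall-site mapping** — relative coverage profiles of stalled
  products, the 0.5-crossing stall position, and polymerase travel
  distances over time.
- **Variant calling** — base substitutions (BS) versus unit-multiple
  expansion/contraction (EC) slippage events in extended reads, with
  quality, de-novo (parental) and unit-arithmetic filters.
- **Genome associations** — STR locus tables, mutability parameters
  (μ, β, p), SNP density around repeat boundaries, and Fisher exact
  boundary-enrichment tests; plus a synthetic genome-fixture generator
  with planted effect sizes.

## Worked example

Score a small simulated assay and read off one G4 control's kinetics:

```python
from strstall import library as lib
from strstall.simulate import sample_ground_truth, simulate_counts
from strstall.kinetics import build_stall_profiles

entries = lib.design_controls(40, 40, 40, 40, seed=1)
truths = sample_ground_truth(entries, seed=1)
counts = simulate_counts(truths, depth=10_000, replicates=2, seed=1)
controls = [e.entry_id for e in entries if e.category == "RANDOM"]
profiles = build_stall_profiles(counts, controls)

p = profiles["G4_0000"]
print({t: round(v, 3) for t, v in p.sigma_mean.items()})
print(f"sigma0={p.sigma0_fit:.3f} lambda={p.lam_fit:.4f} Q={p.q_combined:.2e}")
```

prints

```
{0.5: 0.733, 1.0: 0.91, 2.0: 0.903, 4.0: 0.863, 30.0: 1.0}
sigma0=0.838 lambda=0.0060 Q=3.08e-13
```

This entry stalls strongly at the first time point and is saturated
(detected in the stalled fraction only) by 30 min; the fitted λ is
positive — persistent stalling, the G4 signature — and the tiny Q says
its stalling is far beyond anything seen in the random-GC controls.
(The ground truth behind this simulated entry was a QUAD with
σ₀ = 0.657, λ = 0.0402; the fitted λ is compressed because σ is clamped
at 1 once the entry saturates.)

The same stages are available from the shell:

```sh
strstall design  --seed 1 --out runs/design
strstall run-all --seed 1 --outdir runs/full --subsample 500
```

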