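# Methods

## The assay being modelled

The toolkit models a single-cell assay that profiles several histone
modifications and the transcriptome in the same cells. Chromatin fragments are
produced by antibody-directed Tn5 tagmentation, with each antibody–Tn5 complex
carrying a 5-nt index identifying its target (one complex carries a
non-specific IgG antibody and measures background tagmentation). Nuclear mRNA
is captured by an indexed poly-T primer carrying an 8-nt UMI. Cells then pass
through three split-pool ligation rounds of 48 barcodes each, so a cell's
identity is the combination BC1:BC2:BC3 and the read-level structure of
Read2 is

```
BC3 [1-8]  30-nt linker  BC2 [39-46]  30-nt linker  BC1 [77-84]  30-nt linker  ID [115-119]  UMI [120-127]
```

(1-based inclusive; 127 nt total). Read1 carries genomic or cDNA sequence.

## Barcode model

* Capacity is the product of round whitelist sizes (48³ = 110 592). The ID
  segment is excluded by default: every cell receives all antibody indexes, so
  it cannot distinguish cells within a sublibrary. A flag includes it for
  designs where multiple RT indexes genuinely extend cell identity.
* Collision rate estimators: `linear` = n/N (occupancy fraction, clipped at 1)
  and `birthday` = 1 − (1 − 1/N)^(n−1), the exact per-cell collision
  probability under uniform assignment. The linear form reproduces the
  conventionally quoted 1%/10% figures at n = 1 100/11 000; the birthday form
  is validated against Monte-Carlo simulation in the test suite.
* Shipped whitelists are generated greedily at minimum pairwise Hamming
  distance ≥ 4 (8-mers for the three rounds; 5-mers for six antibody plus two
  RT indexes, disjoint and jointly at distance ≥ 4). Distance 3 is the minimum
  for unambiguous single-substitution correction; distance 4 additionally
  prevents a doubly-corrupted segment from being "corrected" into a different
  whitelist member, which at 1% per-base error and 10⁵-read scale would
  otherwise produce a handful of mis-assigned reads per run. The default
  design is built from a fixed internal seed and is therefore stable across
  installations.

## Synthetic data generator

The generator inverts the assay's read structure and owns the study
conditions. Defaults (one `Scenario`):

| parameter | default | rationale |
|---|---|---|
| cells | 500 | enough for per-cell QC distributions at desk scale |
| cell types | 2 at 50/50 | minimal heterogeneous sample |
| targets | 2 marks + IgG | one active/one repressive mark plus background |
| genome | 5 Mb over 2 contigs | desk-scale; see density note below |
| peaks | 150 × 3 kb per (mark, type) | keeps per-peak molecule density realistic |
| in-peak probability (per mark) | 0.8 | strong-signal mark FRiP |
| DNA molecules/cell/mark | NB(mean 1400, r = 10) | sum over marks straddles the DNA > 2500 filter |
| IgG molecules/cell | NB(300, 10) | background libraries are small |
| RNA UMIs/cell | NB(2300, 10) | straddles the RNA > 2000 filter |
| duplication factor | 2 | each molecule emitted twice (PCR duplicate model) |
| fragment length | U[150, 500] | typical tagmentation library |
| Read1 | 5′ 50 nt of the fragment | single-end toy alignment |
| barcode error rate | 0 | substitutions opt-in per scenario |

Placement: with probability `frip` a mark's fragment is placed wholly inside a
uniformly chosen peak of that (mark, cell type); otherwise it is
rejection-sampled from the genome avoiding that mark's merged peak union, so
the realised in-peak fraction is exactly binomial around `frip`. IgG fragments
are uniform background. RNA molecules pick a gene from cell-type-weighted
multinomial expression (disjoint marker blocks boosted 4×) and a uniform 50-nt
window within the (single-exon) gene body. Identical seeds give byte-identical
output; read synthesis is restartable because the error stream has its own
derived seed.

What the generator does **not** emulate: sequencing quality scores, indels and
chimeras, transcript structure/splicing, doublets (barcode collisions are
injected explicitly via `inject_collisions`), batch effects, and the long-tail
peak-strength heterogeneity of real chromatin. Passing tests therefore show
the *processing logic* is exact, not that real libraries will reach any
particular quality.

## Processing conventions

* **Demultiplexing** — fixed-position extraction; failure classes follow read
  order (bad_BC3 before bad_BC2 …) so statistics are reproducible;
  `valid + Σ failures = total` is asserted. Matching is a dictionary lookup on
  2-bit-packed segments; with `max_mismatch=1` all single-substitution
  neighbours are enumerated up front and neighbours claimed by two entries
  resolve as ambiguous. UMIs are recorded verbatim ('N' included).
* **Alignment** — exact (unique) substring search against the synthetic
  genome, forward then reverse-complement; multi-hits and misses are dropped
  and counted. Externally produced minimal SAM is read through pysam with the
  conventional strict mapping-quality filters (> 10 DNA, > 50 RNA) and
  proper-pair FR merging into fragment-spanning records. Coordinates are
  0-based half-open everywhere internally and in BED outputs. No Tn5 +4/−5
  end shift is applied anywhere; `align.shift_ends` implements one for
  workflows that want it.
* **Deduplication** — DNA: one fragment per distinct mapping position within
  (cell, target); for single-end records the position key is the aligned
  interval plus orientation (the standard single-end duplicate criterion).
  RNA: one molecule per distinct (cell, contig, 5′ position, UMI), the 5′
  base being start on + and end − 1 on −. Both rules conserve
  `Σ dup_count = input records` exactly and are verified against brute-force
  grouping oracles.
* **Gene counting** — a molecule is assigned to the unique gene interval
  containing its 5′ position; molecules overlapping zero or ≥ 2 genes are
  dropped and counted. Overlap counting uses sorted-boundary arithmetic and is
  exact for overlapping annotations.
* **Bin matrices / tracks** — a fragment increments every bin it overlaps
  (interval-overlap dialect, not midpoint); bins at contig ends are truncated;
  bedGraph is the track format.

## Statistics

* **FRiP** — unique fragments sharing ≥ 1 base with the merged peak set,
  per (cell, target); cells with no fragments are reported missing, not 0.
  The IgG target is judged against the union of all mark peaks.
* **Cell filter** — pass iff DNA unique (summed over all targets, IgG
  included) > 2500 AND RNA unique > 2000, both strict; recovery = passing /
  loaded cells.
* **Cramér's V** — activity matrices binarized at count > 0, pooled into one
  2×2 table over all (cell, feature) entries; V = √(χ²/N) with the Pearson
  statistic, no continuity correction (for 2×2, V = |φ|). Degenerate margins
  define V = 0 with a warning. The feature unit (genes vs bins) is the
  caller's choice; gene-level activity is the package default convention.
* **kNN label agreement** — Euclidean distances on the supplied
  representation, self excluded, ties broken by cell index via stable sort.
  At k = n − 1 the score is forced to Σ n_c(n_c − 1)/(n(n − 1)).
* **Poisson binarization** — threshold t(λ) = min{t : P(Poisson(λ) ≥ t) ≤ p},
  computed as ppf(1 − p) + 1 and verified against brute-force tail summation.
  With an IgG control, λ_b = max(genome-wide mean, control_b ×
  total_signal/total_control); the floor prevents single-read calls in
  control-empty bins. λ = 0 yields threshold 1. Default p = 5·10⁻⁷ at 200-bp
  bins.
* **Saturation curves** — subsample n cells without replacement, aggregate,
  correlate to the reference at 5-kb bins; mean and SD over replicates.
* **Depth normalisation** — RPGC-style effective-genome scaling is replaced by
  CPM; Pearson correlation is invariant to affine scaling, so correlation
  analyses are unaffected.

## Numerical and design notes

* On a 5 Mb genome at ~2 800 DNA molecules per cell, distinct molecules
  occasionally coincide in duplicate-key space; unique counts therefore
  undershoot molecule counts by ~0.1%, and the measured duplication rate at
  factor 2 is ≈ 0.5003 rather than 0.5000. The earlier 1 Mb default made this
  bias ten times larger, which motivated both the genome size and the
  strand-aware single-end duplicate key. The pipeline's unique counts equal a
  truth-table dedup (same keys) exactly on error-free input.
* The test suite and acceptance script size their simulations (≤ 500 cells,
  ≤ 5.5 M reads, 10⁵ Monte-Carlo replicates) so a full run completes in a few
  minutes on one CPU; these sizes are the package's chosen study conditions,
  and all statistical tolerances are 3 standard errors at those sizes unless
  a check is exact by construction.
* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; per-stage streams are split from the root seed so stages are
  independently restartable and byte-identical across runs.
* Genes are non-overlapping in the generator, but the gene-assignment code
  handles overlapping annotations (drop-as-ambiguous) since real annotations
  overlap.
* The ``all`` CLI command removes its output directory on failure so partial
  artifacts are never mistaken for results.

## Known limitations

* The toy aligner is exact-match only (optionally ≤ 1 mismatch at small
  scale); it cannot model mapping ambiguity beyond literal repeats, indels or
  splicing.
* Single-end processing: paired SAM input is merged correctly, but the
  simulator's in-memory path emits single-end reads; fragment files from that
  path are 50-nt read intervals, not full tagmentation fragments.
* No UMI-graph (directional) collapsing; exact UMI identity only.
* HMM-based chromatin-state learning, peak calling, LSI/UMAP embeddings and
  metacell construction are deliberately out of scope; peaks and
  representations are inputs.
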