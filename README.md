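# splitmark

Simulation and processing toolkit for **split-pool barcoded multi-target
single-cell CUT&Tag with joint transcriptome capture** — assays in which
several antibody–Tn5 complexes, each carrying a 5-nt antibody index, tagment
chromatin in situ at the sites of different histone modifications, nuclear
mRNA is reverse-transcribed with an indexed, UMI-bearing poly-T primer, and
three rounds of split-pool ligation (48 barcodes per round) give every cell a
combinatorial barcode without physical isolation.

The package is aimed at method developers and analysts who need a fully
ground-truthed, desk-scale replica of such an experiment: every stage of the
dry-lab pipeline is implemented against a simulator that knows the true origin
of every read, so demultiplexing, deduplication and QC logic can be verified
exactly rather than eyeballed.

## What it computes

**Barcode-space combinatorics.** Three rounds of 48 barcodes give
N = 48³ = 110 592 cell-identifying combinations. For *n* loaded cells the
collision rate (probability a cell shares its combination) is estimated as
the occupancy fraction *n*/N, or exactly under uniform assignment as
1 − (1 − 1/N)^(n−1); at 1 100 and 11 000 cells the linear estimate is ≈1%
and ≈10%.

**Demultiplexing.** Segments are cut from fixed positions of the barcode read
(Read2, 127 nt): BC3 at 1–8, BC2 at 39–46, BC1 at 77–84, the 5-nt
antibody/RT index at 115–119 and the 8-nt UMI at 120–127 (1-based inclusive).
Matching is exact by default, or allows one substitution when the whitelists
have minimum pairwise Hamming distance ≥ 3 (the shipped whitelists are built
at distance ≥ 4, so single-substitution correction is unambiguous even on
doubly-corrupted segments). UMIs are never corrected.

**Quantification.** DNA reads are deduplicated per (cell, target) by mapping
position alone — identical coordinates are PCR duplicates regardless of UMI —
and written as 5-column fragment files. RNA molecules are deduplicated per
cell by 5′ mapping position *and* UMI, then counted per gene into a sparse
gene × cell MatrixMarket matrix.

**QC and association statistics.** Per-cell/per-target unique reads,
duplication rate (1 − unique/total), FRiP (fraction of unique fragments
overlapping peaks), cell filtering at unique-count thresholds
(DNA > 2500 summed over targets, RNA > 2000, both strict), Cramér's V
(√(χ²/N) on pooled 2×2 binarized activity tables), and kNN label agreement
(mean fraction of each cell's k = 50 nearest neighbours sharing its lineage
label).

**Pseudobulk aggregation.** Binned coverage tracks per (group, target),
IgG-ratio normalisation ((signal + 1)/(control + 1) on depth-scaled tracks),
genome-wide Pearson correlation at 5-kb bins, cell-subsampling saturation
curves, per-cell median-depth normalisation, and Poisson binarization
(bin = 1 iff count ≥ min{t : P(Poisson(λ) ≥ t) ≤ 5·10⁻⁷}, λ floored at the
genome-wide mean and optionally scaled from the IgG control).

## Worked example

```python
from splitmark import default_design, collision_rate
from splitmark.simulate import Scenario, simulate
from splitmark.pipeline import process_run

design = default_design()
print("combinations:", design.combinations())
print("collision rate at 1100 cells: %.2f%%" % (100 * collision_rate(1100, design.combinations())))

scenario = Scenario(
    n_cells=100,
    fragments_per_cell={"H3K27me3": (300, 10), "H3K27ac": (300, 10), "IgG": (80, 10)},
    umis_per_cell=(300, 10),
    seed=7,
)
result = process_run(simulate(scenario, design))
stats = result.report.dataset
print("reads:", result.demux_stats.total,
      " valid: %.1f%%" % (100 * result.demux_stats.valid_fraction))
print("duplication rate: %.3f" % stats["duplication_rate"])
for target, row in result.report.per_cell_target.groupby("target", observed=True):
    print(f"{target}: FRiP = {row['n_in_peak'].sum() / row['n_fragments'].sum():.3f}")
```

prints

```
combinations: 110592
collision rate at 1100 cells: 0.99%
reads: 199236  valid: 100.0%
duplication rate: 0.500
H3K27ac: FRiP = 0.800
H3K27me3: FRiP = 0.800
IgG: FRiP = 0.310
```

Every barcode decoded (error-free simulation), the PCR duplication factor of 2
recovered as a 0.500 duplication rate, the two marks' in-peak probability of
0.8 measured back as FRiP ≈ 0.800, and the IgG background showing only the
incidental overlap of uniform fragments with the peak annotation.

The same pipeline is available from the shell:

```bash
splitmark all --seed 1 --out out/          # simulate + demux + align + quantify + QC
splitmark simulate --seed 1 --out sim/     # FASTQ + truth tables only
splitmark demux --r1 sim/reads_R1.fastq.gz --r2 sim/reads_R2.fastq.gz \
    --out-r1 valid_R1.fastq.gz --stats demux.json
```

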