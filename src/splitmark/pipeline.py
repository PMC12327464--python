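"""End-to-end orchestration: simulate -> demultiplex -> align -> deduplicate ->
count -> QC, with conservation counters asserted at each stage boundary.

The in-memory path streams read batches straight from the simulator through
the vectorised demultiplexer and aligner without writing FASTQ, so
multi-million-read runs stay within desk-scale time and memory. The CLI uses
the same functions with FASTQ on disk in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignStats, GenomeIndex
from .barcodes import BarcodeDesign
from .demux import MODALITY_DNA, MODALITY_RNA, VALID, Demultiplexer, DemuxStats
from .qc import QCReport, summarize
from .quantify import CountMatrix, count_genes, dedup_dna, dedup_rna
from .simulate import Scenario, SimulatedRun, simulate


@dataclass
class PipelineResult:
    run: SimulatedRun
    demux_stats: DemuxStats
    align_stats_dna: AlignStats
    align_stats_rna: AlignStats
    fragments: pd.DataFrame  # cell, target, contig, start, end, strand, dup_count
    molecules: pd.DataFrame  # cell, contig, pos, umi, dup_count
    count_matrix: CountMatrix
    count_stats: dict
    report: QCReport = None
    truth_mismatch: dict = field(default_factory=dict)


def process_run(
    run: SimulatedRun,
    max_mismatch: int = 0,
    batch_size: int = 400_000,
    dna_min: int = 2500,
    rna_min: int = 2000,
    compare_truth: bool = True,
) -> PipelineResult:
    """Process a simulated run through demux, alignment and quantification.

    When ``compare_truth`` is set, demultiplexed assignments are checked
    against the simulator's truth table per batch and mismatches counted
    (cell or target assignment differing from truth among valid reads).
    """
    design = run.design
    sc = run.scenario
    demux = Demultiplexer(design, max_mismatch=max_mismatch, modality="auto")
    index = GenomeIndex(run.genome, sc.read1_length)
    dstats = DemuxStats()
    astats_dna = AlignStats()
    astats_rna = AlignStats()
    frag_parts = []
    mol_parts = []
    mismatch = {"cell": 0, "target": 0, "valid_reads": 0}
    tgt_index = {t: i for i, t in enumerate(sc.targets)}
    label_to_tgt = np.array(
        [tgt_index.get(lbl, -1) for lbl in demux.id_labels], dtype=np.int64
    )
    cells_bc = run.cells[["bc1", "bc2", "bc3"]].to_numpy()
    for batch in run.iter_read_batches(batch_size):
        ann = demux.annotate_matrix(batch["read2"])
        labels = [demux.id_labels[j] for j in ann["id_idx"][ann["status"] == VALID]]
        dstats.add(ann["status"], labels)
        valid = ann["status"] == VALID
        if compare_truth:
            tc = batch["cell"]
            truth_bc = cells_bc[tc]
            ok_bc = (
                (ann["bc1"] == truth_bc[:, 0])
                & (ann["bc2"] == truth_bc[:, 1])
                & (ann["bc3"] == truth_bc[:, 2])
            )
            mismatch["valid_reads"] += int(valid.sum())
            mismatch["cell"] += int((valid & ~ok_bc).sum())
            mol = run.molecule_of_read(batch["serial"])
            truth_tgt = np.where(
                batch["modality"] == 0,
                run._dna["target"][np.clip(mol, 0, run._dna_n - 1)].astype(np.int64),
                -2,  # RNA: target slot holds the RT label instead
            )
            ann_tgt = np.where(
                ann["id_idx"] >= 0, label_to_tgt[np.clip(ann["id_idx"], 0, None)], -3
            )
            ann_tgt = np.where(ann["modality"] == MODALITY_RNA, -2, ann_tgt)
            mismatch["target"] += int((valid & (ann_tgt != truth_tgt)).sum())
        # cell code: packed bc indices (stable, compact)
        n1 = len(design.rounds[0])
        n2 = len(design.rounds[1])
        cell_code = ann["bc1"] + n1 * (ann["bc2"] + n2 * ann["bc3"])
        # ---- DNA
        m_dna = valid & (ann["modality"] == MODALITY_DNA)
        if m_dna.any():
            contig, start, strand, status = index.map_reads(batch["read1"][m_dna])
            astats_dna.total += int(m_dna.sum())
            astats_dna.mapped += int((status == 0).sum())
            astats_dna.multi += int((status == 1).sum())
            astats_dna.unmapped += int((status == 2).sum())
            ok = status == 0
            tgt = label_to_tgt[ann["id_idx"][m_dna]]
            frag_parts.append(
                pd.DataFrame(
                    {
                        "cell": cell_code[m_dna][ok],
                        "target": tgt[ok],
                        "contig": contig[ok],
                        "start": start[ok],
                        "end": start[ok] + sc.read1_length,
                        "strand": strand[ok],
                    }
                )
            )
        # ---- RNA
        m_rna = valid & (ann["modality"] == MODALITY_RNA)
        if m_rna.any():
            contig, start, strand, status = index.map_reads(batch["read1"][m_rna])
            astats_rna.total += int(m_rna.sum())
            astats_rna.mapped += int((status == 0).sum())
            astats_rna.multi += int((status == 1).sum())
            astats_rna.unmapped += int((status == 2).sum())
            ok = status == 0
            from ._encode import encode_kmers

            umi_keys, _ = encode_kmers(ann["umi"][m_rna])
            mol_parts.append(
                pd.DataFrame(
                    {
                        "cell": cell_code[m_rna][ok],
                        "contig": contig[ok],
                        "start": start[ok],
                        "end": start[ok] + sc.read1_length,
                        "strand": strand[ok],
                        "umi": umi_keys[ok],
                    }
                )
            )
    dstats.check_conservation()
    dna_records = (
        pd.concat(frag_parts, ignore_index=True)
        if frag_parts
        else pd.DataFrame(columns=["cell", "target", "contig", "start", "end", "strand"])
    )
    rna_records = (
        pd.concat(mol_parts, ignore_index=True)
        if mol_parts
        else pd.DataFrame(columns=["cell", "contig", "start", "end", "strand", "umi"])
    )
    fragments = dedup_dna(dna_records)
    molecules = dedup_rna(rna_records)
    # translate codes back to human-readable labels
    fragments["target"] = pd.Categorical.from_codes(
        fragments["target"], categories=list(sc.targets)
    )
    contig_names = index.contig_names
    fragments["contig"] = pd.Categorical.from_codes(
        fragments["contig"], categories=contig_names
    )
    molecules["contig"] = pd.Categorical.from_codes(
        molecules["contig"], categories=contig_names
    )
    genes = run.genes
    cm, count_stats = count_genes(molecules, genes)
    result = PipelineResult(
        run=run,
        demux_stats=dstats,
        align_stats_dna=astats_dna,
        align_stats_rna=astats_rna,
        fragments=fragments,
        molecules=molecules,
        count_matrix=cm,
        count_stats=count_stats,
        truth_mismatch=mismatch,
    )
    peaks = dict(run.merged_peaks)
    if sc.control not in peaks and peaks:
        # background target: judged against the union of all mark peaks
        peaks[sc.control] = pd.concat(peaks.values(), ignore_index=True)
    result.report = summarize(
        dstats,
        fragments,
        molecules,
        peaks,
        run.design,
        n_cells_loaded=sc.n_cells,
        count_matrix=cm,
        dna_min=dna_min,
        rna_min=rna_min,
    )
    return result


def cell_code_of_truth(run: SimulatedRun) -> np.ndarray:
    """Pack each truth cell's barcode indices with the pipeline's cell code."""
    n1 = len(run.design.rounds[0])
    n2 = len(run.design.rounds[1])
    c = run.cells
    return (c["bc1"] + n1 * (c["bc2"] + n2 * c["bc3"])).to_numpy()


def run_pipeline(scenario: Scenario, design: BarcodeDesign, **kwargs) -> PipelineResult:
    """Simulate a scenario and process it in one call."""
    return process_run(simulate(scenario, design), **kwargs)
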