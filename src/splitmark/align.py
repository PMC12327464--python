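"""Desk-scale alignment: exact substring mapping to the synthetic genome, plus
a reader for externally produced minimal SAM records.

The exact aligner indexes every read-length window of the genome and reports
unique hits only (mapq 60); multi-mapping and unmapped reads are dropped and
counted, mirroring unique-mapping filters applied to real data. The SAM reader
applies the conventional mapping-quality filters (strictly > 10 for DNA,
> 50 for RNA) and merges properly paired mates into one fragment-spanning
record. Coordinates are 0-based half-open internally and in all BED outputs;
SAM input is converted from 1-based. No Tn5 +4/-5 end shift is applied
anywhere (``shift_ends`` exposes one if a workflow needs it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from ._encode import revcomp_matrix

DNA_MAPQ_MIN = 10  # strict >
RNA_MAPQ_MIN = 50  # strict >


@dataclass
class AlignStats:
    total: int = 0
    mapped: int = 0
    multi: int = 0
    unmapped: int = 0
    malformed: int = 0
    filtered: int = 0

    def check_conservation(self) -> None:
        if self.mapped + self.multi + self.unmapped + self.malformed + self.filtered != self.total:
            raise AssertionError("alignment conservation violated")


class GenomeIndex:
    """Exact lookup of every k-mer window of the genome.

    Windows occurring more than once (on the forward strand) are flagged as
    multi-mapping. Queries are matched forward first, then by reverse
    complement.
    """

    def __init__(self, genome: dict[str, np.ndarray], k: int):
        if not genome:
            raise ValueError("empty genome")
        self.k = k
        self.contig_names = list(genome)
        self.contig_lengths = {c: len(a) for c, a in genome.items()}
        kmers = []
        contig_idx = []
        pos = []
        for ci, name in enumerate(self.contig_names):
            arr = np.ascontiguousarray(genome[name], dtype=np.uint8)
            if len(arr) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(arr, k)
            kmers.append(np.ascontiguousarray(win))
            contig_idx.append(np.full(win.shape[0], ci, dtype=np.int32))
            pos.append(np.arange(win.shape[0], dtype=np.int64))
        mat = np.concatenate(kmers)
        self._void = np.dtype((np.void, k))
        keys = mat.reshape(mat.shape[0], k).view(self._void).ravel()
        order = np.argsort(keys)
        self._keys = keys[order]
        self._contig = np.concatenate(contig_idx)[order]
        self._pos = np.concatenate(pos)[order]
        # multi-mapping windows: identical neighbours after sort
        dup = np.zeros(len(self._keys), dtype=bool)
        same = self._keys[1:] == self._keys[:-1]
        dup[1:] |= same
        dup[:-1] |= same
        self._multi = dup

    def _lookup(self, reads: np.ndarray):
        keys = np.ascontiguousarray(reads, dtype=np.uint8).reshape(
            reads.shape[0], self.k
        ).view(self._void).ravel()
        idx = np.searchsorted(self._keys, keys)
        idx_c = np.clip(idx, 0, len(self._keys) - 1)
        hit = self._keys[idx_c] == keys
        multi = hit & self._multi[idx_c]
        return hit, multi, idx_c

    def map_reads(self, reads: np.ndarray):
        """Map a (n, k) ASCII matrix; returns (contig_idx, start, strand, status).

        status codes: 0 mapped, 1 multi, 2 unmapped. ``strand`` is 0 for
        forward, 1 for reverse-complement hits. Reads hit on both strands are
        multi-mapping.
        """
        n = reads.shape[0]
        hit_f, multi_f, idx_f = self._lookup(reads)
        rc = revcomp_matrix(reads)
        hit_r, multi_r, idx_r = self._lookup(rc)
        status = np.full(n, 2, dtype=np.int8)
        both = hit_f & hit_r
        multi = multi_f | multi_r | both
        status[hit_f | hit_r] = 0
        status[(hit_f | hit_r) & multi] = 1
        use_r = hit_r & ~hit_f
        contig = np.where(use_r, self._contig[idx_r], self._contig[idx_f])
        start = np.where(use_r, self._pos[idx_r], self._pos[idx_f])
        strand = use_r.astype(np.int8)
        return contig.astype(np.int32), start.astype(np.int64), strand, status


def align_exact(reads, genome: dict[str, np.ndarray], stats: AlignStats | None = None):
    """Align a (n, k) ASCII read matrix (or list of equal-length strings).

    Returns a DataFrame of unique hits with 0-based half-open coordinates and
    mapq 60, plus the :class:`AlignStats` used for conservation accounting.
    """
    from ._encode import to_matrix

    if not isinstance(reads, np.ndarray):
        reads = to_matrix(list(reads))
    if stats is None:
        stats = AlignStats()
    index = GenomeIndex(genome, reads.shape[1])
    return align_with_index(reads, index, stats), stats


def align_with_index(reads: np.ndarray, index: GenomeIndex, stats: AlignStats):
    contig, start, strand, status = index.map_reads(reads)
    stats.total += reads.shape[0]
    stats.mapped += int((status == 0).sum())
    stats.multi += int((status == 1).sum())
    stats.unmapped += int((status == 2).sum())
    ok = status == 0
    return pd.DataFrame(
        {
            "row": np.flatnonzero(ok),
            "contig": contig[ok],
            "start": start[ok],
            "end": start[ok] + index.k,
            "strand": strand[ok],
            "mapq": np.full(int(ok.sum()), 60, dtype=np.int16),
        }
    )


# ---------------------------------------------------------------------------
# Minimal SAM input
# ---------------------------------------------------------------------------

def _ref_span(rec: pysam.AlignedSegment) -> tuple[int, int]:
    return rec.reference_start, rec.reference_end


def read_alignments(
    path,
    modality: str = "DNA",
    mapq_min: int | None = None,
    paired: bool | None = None,
) -> tuple[pd.DataFrame, AlignStats]:
    """Read a minimal SAM file into uniform aligned records.

    Applies the modality's mapping-quality filter (strict >; DNA default 10,
    RNA default 50). For paired input only proper pairs in FR orientation are
    kept, and both mates are merged into one record spanning
    (min start, max end) on the shared contig. Malformed lines are skipped and
    counted rather than aborting the run.
    """
    if mapq_min is None:
        mapq_min = DNA_MAPQ_MIN if modality.upper() == "DNA" else RNA_MAPQ_MIN
    stats = AlignStats()
    header_lines = []
    records = []
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("@"):
            header_lines.append(line)
    header = pysam.AlignmentHeader.from_text("".join(header_lines)) if header_lines else None
    if header is None:
        raise ValueError("SAM input lacks a header (@SQ lines are required)")
    pending: dict[str, pysam.AlignedSegment] = {}
    rows = []
    for line in lines:
        if line.startswith("@") or not line.strip():
            continue
        stats.total += 1
        try:
            rec = pysam.AlignedSegment.fromstring(line.rstrip("\n"), header)
        except (ValueError, KeyError):
            stats.malformed += 1
            continue
        if rec.is_unmapped or rec.reference_id < 0:
            stats.unmapped += 1
            continue
        if rec.mapping_quality <= mapq_min:
            stats.filtered += 1
            continue
        is_paired = rec.is_paired if paired is None else paired
        if not is_paired:
            s, e = _ref_span(rec)
            rows.append((rec.query_name, rec.reference_name, s, e,
                         "-" if rec.is_reverse else "+", rec.mapping_quality))
            stats.mapped += 1
            continue
        if not rec.is_proper_pair:
            stats.filtered += 1
            continue
        # FR orientation: exactly one mate reversed
        if rec.is_reverse == rec.mate_is_reverse:
            stats.filtered += 1
            continue
        mate = pending.pop(rec.query_name, None)
        if mate is None:
            pending[rec.query_name] = rec
            continue
        if mate.reference_id != rec.reference_id:
            stats.filtered += 2
            continue
        s = min(mate.reference_start, rec.reference_start)
        e = max(mate.reference_end, rec.reference_end)
        fwd = mate if not mate.is_reverse else rec
        rows.append((rec.query_name, rec.reference_name, s, e,
                     "-" if fwd.is_reverse else "+", min(mate.mapping_quality, rec.mapping_quality)))
        stats.mapped += 2
    # unpaired leftovers
    stats.filtered += len(pending)
    records = pd.DataFrame(
        rows, columns=["name", "contig", "start", "end", "strand", "mapq"]
    )
    stats.check_conservation()
    return records, stats


def shift_ends(records: pd.DataFrame, plus: int = 4, minus: int = -5) -> pd.DataFrame:
    """Optional transposase end shift (+4/-5 by convention); off by default."""
    out = records.copy()
    pos = out["strand"] == "+"
    out.loc[pos, "start"] += plus
    out.loc[~pos, "end"] += minus
    return out


def write_records_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)
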