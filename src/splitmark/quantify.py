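"""Modality-specific deduplication and quantification.

DNA reads are collapsed purely by mapping position within each (cell, target):
reads at identical coordinates are PCR duplicates regardless of UMI. RNA
molecules are collapsed by mapping position *and* UMI within each cell, the
UMI being the 8-nt random tag on the reverse-transcription primer; the
position used is the 5'-most aligned base (strand-aware), the standard UMI
anchor. UMIs are compared exactly (no graph collapsing).

Deduplicated DNA becomes per-target fragment files (5-column dialect: contig,
start, end, cell barcode, duplicate count); deduplicated RNA is counted per
gene into a sparse gene x cell matrix written as MatrixMarket with
features/barcodes sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def dedup_dna(records: pd.DataFrame) -> pd.DataFrame:
    """One fragment per distinct mapping position within each (cell, target).

    For single-end records the duplicate key is (contig, start, end, strand) —
    the standard single-end criterion (5' coordinate plus orientation); for
    strand-less input the key is the coordinates alone. ``dup_count`` is the
    multiplicity; the UMI is deliberately ignored.
    Conservation: ``fragments["dup_count"].sum() == len(records)``.
    """
    required = ["cell", "target", "contig", "start", "end"]
    if "strand" in records.columns:
        required = required + ["strand"]
    frags = (
        records.groupby(required, sort=True, observed=True)
        .size()
        .rename("dup_count")
        .reset_index()
    )
    assert int(frags["dup_count"].sum()) == len(records)
    return frags


def dedup_rna(records: pd.DataFrame) -> pd.DataFrame:
    """One molecule per distinct (cell, contig, 5' position, UMI).

    The 5' position is ``start`` on the forward strand and ``end - 1`` on the
    reverse strand. Exact UMI comparison; a UMI containing 'N' is kept
    verbatim and treated as its own sequence.
    """
    rec = records.copy()
    if "strand" in rec.columns:
        strand = rec["strand"].astype(str)
        rec["pos"] = np.where(strand.isin(["-", "1"]), rec["end"] - 1, rec["start"])
    else:
        rec["pos"] = rec["start"]
    mols = (
        rec.groupby(["cell", "contig", "pos", "umi"], sort=True, observed=True)
        .size()
        .rename("dup_count")
        .reset_index()
    )
    assert int(mols["dup_count"].sum()) == len(records)
    return mols


# ---------------------------------------------------------------------------
# Gene counting
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with its row/column labels."""

    matrix: scipy.sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def genes_detected_per_cell(self) -> np.ndarray:
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def write_mtx(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), self.matrix.tocoo())
        with open(os.path.join(outdir, "features.tsv"), "w") as fh:
            fh.writelines(f"{g}\n" for g in self.gene_ids)
        with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
            fh.writelines(f"{c}\n" for c in self.cell_ids)

    @classmethod
    def read_mtx(cls, outdir) -> "CountMatrix":
        import os

        m = scipy.io.mmread(os.path.join(outdir, "matrix.mtx")).tocsr()
        genes = [l.strip() for l in open(os.path.join(outdir, "features.tsv"))]
        cells = [l.strip() for l in open(os.path.join(outdir, "barcodes.tsv"))]
        return cls(m, genes, cells)

    def to_anndata(self):
        import anndata

        return anndata.AnnData(
            X=self.matrix.T.tocsr(),
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )


def _assign_points_to_intervals(contigs, pos, intervals: pd.DataFrame):
    """Assign each (contig, pos) point to the unique containing interval.

    Returns (interval_index, n_overlaps); index is -1 where overlaps != 1.
    Handles overlapping intervals exactly: the overlap count is computed from
    sorted boundaries, and ambiguous (>=2) points are rejected.
    """
    idx_out = np.full(len(pos), -1, dtype=np.int64)
    n_over = np.zeros(len(pos), dtype=np.int64)
    pos = np.asarray(pos)
    contigs = np.asarray(contigs)
    for contig, sub in intervals.groupby("contig", sort=False, observed=True):
        m = contigs == contig
        if not m.any():
            continue
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        rows = sub.index.to_numpy()
        p = pos[m]
        count = np.searchsorted(np.sort(starts), p, side="right") - np.searchsorted(
            np.sort(ends), p, side="right"
        )
        n_over[m] = count
        cand = np.searchsorted(starts, p, side="right") - 1
        good = (cand >= 0) & (count == 1)
        inside = good & (p < ends[np.clip(cand, 0, None)])
        res = np.full(p.size, -1, dtype=np.int64)
        res[inside] = rows[cand[inside]]
        # count==1 but the candidate (latest-starting) interval does not
        # contain the point: an earlier, longer interval does — rare, scan back
        stray = np.flatnonzero(good & ~inside)
        for i in stray:
            j = cand[i]
            while j >= 0:
                if starts[j] <= p[i] < ends[j]:
                    res[i] = rows[j]
                    break
                j -= 1
        idx_out[m] = res
    return idx_out, n_over


def count_genes(
    molecules: pd.DataFrame,
    annotation: pd.DataFrame,
    cell_ids: list | None = None,
) -> tuple[CountMatrix, dict]:
    """Build the gene x cell UMI matrix from deduplicated RNA molecules.

    A molecule is assigned to the unique gene whose interval contains its 5'
    position; molecules overlapping zero or >=2 genes are dropped and counted.
    ``annotation`` is BED-like with columns contig/start/end/name.
    """
    gene_idx, n_over = _assign_points_to_intervals(
        molecules["contig"].to_numpy(), molecules["pos"].to_numpy(), annotation
    )
    assigned = gene_idx >= 0
    stats = {
        "assigned": int(assigned.sum()),
        "unassigned": int((n_over == 0).sum()),
        "ambiguous": int((n_over >= 2).sum()),
    }
    gene_names = annotation["name"].tolist()
    if cell_ids is None:
        cell_ids = sorted(molecules["cell"].unique().tolist())
    cell_col = {c: i for i, c in enumerate(cell_ids)}
    rows = annotation.index.get_indexer(pd.Index(gene_idx[assigned]))
    cols = molecules["cell"].map(cell_col).to_numpy()[assigned]
    mat = scipy.sparse.coo_matrix(
        (np.ones(int(assigned.sum()), dtype=np.int64), (rows, cols)),
        shape=(len(gene_names), len(cell_ids)),
    ).tocsr()
    cm = CountMatrix(mat, gene_names, [str(c) for c in cell_ids])
    assert cm.total == stats["assigned"]
    return cm, stats


# ---------------------------------------------------------------------------
# Fragment files and bin matrices
# ---------------------------------------------------------------------------

def write_fragments(fragments: pd.DataFrame, path) -> None:
    """Sorted 5-column fragment file (contig, start, end, barcode, count);
    block-gzipped when the path ends in .gz."""
    out = fragments.sort_values(["contig", "start", "end"])[
        ["contig", "start", "end", "cell", "dup_count"]
    ]
    text = out.to_csv(sep="\t", index=False, header=False)
    path = str(path)
    if path.endswith(".gz"):
        import pysam

        with pysam.BGZFile(path, "wb") as fh:
            fh.write(text.encode())
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "cell", "dup_count"],
        compression="gzip" if str(path).endswith(".gz") else None,
    )
    return df


def make_bin_matrix(
    fragments: pd.DataFrame,
    bin_size: int,
    contig_lengths: dict[str, int],
    cell_ids: list | None = None,
) -> tuple[scipy.sparse.csr_matrix, list, list]:
    """Genome-wide bins x cells matrix (default dialect: a fragment increments
    every bin it overlaps by 1).

    Returns (matrix, bin_labels, cell_ids); bins are ordered by contig then
    coordinate, labels are '<contig>:<bin_start>'.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    contig_names = list(contig_lengths)
    n_bins_per = {c: -(-contig_lengths[c] // bin_size) for c in contig_names}
    bin_offset = {}
    total_bins = 0
    labels = []
    for c in contig_names:
        bin_offset[c] = total_bins
        total_bins += n_bins_per[c]
        labels.extend(f"{c}:{i * bin_size}" for i in range(n_bins_per[c]))
    if cell_ids is None:
        cell_ids = sorted(fragments["cell"].unique().tolist())
    cell_col = {c: i for i, c in enumerate(cell_ids)}
    if len(fragments):
        b0 = fragments["start"].to_numpy() // bin_size
        b1 = (fragments["end"].to_numpy() - 1) // bin_size
        span = (b1 - b0 + 1).astype(np.int64)
        rep = np.repeat(np.arange(len(fragments)), span)
        bins = b0[rep] + (np.arange(span.sum()) - np.repeat(np.cumsum(span) - span, span))
        off = fragments["contig"].map(bin_offset).to_numpy()[rep]
        rows = off + bins
        cols = fragments["cell"].map(cell_col).to_numpy()[rep]
        mat = scipy.sparse.coo_matrix(
            (np.ones(rows.size, dtype=np.int64), (rows, cols)),
            shape=(total_bins, len(cell_ids)),
        ).tocsr()
    else:
        mat = scipy.sparse.csr_matrix((total_bins, len(cell_ids)), dtype=np.int64)
    return mat, labels, list(cell_ids)
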