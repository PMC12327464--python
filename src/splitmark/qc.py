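"""Cell- and dataset-level quality metrics and association statistics.

* FRiP — fraction of a cell's unique fragments overlapping (>=1 shared base) a
  merged peak set; the standard signal-to-background measure.
* Cell filtering — a cell is kept iff its summed unique DNA fragments exceed
  ``dna_min`` (default 2500, strict >) AND its unique RNA molecules exceed
  ``rna_min`` (default 2000, strict >).
* Cramér's V — association in [0, 1] between two binarized cells x features
  activity matrices, pooled over all entries into a 2x2 contingency table
  (V = sqrt(chi2 / N), no continuity correction; for 2x2 this equals |phi|).
* kNN label agreement — mean fraction of each cell's k nearest neighbours
  (Euclidean, self excluded, distance ties broken by cell index) sharing its
  label; quantifies how well a representation separates known lineages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.stats import chi2_contingency
from sklearn.metrics import pairwise_distances


# ---------------------------------------------------------------------------
# FRiP
# ---------------------------------------------------------------------------

def _merge_peaks(peaks: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = {}
    for contig, sub in peaks.groupby("contig", sort=False, observed=True):
        sub = sub.sort_values("start")
        starts, ends = [], []
        for s, e in zip(sub["start"], sub["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[contig] = (np.asarray(starts), np.asarray(ends))
    return merged


def fragments_in_peaks(fragments: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each fragment share >=1 base with any peak?"""
    merged = _merge_peaks(peaks)
    out = np.zeros(len(fragments), dtype=bool)
    contigs = fragments["contig"].to_numpy()
    fs = fragments["start"].to_numpy()
    fe = fragments["end"].to_numpy()
    for contig, (ps, pe) in merged.items():
        m = contigs == contig
        if not m.any():
            continue
        idx = np.searchsorted(ps, fe[m], side="left") - 1
        out[np.flatnonzero(m)] = (idx >= 0) & (pe[np.clip(idx, 0, None)] > fs[m])
    return out


def frip(fragments: pd.DataFrame, peaks) -> tuple[pd.DataFrame, pd.Series]:
    """FRiP per (cell, target) and aggregate per target.

    ``peaks`` is either one BED-like DataFrame applied to every target or a
    mapping target -> DataFrame. Cells with zero fragments for a target are
    reported as missing (NaN), never as 0.
    """
    frames = []
    for target, sub in fragments.groupby("target", sort=True, observed=True):
        pk = peaks[target] if isinstance(peaks, dict) else peaks
        hit = fragments_in_peaks(sub, pk)
        per_cell = (
            pd.DataFrame({"cell": sub["cell"].to_numpy(), "hit": hit})
            .groupby("cell")
            .agg(n_fragments=("hit", "size"), n_in_peak=("hit", "sum"))
            .reset_index()
        )
        per_cell["target"] = target
        per_cell["frip"] = per_cell["n_in_peak"] / per_cell["n_fragments"]
        frames.append(per_cell)
    if not frames:
        return (
            pd.DataFrame(columns=["cell", "target", "n_fragments", "n_in_peak", "frip"]),
            pd.Series(dtype=float),
        )
    table = pd.concat(frames, ignore_index=True)
    aggregate = table.groupby("target").apply(
        lambda d: d["n_in_peak"].sum() / d["n_fragments"].sum(), include_groups=False
    )
    return table, aggregate


# ---------------------------------------------------------------------------
# Cell filtering
# ---------------------------------------------------------------------------

def filter_cells(
    per_cell: pd.DataFrame,
    dna_min: int = 2500,
    rna_min: int = 2000,
    n_input: int | None = None,
) -> tuple[pd.Index, float]:
    """Cells passing both unique-count thresholds (strict >), plus recovery.

    ``per_cell`` must carry columns ``dna_unique`` (summed over all targets,
    including the IgG control) and ``rna_unique``. Recovery is passing /
    ``n_input`` when the loaded cell count is supplied, else passing / rows.
    """
    ok = (per_cell["dna_unique"] > dna_min) & (per_cell["rna_unique"] > rna_min)
    passing = per_cell.index[ok]
    denom = n_input if n_input is not None else len(per_cell)
    recovery = len(passing) / denom if denom else float("nan")
    return passing, recovery


# ---------------------------------------------------------------------------
# Cramér's V
# ---------------------------------------------------------------------------

def contingency_2x2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2x2 table over paired binary observations."""
    a = np.asarray(a).ravel().astype(bool)
    b = np.asarray(b).ravel().astype(bool)
    if a.shape != b.shape:
        raise ValueError("matrices must share shape (same cells and features)")
    t11 = int((a & b).sum())
    t10 = int((a & ~b).sum())
    t01 = int((~a & b).sum())
    t00 = int((~a & ~b).sum())
    return np.array([[t11, t10], [t01, t00]], dtype=np.int64)


def cramers_v_table(table: np.ndarray) -> float:
    """Cramér's V of a contingency table (Pearson chi2, no Yates correction)."""
    table = np.asarray(table)
    n = table.sum()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin in contingency table; V defined as 0")
        return 0.0
    chi2 = chi2_contingency(table, correction=False).statistic
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def cramers_v(matrix_a, matrix_b) -> float:
    """Association between two cells x features count matrices.

    Entries are binarized at count > 0 and pooled into a single 2x2 table
    over all (cell, feature) positions. Symmetric in its arguments.
    """
    a = matrix_a.toarray() if scipy.sparse.issparse(matrix_a) else np.asarray(matrix_a)
    b = matrix_b.toarray() if scipy.sparse.issparse(matrix_b) else np.asarray(matrix_b)
    return cramers_v_table(contingency_2x2(a > 0, b > 0))


# ---------------------------------------------------------------------------
# kNN label agreement
# ---------------------------------------------------------------------------

def knn_label_agreement(features, labels, k: int = 50) -> float:
    """Mean per-cell fraction of k nearest neighbours sharing the cell's label.

    Euclidean distance on the supplied representation; self excluded;
    distance ties broken deterministically by cell index (stable sort).
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = x.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    d = pairwise_distances(x, metric="euclidean")
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    same = labels[nn] == labels[:, None]
    return float(same.mean())


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-cell-per-target and dataset-level quality summary."""

    per_cell_target: pd.DataFrame  # cell, target, unique, total, duplication_rate, frip
    per_cell: pd.DataFrame  # cell_id index: dna_unique, rna_unique, genes_detected, pass
    dataset: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "dataset": self.dataset,
            "per_target": {
                str(t): {
                    "unique_reads_per_cell_mean": float(d["unique"].mean()),
                    "duplication_rate": float(
                        1.0 - d["unique"].sum() / d["total"].sum()
                    ) if d["total"].sum() else None,
                    "frip": float(
                        d["n_in_peak"].sum() / d["n_fragments"].sum()
                    ) if "n_in_peak" in d and d["n_fragments"].sum() else None,
                }
                for t, d in self.per_cell_target.groupby("target", observed=True)
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def write_per_cell_tsv(self, path) -> None:
        self.per_cell.to_csv(path, sep="\t")


def summarize(
    demux_stats,
    fragments: pd.DataFrame,
    molecules: pd.DataFrame,
    peaks,
    design,
    n_cells_loaded: int | None = None,
    count_matrix=None,
    dna_min: int = 2500,
    rna_min: int = 2000,
) -> QCReport:
    """Deterministic QC report combining all upstream outputs.

    Duplication rate per (cell, target) is ``1 - unique/total``; the dataset
    block carries demultiplexing fractions, the barcode-collision estimate for
    the loaded cell count, and filter outcomes at the supplied thresholds.
    """
    from .barcodes import collision_rate

    pct = fragments.groupby(["cell", "target"], sort=True, observed=True).agg(
        unique=("dup_count", "size"), total=("dup_count", "sum")
    ).reset_index()
    pct["duplication_rate"] = 1.0 - pct["unique"] / pct["total"]
    frip_table, _frip_agg = frip(fragments, peaks)
    pct = pct.merge(
        frip_table[["cell", "target", "n_fragments", "n_in_peak", "frip"]],
        on=["cell", "target"],
        how="left",
    )
    dna_unique = fragments.groupby("cell", observed=True).size()
    rna_unique = molecules.groupby("cell", observed=True).size()
    cells = sorted(set(dna_unique.index) | set(rna_unique.index))
    per_cell = pd.DataFrame(
        {
            "dna_unique": dna_unique.reindex(cells, fill_value=0),
            "rna_unique": rna_unique.reindex(cells, fill_value=0),
        },
        index=pd.Index(cells, name="cell"),
    )
    if count_matrix is not None:
        genes_det = pd.Series(
            count_matrix.genes_detected_per_cell(), index=count_matrix.cell_ids
        )
        per_cell["genes_detected"] = genes_det.reindex([str(c) for c in cells]).to_numpy()
    passing, recovery = filter_cells(
        per_cell, dna_min=dna_min, rna_min=rna_min, n_input=n_cells_loaded
    )
    per_cell["pass"] = per_cell.index.isin(passing)
    dataset = {
        "n_cells_observed": int(len(per_cell)),
        "n_cells_passing": int(len(passing)),
        "recovery_rate": float(recovery),
        "dna_min": dna_min,
        "rna_min": rna_min,
        "duplication_rate": float(1.0 - pct["unique"].sum() / pct["total"].sum())
        if len(pct)
        else None,
        "collision_estimate_linear": collision_rate(
            n_cells_loaded or len(per_cell), design.combinations(), "linear"
        ),
    }
    if demux_stats is not None:
        dataset["demux_total"] = demux_stats.total
        dataset["demux_valid_fraction"] = demux_stats.valid_fraction
        dataset["demux_counts"] = dict(demux_stats.counts)
    return QCReport(per_cell_target=pct, per_cell=per_cell, dataset=dataset)
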