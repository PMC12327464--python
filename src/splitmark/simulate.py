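"""Ground-truthed simulator for split-pool multi-target single-cell libraries.

The generator inverts the assay's read structure: it draws a random genome,
assigns each cell a type and a unique three-round barcode combination, places
per-target DNA fragments either inside target/cell-type-specific peak regions
(with probability ``frip``) or in background (rejection-sampled off-peak, so
the realised in-peak fraction is exactly binomial around ``frip``), draws RNA
molecules from cell-type-weighted gene expression, and emits paired reads:

* Read1 — the fragment's 5' end (DNA) or an exonic 50-nt window (RNA);
* Read2 — ``BC3 + linker + BC2 + linker + BC1 + linker + ID + UMI`` (127 nt),
  with optional uniform per-base substitution errors.

Molecule counts per cell are negative-binomially distributed per target; PCR
duplication is modelled by re-emitting each molecule ``duplication_factor``
times. One IgG-like target receives background-only fragments. Identical seeds
give byte-identical output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._encode import _BASES, _CODE, random_dna_array, revcomp_matrix, to_matrix
from .barcodes import BarcodeDesign


def _default_fragments_per_cell():
    return {"H3K27me3": (1400.0, 10.0), "H3K27ac": (1400.0, 10.0), "IgG": (300.0, 10.0)}


@dataclass
class Scenario:
    """Study conditions for one simulated experiment.

    Negative-binomial parameters are (mean, dispersion r); variance is
    ``mean + mean**2 / r``. Defaults describe a 500-cell run with two active
    marks plus an IgG background target, in-peak probability 0.8 per mark,
    duplication factor 2, and per-cell depths chosen so that the standard
    quality thresholds (DNA > 2500 summed over targets, RNA > 2000) split the
    population into a realistic pass/fail mixture (~ half recovery).
    """

    n_cells: int = 500
    cell_types: tuple = (("typeA", 0.5), ("typeB", 0.5))
    marks: tuple = ("H3K27me3", "H3K27ac")
    control: str = "IgG"
    contigs: tuple = (("chr1", 3_000_000), ("chr2", 2_000_000))
    peaks_per_mark_per_type: int = 150
    peak_width: int = 3000
    frip: float = 0.8
    fragments_per_cell: dict = field(default_factory=_default_fragments_per_cell)
    n_genes: int = 200
    gene_length: int = 1000
    marker_fraction: float = 0.25
    marker_boost: float = 4.0
    umis_per_cell: tuple = (2300.0, 10.0)
    rt_label: str = "RT1"
    barcode_error_rate: float = 0.0
    duplication_factor: int = 2
    fragment_length: tuple = (150, 500)
    read1_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(p for _, p in self.cell_types) - 1.0) > 1e-9:
            raise ValueError("cell-type proportions must sum to 1")
        if not 0.0 <= self.frip <= 1.0:
            raise ValueError("frip must be in [0, 1]")
        if not 0.0 <= self.barcode_error_rate < 1.0:
            raise ValueError("barcode_error_rate must be in [0, 1)")
        if self.duplication_factor < 1:
            raise ValueError("duplication_factor must be >= 1")
        if self.peak_width < self.fragment_length[1]:
            raise ValueError("peak_width must accommodate the longest fragment")
        if self.gene_length < self.read1_length:
            raise ValueError("gene_length must accommodate read1_length")
        missing = [t for t in (*self.marks, self.control) if t not in self.fragments_per_cell]
        if missing:
            raise ValueError(f"fragments_per_cell missing parameters for {missing}")

    @property
    def targets(self) -> tuple:
        return (*self.marks, self.control)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["cell_types"] = [list(x) for x in self.cell_types]
        data["contigs"] = [list(x) for x in self.contigs]
        data["fragments_per_cell"] = {k: list(v) for k, v in self.fragments_per_cell.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("cell_types", "contigs", "marks", "umis_per_cell", "fragment_length"):
            if key in data:
                data[key] = tuple(tuple(x) if isinstance(x, list) else x for x in data[key]) \
                    if key in ("cell_types", "contigs") else tuple(data[key])
        if "fragments_per_cell" in data:
            data["fragments_per_cell"] = {k: tuple(v) for k, v in data["fragments_per_cell"].items()}
        return cls(**data)


def _nb(rng, mean, r, size):
    """Negative-binomial draw parameterised by (mean, dispersion)."""
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/touching intervals per contig (BED-style)."""
    out = []
    for contig, sub in df.groupby("contig", sort=True):
        sub = sub.sort_values("start")
        starts, ends = [], []
        for s, e in zip(sub["start"], sub["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out.append(pd.DataFrame({"contig": contig, "start": starts, "end": ends}))
    return pd.concat(out, ignore_index=True) if out else df.iloc[:0].copy()


class SimulatedRun:
    """Output of :func:`simulate`: genome, truth tables and read streams.

    Molecule-level truth is stored in compact arrays; reads are synthesised on
    demand (deterministically) so multi-million-read runs never hold all read
    matrices in memory at once.
    """

    def __init__(self, scenario: Scenario, design: BarcodeDesign):
        self.scenario = scenario
        self.design = design
        rng = np.random.default_rng(scenario.seed)
        self._build_genome(rng)
        self._build_cells(rng)
        self._build_peaks_and_genes(rng)
        self._build_dna_molecules(rng)
        self._build_rna_molecules(rng)
        f = scenario.duplication_factor
        self.n_molecules = self._dna_n + self._rna_n
        self.total_reads = self.n_molecules * f
        self._perm = rng.permutation(self.total_reads).astype(np.int64)
        # independent substream so read synthesis is restartable
        self._error_seed = int(rng.integers(0, 2**31 - 1))

    # -- construction -------------------------------------------------------

    def _build_genome(self, rng) -> None:
        self.contig_names = [name for name, _ in self.scenario.contigs]
        self.contig_lengths = {name: int(ln) for name, ln in self.scenario.contigs}
        self.genome = {name: random_dna_array(rng, ln) for name, ln in self.scenario.contigs}
        lens = np.array([self.contig_lengths[c] for c in self.contig_names], dtype=np.int64)
        self._offsets = np.concatenate([[0], np.cumsum(lens)])
        self._flat_genome = np.concatenate([self.genome[c] for c in self.contig_names])

    def _build_cells(self, rng) -> None:
        sc = self.scenario
        n_comb = self.design.combinations()
        if sc.n_cells > n_comb:
            raise ValueError("more cells than barcode combinations")
        combos = rng.choice(n_comb, size=sc.n_cells, replace=False)
        n1 = len(self.design.rounds[0])
        n2 = len(self.design.rounds[1])
        bc1 = combos % n1
        bc2 = (combos // n1) % n2
        bc3 = combos // (n1 * n2)
        probs = np.array([p for _, p in sc.cell_types])
        types = rng.choice(len(probs), size=sc.n_cells, p=probs)
        self.cells = pd.DataFrame(
            {
                "cell": np.arange(sc.n_cells),
                "bc1": bc1.astype(np.int32),
                "bc2": bc2.astype(np.int32),
                "bc3": bc3.astype(np.int32),
                "cell_type": [sc.cell_types[t][0] for t in types],
                "type_idx": types.astype(np.int32),
                "collided_with": np.full(sc.n_cells, -1, dtype=np.int64),
                "collided": np.zeros(sc.n_cells, dtype=bool),
            }
        )

    def cell_id_strings(self) -> list[str]:
        r1, r2, r3 = self.design.rounds[:3]
        return [
            f"{r1[a]}:{r2[b]}:{r3[c]}"
            for a, b, c in zip(self.cells["bc1"], self.cells["bc2"], self.cells["bc3"])
        ]

    def _sample_intervals(self, rng, n, width) -> tuple[np.ndarray, np.ndarray]:
        """n interval starts of fixed width, contigs weighted by length."""
        lens = np.array([self.contig_lengths[c] for c in self.contig_names], dtype=np.float64)
        contig = rng.choice(len(lens), size=n, p=lens / lens.sum())
        start = (rng.random(n) * (lens[contig] - width)).astype(np.int64)
        return contig, start

    def _build_peaks_and_genes(self, rng) -> None:
        sc = self.scenario
        self.peaks = {}  # (mark, type_name) -> DataFrame(contig, start, end)
        for mark in sc.marks:
            for type_name, _ in sc.cell_types:
                contig, start = self._sample_intervals(rng, sc.peaks_per_mark_per_type, sc.peak_width)
                self.peaks[(mark, type_name)] = pd.DataFrame(
                    {
                        "contig": [self.contig_names[c] for c in contig],
                        "start": start,
                        "end": start + sc.peak_width,
                    }
                )
        self.merged_peaks = {
            mark: _merge_intervals(
                pd.concat([self.peaks[(mark, t)] for t, _ in sc.cell_types], ignore_index=True)
            )
            for mark in sc.marks
        }
        # genes: non-overlapping, evenly spaced across contigs (toy transcript model)
        lens = np.array([self.contig_lengths[c] for c in self.contig_names], dtype=np.float64)
        per_contig = np.maximum(1, np.round(sc.n_genes * lens / lens.sum()).astype(int))
        per_contig[-1] = sc.n_genes - per_contig[:-1].sum()
        rows = []
        g = 0
        for ci, name in enumerate(self.contig_names):
            k = int(per_contig[ci])
            spacing = self.contig_lengths[name] / k
            if spacing < sc.gene_length:
                raise ValueError("genes do not fit on the genome without overlap")
            for j in range(k):
                s = int(j * spacing)
                rows.append((name, s, s + sc.gene_length, f"gene{g:04d}", 0, "+"))
                g += 1
        self.genes = pd.DataFrame(
            rows, columns=["contig", "start", "end", "name", "score", "strand"]
        )

    def _off_peak_positions(self, rng, n, lengths, merged: pd.DataFrame):
        """Rejection-sample n fragment placements avoiding the merged peaks."""
        contig = np.empty(n, dtype=np.int64)
        start = np.empty(n, dtype=np.int64)
        todo = np.arange(n)
        # per-contig sorted merged peaks for overlap queries
        peaks_by_contig = {
            ci: merged[merged["contig"] == cname].sort_values("start")
            for ci, cname in enumerate(self.contig_names)
        }
        while todo.size:
            c, s = self._sample_intervals_var(rng, lengths[todo])
            contig[todo] = c
            start[todo] = s
            bad = np.zeros(todo.size, dtype=bool)
            for ci, sub in peaks_by_contig.items():
                if sub.empty:
                    continue
                m = c == ci
                if not m.any():
                    continue
                ps = sub["start"].to_numpy()
                pe = sub["end"].to_numpy()
                fs = s[m]
                fe = fs + lengths[todo][m]
                idx = np.searchsorted(ps, fe, side="left") - 1
                overlap = (idx >= 0) & (pe[np.clip(idx, 0, None)] > fs)
                bad[m] = overlap
            todo = todo[bad]
        return contig, start

    def _sample_intervals_var(self, rng, lengths):
        lens = np.array([self.contig_lengths[c] for c in self.contig_names], dtype=np.float64)
        contig = rng.choice(len(lens), size=lengths.size, p=lens / lens.sum())
        start = (rng.random(lengths.size) * (lens[contig] - lengths)).astype(np.int64)
        return contig, start

    def _build_dna_molecules(self, rng) -> None:
        sc = self.scenario
        per_ct = []  # (cell, target_idx, count)
        for ti, target in enumerate(sc.targets):
            mean, r = sc.fragments_per_cell[target]
            counts = _nb(rng, mean, r, sc.n_cells)
            per_ct.append((ti, counts))
        cell = np.concatenate([np.repeat(np.arange(sc.n_cells), c) for _, c in per_ct])
        tgt = np.concatenate(
            [np.full(int(c.sum()), ti, dtype=np.int8) for ti, c in per_ct]
        )
        n = cell.size
        lmin, lmax = sc.fragment_length
        length = rng.integers(lmin, lmax + 1, size=n)
        is_mark = tgt < len(sc.marks)
        in_peak = np.zeros(n, dtype=bool)
        in_peak[is_mark] = rng.random(int(is_mark.sum())) < sc.frip
        contig = np.empty(n, dtype=np.int64)
        start = np.empty(n, dtype=np.int64)
        type_idx = self.cells["type_idx"].to_numpy()[cell]
        for ti, target in enumerate(sc.targets):
            for tyi, (type_name, _) in enumerate(sc.cell_types):
                m_on = (tgt == ti) & (type_idx == tyi) & in_peak
                if m_on.any():
                    pk = self.peaks[(target, type_name)]
                    pidx = rng.integers(0, len(pk), size=int(m_on.sum()))
                    ps = pk["start"].to_numpy()[pidx]
                    pc = pk["contig"].map(self.contig_names.index).to_numpy()[pidx]
                    slack = sc.peak_width - length[m_on]
                    start[m_on] = ps + (rng.random(int(m_on.sum())) * (slack + 1)).astype(np.int64)
                    contig[m_on] = pc
            m_off = (tgt == ti) & ~in_peak
            if m_off.any():
                merged = self.merged_peaks.get(target)
                if merged is None or merged.empty:
                    c, s = self._sample_intervals_var(rng, length[m_off])
                else:
                    c, s = self._off_peak_positions(rng, int(m_off.sum()), length[m_off], merged)
                contig[m_off] = c
                start[m_off] = s
        self._dna = {
            "cell": cell.astype(np.int32),
            "target": tgt,
            "contig": contig.astype(np.int8),
            "start": start,
            "end": start + length,
            "strand": (rng.random(n) < 0.5).astype(np.int8),  # 0='+', 1='-'
            "in_peak": in_peak,
            "umi": rng.integers(0, 4**8, size=n, dtype=np.uint32),
        }
        self._dna_n = n

    def _build_rna_molecules(self, rng) -> None:
        sc = self.scenario
        mean, r = sc.umis_per_cell
        counts = _nb(rng, mean, r, sc.n_cells)
        cell = np.repeat(np.arange(sc.n_cells), counts)
        n = cell.size
        # per-type gene weights: disjoint marker blocks boosted over base 1.0
        n_types = len(sc.cell_types)
        m = int(sc.marker_fraction * sc.n_genes)
        weights = np.ones((n_types, sc.n_genes))
        for t in range(n_types):
            weights[t, t * m : (t + 1) * m] = sc.marker_boost
        weights /= weights.sum(axis=1, keepdims=True)
        self.gene_weights = weights
        type_idx = self.cells["type_idx"].to_numpy()[cell]
        gene = np.empty(n, dtype=np.int64)
        for t in range(n_types):
            mask = type_idx == t
            gene[mask] = rng.choice(sc.n_genes, size=int(mask.sum()), p=weights[t])
        gs = self.genes["start"].to_numpy()[gene]
        gc = self.genes["contig"].map(self.contig_names.index).to_numpy()[gene]
        offset = rng.integers(0, sc.gene_length - sc.read1_length + 1, size=n)
        self._rna = {
            "cell": cell.astype(np.int32),
            "gene": gene.astype(np.int32),
            "contig": gc.astype(np.int8),
            "pos": gs + offset,
            "umi": rng.integers(0, 4**8, size=n, dtype=np.uint32),
        }
        self._rna_n = n

    # -- truth tables -------------------------------------------------------

    def cell_table(self) -> pd.DataFrame:
        out = self.cells.copy()
        out["cell_id"] = self.cell_id_strings()
        return out

    def dna_molecule_table(self) -> pd.DataFrame:
        sc = self.scenario
        d = self._dna
        return pd.DataFrame(
            {
                "cell": d["cell"],
                "target": [sc.targets[t] for t in d["target"]],
                "contig": [self.contig_names[c] for c in d["contig"]],
                "start": d["start"],
                "end": d["end"],
                "strand": np.where(d["strand"] == 0, "+", "-"),
                "in_peak": d["in_peak"],
            }
        )

    def rna_molecule_table(self) -> pd.DataFrame:
        r = self._rna
        return pd.DataFrame(
            {
                "cell": r["cell"],
                "gene": self.genes["name"].to_numpy()[r["gene"]],
                "contig": [self.contig_names[c] for c in r["contig"]],
                "pos": r["pos"],
                "umi": r["umi"],
            }
        )

    def molecule_of_read(self, serials: np.ndarray) -> np.ndarray:
        """Global molecule index (DNA first, then RNA) for read serials."""
        return self._perm[serials] // self.scenario.duplication_factor

    def truth_read_table(self) -> pd.DataFrame:
        """One row per emitted read: identity and true origin (small runs)."""
        sc = self.scenario
        mol = self.molecule_of_read(np.arange(self.total_reads))
        is_dna = mol < self._dna_n
        cid = np.array(self.cell_id_strings())
        rows = {
            "read": np.arange(self.total_reads),
            "modality": np.where(is_dna, "DNA", "RNA"),
        }
        cell = np.where(is_dna, self._dna["cell"][np.clip(mol, 0, self._dna_n - 1)],
                        self._rna["cell"][np.clip(mol - self._dna_n, 0, max(self._rna_n - 1, 0))])
        rows["cell"] = cell
        rows["cell_id"] = cid[cell]
        tgt = np.empty(self.total_reads, dtype=object)
        tgt[is_dna] = [sc.targets[t] for t in self._dna["target"][mol[is_dna]]]
        tgt[~is_dna] = sc.rt_label
        rows["target_or_rt"] = tgt
        umi = np.where(is_dna, self._dna["umi"][np.clip(mol, 0, self._dna_n - 1)],
                       self._rna["umi"][np.clip(mol - self._dna_n, 0, max(self._rna_n - 1, 0))])
        rows["umi"] = umi
        in_peak = np.zeros(self.total_reads, dtype=bool)
        in_peak[is_dna] = self._dna["in_peak"][mol[is_dna]]
        rows["in_peak"] = in_peak
        return pd.DataFrame(rows)

    def truth_unique_counts(self) -> pd.DataFrame:
        """Per-cell unique molecule counts after position-level deduplication.

        Applies the same rules the pipeline uses — DNA: distinct aligned
        5'-read intervals per (cell, target); RNA: distinct (position, UMI)
        per cell — to the truth coordinates, giving the exact expected
        unique counts for an error-free run.
        """
        sc = self.scenario
        L = sc.read1_length
        d = self._dna
        # the pipeline's single-end fragment key is the aligned read interval
        # plus orientation (standard single-end duplicate criterion)
        rs = np.where(d["strand"] == 0, d["start"], d["end"] - L)
        dna = pd.DataFrame(
            {"cell": d["cell"], "target": d["target"], "contig": d["contig"], "rs": rs,
             "strand": d["strand"]}
        )
        dna_unique = (
            dna.drop_duplicates().groupby("cell").size().reindex(range(sc.n_cells), fill_value=0)
        )
        per_target = (
            dna.drop_duplicates()
            .groupby(["cell", "target"])
            .size()
            .unstack(fill_value=0)
            .reindex(range(sc.n_cells), fill_value=0)
        )
        per_target.columns = [sc.targets[t] for t in per_target.columns]
        r = self._rna
        rna = pd.DataFrame({"cell": r["cell"], "contig": r["contig"], "pos": r["pos"], "umi": r["umi"]})
        rna_unique = (
            rna.drop_duplicates().groupby("cell").size().reindex(range(sc.n_cells), fill_value=0)
        )
        out = pd.DataFrame(
            {"dna_unique": dna_unique, "rna_unique": rna_unique}
        )
        for col in per_target.columns:
            out[f"dna_{col}"] = per_target[col]
        out.index.name = "cell"
        return out.fillna(0).astype(int)

    # -- read synthesis -----------------------------------------------------

    def _read2_template(self) -> np.ndarray:
        layout = self.design.layout
        tpl = np.full(layout.min_read_length, ord("A"), dtype=np.uint8)
        gaps = []
        spans = sorted(layout.span(n) for n in ("BC3", "BC2", "BC1", "ID", "UMI"))
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 > e1:
                gaps.append((e1, s2))
        linkers = self.design.linkers
        if len(linkers) < len(gaps):
            raise ValueError("design does not define enough linker sequences for the layout")
        for (gs, ge), linker in zip(gaps, linkers):
            if len(linker) != ge - gs:
                raise ValueError("linker length does not match layout gap")
            tpl[gs:ge] = np.frombuffer(linker.encode(), dtype=np.uint8)
        return tpl

    def iter_read_batches(self, batch_size: int = 500_000):
        """Yield dicts of read arrays in serial order (deterministic)."""
        sc = self.scenario
        design = self.design
        layout = design.layout
        tpl = self._read2_template()
        wl1 = to_matrix(list(design.rounds[0]))
        wl2 = to_matrix(list(design.rounds[1]))
        wl3 = to_matrix(list(design.rounds[2]))
        ab_by_target = {}
        for seq, t in design.antibody_index.items():
            ab_by_target[t] = seq
        id_seqs = [ab_by_target[t] for t in sc.targets]
        rt_seq = {v: k for k, v in design.rt_index.items()}[sc.rt_label]
        idm = to_matrix(id_seqs + [rt_seq])
        rt_row = len(id_seqs)
        err_rng = np.random.default_rng(self._error_seed)
        bc1 = self.cells["bc1"].to_numpy()
        bc2 = self.cells["bc2"].to_numpy()
        bc3 = self.cells["bc3"].to_numpy()
        L = sc.read1_length
        umi_len = layout.length("UMI")
        for lo in range(0, self.total_reads, batch_size):
            serials = np.arange(lo, min(lo + batch_size, self.total_reads))
            mol = self.molecule_of_read(serials)
            is_dna = mol < self._dna_n
            n = serials.size
            cell = np.where(is_dna, self._dna["cell"][np.clip(mol, 0, self._dna_n - 1)],
                            self._rna["cell"][np.clip(mol - self._dna_n, 0, max(self._rna_n - 1, 0))])
            umi = np.where(is_dna, self._dna["umi"][np.clip(mol, 0, self._dna_n - 1)],
                           self._rna["umi"][np.clip(mol - self._dna_n, 0, max(self._rna_n - 1, 0))])
            id_row = np.full(n, rt_row, dtype=np.int64)
            id_row[is_dna] = self._dna["target"][mol[is_dna]]
            # ---- Read2
            read2 = np.tile(tpl, (n, 1))
            s, e = layout.span("BC3")
            read2[:, s:e] = wl3[bc3[cell]]
            s, e = layout.span("BC2")
            read2[:, s:e] = wl2[bc2[cell]]
            s, e = layout.span("BC1")
            read2[:, s:e] = wl1[bc1[cell]]
            s, e = layout.span("ID")
            read2[:, s:e] = idm[id_row]
            s, e = layout.span("UMI")
            shifts = (2 * np.arange(umi_len - 1, -1, -1)).astype(np.uint32)
            codes = (umi[:, None] >> shifts[None, :]) & 3
            read2[:, s:e] = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
            if sc.barcode_error_rate > 0:
                mask = err_rng.random(read2.shape) < sc.barcode_error_rate
                k = int(mask.sum())
                if k:
                    orig = _CODE[read2[mask]]
                    read2[mask] = _BASES[(orig + err_rng.integers(1, 4, size=k)) % 4]
            # ---- Read1
            read1 = np.empty((n, L), dtype=np.uint8)
            if is_dna.any():
                dmol = mol[is_dna]
                strand = self._dna["strand"][dmol]
                start5 = np.where(strand == 0, self._dna["start"][dmol],
                                  self._dna["end"][dmol] - L)
                gpos = self._offsets[self._dna["contig"][dmol]] + start5
                block = self._flat_genome[gpos[:, None] + np.arange(L)[None, :]]
                neg = strand == 1
                if neg.any():
                    block[neg] = revcomp_matrix(block[neg])
                read1[is_dna] = block
            if (~is_dna).any():
                rmol = mol[~is_dna] - self._dna_n
                gpos = self._offsets[self._rna["contig"][rmol]] + self._rna["pos"][rmol]
                read1[~is_dna] = self._flat_genome[gpos[:, None] + np.arange(L)[None, :]]
            yield {
                "serial": serials,
                "read1": read1,
                "read2": read2,
                "cell": cell,
                "modality": np.where(is_dna, 0, 1).astype(np.int8),
            }

    def write_fastq(self, r1_path, r2_path, batch_size: int = 200_000) -> None:
        """Gzipped 4-line FASTQ pairs, names ``read{serial}``, quality 'I'."""
        q1 = "I" * self.scenario.read1_length
        q2 = "I" * self.design.layout.min_read_length
        with gzip.open(r1_path, "wt", compresslevel=2) as f1, \
                gzip.open(r2_path, "wt", compresslevel=2) as f2:
            for batch in self.iter_read_batches(batch_size):
                r1 = batch["read1"].tobytes()
                r2 = batch["read2"].tobytes()
                L1 = batch["read1"].shape[1]
                L2 = batch["read2"].shape[1]
                for i, serial in enumerate(batch["serial"]):
                    s1 = r1[i * L1 : (i + 1) * L1].decode()
                    s2 = r2[i * L2 : (i + 1) * L2].decode()
                    f1.write(f"@read{serial}\n{s1}\n+\n{q1}\n")
                    f2.write(f"@read{serial}\n{s2}\n+\n{q2}\n")

    def write_genome_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq(bytes(self.genome[c]).decode()), id=c, description="")
            for c in self.contig_names
        ]
        seqio_write(recs, str(path), "fasta")


def simulate(scenario: Scenario, design: BarcodeDesign) -> SimulatedRun:
    """Run the generator; identical scenario and design give identical output."""
    return SimulatedRun(scenario, design)


def inject_collisions(cells: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    """Reassign a Bernoulli(rate) fraction of cells the barcode combination of
    another cell, emulating barcode collisions. Both members of each colliding
    pair are flagged; reassigned cells record their partner in
    ``collided_with``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("collision rate must be in [0, 1)")
    out = cells.copy()
    if rate == 0.0 or len(out) < 2:
        return out
    hit = rng.random(len(out)) < rate
    keep = np.flatnonzero(~hit)
    if keep.size == 0:
        raise ValueError("collision rate left no unaffected cells to collide with")
    hit_idx = np.flatnonzero(hit)
    partners = keep[rng.integers(0, keep.size, size=hit_idx.size)]
    for col in ("bc1", "bc2", "bc3"):
        loc = out.columns.get_loc(col)
        out.iloc[hit_idx, loc] = out.iloc[partners, loc].to_numpy()
    out.iloc[hit_idx, out.columns.get_loc("collided_with")] = partners
    out.iloc[np.concatenate([hit_idx, partners]), out.columns.get_loc("collided")] = True
    return out
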