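"""Decode the barcode read into (cell, modality, target/RT, UMI) assignments.

Segments are taken from fixed positions of Read2 (no anchoring or sliding) and
matched against the round whitelists either exactly (default, mirroring
exact/unique forward-strand matching) or allowing a single substitution when
the whitelists have minimum pairwise distance >= 3, which makes 1-mismatch
correction unambiguous. The UMI is never corrected; it is recorded verbatim,
including any 'N'. Failure precedence follows read order (BC3 first), so the
reported failure class for a multiply-bad read is deterministic.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field

import numpy as np

from ._encode import encode_kmers, encode_seq, to_matrix, to_strings
from .barcodes import BarcodeDesign, InvalidDesignError, ReadLayout

STATUS_NAMES = ("valid", "bad_BC3", "bad_BC2", "bad_BC1", "bad_ID", "too_short", "ambiguous")
VALID, BAD_BC3, BAD_BC2, BAD_BC1, BAD_ID, TOO_SHORT, AMBIGUOUS = range(7)

MODALITY_DNA, MODALITY_RNA, MODALITY_NONE = 0, 1, -1


@dataclass
class DemuxStats:
    """Read-conservation bookkeeping: valid + every failure class = total."""

    total: int = 0
    counts: dict = field(default_factory=lambda: {name: 0 for name in STATUS_NAMES})
    per_target: dict = field(default_factory=dict)

    def add(self, status_codes: np.ndarray, target_labels: list[str] | None = None) -> None:
        self.total += int(status_codes.size)
        binc = np.bincount(status_codes, minlength=len(STATUS_NAMES))
        for code, name in enumerate(STATUS_NAMES):
            self.counts[name] += int(binc[code])
        if target_labels is not None:
            for t in target_labels:
                self.per_target[t] = self.per_target.get(t, 0) + 1

    @property
    def valid_fraction(self) -> float:
        return self.counts["valid"] / self.total if self.total else float("nan")

    def check_conservation(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise AssertionError("demux conservation violated: valid + failures != total")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"total": self.total, "counts": self.counts, "per_target": self.per_target},
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# Scalar reference operations (the vectorised batch path below is equivalent)
# ---------------------------------------------------------------------------

def parse_read2(sequence: str, layout: ReadLayout) -> tuple[str, str, str, str, str] | None:
    """Extract (BC3, BC2, BC1, ID, UMI) from fixed positions; None if too short."""
    if len(sequence) < layout.min_read_length:
        return None
    out = []
    for name in ("BC3", "BC2", "BC1", "ID", "UMI"):
        s, e = layout.span(name)
        out.append(sequence[s:e])
    return tuple(out)


def match_segment(raw: str, whitelist, max_mismatch: int = 0) -> str | None:
    """Match one raw segment against a whitelist.

    Returns the (corrected) whitelist member, or None on failure — including
    the ambiguous case where two members sit at Hamming distance 1.
    """
    entries = list(whitelist)
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if any(len(e) != len(raw) for e in entries):
        return None
    if raw in set(entries):
        return raw
    if max_mismatch == 0:
        return None
    hits = [e for e in entries if sum(a != b for a, b in zip(raw, e)) <= 1]
    return hits[0] if len(hits) == 1 else None


# ---------------------------------------------------------------------------
# Vectorised whitelist matcher
# ---------------------------------------------------------------------------

class SegmentMatcher:
    """Maps packed segment keys to whitelist indices.

    With ``max_mismatch=1`` every single-substitution neighbour of every
    whitelist entry is enumerated once up front; neighbours claimed by two or
    more entries resolve to 'ambiguous'. Exact membership always wins.
    """

    _AMBIG = -2
    _FAIL = -1

    def __init__(self, whitelist, max_mismatch: int = 0):
        self.entries = list(whitelist)
        self.length = len(self.entries[0])
        lut: dict[int, int] = {}
        for i, seq in enumerate(self.entries):
            lut[encode_seq(seq)] = i
        if len(lut) != len(self.entries):
            raise InvalidDesignError("duplicate whitelist entries")
        if max_mismatch == 1:
            exact = dict(lut)
            for i, seq in enumerate(self.entries):
                key = encode_seq(seq)
                for pos in range(self.length):
                    shift = 2 * (self.length - 1 - pos)
                    base = (key >> shift) & 3
                    for b in range(4):
                        if b == base:
                            continue
                        nb = (key & ~(3 << shift)) | (b << shift)
                        if nb in exact:
                            continue  # exact membership wins
                        prev = lut.get(nb)
                        if prev is None:
                            lut[nb] = i
                        elif prev != i:
                            lut[nb] = self._AMBIG
        keys = np.fromiter(lut.keys(), dtype=np.uint64, count=len(lut))
        vals = np.fromiter(lut.values(), dtype=np.int64, count=len(lut))
        order = np.argsort(keys)
        self._keys = keys[order]
        self._vals = vals[order]

    def match(self, keys: np.ndarray, key_valid: np.ndarray) -> np.ndarray:
        """Return whitelist index per key; -1 = no match, -2 = ambiguous."""
        pos = np.searchsorted(self._keys, keys)
        pos[pos == len(self._keys)] = 0
        hit = (self._keys[pos] == keys) & key_valid
        out = np.full(keys.shape, self._FAIL, dtype=np.int64)
        out[hit] = self._vals[pos[hit]]
        return out


class Demultiplexer:
    """Vectorised Read2 decoder for one barcode design."""

    def __init__(self, design: BarcodeDesign, max_mismatch: int = 0, modality: str = "auto"):
        if modality not in ("DNA", "RNA", "auto"):
            raise ValueError("modality must be DNA, RNA or auto")
        if modality == "auto" and not (design.antibody_index and design.rt_index):
            raise InvalidDesignError("auto modality needs both antibody and RT index tables")
        self.design = design
        self.modality = modality
        self.max_mismatch = max_mismatch
        bc1, bc2, bc3 = design.rounds[0], design.rounds[1], design.rounds[2]
        self._m = {
            "BC1": SegmentMatcher(bc1, max_mismatch),
            "BC2": SegmentMatcher(bc2, max_mismatch),
            "BC3": SegmentMatcher(bc3, max_mismatch),
        }
        ab = list(design.antibody_index)
        rt = list(design.rt_index)
        if modality == "DNA":
            id_entries, self._id_modality = ab, np.zeros(len(ab), dtype=np.int8)
        elif modality == "RNA":
            id_entries, self._id_modality = rt, np.ones(len(rt), dtype=np.int8)
        else:
            id_entries = ab + rt
            self._id_modality = np.array([MODALITY_DNA] * len(ab) + [MODALITY_RNA] * len(rt),
                                         dtype=np.int8)
        self._m["ID"] = SegmentMatcher(id_entries, max_mismatch)
        self.id_labels = [design.antibody_index.get(s) or design.rt_index[s] for s in id_entries]

    def annotate_matrix(self, read2: np.ndarray) -> dict:
        """Decode a (n, >=min_read_length) ASCII matrix of Read2 sequences.

        Returns a dict of arrays: ``status`` (codes into STATUS_NAMES),
        ``bc1``/``bc2``/``bc3`` whitelist indices, ``id_idx`` index into
        ``id_labels``, ``modality`` (0=DNA, 1=RNA, -1), and the verbatim
        ``umi`` ASCII matrix.
        """
        layout = self.design.layout
        n = read2.shape[0]
        if read2.shape[1] < layout.min_read_length:
            raise ValueError("Read2 matrix narrower than layout; filter short reads upstream")
        status = np.full(n, VALID, dtype=np.int8)
        seg_idx = {}
        for name, bad in (("BC3", BAD_BC3), ("BC2", BAD_BC2), ("BC1", BAD_BC1), ("ID", BAD_ID)):
            s, e = layout.span(name)
            keys, kv = encode_kmers(read2[:, s:e])
            idx = self._m[name].match(keys, kv)
            seg_idx[name] = idx
            # precedence: only label reads not already failed on an earlier segment
            fresh = status == VALID
            status[fresh & (idx == SegmentMatcher._FAIL)] = bad
            status[fresh & (idx == SegmentMatcher._AMBIG)] = AMBIGUOUS
        us, ue = layout.span("UMI")
        modality = np.where(
            seg_idx["ID"] >= 0, self._id_modality[np.clip(seg_idx["ID"], 0, None)], MODALITY_NONE
        ).astype(np.int8)
        modality[status != VALID] = MODALITY_NONE
        return {
            "status": status,
            "bc1": seg_idx["BC1"],
            "bc2": seg_idx["BC2"],
            "bc3": seg_idx["BC3"],
            "id_idx": seg_idx["ID"],
            "modality": modality,
            "umi": read2[:, us:ue].copy(),
        }

    def cell_ids(self, ann: dict, mask: np.ndarray | None = None) -> list[str]:
        """'BC1:BC2:BC3' strings built from the matched whitelist sequences."""
        bc1, bc2, bc3 = self.design.rounds[0], self.design.rounds[1], self.design.rounds[2]
        idx = np.flatnonzero(mask) if mask is not None else np.arange(len(ann["status"]))
        return [
            f"{bc1[ann['bc1'][i]]}:{bc2[ann['bc2'][i]]}:{bc3[ann['bc3'][i]]}" for i in idx
        ]


# ---------------------------------------------------------------------------
# FASTQ-level driver
# ---------------------------------------------------------------------------

def _open_maybe_gz(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def annotate_fastq(
    r1_path,
    r2_path,
    design: BarcodeDesign,
    out_r1,
    rejects_r1=None,
    modality: str = "auto",
    max_mismatch: int = 0,
    chunk_size: int = 200_000,
) -> DemuxStats:
    """Demultiplex paired FASTQ: valid reads are re-emitted as Read1 records
    named ``cell_id:target_or_rt:umi:serial``; rejects keep their original name
    with the failure class appended as a comment. Returns conservation stats.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    demux = Demultiplexer(design, max_mismatch=max_mismatch, modality=modality)
    stats = DemuxStats()
    min_len = design.layout.min_read_length
    serial = 0
    with _open_maybe_gz(r1_path) as fh1, _open_maybe_gz(r2_path) as fh2, \
            _open_maybe_gz(out_r1, "wt") as out:
        rej = _open_maybe_gz(rejects_r1, "wt") if rejects_r1 is not None else None
        try:
            it = zip(FastqGeneralIterator(fh1), FastqGeneralIterator(fh2))
            batch: list[tuple] = []
            while True:
                batch = [rec for rec, _ in zip(it, range(chunk_size))]
                if not batch:
                    break
                _annotate_batch(batch, demux, min_len, stats, out, rej, serial)
                serial += len(batch)
        finally:
            if rej is not None:
                rej.close()
    stats.check_conservation()
    return stats


def _annotate_batch(batch, demux, min_len, stats, out, rej, serial0):
    short = [len(r2seq) < min_len for (_t1, (_n2, r2seq, _q2)) in batch]
    full = [i for i, s in enumerate(short) if not s]
    if full:
        mat = to_matrix([batch[i][1][1][:min_len] for i in full])
        ann = demux.annotate_matrix(mat)
    else:
        ann = None
    n = len(batch)
    status = np.full(n, TOO_SHORT, dtype=np.int8)
    if ann is not None:
        status[np.array(full)] = ann["status"]
    valid_mask_full = ann["status"] == VALID if ann is not None else np.zeros(0, bool)
    cell_ids = demux.cell_ids(ann, valid_mask_full) if ann is not None else []
    umis = to_strings(ann["umi"][valid_mask_full]) if ann is not None and valid_mask_full.any() else []
    labels = [demux.id_labels[j] for j in ann["id_idx"][valid_mask_full]] if ann is not None else []
    stats.add(status, labels)
    k = 0
    pos_in_full = {gi: li for li, gi in enumerate(full)}
    valid_local = np.flatnonzero(valid_mask_full) if ann is not None else np.array([], int)
    local_rank = {int(v): r for r, v in enumerate(valid_local)}
    for i, ((n1, s1, q1), (_n2, _s2, _q2)) in enumerate(batch):
        li = pos_in_full.get(i)
        if li is not None and ann["status"][li] == VALID:
            r = local_rank[li]
            name = f"{cell_ids[r]}:{labels[r]}:{umis[r]}:{serial0 + i}"
            out.write(f"@{name}\n{s1}\n+\n{q1}\n")
            k += 1
        elif rej is not None:
            st = STATUS_NAMES[status[i]]
            rej.write(f"@{n1} status={st}\n{s1}\n+\n{q1}\n")
    return k


def split_read_name(name: str) -> tuple[str, str, str, int]:
    """Parse 'BC1:BC2:BC3:target:umi:serial' into (cell_id, target, umi, serial)."""
    parts = name.split(":")
    if len(parts) != 6:
        raise ValueError(f"unparsable read name {name!r}")
    return ":".join(parts[:3]), parts[3], parts[4], int(parts[5])
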