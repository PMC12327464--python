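"""Barcode architecture of split-pool multi-target single-cell libraries.

Cells are labelled by three rounds of split-pool ligation (48 barcodes of 8 nt
per round by default), giving a combinatorial cell-identifying space of
``48**3 = 110592``. A fourth, 5-nt index at a fixed position distinguishes the
molecule's origin: an antibody index (which antibody-Tn5 complex, hence which
chromatin target, produced a DNA fragment) or an RT index (reverse-transcription
primer, marking RNA-derived molecules). Because every cell receives all antibody
indexes, the ID segment does not identify cells and is excluded from the
capacity calculation by default.

The barcode read (Read2) has a fixed layout::

    BC3 [1-8]  linker  BC2 [39-46]  linker  BC1 [77-84]  linker  ID [115-119]  UMI [120-127]

(1-based inclusive, as conventionally printed; stored 0-based half-open.)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._encode import to_matrix


class InvalidDesignError(ValueError):
    """Raised when a barcode design or whitelist violates its invariants."""


# ---------------------------------------------------------------------------
# Read2 layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadLayout:
    """Fixed-position segments of the barcode read, 0-based half-open."""

    segments: tuple[tuple[str, int, int], ...]  # (name, start, length)

    def __post_init__(self) -> None:
        spans = sorted((s, s + ln) for _, s, ln in self.segments)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise InvalidDesignError("layout segments overlap")
        if any(ln <= 0 or s < 0 for _, s, ln in self.segments):
            raise InvalidDesignError("segment coordinates must be non-negative with positive length")

    @classmethod
    def default(cls) -> "ReadLayout":
        return cls.from_one_based(
            {"BC3": (1, 8), "BC2": (39, 46), "BC1": (77, 84), "ID": (115, 119), "UMI": (120, 127)}
        )

    @classmethod
    def from_one_based(cls, coords: dict[str, tuple[int, int]]) -> "ReadLayout":
        """Build from 1-based inclusive (start, end) coordinates."""
        return cls(tuple((name, s - 1, e - s + 1) for name, (s, e) in coords.items()))

    def to_one_based(self) -> dict[str, list[int]]:
        return {name: [s + 1, s + ln] for name, s, ln in self.segments}

    @property
    def min_read_length(self) -> int:
        return max(s + ln for _, s, ln in self.segments)

    def span(self, name: str) -> tuple[int, int]:
        """(start, end) of a named segment, 0-based half-open."""
        for n, s, ln in self.segments:
            if n == name:
                return s, s + ln
        raise KeyError(name)

    def length(self, name: str) -> int:
        s, e = self.span(name)
        return e - s


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass
class BarcodeDesign:
    """Whitelists for each split-pool round plus the antibody/RT index tables.

    ``rounds`` is ordered by ligation round: ``rounds[0]`` is BC1, ``rounds[2]``
    is BC3 (read first on Read2). ``antibody_index`` maps 5-nt sequences to
    chromatin-target names (including the IgG background control);
    ``rt_index`` maps 5-nt sequences to sample labels for RNA molecules.
    ``linkers`` are the fixed spacer sequences between barcode segments; they
    are needed to synthesise reads but are never matched during decoding.
    """

    rounds: tuple[tuple[str, ...], ...]
    antibody_index: dict[str, str]
    rt_index: dict[str, str]
    layout: ReadLayout = field(default_factory=ReadLayout.default)
    linkers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.rounds:
            raise InvalidDesignError("design needs at least one barcoding round")
        for i, wl in enumerate(self.rounds):
            if len(wl) == 0:
                raise InvalidDesignError(f"round {i + 1} whitelist is empty")
            if len(set(wl)) != len(wl):
                raise InvalidDesignError(f"round {i + 1} whitelist has duplicate entries")
            if len({len(s) for s in wl}) != 1:
                raise InvalidDesignError(f"round {i + 1} barcodes have unequal lengths")
        for table, what in ((self.antibody_index, "antibody"), (self.rt_index, "rt")):
            if table and len({len(s) for s in table}) != 1:
                raise InvalidDesignError(f"{what} index sequences have unequal lengths")
        if set(self.antibody_index) & set(self.rt_index):
            raise InvalidDesignError("antibody and RT index sequences must be disjoint")

    # -- capacity -----------------------------------------------------------

    def combinations(self, include_ids: bool = False) -> int:
        """Number of distinct barcode combinations.

        By default only the cell-identifying BC1 x BC2 x BC3 space is counted;
        ``include_ids=True`` additionally multiplies by the number of ID
        sequences (useful when several RT indexes are used per sublibrary and
        genuinely extend cell identity).
        """
        n = 1
        for wl in self.rounds:
            n *= len(wl)
        if include_ids:
            n *= len(self.antibody_index) + len(self.rt_index)
        return n

    def targets(self) -> list[str]:
        return list(dict.fromkeys(self.antibody_index.values()))

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "rounds": [list(wl) for wl in self.rounds],
            "antibody_index": dict(self.antibody_index),
            "rt_index": dict(self.rt_index),
            # printed 1-based inclusive, as in protocol write-ups
            "layout": self.layout.to_one_based(),
            "linkers": list(self.linkers),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BarcodeDesign":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            rounds=tuple(tuple(wl) for wl in data["rounds"]),
            antibody_index=dict(data["antibody_index"]),
            rt_index=dict(data["rt_index"]),
            layout=ReadLayout.from_one_based(
                {k: tuple(v) for k, v in data["layout"].items()}
            ),
            linkers=tuple(data.get("linkers", ())),
        )


def combinations(design: BarcodeDesign, include_ids: bool = False) -> int:
    """Barcode-space capacity; see :meth:`BarcodeDesign.combinations`."""
    return design.combinations(include_ids=include_ids)


# ---------------------------------------------------------------------------
# Collision combinatorics
# ---------------------------------------------------------------------------

def collision_rate(n_cells: int, n_combinations: int, method: str = "linear") -> float:
    """Estimated probability that a cell shares its barcode combination.

    ``linear``
        ``n_cells / n_combinations`` (clipped at 1) — the occupancy-fraction
        estimate conventionally quoted for split-pool designs.
    ``birthday``
        ``1 - (1 - 1/B)**(n_cells - 1)`` — the exact probability that a given
        cell collides with at least one other under uniform assignment.
    """
    if n_cells < 1 or n_combinations < 1:
        raise ValueError("n_cells and n_combinations must be positive")
    if method == "linear":
        return min(n_cells / n_combinations, 1.0)
    if method == "birthday":
        return 1.0 - (1.0 - 1.0 / n_combinations) ** (n_cells - 1)
    raise ValueError(f"unknown method {method!r}")


def min_pairwise_distance(whitelist) -> int:
    """Minimum Hamming distance over all pairs of whitelist sequences.

    Guards mismatch-correction safety: single-substitution correction is
    unambiguous iff this is >= 3.
    """
    seqs = list(whitelist)
    if len(seqs) < 2:
        raise InvalidDesignError("need at least two sequences")
    if len(set(seqs)) != len(seqs):
        raise InvalidDesignError("whitelist contains duplicate sequences")
    try:
        m = to_matrix(seqs)
    except ValueError as exc:
        raise InvalidDesignError("whitelist sequences have unequal lengths") from exc
    # all-pairs Hamming; whitelists are small (tens of entries)
    d = (m[:, None, :] != m[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, d.max() + 1)
    return int(d.min())


# ---------------------------------------------------------------------------
# Whitelist construction and I/O
# ---------------------------------------------------------------------------

def make_whitelist(
    n: int, length: int, min_distance: int, rng: np.random.Generator, max_trials: int = 2_000_000
) -> tuple[str, ...]:
    """Greedy random construction of ``n`` barcodes with pairwise Hamming
    distance >= ``min_distance``."""
    kept: list[np.ndarray] = []
    for _ in range(max_trials):
        cand = rng.integers(0, 4, size=length)
        if all(int((a != cand).sum()) >= min_distance for a in kept):
            kept.append(cand)
            if len(kept) == n:
                break
    else:
        raise InvalidDesignError(
            f"could not place {n} barcodes of length {length} at distance >= {min_distance}"
        )
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return tuple(bytes(alphabet[c]).decode() for c in kept)


_DEFAULT_TARGETS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "H3K36me3", "IgG")
_DEFAULT_SEED = 20_240_817  # fixed so the shipped default design is stable


def default_design(
    n_per_round: int = 48,
    barcode_length: int = 8,
    targets: tuple[str, ...] = _DEFAULT_TARGETS,
    rt_labels: tuple[str, ...] = ("RT1", "RT2"),
    min_distance: int = 4,
) -> BarcodeDesign:
    """The shipped 3 x 48 design with distance->=4 whitelists and 5-nt indexes.

    Distance >= 4 (rather than the minimum safe 3) keeps single-substitution
    correction unambiguous even for reads carrying two errors in one segment.
    """
    rng = np.random.default_rng(_DEFAULT_SEED)
    rounds = tuple(
        make_whitelist(n_per_round, barcode_length, min_distance, rng) for _ in range(3)
    )
    ids = make_whitelist(len(targets) + len(rt_labels), 5, min_distance, rng)
    antibody_index = dict(zip(ids[: len(targets)], targets))
    rt_index = dict(zip(ids[len(targets):], rt_labels))
    linkers = tuple("".join(rng.choice(list("ACGT"), 30)) for _ in range(3))
    return BarcodeDesign(
        rounds=rounds,
        antibody_index=antibody_index,
        rt_index=rt_index,
        layout=ReadLayout.default(),
        linkers=linkers,
    )


def write_whitelist_tsv(design: BarcodeDesign, path) -> None:
    """Headered TSV with columns name, sequence, role."""
    rows = []
    for r, wl in enumerate(design.rounds, start=1):
        for i, seq in enumerate(wl, start=1):
            rows.append((f"BC{r}-{i:02d}", seq, f"round{r}"))
    for seq, label in design.antibody_index.items():
        rows.append((label, seq, "antibody"))
    for seq, label in design.rt_index.items():
        rows.append((label, seq, "rt"))
    pd.DataFrame(rows, columns=["name", "sequence", "role"]).to_csv(path, sep="\t", index=False)


def read_whitelist_tsv(path, layout: ReadLayout | None = None,
                       linkers: tuple[str, ...] = ()) -> BarcodeDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    rounds = []
    for r in itertools.count(1):
        sub = df[df["role"] == f"round{r}"]
        if sub.empty:
            break
        rounds.append(tuple(sub["sequence"]))
    ab = df[df["role"] == "antibody"]
    rt = df[df["role"] == "rt"]
    return BarcodeDesign(
        rounds=tuple(rounds),
        antibody_index=dict(zip(ab["sequence"], ab["name"])),
        rt_index=dict(zip(rt["sequence"], rt["name"])),
        layout=layout or ReadLayout.default(),
        linkers=linkers,
    )
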