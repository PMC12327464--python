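"""Vectorised 2-bit nucleotide encoding shared by the demultiplexer and simulator.

Reads are handled as ``uint8`` ASCII matrices of shape (n_reads, read_length);
fixed-width segments are packed into ``uint64`` keys (2 bits per base) so that
whitelist matching reduces to integer set membership.
"""

from __future__ import annotations

import numpy as np

# A/C/G/T -> 0..3, everything else (incl. N) -> 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.full(256, ord("N"), dtype=np.uint8)
for _a, _b in zip(b"ACGTacgtNn", b"TGCATGCANN"):
    _COMP[_a] = _b

BASES = _BASES


def to_matrix(seqs: list[str] | list[bytes]) -> np.ndarray:
    """Stack equal-length sequences into a (n, L) uint8 ASCII matrix."""
    rows = [s.encode() if isinstance(s, str) else s for s in seqs]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    return np.frombuffer(b"".join(rows), dtype=np.uint8).reshape(len(rows), -1)


def to_strings(matrix: np.ndarray) -> list[str]:
    """Inverse of :func:`to_matrix`."""
    m = np.ascontiguousarray(matrix, dtype=np.uint8)
    raw = m.tobytes()
    ln = m.shape[1]
    return [raw[i : i + ln].decode() for i in range(0, len(raw), ln)]


def encode_kmers(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pack each row of an ASCII matrix into a uint64 key.

    Returns ``(keys, valid)`` where ``valid`` is False for rows containing any
    non-ACGT character (those rows get an arbitrary key and must be masked).
    Row length is limited to 32 bases.
    """
    if matrix.shape[1] > 32:
        raise ValueError("k-mer too long for 64-bit packing")
    codes = _CODE[matrix]
    valid = (codes < 4).all(axis=1)
    codes = np.where(codes < 4, codes, 0).astype(np.uint64)
    keys = np.zeros(matrix.shape[0], dtype=np.uint64)
    for j in range(matrix.shape[1]):
        keys = (keys << np.uint64(2)) | codes[:, j]
    return keys, valid


def encode_seq(seq: str) -> int:
    """Pack a single ACGT string into an integer key."""
    key, valid = encode_kmers(to_matrix([seq]))
    if not valid[0]:
        raise ValueError(f"non-ACGT character in {seq!r}")
    return int(key[0])


def decode_key(key: int, length: int) -> str:
    out = bytearray(length)
    for j in range(length - 1, -1, -1):
        out[j] = _BASES[key & 3]
        key >>= 2
    return out.decode()


def decode_keys(keys: np.ndarray, length: int) -> list[str]:
    """Unpack an array of integer keys back into ACGT strings."""
    keys = np.asarray(keys, dtype=np.uint64)
    shifts = (2 * np.arange(length - 1, -1, -1)).astype(np.uint64)
    codes = (keys[:, None] >> shifts[None, :]) & np.uint64(3)
    return to_strings(_BASES[codes.astype(np.intp)])


def revcomp_matrix(matrix: np.ndarray) -> np.ndarray:
    """Reverse-complement every row of an ASCII matrix."""
    return _COMP[matrix][:, ::-1]


def revcomp(seq: str) -> str:
    return bytes(_COMP[np.frombuffer(seq.encode(), dtype=np.uint8)][::-1]).decode()


def random_dna_array(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uniform random DNA as an ASCII uint8 array."""
    return _BASES[rng.integers(0, 4, size=length)]
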