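"""Canonical k-mer encoding shared by the mapper, subtraction and assembler.

k-mers over A/C/G/T are packed 2 bits per base into integers (k <= 31 fits a
uint64); the canonical form of a k-mer is the smaller of the packed forward
and reverse-complement values.  Windows containing any non-ACGT character are
treated as invalid and never indexed.
"""

from __future__ import annotations

import numpy as np

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i

_TO_DIGIT = str.maketrans("ACGT", "0123")
_ACGT_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (fast path; seqio handles full IUPAC)."""
    return seq.translate(_ACGT_COMP)[::-1]


def encode(kmer: str) -> int | None:
    """Pack one k-mer into an int, or None if it contains a non-ACGT base."""
    try:
        return int(kmer.translate(_TO_DIGIT), 4)
    except ValueError:
        return None


def decode(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[value & 3])
        value >>= 2
    return "".join(reversed(out))


def seq_codes(seq: str) -> np.ndarray:
    """Per-base 2-bit codes (255 marks non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rolling(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    arr = np.zeros(n, dtype=np.uint64)
    safe = np.where(codes > 3, 0, codes).astype(np.uint64)
    for j in range(k):
        arr = arr * np.uint64(4) + safe[j:j + n]
    return arr


def window_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All k-windows of ``seq`` as packed ints.

    Returns ``(fwd, canonical, valid)`` arrays of length ``len(seq) - k + 1``;
    ``valid`` is False for windows containing a non-ACGT base.
    """
    codes = seq_codes(seq)
    n = codes.size - k + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, z.copy(), np.zeros(0, dtype=bool)
    fwd = _rolling(codes, k)
    rc_codes = (np.uint8(3) - np.where(codes > 3, 3, codes).astype(np.uint8))[::-1]
    rc = _rolling(rc_codes, k)[::-1]
    bad = (codes > 3).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return fwd, np.minimum(fwd, rc), valid


def canonical_int(kmer: str) -> int | None:
    """Canonical packed value of one k-mer, or None if it contains non-ACGT."""
    f = encode(kmer)
    if f is None:
        return None
    r = encode(revcomp(kmer))
    return min(f, r)  # type: ignore[type-var]


def canonical_str(kmer: str) -> str:
    """Lexicographic canonicalization in string space (assembler convenience)."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def canonical_set(seqs: list[str] | tuple[str, ...], k: int) -> np.ndarray:
    """Sorted unique canonical k-mers from many sequences (one numpy pass)."""
    if not seqs:
        return np.zeros(0, dtype=np.uint64)
    joined = "N".join(seqs)
    _, canon, valid = window_kmers(joined, k)
    return np.unique(canon[valid])


def in_sorted(values: np.ndarray, sorted_keys: np.ndarray) -> np.ndarray:
    """Vectorized membership of ``values`` in a sorted unique key array."""
    if sorted_keys.size == 0:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(sorted_keys, values)
    idx_c = np.clip(idx, 0, sorted_keys.size - 1)
    return (idx < sorted_keys.size) & (sorted_keys[idx_c] == values)
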