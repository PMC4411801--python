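"""Vectorized k-mer encoding.

Sequences are encoded as 2-bit-per-base integer codes packed into uint64,
which supports k up to 31. Windows containing a non-ACGT base are marked
invalid rather than silently mis-encoded. Canonical codes collapse a k-mer
with its reverse complement (the numerically smaller packed code wins, which
for the 2-bit A<C<G<T encoding coincides with lexicographic order).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "encode_bases",
    "kmer_codes",
    "canonical_kmer_codes",
    "reverse_complement",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Return uint8 base codes (A=0 C=1 G=2 T=3, 255 = ambiguous)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed forward-strand k-mer codes for every window of ``codes``.

    Returns ``(kmers, valid)`` with ``kmers`` uint64 of length
    ``len(codes) - k + 1`` and ``valid`` a boolean mask that is False for
    windows containing an ambiguous base. Invalid windows hold arbitrary
    values and must be filtered via the mask.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = (codes == 255).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    safe = np.where(codes == 255, 0, codes).astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | safe[j : j + n]
    return out, valid


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Distinct-preserving canonical k-mer codes of ``seq`` (invalid windows
    dropped). Position i of the result corresponds to window i of the valid
    subset in sequence order."""
    codes = encode_bases(seq)
    fwd, valid = kmer_codes(codes, k)
    rc_codes = (3 - np.where(codes == 255, np.uint8(0), codes))[::-1]
    rc_codes = np.where(codes[::-1] == 255, np.uint8(255), rc_codes.astype(np.uint8))
    rev, _ = kmer_codes(rc_codes, k)
    rev = rev[::-1]
    canon = np.minimum(fwd, rev)
    return canon[valid]


def canonical_kmer_codes_with_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`canonical_kmer_codes` but also returns window start
    positions of the retained (valid) windows."""
    codes = encode_bases(seq)
    fwd, valid = kmer_codes(codes, k)
    rc_codes = np.where(codes[::-1] == 255, np.uint8(255), (3 - np.where(codes == 255, np.uint8(0), codes))[::-1].astype(np.uint8))
    rev, _ = kmer_codes(rc_codes, k)
    rev = rev[::-1]
    canon = np.minimum(fwd, rev)
    pos = np.nonzero(valid)[0]
    return canon[valid], pos
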