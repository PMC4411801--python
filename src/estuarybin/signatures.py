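"""Tetranucleotide signatures on 5-kb contig fragments.

Genomes carry a characteristic distribution of overlapping 4-mers; computed
on 5-kb windows of assembled contigs this signature is the primary binning
feature. Reverse-complement 4-mers are collapsed into 136 canonical classes
(16 palindromes plus (256-16)/2 strand pairs) so the signature does not
depend on contig orientation; the raw 256-class mode is available for
pipelines that did not collapse strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .kmers import reverse_complement

__all__ = [
    "Fragment",
    "TetraVector",
    "FeatureMatrix",
    "fragment_contigs",
    "canonical_tetramer",
    "tetramer_classes",
    "tetra_frequencies",
    "tetra_feature_matrix",
    "normalize_features",
]


@dataclass
class Fragment:
    """A window of a contig, 0-based half-open coordinates."""

    contig_id: str
    index: int
    start: int
    end: int
    sequence: str

    @property
    def fragment_id(self) -> str:
        return f"{self.contig_id}|{self.index}"


@dataclass
class TetraVector:
    values: np.ndarray  # length 136 (or 256 in raw mode), sums to 1
    n_windows: int


@dataclass
class FeatureMatrix:
    """Row-aligned feature table plus the normalization used to build it."""

    data: pd.DataFrame  # rows = fragment/contig ids, columns = feature names
    normalization: dict = field(default_factory=lambda: {"method": "none"})

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)


def fragment_contigs(
    contigs: dict[str, str],
    window: int = 5000,
    min_last: int | None = None,
    min_contig: int = 2500,
) -> list[Fragment]:
    """Cut contigs into consecutive non-overlapping windows.

    A terminal remainder of at least ``min_last`` (default ``window // 2``)
    becomes its own fragment, otherwise it is merged into the previous
    window; contigs shorter than ``min_contig`` yield no fragments.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if min_last is None:
        min_last = window // 2
    out: list[Fragment] = []
    for cid, seq in contigs.items():
        n = len(seq)
        if n < min_contig:
            continue
        bounds = list(range(0, n, window))
        if len(bounds) > 1 and n - bounds[-1] < min_last:
            bounds.pop()
        bounds.append(n)
        for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            out.append(Fragment(cid, i, s, e, seq[s:e]))
    return out


def canonical_tetramer(kmer: str) -> str:
    """Lexicographic minimum of a 4-mer and its reverse complement."""
    if len(kmer) != 4 or any(b not in "ACGT" for b in kmer):
        raise ValueError(f"not a canonicalizable tetramer: {kmer!r}")
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def tetramer_classes(canonical: bool = True) -> list[str]:
    """Feature names: 136 canonical classes (or all 256 raw tetramers),
    lexicographic order of class representatives."""
    all_kmers = ["".join(p) for p in product("ACGT", repeat=4)]
    if not canonical:
        return all_kmers
    return sorted({canonical_tetramer(k) for k in all_kmers})


_CODE4 = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE4[ord(_b)] = _i


def _class_index_table(canonical: bool) -> np.ndarray:
    """Map packed tetramer code (0..255) -> feature column index."""
    classes = tetramer_classes(canonical)
    col = {c: j for j, c in enumerate(classes)}
    table = np.empty(256, dtype=np.int64)
    all_kmers = ["".join(p) for p in product("ACGT", repeat=4)]
    for code, kmer in enumerate(all_kmers):
        key = canonical_tetramer(kmer) if canonical else kmer
        table[code] = col[key]
    return table


_TABLES = {True: _class_index_table(True), False: _class_index_table(False)}


def tetra_frequencies(sequence: str, canonical: bool = True) -> TetraVector:
    """Normalized tetramer frequencies over all valid overlapping windows.

    Windows containing a non-ACGT base are skipped; a fragment with no valid
    window is unusable and raises ``ValueError``.
    """
    if len(sequence) < 4:
        raise ValueError("sequence shorter than 4 bases")
    codes = _CODE4[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    n = codes.size - 3
    packed = (codes[:n] << 6) | (codes[1 : n + 1] << 4) | (codes[2 : n + 2] << 2) | codes[3 : n + 3]
    valid = (
        (codes[:n] >= 0) & (codes[1 : n + 1] >= 0)
        & (codes[2 : n + 2] >= 0) & (codes[3 : n + 3] >= 0)
    )
    packed = packed[valid]
    if packed.size == 0:
        raise ValueError("no valid 4-mer window in fragment")
    table = _TABLES[canonical]
    n_classes = 136 if canonical else 256
    counts = np.bincount(table[packed], minlength=n_classes).astype(float)
    return TetraVector(values=counts / counts.sum(), n_windows=int(packed.size))


def tetra_feature_matrix(
    fragments: list[Fragment],
    canonical: bool = True,
) -> FeatureMatrix:
    classes = tetramer_classes(canonical)
    rows = np.empty((len(fragments), len(classes)))
    for i, frag in enumerate(fragments):
        rows[i] = tetra_frequencies(frag.sequence, canonical).values
    df = pd.DataFrame(rows, index=[f.fragment_id for f in fragments], columns=classes)
    return FeatureMatrix(df)


def _robust_scale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (location, scale): median and MAD, falling back to the
    standard deviation when the MAD is degenerate (a sparse feature that is
    zero in most rows has MAD 0, and dividing by a tiny floor would blow
    occasional nonzero values up by orders of magnitude), and to 1 for a
    constant column so it maps to exact zeros."""
    loc = np.median(x, axis=0)
    mad = np.median(np.abs(x - loc), axis=0)
    std = x.std(axis=0)
    scale = np.where(mad > 1e-12, mad, np.where(std > 1e-12, std, 1.0))
    return loc, scale


def normalize_features(matrix: FeatureMatrix, method: str = "robust_z") -> FeatureMatrix:
    """Per-feature robust z-score: ``(x - median) / MAD`` with a standard
    deviation fallback for degenerate (mostly-zero) features and unit scale
    for constant ones. Location/scale are stored so the transform is
    invertible. ``method="none"`` passes through."""
    if method == "none":
        return FeatureMatrix(matrix.data.copy(), {"method": "none"})
    if method != "robust_z":
        raise ValueError(f"unknown normalization method: {method}")
    if len(matrix.data) < 2:
        raise ValueError("normalization needs at least 2 rows")
    x = matrix.data.to_numpy(dtype=float)
    loc, scale = _robust_scale(x)
    z = (x - loc) / scale
    df = pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)
    return FeatureMatrix(
        df,
        {"method": "robust_z", "location": loc, "scale": scale},
    )


def denormalize_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Invert :func:`normalize_features` using the stored metadata."""
    meta = matrix.normalization
    if meta.get("method") == "none":
        return FeatureMatrix(matrix.data.copy())
    x = matrix.data.to_numpy(dtype=float) * meta["scale"] + meta["location"]
    return FeatureMatrix(
        pd.DataFrame(x, index=matrix.data.index, columns=matrix.data.columns)
    )
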