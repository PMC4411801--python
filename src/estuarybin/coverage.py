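"""Per-library read recruitment and coverage signatures.

Genomes of different abundance leave different sequencing depths in each
library, so per-contig depth across libraries is a binning feature that
separates even compositionally identical genomes. Reads are recruited to
contigs by canonical k-mer containment (k = 21 by default): a read is
assigned to the contig sharing the largest fraction of the read's distinct
canonical k-mers, provided that fraction reaches ``min_kmer_fraction``. This
replaces alignment-based recruitment with a deterministic, self-contained
rule adequate for error-free synthetic reads; an adapter ingesting external
per-contig count tables supports real-data workflows.

Depth is normalized per library: ``count * read_length / contig_length``
scaled to a per-million-reads library size, so libraries of different depth
are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmers import canonical_kmer_codes, canonical_kmer_codes_with_positions
from .qc import ReadRecord

__all__ = [
    "LibraryInfo",
    "ContigIndex",
    "recruit_reads",
    "normalize_coverage",
    "positional_coverage",
    "detect_coverage_dips",
    "read_counts_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class LibraryInfo:
    library_id: str
    total_reads: int
    read_length_mean: float

    def validate(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")


class ContigIndex:
    """Sorted canonical k-mer index over a contig set (CSR-like layout)."""

    def __init__(self, contigs: dict[str, str], k: int = 21):
        if not 1 <= k <= 31:
            raise ValueError("k must be in [1, 31]")
        self.k = k
        # contigs sorted by id so recruitment ties break lexicographically
        self.contig_ids = sorted(contigs)
        pairs_k = []
        pairs_c = []
        for ci, cid in enumerate(self.contig_ids):
            codes = np.unique(canonical_kmer_codes(contigs[cid], k))
            pairs_k.append(codes)
            pairs_c.append(np.full(codes.size, ci, dtype=np.int32))
        kk = np.concatenate(pairs_k) if pairs_k else np.empty(0, np.uint64)
        cc = np.concatenate(pairs_c) if pairs_c else np.empty(0, np.int32)
        order = np.lexsort((cc, kk))
        kk, cc = kk[order], cc[order]
        self.uniq, starts = np.unique(kk, return_index=True)
        self.offsets = np.append(starts, kk.size)
        self.contig_of_pair = cc

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For a batch of k-mer codes return (query_index, contig_index)
        pairs for every (code, contig) containment."""
        pos = np.searchsorted(self.uniq, codes)
        pos = np.clip(pos, 0, self.uniq.size - 1)
        hit = self.uniq.size > 0
        found = hit & (self.uniq[pos] == codes) if codes.size else np.empty(0, bool)
        qidx = np.nonzero(found)[0]
        upos = pos[qidx]
        counts = (self.offsets[upos + 1] - self.offsets[upos]).astype(np.int64)
        out_q = np.repeat(qidx, counts)
        total = int(counts.sum())
        if total == 0:
            return out_q, np.empty(0, np.int32)
        # ragged gather: for each group, indices starts[g] .. starts[g]+cnt[g]
        starts = self.offsets[upos].astype(np.int64)
        group_out_start = counts.cumsum() - counts
        idx = np.arange(total, dtype=np.int64) - np.repeat(group_out_start, counts) + np.repeat(starts, counts)
        return out_q, self.contig_of_pair[idx]


def recruit_reads(
    contigs: dict[str, str] | ContigIndex,
    reads_by_library: dict[str, list[ReadRecord]],
    k: int = 21,
    min_kmer_fraction: float = 0.6,
    chunk_size: int = 100_000,
) -> pd.DataFrame:
    """Best-hit recruitment of reads to contigs per library.

    Returns a contigs x libraries DataFrame of recruited read counts. Each
    read recruits to at most one contig (the one sharing the largest
    fraction of the read's distinct canonical k-mers, ties to the
    lexicographically smallest contig id), and only if that fraction is at
    least ``min_kmer_fraction``.
    """
    index = contigs if isinstance(contigs, ContigIndex) else ContigIndex(contigs, k)
    libs = list(reads_by_library)
    counts = pd.DataFrame(
        0, index=index.contig_ids, columns=libs, dtype=np.int64
    )
    for lib, reads in reads_by_library.items():
        col = np.zeros(len(index.contig_ids), dtype=np.int64)
        for lo in range(0, len(reads), chunk_size):
            chunk = reads[lo : lo + chunk_size]
            codes_list = []
            read_idx = []
            denom = np.zeros(len(chunk), dtype=np.int64)
            for i, rec in enumerate(chunk):
                if len(rec.bases) < index.k:
                    raise ValueError(
                        f"read {rec.read_id} shorter than k={index.k}"
                    )
                codes = np.unique(canonical_kmer_codes(rec.bases, index.k))
                denom[i] = codes.size
                codes_list.append(codes)
                read_idx.append(np.full(codes.size, i, dtype=np.int64))
            allcodes = np.concatenate(codes_list)
            allreads = np.concatenate(read_idx)
            q, c = index.lookup(allcodes)
            if q.size == 0:
                continue
            r = allreads[q]
            # count shared distinct kmers per (read, contig)
            key = r.astype(np.int64) * len(index.contig_ids) + c
            ukey, shared = np.unique(key, return_counts=True)
            rr = ukey // len(index.contig_ids)
            cc = (ukey % len(index.contig_ids)).astype(np.int64)
            frac = shared / denom[rr]
            # best hit per read: sort by (read, -frac, contig)
            order = np.lexsort((cc, -frac, rr))
            rr_s, cc_s, frac_s = rr[order], cc[order], frac[order]
            first = np.ones(rr_s.size, dtype=bool)
            first[1:] = rr_s[1:] != rr_s[:-1]
            sel = first & (frac_s >= min_kmer_fraction)
            np.add.at(col, cc_s[sel], 1)
        counts[lib] = col
    return counts


def normalize_coverage(
    counts: pd.DataFrame,
    libraries: dict[str, LibraryInfo],
    contig_lengths: dict[str, int],
) -> pd.DataFrame:
    """Normalized depth: ``count * read_length_mean / contig_length`` scaled
    per million library reads."""
    cov = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    lengths = np.array([contig_lengths[c] for c in counts.index], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("zero-length contig in coverage normalization")
    for lib in counts.columns:
        info = libraries[lib]
        info.validate()
        if info.total_reads == 0:
            if counts[lib].any():
                raise ValueError(f"library {lib} has recruits but zero total reads")
            cov[lib] = 0.0
            continue
        raw_depth = counts[lib].to_numpy(dtype=float) * info.read_length_mean / lengths
        cov[lib] = raw_depth * 1e6 / info.total_reads
    return cov


def positional_coverage(
    contig: str,
    reads: list[ReadRecord],
    k: int = 21,
    min_kmer_fraction: float = 0.6,
) -> np.ndarray:
    """Per-base depth along one contig from k-mer seed hits.

    Each read whose matched k-mer fraction reaches the recruitment threshold
    adds 1 over the span of its matched seed positions.
    """
    codes, pos = canonical_kmer_codes_with_positions(contig, k)
    order = np.argsort(codes, kind="stable")
    sorted_codes, sorted_pos = codes[order], pos[order]
    depth = np.zeros(len(contig), dtype=np.int64)
    for rec in reads:
        rcodes = np.unique(canonical_kmer_codes(rec.bases, k))
        if rcodes.size == 0:
            continue
        loc = np.searchsorted(sorted_codes, rcodes)
        loc = np.clip(loc, 0, max(sorted_codes.size - 1, 0))
        found = sorted_codes.size > 0 and (sorted_codes[loc] == rcodes)
        found = np.asarray(found, dtype=bool)
        if found.sum() / rcodes.size < min_kmer_fraction:
            continue
        hitpos = sorted_pos[loc[found]]
        depth[hitpos.min() : hitpos.max() + k] += 1
    return depth


def detect_coverage_dips(
    pos_cov: np.ndarray,
    window: int = 500,
    dip_factor: float = 0.2,
) -> list[tuple[int, int]]:
    """Flag internal windows whose mean depth collapses below
    ``dip_factor`` times the contig's median depth — the signature of a
    chimeric junction. Terminal windows are exempt (coverage ramps down at
    contig ends for purely geometric reasons). Adjacent flagged windows are
    merged. Raises if the contig is unevaluable (median depth 0 or shorter
    than three windows)."""
    n = pos_cov.size
    if n < 3 * window:
        raise ValueError("contig shorter than three windows")
    med = float(np.median(pos_cov))
    if med == 0:
        raise ValueError("median depth is zero; contig unevaluable")
    flags: list[tuple[int, int]] = []
    for start in range(window, n - window, window):
        end = min(start + window, n - window)
        if end <= start:
            break
        if float(pos_cov[start:end].mean()) < dip_factor * med:
            if flags and flags[-1][1] == start:
                flags[-1] = (flags[-1][0], end)
            else:
                flags.append((start, end))
    return flags


def read_counts_tsv(path) -> pd.DataFrame:
    """Ingest an external per-contig recruitment table
    (``contig_id<TAB>library<TAB>count`` or a wide contigs x libraries TSV)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if set(df.columns[:3]) >= {"contig_id", "library", "count"}:
        wide = df.pivot(index="contig_id", columns="library", values="count")
        return wide.fillna(0).astype(np.int64)
    return df.set_index(df.columns[0]).astype(np.int64)
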