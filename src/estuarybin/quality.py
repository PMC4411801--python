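"""Bin quality and community/functional profiles.

*Completeness* of a bin is the percentage of a universal single-copy marker
set detected at least once; *redundancy* is the percentage of surplus marker
copies, a simplified analog of lineage-aware contamination estimates. A bin
in which a large fraction of its detected markers is duplicated likely
contains several closely related genomes and is flagged for
differential-coverage splitting.

Community composition is profiled by recruiting reads to ribosomal protein
S3 genes and normalizing per library; carbohydrate-degradation potential is
summarized by counting glycoside hydrolase (GH) annotations restricted to an
include list of degradation-relevant families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .coverage import ContigIndex, recruit_reads
from .kmers import canonical_kmer_codes_with_positions
from .markers import RIBOSOMAL_PROTEINS, MarkerCatalog, make_default_catalog
from .qc import ReadRecord

__all__ = [
    "MarkerCatalog",
    "make_default_catalog",
    "RIBOSOMAL_PROTEINS",
    "BinQuality",
    "detect_markers",
    "marker_hit_table",
    "completeness",
    "redundancy",
    "flag_multigenome",
    "assess_bins",
    "rps3_abundance",
    "default_gh_include_list",
    "gh_profile",
    "read_marker_hits_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class BinQuality:
    completeness_pct: float
    redundancy_pct: float
    multi_genome: bool


def detect_markers(
    bin_contigs: dict[str, str],
    catalog: MarkerCatalog,
    k: int = 31,
    min_kmer_fraction: float = 0.9,
    merge_gap: int = 200,
) -> dict[str, int]:
    """Count marker copies in a set of contigs by exact k-mer containment.

    A copy is a maximal run of marker k-mer hits on one contig (runs closer
    than ``merge_gap`` merge) that recovers at least ``min_kmer_fraction`` of
    the representative's distinct k-mers.
    """
    counts = {mid: 0 for mid in catalog.sequences}
    if not catalog.sequences:
        return counts
    marker_kmers: dict[str, np.ndarray] = {}
    kmer_to_marker: dict[int, str] = {}
    for mid, seq in catalog.sequences.items():
        if len(seq) < k:
            raise ValueError(f"marker {mid} shorter than k={k}")
        codes = np.unique(canonical_kmer_codes_with_positions(seq, k)[0])
        marker_kmers[mid] = codes
        for c in codes:
            kmer_to_marker[int(c)] = mid
    all_marker_kmers = np.sort(
        np.concatenate([v for v in marker_kmers.values()])
    )
    for cid, seq in bin_contigs.items():
        if len(seq) < k:
            continue
        codes, pos = canonical_kmer_codes_with_positions(seq, k)
        # vectorized prefilter: marker k-mers are a vanishing fraction of a
        # contig, so only the matching windows reach the Python loop
        loc = np.searchsorted(all_marker_kmers, codes)
        loc = np.clip(loc, 0, all_marker_kmers.size - 1)
        is_hit = all_marker_kmers[loc] == codes
        hits: dict[str, list[tuple[int, int]]] = {}
        for c, p in zip(codes[is_hit], pos[is_hit]):
            mid = kmer_to_marker[int(c)]
            hits.setdefault(mid, []).append((int(p), int(c)))
        for mid, plist in hits.items():
            plist.sort()
            runs: list[list[tuple[int, int]]] = [[plist[0]]]
            for p, c in plist[1:]:
                if p - runs[-1][-1][0] <= merge_gap:
                    runs[-1].append((p, c))
                else:
                    runs.append([(p, c)])
            need = min_kmer_fraction * marker_kmers[mid].size
            for run in runs:
                if len({c for _p, c in run}) >= need:
                    counts[mid] += 1
    return counts


def marker_hit_table(
    bins: dict[str, dict[str, str]],
    catalog: MarkerCatalog,
    k: int = 31,
) -> pd.DataFrame:
    """Bins x markers copy-count table from sequence-level detection."""
    rows = {
        bin_id: detect_markers(contigs, catalog, k=k)
        for bin_id, contigs in bins.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


def completeness(hits: dict[str, int], catalog: MarkerCatalog) -> float:
    """Percent of catalog markers present at least once."""
    if len(catalog) == 0:
        raise ValueError("empty marker catalog")
    present = sum(1 for mid in catalog.sequences if hits.get(mid, 0) >= 1)
    return 100.0 * present / len(catalog)


def redundancy(hits: dict[str, int], catalog: MarkerCatalog) -> float:
    """Percent of surplus marker copies: ``100 * sum(max(c - 1, 0)) / M``."""
    if len(catalog) == 0:
        raise ValueError("empty marker catalog")
    extra = sum(max(hits.get(mid, 0) - 1, 0) for mid in catalog.sequences)
    return 100.0 * extra / len(catalog)


def flag_multigenome(
    hits: dict[str, int],
    duplicated_fraction_threshold: float = 0.10,
) -> bool:
    """Flag a bin whose detected markers are predominantly duplicated.

    True iff (#markers with >= 2 copies) / (#markers present) strictly
    exceeds the threshold. A bin with no markers at all is left unflagged.
    """
    present = sum(1 for v in hits.values() if v >= 1)
    if present == 0:
        logger.warning("no markers present; multi-genome flag not evaluable")
        return False
    dup = sum(1 for v in hits.values() if v >= 2)
    return dup / present > duplicated_fraction_threshold


def assess_bins(
    bins: dict[str, dict[str, str]],
    catalog: MarkerCatalog,
    k: int = 31,
    duplicated_fraction_threshold: float = 0.10,
) -> pd.DataFrame:
    """Quality table (completeness, redundancy, multi-genome flag) per bin."""
    rows = []
    for bin_id, contigs in sorted(bins.items()):
        hits = detect_markers(contigs, catalog, k=k)
        rows.append(
            {
                "bin_id": bin_id,
                "completeness": completeness(hits, catalog),
                "redundancy": redundancy(hits, catalog),
                "multi_genome": flag_multigenome(hits, duplicated_fraction_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("bin_id") if rows else pd.DataFrame()


def rps3_abundance(
    reads_by_library: dict[str, list[ReadRecord]],
    rps3_genes: dict[str, str],
    k: int = 21,
    min_kmer_fraction: float = 0.6,
) -> pd.DataFrame:
    """Community profile from reads recruited to ribosomal protein S3 genes.

    ``rps3_genes`` maps taxon label to its rpS3 gene sequence. Returns a
    taxa x libraries table of relative abundances (each library sums to 1
    when any reads map; an all-zero column is emitted with a warning
    otherwise).
    """
    index = ContigIndex(rps3_genes, k)
    counts = recruit_reads(
        index, reads_by_library, k=k, min_kmer_fraction=min_kmer_fraction
    )
    profile = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for lib in counts.columns:
        total = int(counts[lib].sum())
        if total == 0:
            logger.warning("no reads mapped to rpS3 genes in library %s", lib)
            profile[lib] = 0.0
        else:
            profile[lib] = counts[lib] / total
    return profile


def default_gh_include_list() -> list[str]:
    """Degradation-relevant GH families shipped with the package.

    An editable default modeled on lists of families with direct
    polysaccharide-degradation activity (cellulases, hemicellulases,
    chitinases, ...); real-data analyses should supply their own list.
    """
    path = resources.files("estuarybin").joinpath("data/gh_include.tsv")
    fams = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            fams.append(line.split("\t")[0])
    return fams


def gh_profile(
    gene_annotations: pd.DataFrame,
    include_list: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count include-listed GH-family genes per bin.

    ``gene_annotations`` needs columns ``gene_id``, ``bin_id``,
    ``gh_family``. Returns ``(counts, drop_report)`` where ``counts`` is a
    bins x families table restricted to the include list and ``drop_report``
    tallies excluded or malformed rows; counted + dropped = rows parsed.
    """
    if include_list is None:
        include_list = default_gh_include_list()
    include = set(include_list)
    required = {"gene_id", "bin_id", "gh_family"}
    if not required <= set(gene_annotations.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    ok_rows = []
    dropped: dict[str, int] = {"excluded_family": 0, "malformed": 0}
    for _, row in gene_annotations.iterrows():
        fam = row["gh_family"]
        if not isinstance(fam, str) or not fam.startswith("GH") or not fam[2:].isdigit():
            dropped["malformed"] += 1
            logger.warning("malformed GH family label skipped: %r", fam)
            continue
        if fam not in include:
            dropped["excluded_family"] += 1
            continue
        ok_rows.append((row["bin_id"], fam))
    if ok_rows:
        df = pd.DataFrame(ok_rows, columns=["bin_id", "gh_family"])
        counts = df.groupby(["bin_id", "gh_family"]).size().unstack(fill_value=0)
    else:
        counts = pd.DataFrame()
    drop_report = pd.DataFrame(
        [{"reason": r, "n": n} for r, n in dropped.items()]
    ).set_index("reason")
    return counts, drop_report


def read_marker_hits_tsv(path) -> pd.DataFrame:
    """Ingest an external marker hit table
    (``bin_id<TAB>marker_id<TAB>count``) into a bins x markers DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#")
    wide = df.pivot(index="bin_id", columns="marker_id", values="count")
    return wide.fillna(0).astype(int)
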