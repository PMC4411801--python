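"""Concatenated-marker phylogenies.

Taxa are screened for presence of the 16 syntenic ribosomal proteins
(those with fewer than half the genes are dropped), the per-gene amino-acid
alignments are concatenated with gap fill for missing genes, pairwise
distances are computed under a Jukes–Cantor model generalized to 20 states
(4-state mode available for nucleotides), and trees are built by UPGMA
(rooted, ultrametric) or neighbor joining (unrooted). Branch supports come
from a column bootstrap: resample alignment columns with replacement,
rebuild, and report the percentage of replicates containing each internal
bipartition of the reference tree.

Distances use pairwise gap deletion — a column is excluded for a pair only
if either member has a gap there — so heavily gapped concatenations remain
comparable.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .markers import RIBOSOMAL_PROTEINS

__all__ = [
    "MARKER_GENE_SET",
    "ConcatenatedAlignment",
    "TreeNode",
    "filter_taxa",
    "concatenate",
    "jc_distance",
    "distance_matrix",
    "upgma",
    "neighbor_joining",
    "bootstrap",
    "write_newick",
    "bipartitions",
]

logger = logging.getLogger(__name__)

#: Default ordered gene list: the 16 syntenic ribosomal proteins.
MARKER_GENE_SET: tuple[str, ...] = RIBOSOMAL_PROTEINS

GAP = "-"


@dataclass
class ConcatenatedAlignment:
    taxa: list[str]
    rows: dict[str, str]  # taxon -> concatenated sequence
    partitions: list[tuple[str, int, int]]  # (gene, start, end), half-open

    @property
    def n_columns(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def validate(self) -> None:
        n = self.n_columns
        for t in self.taxa:
            if len(self.rows[t]) != n:
                raise ValueError(f"row length mismatch for taxon {t}")
        pos = 0
        for _g, s, e in self.partitions:
            if s != pos or e < s:
                raise ValueError("partitions must tile the columns")
            pos = e


@dataclass
class TreeNode:
    """A rooted (or arbitrarily rooted unrooted) tree node."""

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name or ""]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


# ---------------------------------------------------------------------------
# taxon filtering and concatenation


def filter_taxa(
    presence: dict[str, dict[str, bool]],
    gene_set: tuple[str, ...] = MARKER_GENE_SET,
    min_fraction: float = 0.5,
) -> list[str]:
    """Retain taxa carrying at least ``ceil(min_fraction * n_genes)`` of the
    marker genes (a taxon with exactly half is retained)."""
    need = math.ceil(min_fraction * len(gene_set))
    out = []
    for taxon, genes in presence.items():
        n = sum(1 for g in gene_set if genes.get(g, False))
        if n >= need:
            out.append(taxon)
    return out


def concatenate(
    per_gene_alignments: dict[str, dict[str, str]],
    gene_set: tuple[str, ...] = MARKER_GENE_SET,
    taxa: list[str] | None = None,
) -> ConcatenatedAlignment:
    """Concatenate per-gene alignments in catalog order, gap-filling genes a
    taxon lacks. Raises if rows within one gene have unequal lengths."""
    if taxa is None:
        taxa = sorted({t for aln in per_gene_alignments.values() for t in aln})
    partitions: list[tuple[str, int, int]] = []
    widths: dict[str, int] = {}
    pos = 0
    for gene in gene_set:
        aln = per_gene_alignments.get(gene, {})
        lens = {len(s) for s in aln.values()}
        if len(lens) > 1:
            raise ValueError(f"ragged rows in gene alignment {gene}")
        w = lens.pop() if lens else 0
        widths[gene] = w
        partitions.append((gene, pos, pos + w))
        pos += w
    rows = {}
    for t in taxa:
        parts = []
        for gene in gene_set:
            aln = per_gene_alignments.get(gene, {})
            parts.append(aln.get(t, GAP * widths[gene]))
        rows[t] = "".join(parts)
    out = ConcatenatedAlignment(taxa=list(taxa), rows=rows, partitions=partitions)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# distances


def jc_distance(row_a: str, row_b: str, n_states: int = 20) -> float:
    """Jukes–Cantor distance with pairwise gap deletion.

    ``d = -((n-1)/n) * ln(1 - (n/(n-1)) * p)`` with p the mismatch
    proportion over columns where neither row is gapped. Near-saturated
    pairs (p within 0.1% of the (n-1)/n ceiling) raise, as the distance is
    undefined there.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    shared = mismatch = 0
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP:
            continue
        shared += 1
        if a != b:
            mismatch += 1
    if shared == 0:
        raise ValueError("no shared ungapped columns; pair incomparable")
    p = mismatch / shared
    ceiling = (n_states - 1) / n_states
    if p >= ceiling * 0.999:
        raise ValueError(f"saturated pair (p={p:.4f}); distance undefined")
    return -ceiling * math.log(1.0 - p / ceiling)


def distance_matrix(
    alignment: ConcatenatedAlignment,
    n_states: int = 20,
) -> tuple[np.ndarray, list[str]]:
    taxa = list(alignment.taxa)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(
                alignment.rows[taxa[i]], alignment.rows[taxa[j]], n_states
            )
    return d, taxa


# ---------------------------------------------------------------------------
# tree building


def _check_matrix(d: np.ndarray) -> None:
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains NaN/inf")
    if d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("need a square matrix over >= 2 taxa")


def upgma(d: np.ndarray, taxa: list[str]) -> TreeNode:
    """UPGMA: iteratively merge the closest clusters; inter-cluster distance
    is the size-weighted (i.e. all-pairs) average; node height is half the
    merge distance, so the tree is rooted and ultrametric. Among tied pairs
    the one whose clusters have the lexicographically smallest leaf labels
    merges first."""
    _check_matrix(d)
    d = d.astype(float).copy()
    nodes = [TreeNode(name=t) for t in taxa]
    sizes = [1] * len(taxa)
    heights = [0.0] * len(taxa)
    labels = [min(n.leaves()) for n in nodes]
    active = list(range(len(taxa)))
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                a, b = (i, j) if labels[i] <= labels[j] else (j, i)
                key = (d[i, j], labels[a], labels[b])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        h = d[i, j] / 2.0
        ni, nj = nodes[i], nodes[j]
        ni.length = h - heights[i]
        nj.length = h - heights[j]
        merged = TreeNode(children=sorted([ni, nj], key=lambda n: min(n.leaves())))
        nodes.append(merged)
        sizes.append(sizes[i] + sizes[j])
        heights.append(h)
        labels.append(min(labels[i], labels[j]))
        k = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for m in active:
            if m in (i, j):
                continue
            dm = (sizes[i] * d[i, m] + sizes[j] * d[j, m]) / (sizes[i] + sizes[j])
            d[k, m] = d[m, k] = dm
        active = [m for m in active if m not in (i, j)] + [k]
    return nodes[active[0]]


def neighbor_joining(d: np.ndarray, taxa: list[str]) -> TreeNode:
    """Standard neighbor joining (Q-criterion), returned as an arbitrarily
    rooted tree whose root has three children (the final star). Negative
    branch lengths are clamped to zero with a log note. Ties in Q break
    toward the lexicographically smallest pair of cluster labels."""
    _check_matrix(d)
    n0 = d.shape[0]
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = d.astype(float).copy()
    nodes = [TreeNode(name=t) for t in taxa]
    labels = [t for t in taxa]
    active = list(range(n0))
    while len(active) > 3:
        r = {i: sum(d[i, m] for m in active if m != i) for i in active}
        best = None
        nn = len(active)
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (nn - 2) * d[i, j] - r[i] - r[j]
                a, b = (i, j) if labels[i] <= labels[j] else (j, i)
                key = (q, labels[a], labels[b])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (nn - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li), _clamp(lj)
        nodes[i].length, nodes[j].length = li, lj
        merged = TreeNode(children=sorted([nodes[i], nodes[j]], key=lambda x: min(x.leaves())))
        nodes.append(merged)
        labels.append(min(labels[i], labels[j]))
        k = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for m in active:
            if m in (i, j):
                continue
            d[k, m] = d[m, k] = 0.5 * (d[i, m] + d[j, m] - d[i, j])
        active = [m for m in active if m not in (i, j)] + [k]
    i, j, k = active
    li = _clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = _clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = _clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    for idx, L in zip((i, j, k), (li, lj, lk)):
        nodes[idx].length = L
    root = TreeNode(
        children=sorted((nodes[i], nodes[j], nodes[k]), key=lambda x: min(x.leaves()))
    )
    return root


def _clamp(x: float) -> float:
    if x < 0:
        logger.info("negative branch length %.3g clamped to 0", x)
        return 0.0
    return x


# ---------------------------------------------------------------------------
# bootstrap


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal bipartitions of a tree, each encoded as the smaller side
    (ties broken lexicographically) so rooted and unrooted trees compare."""
    all_leaves = frozenset(tree.leaves())
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name or ""])
        below = frozenset().union(*(walk(ch) for ch in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves):
            comp = all_leaves - below
            side = min(below, comp, key=lambda s: (len(s), tuple(sorted(s))))
            out.add(side)
        return below

    walk(tree)
    return out


def _resample(alignment: ConcatenatedAlignment, rng) -> ConcatenatedAlignment:
    n = alignment.n_columns
    cols = rng.integers(0, n, size=n)
    rows = {t: "".join(alignment.rows[t][c] for c in cols) for t in alignment.taxa}
    return ConcatenatedAlignment(
        taxa=list(alignment.taxa),
        rows=rows,
        partitions=[("resampled", 0, n)],
    )


def bootstrap(
    alignment: ConcatenatedAlignment,
    builder=upgma,
    n_replicates: int = 100,
    seed: int = 0,
    n_states: int = 20,
    max_dropped_fraction: float = 0.2,
) -> TreeNode:
    """Column bootstrap: annotate the reference tree's internal nodes with
    the percentage of replicates containing the same bipartition.

    A replicate in which some pair shares no ungapped column (or is
    saturated) is dropped and counted; more than ``max_dropped_fraction``
    dropped replicates is an error.
    """
    if alignment.n_columns < 2:
        raise ValueError("alignment must have at least 2 columns")
    d, taxa = distance_matrix(alignment, n_states)
    ref = builder(d, taxa)
    if n_replicates == 0:
        return ref
    rng = np.random.default_rng(derive_seed(seed, "bootstrap"))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(ref)}
    dropped = 0
    used = 0
    for _rep in range(n_replicates):
        rep_aln = _resample(alignment, rng)
        try:
            dr, _ = distance_matrix(rep_aln, n_states)
            rep_tree = builder(dr, taxa)
        except ValueError:
            dropped += 1
            continue
        used += 1
        reps = bipartitions(rep_tree)
        for bp in counts:
            if bp in reps:
                counts[bp] += 1
    if dropped > max_dropped_fraction * n_replicates:
        raise ValueError(f"{dropped}/{n_replicates} bootstrap replicates dropped")
    if used == 0:
        return ref
    all_leaves = frozenset(ref.leaves())

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name or ""])
        below = frozenset().union(*(annotate(ch) for ch in node.children))
        if node is not ref and 1 < len(below) < len(all_leaves):
            side = min(below, all_leaves - below, key=lambda s: (len(s), tuple(sorted(s))))
            node.support = round(100.0 * counts.get(side, 0) / used)
        return below

    annotate(ref)
    return ref


# ---------------------------------------------------------------------------
# Newick serialization

_META = re.compile(r"[\s()\[\]{}:;,']")


def _quote(name: str) -> str:
    if _META.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: TreeNode) -> str:
    """Newick text: branch lengths to 6 significant figures, integer
    bootstrap supports as internal node labels, trailing semicolon."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf():
            return f"{_quote(node.name or '')}:{node.length:.6g}"
        inner = ",".join(fmt(ch, False) for ch in node.children)
        label = "" if node.support is None else str(int(node.support))
        if is_root:
            return f"({inner}){label}"
        return f"({inner}){label}:{node.length:.6g}"

    if tree.is_leaf():
        return f"{_quote(tree.name or '')}:{tree.length:.6g};"
    return fmt(tree, True) + ";"
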