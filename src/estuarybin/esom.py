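"""Emergent self-organizing maps for fragment binning.

An emergent SOM is a large toroidal lattice of weight vectors — many more
neurons than data points — trained online so that compositional clusters in
the data occupy contiguous patches of the map. The U-matrix (each neuron's
mean distance to its 8 toroidal neighbours) exposes cluster structure as
valleys separated by ridges.

The original workflow delineated bins on the map by hand; here delineation
is automated: neurons whose U-matrix value falls below a quantile threshold
form basins, connected components of basins (8-connectivity with toroidal
wrap) are clusters, and fragments inherit the cluster of their best-matching
unit. An import path for externally drawn cluster masks is provided for
workflows where maps are still curated by hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .signatures import FeatureMatrix

__all__ = [
    "SOMConfig",
    "SOMGrid",
    "UMatrix",
    "default_grid_shape",
    "train",
    "compute_umatrix",
    "assign_bmu",
    "delineate_clusters",
    "import_cluster_map",
]

logger = logging.getLogger(__name__)

_GOLDEN = (1 + 5**0.5) / 2


@dataclass
class SOMConfig:
    rows: int
    cols: int
    toroidal: bool = True
    epochs: int = 20
    radius_start: float | None = None  # default: grid diagonal / 4
    radius_end: float = 1.0
    rate_start: float = 0.5
    rate_end: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.rows * self.cols < 4:
            raise ValueError("grid must have at least 4 neurons")
        r0 = self.resolved_radius_start()
        if not r0 >= self.radius_end > 0:
            raise ValueError("need radius_start >= radius_end > 0")
        if not 0 < self.rate_end <= self.rate_start <= 1:
            raise ValueError("need 0 < rate_end <= rate_start <= 1")

    def resolved_radius_start(self) -> float:
        if self.radius_start is not None:
            return self.radius_start
        return float(np.hypot(self.rows, self.cols)) / 4.0


@dataclass
class SOMGrid:
    weights: np.ndarray  # (rows, cols, n_features)
    config: SOMConfig
    trained: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape[0], self.weights.shape[1]


@dataclass
class UMatrix:
    values: np.ndarray  # (rows, cols), mean distance to 8 toroidal neighbours


def default_grid_shape(n_fragments: int, neurons_per_datum: int = 5) -> tuple[int, int]:
    """Grid shape with >= ``neurons_per_datum`` neurons per fragment, roughly
    golden-ratio rectangular, never smaller than 50 x 80. Returns
    ``(rows, cols)`` with rows <= cols."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    target = neurons_per_datum * n_fragments
    rows = max(50, int(np.ceil(np.sqrt(target / _GOLDEN))))
    cols = max(80, int(np.ceil(target / rows)))
    if rows > cols:
        rows, cols = cols, rows
    return rows, cols


def _toroidal_sq_dist(rows: int, cols: int, r0: int, c0: int) -> np.ndarray:
    """Squared toroidal grid distance of every neuron to (r0, c0)."""
    dr = np.abs(np.arange(rows) - r0)
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(np.arange(cols) - c0)
    dc = np.minimum(dc, cols - dc)
    return dr[:, None] ** 2 + dc[None, :] ** 2


def train(matrix: FeatureMatrix, config: SOMConfig) -> SOMGrid:
    """Online SOM training.

    Each epoch presents the rows in a freshly seeded random order; the winner
    is the Euclidean-nearest neuron and weights move toward the datum with a
    Gaussian neighbourhood on the torus, learning rate and radius both
    decaying exponentially over the run. Deterministic given the seed.
    """
    config.validate()
    x = matrix.data.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("feature matrix contains non-finite values")
    n, dim = x.shape
    rows, cols = config.rows, config.cols
    rng = np.random.default_rng(config.seed)
    # initialize from random data rows plus small jitter: starts the map
    # inside the data cloud, which speeds self-organization
    init_idx = rng.integers(0, n, size=rows * cols)
    w = x[init_idx].reshape(rows, cols, dim).astype(float)
    w += 0.01 * rng.standard_normal(w.shape) * (x.std(axis=0) + 1e-12)

    total_steps = config.epochs * n
    r0, r1 = config.resolved_radius_start(), config.radius_end
    a0, a1 = config.rate_start, config.rate_end
    flat = w.reshape(rows * cols, dim)
    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / max(total_steps - 1, 1)
            sigma = r0 * (r1 / r0) ** frac
            alpha = a0 * (a1 / a0) ** frac
            xi = x[i]
            d2 = ((flat - xi) ** 2).sum(axis=1)
            bmu = int(np.argmin(d2))
            br, bc = divmod(bmu, cols)
            g2 = _toroidal_sq_dist(rows, cols, br, bc)
            h = np.exp(-g2 / (2.0 * sigma * sigma))
            # skip negligible updates beyond 3 sigma for speed
            mask = g2 <= (3.0 * sigma) ** 2
            hm = (alpha * h)[mask]
            w[mask] += hm[:, None] * (xi - w[mask])
            step += 1
    return SOMGrid(weights=w, config=config, trained=True)


def compute_umatrix(grid: SOMGrid) -> UMatrix:
    """Mean Euclidean distance from each neuron to its 8 toroidal neighbours."""
    if not grid.trained:
        raise ValueError("grid is not trained")
    w = grid.weights
    acc = np.zeros(w.shape[:2])
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(w, dr, axis=0), dc, axis=1)
            acc += np.sqrt(((w - shifted) ** 2).sum(axis=2))
    return UMatrix(values=acc / 8.0)


def assign_bmu(grid: SOMGrid, matrix: FeatureMatrix) -> dict[str, tuple[int, int]]:
    """Map each row id to its best-matching unit.

    Ties are broken toward the lexicographically smallest (row, col), which
    ``argmin`` over the row-major flattened distance array guarantees.
    """
    if not grid.trained:
        raise ValueError("grid is not trained")
    rows, cols = grid.shape
    flat = grid.weights.reshape(rows * cols, -1)
    x = matrix.data.to_numpy(dtype=float)
    out: dict[str, tuple[int, int]] = {}
    for i, rid in enumerate(matrix.data.index):
        d2 = ((flat - x[i]) ** 2).sum(axis=1)
        bmu = int(np.argmin(d2))  # first occurrence = lexicographic (row, col)
        out[rid] = divmod(bmu, cols)
    return out


def _toroidal_label(basin: np.ndarray) -> np.ndarray:
    """Connected components (8-connectivity) of a boolean mask with toroidal
    wrap-around, via union-find across the seam rows/columns."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(basin, structure=structure)
    if n == 0:
        return labels
    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    rows, cols = basin.shape
    for c in range(cols):
        if labels[0, c] and labels[-1, c]:
            union(labels[0, c], labels[-1, c])
        for dc in (-1, 1):  # diagonal wrap across the horizontal seam
            cc = (c + dc) % cols
            if labels[0, c] and labels[-1, cc]:
                union(labels[0, c], labels[-1, cc])
    for r in range(rows):
        if labels[r, 0] and labels[r, -1]:
            union(labels[r, 0], labels[r, -1])
        for dr in (-1, 1):
            rr = (r + dr) % rows
            if labels[r, 0] and labels[rr, -1]:
                union(labels[r, 0], labels[rr, -1])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    nxt = 0
    for lab in range(1, n + 1):
        root = find(lab)
        if remap[root] == 0:
            nxt += 1
            remap[root] = nxt
        remap[lab] = remap[root]
    return remap[labels]


def delineate_clusters(
    umatrix: UMatrix,
    bmu_map: dict[str, tuple[int, int]],
    boundary_quantile: float = 0.7,
) -> dict[str, str | None]:
    """Automated cluster delineation on the U-matrix.

    Neurons with U at or below the ``boundary_quantile`` quantile form
    basins; toroidal 8-connected components of basins are clusters. A
    fragment whose BMU lies on a boundary (ridge) neuron is attached to the
    nearest basin by toroidal grid distance; an exact tie between different
    clusters leaves it unassigned (``None``). Cluster ids are ``cl_001``...
    in component-label order.
    """
    u = umatrix.values
    thr = float(np.quantile(u, boundary_quantile))
    basin = u <= thr
    if not basin.any():
        raise ValueError("no basin neurons at this quantile; raise boundary_quantile")
    labels = _toroidal_label(basin)
    rows, cols = u.shape
    basin_coords = np.argwhere(basin)
    basin_labels = labels[basin]
    out: dict[str, str | None] = {}
    for rid, (r, c) in bmu_map.items():
        if labels[r, c] > 0:
            out[rid] = f"cl_{labels[r, c]:03d}"
            continue
        d2 = _toroidal_sq_dist(rows, cols, r, c)[basin_coords[:, 0], basin_coords[:, 1]]
        best = d2.min()
        cand = np.unique(basin_labels[d2 == best])
        out[rid] = f"cl_{cand[0]:03d}" if cand.size == 1 else None
    return out


def import_cluster_map(path, expected_ids: list[str]) -> dict[str, str]:
    """Read an externally curated fragment->cluster TSV and validate that it
    covers every expected fragment id exactly once."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("fragment_id\t"):
                continue
            fid, cid = line.split("\t")[:2]
            if fid in mapping:
                raise ValueError(f"duplicate fragment id in cluster map: {fid}")
            mapping[fid] = cid
    missing = set(expected_ids) - set(mapping)
    if missing:
        raise ValueError(f"cluster map missing {len(missing)} fragment ids")
    return mapping
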