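"""Cluster detection on the distance map and meta-measure construction.

On the feature map, body measures with similar profiles across the cohort
land on nearby units; ridges of the U-matrix (units whose codebooks are
far from their neighbors) surround groups of similar measures.  A cluster
is an area enclosed by such (local) maximum-distance ridges.  Detection is
watershed-by-steepest-descent:

1. every unit follows its lowest-valued lattice neighbor downhill to a
   local minimum, defining catchment basins;
2. basins separated by a shallow ridge — saddle height minus the deeper
   basin minimum below ``theta`` times the map's dynamic range — are
   merged, so noise wrinkles inside one valley do not split a cluster;
3. items (measures) inherit the basin of their best-matching unit; basins
   without items are background.

Clusters of measures become *meta-measures*: per-participant means over
the member measure columns, labelled "A", "B", ... clockwise around the
map center.  Singleton clusters are pruned, and each participant's
meta-measure vector is finally Z-normalized across meta-measures to
remove additive offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import MeasureTable

__all__ = [
    "ClusterAssignment",
    "MetaMeasureTable",
    "detect_clusters",
    "prune_singletons",
    "aggregate_meta_measures",
    "z_normalize_rows",
]

#: sentinel for background units / unassigned items
UNASSIGNED = -1


class ClusterError(ValueError):
    pass


@dataclass
class ClusterAssignment:
    """Unit -> cluster and item -> cluster labels from a distance map.

    ``unit_labels`` is an (H, W) int grid; ``item_labels`` a length-n int
    array.  Cluster ids are 0..n_clusters-1; ``UNASSIGNED`` (-1) marks
    background units and unassigned items.
    """

    unit_labels: np.ndarray
    item_labels: np.ndarray
    bmu: np.ndarray  # (n_items, 2) BMU coordinates the items were mapped with

    @property
    def n_clusters(self) -> int:
        labs = self.item_labels[self.item_labels != UNASSIGNED]
        return int(len(np.unique(labs)))

    @property
    def cluster_sizes(self) -> dict:
        labs, counts = np.unique(
            self.item_labels[self.item_labels != UNASSIGNED], return_counts=True
        )
        return {int(l): int(c) for l, c in zip(labs, counts)}

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.item_labels == cluster_id)


def _neighbors(r: int, c: int, h: int, w: int):
    if r > 0:
        yield r - 1, c
    if r < h - 1:
        yield r + 1, c
    if c > 0:
        yield r, c - 1
    if c < w - 1:
        yield r, c + 1


def _steepest_descent_basins(dmap: np.ndarray) -> np.ndarray:
    """Label each unit with the local minimum its downhill path reaches.

    Moves to the strictly lower neighbor of minimum value; on plateaus it
    moves to an equal-valued neighbor of lower row-major index, which
    resolves flat regions deterministically and guarantees termination
    (the (value, index) pair decreases lexicographically along paths).
    """
    h, w = dmap.shape
    nxt = np.full((h, w), -1, dtype=int)  # linear index of downhill step, -1 = local min
    for r in range(h):
        for c in range(w):
            best = (dmap[r, c], r * w + c)
            for rr, cc in _neighbors(r, c, h, w):
                cand = (dmap[rr, cc], rr * w + cc)
                if cand < best:
                    best = cand
            if best[1] != r * w + c:
                nxt[r, c] = best[1]
    # path compression to terminal minima
    flat_next = nxt.ravel()
    basin = np.full(h * w, -1, dtype=int)
    for u in range(h * w):
        path = []
        v = u
        while basin[v] == -1 and flat_next[v] != -1:
            path.append(v)
            v = flat_next[v]
        root = basin[v] if basin[v] != -1 else v
        basin[v] = root
        for p in path:
            basin[p] = root
    return basin.reshape(h, w)


def _merge_shallow_basins(dmap: np.ndarray, basin: np.ndarray, theta: float) -> np.ndarray:
    """Union basins whose separating ridge is insufficiently prominent.

    For each pair of lattice-adjacent basins the saddle height is the
    minimum over boundary unit pairs of ``max(dmap[u], dmap[v])``; the
    ridge prominence is saddle minus the higher of the two basin minima.
    Pairs are merged lowest-prominence-first until every remaining ridge
    reaches ``theta * (dmap.max() - dmap.min())``.
    """
    h, w = dmap.shape
    rng_span = float(dmap.max() - dmap.min())
    roots = {int(b) for b in np.unique(basin)}
    if rng_span == 0.0 or len(roots) == 1:
        return np.zeros_like(basin)

    parent = {b: b for b in roots}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    minima = {b: float(dmap[basin == b].min()) for b in roots}
    saddle: dict[tuple, float] = {}
    for r in range(h):
        for c in range(w):
            a = basin[r, c]
            for rr, cc in ((r + 1, c), (r, c + 1)):
                if rr >= h or cc >= w:
                    continue
                b = basin[rr, cc]
                if a == b:
                    continue
                key = (min(a, b), max(a, b))
                hgt = max(float(dmap[r, c]), float(dmap[rr, cc]))
                if hgt < saddle.get(key, math.inf):
                    saddle[key] = hgt

    threshold = theta * rng_span
    while True:
        # collapse edges onto current roots
        edges: dict[tuple, float] = {}
        for (a, b), s in saddle.items():
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            key = (min(ra, rb), max(ra, rb))
            if s < edges.get(key, math.inf):
                edges[key] = s
        if not edges:
            break
        prom = {
            k: s - max(minima[find(k[0])], minima[find(k[1])]) for k, s in edges.items()
        }
        (a, b), best = min(prom.items(), key=lambda kv: (kv[1], kv[0]))
        if best >= threshold:
            break
        ra, rb = find(a), find(b)
        parent[rb] = ra
        minima[ra] = min(minima[ra], minima[rb])

    out = np.array([find(int(b)) for b in basin.ravel()]).reshape(h, w)
    return out


def detect_clusters(
    dmap: np.ndarray,
    bmu: np.ndarray,
    theta: float = 0.30,
    smooth_sigma: float = 0.0,
) -> ClusterAssignment:
    """Watershed the distance map and assign items via their BMUs.

    ``dmap`` is the (H, W) U-matrix; ``bmu`` the (n_items, 2) BMU
    coordinates of the items on the same grid.  ``theta`` is the ridge
    prominence merge threshold as a fraction of the map's dynamic range.
    ``smooth_sigma`` > 0 Gaussian-filters the distance map first — useful
    on sparsely occupied participant maps (< 1 item per unit) whose raw
    U-matrix is dominated by per-unit sampling noise.  Basins that collect
    no items become background; surviving clusters are relabelled 0..K-1
    in row-major order of their basin minimum.
    """
    dmap = np.asarray(dmap, dtype=float)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        dmap = gaussian_filter(dmap, smooth_sigma)
    bmu = np.asarray(bmu, dtype=int)
    if bmu.ndim != 2 or bmu.shape[1] != 2:
        raise ClusterError("bmu must be an (n_items, 2) array of unit coordinates")
    h, w = dmap.shape
    if bmu.size and (bmu[:, 0].max() >= h or bmu[:, 1].max() >= w):
        raise ClusterError("bmu coordinates exceed the distance-map grid")

    basin = _steepest_descent_basins(dmap)
    basin = _merge_shallow_basins(dmap, basin, theta)

    item_basin = basin[bmu[:, 0], bmu[:, 1]]
    occupied = np.unique(item_basin)
    relabel = {int(b): i for i, b in enumerate(sorted(int(x) for x in occupied))}
    unit_labels = np.full((h, w), UNASSIGNED, dtype=int)
    for b, lab in relabel.items():
        unit_labels[basin == b] = lab
    item_labels = np.array([relabel[int(b)] for b in item_basin], dtype=int)
    return ClusterAssignment(unit_labels=unit_labels, item_labels=item_labels, bmu=bmu)


def prune_singletons(
    assignment: ClusterAssignment, min_members: int = 2
) -> ClusterAssignment:
    """Dissolve clusters with fewer than ``min_members`` items.

    Items of dissolved clusters become unassigned and their units
    background; surviving clusters are relabelled compactly, preserving
    order.
    """
    sizes = assignment.cluster_sizes
    keep = sorted(k for k, n in sizes.items() if n >= min_members)
    if not keep and sizes:
        raise ClusterError("prune_singletons dissolved every cluster")
    relabel = {old: new for new, old in enumerate(keep)}
    item_labels = np.array(
        [relabel.get(int(l), UNASSIGNED) for l in assignment.item_labels], dtype=int
    )
    unit_labels = np.full_like(assignment.unit_labels, UNASSIGNED)
    for old, new in relabel.items():
        unit_labels[assignment.unit_labels == old] = new
    return ClusterAssignment(
        unit_labels=unit_labels, item_labels=item_labels, bmu=assignment.bmu
    )


# ---------------------------------------------------------------------------
# meta-measures
# ---------------------------------------------------------------------------

@dataclass
class MetaMeasureTable:
    """Participants x meta-measures table in Z-units.

    ``meta_names`` are "A", "B", ... in clockwise order around the feature
    map center; ``members`` maps each meta-measure to its constituent
    measures; ``singletons_excluded`` lists measures in no meta-measure.
    """

    values: pd.DataFrame
    members: dict
    singletons_excluded: list
    row_normalized: bool = False

    @property
    def meta_names(self) -> list:
        return list(self.values.columns)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]


def _clockwise_order(assignment: ClusterAssignment, shape: tuple) -> list:
    """Cluster ids sorted by centroid angle, clockwise from 12 o'clock.

    The centroid is the mean BMU position of the cluster's items; the
    angle is measured around the map center, 0 pointing up (north),
    increasing clockwise.  Ties broken by distance from center, then id.
    """
    h, w = shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    order = []
    for k in sorted(set(int(l) for l in assignment.item_labels) - {UNASSIGNED}):
        pts = assignment.bmu[assignment.item_labels == k].astype(float)
        cr, cc = pts.mean(axis=0) - center
        angle = math.atan2(cc, -cr) % (2.0 * math.pi)  # up = 0, clockwise
        order.append((angle, math.hypot(cr, cc), k))
    return [k for _, _, k in sorted(order)]


def _spreadsheet_name(i: int) -> str:
    name = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


def aggregate_meta_measures(
    z_table: MeasureTable, assignment: ClusterAssignment
) -> MetaMeasureTable:
    """Average Z-normalized member measures into meta-measure columns.

    ``assignment`` labels the *measures* of ``z_table`` (items of the
    feature map, in column order).  Each meta-measure column is the
    per-participant arithmetic mean over its member measures; columns are
    named "A", "B", ... following the clockwise map order.
    """
    if len(assignment.item_labels) != z_table.n_measures:
        raise ClusterError("assignment does not cover the table's measures")
    order = _clockwise_order(assignment, assignment.unit_labels.shape)
    if not order:
        raise ClusterError("no clusters to aggregate")
    measures = np.asarray(z_table.measure_names)
    cols, members = {}, {}
    for i, k in enumerate(order):
        member_measures = measures[assignment.item_labels == k]
        if len(member_measures) == 0:
            raise ClusterError(f"cluster {k} has no member measures")
        name = _spreadsheet_name(i)
        members[name] = list(member_measures)
        cols[name] = z_table.values[member_measures].mean(axis=1)
    singles = list(measures[assignment.item_labels == UNASSIGNED])
    return MetaMeasureTable(
        values=pd.DataFrame(cols, index=z_table.values.index),
        members=members,
        singletons_excluded=singles,
    )


def z_normalize_rows(meta: MetaMeasureTable, ddof: int = 1) -> MetaMeasureTable:
    """Z-normalize each participant's meta-measure vector (removes offsets)."""
    if meta.values.shape[1] < 2:
        raise ClusterError("row Z-normalization needs >= 2 meta-measures")
    vals = meta.values.astype(float)
    sd = vals.std(axis=1, ddof=ddof)
    flat = sd.index[(sd == 0) | sd.isna()].tolist()
    if flat:
        raise ClusterError(f"zero-variance meta rows for participants: {flat}")
    out = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return replace(meta, values=out, row_normalized=True)
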