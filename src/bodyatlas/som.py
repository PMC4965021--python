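"""Self-organizing map (SOM) core: training, BMU mapping, distance map.

A SOM is a rectangular lattice of codebook vectors trained so that nearby
units represent similar inputs; it projects high-dimensional items
(participants, or body measures viewed as profiles across participants)
onto a 2-D grid.  This module provides:

* batch and online Kohonen training with a linearly decaying Gaussian (or
  bubble) neighborhood,
* deterministic PCA-plane codebook initialization (with a seeded-random
  fallback) so repeated runs do not flip map topology,
* best-matching-unit (BMU) lookup with a fixed row-major tie rule,
* the U-matrix / distance map: per-unit mean Euclidean codebook distance
  to lattice neighbors, whose ridges mark cluster borders,
* plateau-based map-size selection (grow the map until the downstream
  cluster count stops increasing).

Units are indexed ``(row, col)``, 0-based, row-major; the codebook is the
``(height*width, D)`` array in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "TrainingSchedule",
    "SomGrid",
    "train_som",
    "best_matching_units",
    "distance_map",
    "select_map_size",
    "SizeSelection",
]


class SomError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingSchedule:
    """Training schedule for SOM learning.

    The neighborhood radius decays linearly from ``initial_radius``
    (default ``max(width, height) / 2``) to ``final_radius`` over the
    epochs; the learning rate (online mode only) decays linearly from
    ``initial_alpha`` to ``final_alpha``.  The Gaussian kernel weighs
    units by squared lattice distance; the bubble kernel is a hard
    Chebyshev-radius neighborhood.
    """

    n_epochs: int = 100
    initial_radius: float | None = None
    final_radius: float = 1.0
    initial_alpha: float = 0.5
    final_alpha: float = 0.01
    neighborhood_kernel: str = "gaussian"  # gaussian | bubble
    mode: str = "batch"  # batch | online

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise SomError("n_epochs must be >= 1")
        if self.neighborhood_kernel not in ("gaussian", "bubble"):
            raise SomError(f"unknown kernel: {self.neighborhood_kernel}")
        if self.mode not in ("batch", "online"):
            raise SomError(f"unknown mode: {self.mode}")
        if self.initial_radius is not None and self.initial_radius < self.final_radius:
            raise SomError("initial_radius must be >= final_radius")
        if not (0 < self.final_alpha <= self.initial_alpha <= 1):
            raise SomError("alphas must satisfy 0 < final <= initial <= 1")

    def radius_at(self, epoch: int, width: int, height: int) -> float:
        r0 = self.initial_radius if self.initial_radius is not None else max(width, height) / 2.0
        if self.n_epochs == 1:
            return r0
        t = epoch / (self.n_epochs - 1)
        return r0 + t * (self.final_radius - r0)

    def alpha_at(self, epoch: int) -> float:
        if self.n_epochs == 1:
            return self.initial_alpha
        t = epoch / (self.n_epochs - 1)
        return self.initial_alpha + t * (self.final_alpha - self.initial_alpha)


@dataclass
class SomGrid:
    """A trained rectangular SOM lattice."""

    width: int
    height: int
    codebook: np.ndarray  # (height*width, D), row-major unit order
    rng_seed: int
    schedule: TrainingSchedule
    training_log: list = field(default_factory=list)  # per-epoch quantization error

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise SomError("width and height must be >= 2")
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.width * self.height:
            raise SomError("codebook length must equal width*height")
        if not np.all(np.isfinite(self.codebook)):
            raise SomError("codebook must be finite")

    @property
    def n_units(self) -> int:
        return self.width * self.height

    @property
    def dim(self) -> int:
        return self.codebook.shape[1]

    def unit_coords(self) -> np.ndarray:
        """(n_units, 2) array of (row, col) per unit, row-major order."""
        rows, cols = np.divmod(np.arange(self.n_units), self.width)
        return np.column_stack([rows, cols])

    def codebook_grid(self) -> np.ndarray:
        """Codebook reshaped to (height, width, D)."""
        return self.codebook.reshape(self.height, self.width, -1)


# ---------------------------------------------------------------------------
# initialization and training
# ---------------------------------------------------------------------------

def _pca_init(data: np.ndarray, width: int, height: int, seed: int) -> np.ndarray:
    """Codebook on the plane of the first two principal axes.

    Units span +/- 2 SD along PC1 (columns) and PC2 (rows).  Falls back to
    seeded random data samples when the data are too small or degenerate.
    """
    n, d = data.shape
    rng = np.random.default_rng(seed)
    if n >= 3 and d >= 1:
        mean = data.mean(axis=0)
        centered = data - mean
        try:
            _, s, vt = np.linalg.svd(centered, full_matrices=False)
        except np.linalg.LinAlgError:  # pragma: no cover - svd rarely fails
            s = np.zeros(1)
            vt = np.zeros((1, d))
        if len(s) >= 1 and s[0] > 0:
            sd1 = s[0] / math.sqrt(max(n - 1, 1))
            pc1 = vt[0]
            if len(s) >= 2 and s[1] > 0:
                sd2 = s[1] / math.sqrt(max(n - 1, 1))
                pc2 = vt[1]
            else:
                sd2, pc2 = 0.0, np.zeros(d)
            a = np.linspace(-2.0, 2.0, width) * sd1
            b = np.linspace(-2.0, 2.0, height) * sd2
            grid = (
                mean[None, None, :]
                + a[None, :, None] * pc1[None, None, :]
                + b[:, None, None] * pc2[None, None, :]
            )
            return grid.reshape(height * width, d)
    idx = rng.integers(0, n, size=height * width)
    return data[idx].astype(float) + 1e-9 * rng.standard_normal((height * width, d))


def _neighborhood_1d(size: int, radius: float, kernel: str) -> np.ndarray:
    """1-D lattice smoothing matrix; the 2-D kernel is its separable product."""
    delta = np.arange(size)[:, None] - np.arange(size)[None, :]
    if kernel == "gaussian":
        return np.exp(-(delta.astype(float) ** 2) / (2.0 * max(radius, 1e-12) ** 2))
    return (np.abs(delta) <= radius).astype(float)  # bubble (Chebyshev)


def _quantization_error(data: np.ndarray, codebook: np.ndarray) -> float:
    d = cdist(data, codebook)
    return float(d.min(axis=1).mean())


def train_som(
    data: np.ndarray,
    width: int,
    height: int,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
) -> SomGrid:
    """Train a rectangular SOM; deterministic given data and seed.

    ``data`` is an items x features matrix without missing values.  In
    batch mode each epoch assigns every item to its BMU and replaces each
    codebook vector by the neighborhood-weighted mean of the items (the
    Gaussian product kernel is applied separably over rows and columns of
    the lattice, so large maps stay cheap).  The per-epoch quantization
    error (mean item-to-BMU distance before the update) is logged.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
        raise SomError("data must be a non-empty 2-D items x features matrix")
    if not np.all(np.isfinite(data)):
        raise SomError("data must be finite (no NaN/inf)")
    schedule = schedule or TrainingSchedule()
    codebook = _pca_init(data, width, height, seed)
    grid = SomGrid(width=width, height=height, codebook=codebook,
                   rng_seed=seed, schedule=schedule)
    if schedule.mode == "batch":
        _train_batch(grid, data)
    else:
        _train_online(grid, data)
    return grid


def _train_batch(grid: SomGrid, data: np.ndarray) -> None:
    n, d = data.shape
    w, h, sched = grid.width, grid.height, grid.schedule
    codebook = grid.codebook
    for epoch in range(sched.n_epochs):
        dist = cdist(data, codebook)
        bmu = dist.argmin(axis=1)
        grid.training_log.append(float(dist[np.arange(n), bmu].mean()))
        # accumulate per-unit item sums/counts on the lattice
        sums = np.zeros((h * w, d))
        np.add.at(sums, bmu, data)
        counts = np.bincount(bmu, minlength=h * w).astype(float)
        sums = sums.reshape(h, w, d)
        counts = counts.reshape(h, w)
        radius = sched.radius_at(epoch, w, h)
        hr = _neighborhood_1d(h, radius, sched.neighborhood_kernel)
        hc = _neighborhood_1d(w, radius, sched.neighborhood_kernel)
        # separable smoothing: columns then rows
        num = np.tensordot(hr, np.tensordot(hc, sums, axes=(1, 1)).transpose(1, 0, 2), axes=(1, 0))
        den = hr @ counts @ hc.T
        updated = num / np.maximum(den, 1e-12)[:, :, None]
        # units with (numerically) empty neighborhoods keep their codebook
        keep = den < 1e-12
        updated[keep] = codebook.reshape(h, w, d)[keep]
        codebook[:] = updated.reshape(h * w, d)


def _train_online(grid: SomGrid, data: np.ndarray) -> None:
    n, d = data.shape
    w, h, sched = grid.width, grid.height, grid.schedule
    rng = np.random.default_rng(grid.rng_seed)
    coords = grid.unit_coords().astype(float)
    codebook = grid.codebook
    for epoch in range(sched.n_epochs):
        grid.training_log.append(_quantization_error(data, codebook))
        radius = sched.radius_at(epoch, w, h)
        alpha = sched.alpha_at(epoch)
        order = rng.permutation(n)
        for i in order:
            x = data[i]
            bmu = int(((codebook - x) ** 2).sum(axis=1).argmin())
            dr = coords[:, 0] - coords[bmu, 0]
            dc = coords[:, 1] - coords[bmu, 1]
            if sched.neighborhood_kernel == "gaussian":
                influence = np.exp(-(dr**2 + dc**2) / (2.0 * max(radius, 1e-12) ** 2))
            else:
                influence = (np.maximum(np.abs(dr), np.abs(dc)) <= radius).astype(float)
            codebook += alpha * influence[:, None] * (x - codebook)


# ---------------------------------------------------------------------------
# BMU mapping and distance map
# ---------------------------------------------------------------------------

def best_matching_units(som: SomGrid, data: np.ndarray) -> np.ndarray:
    """Per-item BMU coordinates, shape (n_items, 2) of (row, col).

    Each item maps to the unit whose codebook vector is nearest in
    Euclidean distance; exact ties go to the lowest row-major unit index.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != som.dim:
        raise SomError(
            f"feature dimension {data.shape[1]} does not match codebook dim {som.dim}"
        )
    linear = cdist(data, som.codebook).argmin(axis=1)  # argmin -> first (lowest) index
    rows, cols = np.divmod(linear, som.width)
    return np.column_stack([rows, cols])


def bmu_linear(som: SomGrid, data: np.ndarray) -> np.ndarray:
    """Row-major linear BMU indices (convenience wrapper)."""
    rc = best_matching_units(som, data)
    return rc[:, 0] * som.width + rc[:, 1]


def distance_map(som: SomGrid, neighborhood: int = 4) -> np.ndarray:
    """U-matrix: per-unit mean Euclidean distance to adjacent codebooks.

    ``neighborhood`` is 4 (von Neumann, default) or 8 (Moore); border
    units average over their existing neighbors only.
    """
    if neighborhood not in (4, 8):
        raise SomError("neighborhood must be 4 or 8")
    cb = som.codebook_grid()
    h, w = som.height, som.width
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if neighborhood == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    total = np.zeros((h, w))
    count = np.zeros((h, w))
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = cb[r0:r1, c0:c1]
        b = cb[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        d = np.sqrt(((a - b) ** 2).sum(axis=-1))
        total[r0:r1, c0:c1] += d
        count[r0:r1, c0:c1] += 1
    return total / count


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_som(som: SomGrid, path) -> None:
    """Write a map as JSON metadata plus a delimited-text codebook.

    ``path`` gets the metadata (width/height/seed/schedule/training log);
    the codebook goes to ``<path>.codebook.csv``, one unit per row in
    row-major order.
    """
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    meta = {
        "width": som.width,
        "height": som.height,
        "rng_seed": som.rng_seed,
        "schedule": asdict(som.schedule),
        "training_log": som.training_log,
        "codebook_file": path.name + ".codebook.csv",
    }
    path.write_text(json.dumps(meta, indent=2))
    np.savetxt(path.with_name(meta["codebook_file"]), som.codebook, delimiter=",")


def load_som(path) -> SomGrid:
    """Inverse of :func:`save_som`."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.read_text())
    codebook = np.loadtxt(path.with_name(meta["codebook_file"]), delimiter=",", ndmin=2)
    som = SomGrid(
        width=meta["width"],
        height=meta["height"],
        codebook=codebook,
        rng_seed=meta["rng_seed"],
        schedule=TrainingSchedule(**meta["schedule"]),
    )
    som.training_log = list(meta["training_log"])
    return som


# ---------------------------------------------------------------------------
# map-size selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeSelection:
    chosen: int
    sizes: tuple
    counts: tuple
    plateau_found: bool


def select_map_size(
    data: np.ndarray,
    candidate_sizes: Sequence[int],
    downstream_cluster_counter: Callable[[np.ndarray, int, int], int],
    seed: int = 0,
    patience: int = 2,
) -> SizeSelection:
    """Choose the smallest map size at which the cluster count plateaus.

    ``downstream_cluster_counter(data, size, seed)`` runs the full
    training + cluster-detection pipeline at a square ``size`` x ``size``
    grid and returns the number of clusters.  The chosen size is the
    smallest whose following ``patience`` candidates yield no increase in
    cluster count; if no plateau exists the largest candidate is returned
    with ``plateau_found=False``.
    """
    sizes = list(candidate_sizes)
    if sizes != sorted(sizes) or len(set(sizes)) != len(sizes):
        raise SomError("candidate_sizes must be strictly increasing")
    counts = [int(downstream_cluster_counter(data, s, seed)) for s in sizes]
    for i in range(len(sizes)):
        later = counts[i + 1 : i + 1 + patience]
        if len(later) == patience and all(c <= counts[i] for c in later):
            return SizeSelection(sizes[i], tuple(sizes), tuple(counts), True)
    return SizeSelection(sizes[-1], tuple(sizes), tuple(counts), False)
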