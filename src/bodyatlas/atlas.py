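"""Bodygrams and body-map stainings (the atlas layer).

A *bodygram* is a polar profile of one participant's (or one stratum's
mean) meta-measures in Z-units, with axes ordered exactly like the
meta-measures around the feature map and the Z = 0 polygon as the cohort
reference.  A *staining* overlays a per-participant characteristic (age,
gender, BMI, a meta-measure tertile class, ...) onto the body map by
aggregating over the participants mapped to each unit.

All atlas products are materialized as plain arrays/tables first;
matplotlib rendering is a thin optional layer on top, so tests compare
numbers, never pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Bodygram",
    "MapOverlay",
    "bodygram",
    "mean_bodygram",
    "stain_map",
    "tertile_map",
    "plot_bodygram",
    "plot_overlay",
]


class AtlasError(ValueError):
    pass


@dataclass
class Bodygram:
    """Ordered meta-measure Z-profile for polar display.

    Axis i sits at angle ``2*pi*i/K`` measured clockwise from 12 o'clock;
    a radius of 0 lies on the Z = 0 reference polygon.
    """

    axis_order: tuple
    radii: np.ndarray
    stratum: str
    n: int

    def angles(self) -> np.ndarray:
        """Axis angles in radians, clockwise from 12 o'clock."""
        k = len(self.axis_order)
        return 2.0 * math.pi * np.arange(k) / k

    def vertices(self, offset: float = 3.0) -> np.ndarray:
        """(K, 2) Cartesian polygon vertices; radial coordinate offset + Z.

        ``offset`` shifts all radii so negative Z-values stay plottable;
        the Z = 0 reference polygon is the circle of radius ``offset``.
        Screen convention: x to the right, y up, 12 o'clock = (0, +r).
        """
        theta = self.angles()
        r = offset + self.radii
        return np.column_stack([r * np.sin(theta), r * np.cos(theta)])


def bodygram(
    meta_row: Sequence[float] | pd.Series,
    axis_order: Sequence[str],
    stratum: str = "",
) -> Bodygram:
    """Bodygram of a single participant's meta-measure vector."""
    if isinstance(meta_row, pd.Series):
        meta_row = meta_row.reindex(list(axis_order))
        if meta_row.isna().any():
            raise AtlasError("meta_row is missing axes of axis_order")
        radii = meta_row.to_numpy(dtype=float)
    else:
        radii = np.asarray(meta_row, dtype=float)
        if len(radii) != len(axis_order):
            raise AtlasError(
                f"vector length {len(radii)} != axis count {len(axis_order)}"
            )
    return Bodygram(
        axis_order=tuple(axis_order), radii=radii, stratum=stratum or "participant", n=1
    )


def mean_bodygram(
    meta_values: pd.DataFrame,
    stratum_filter: Callable[[pd.DataFrame], pd.Series] | pd.Series,
    covariates: pd.DataFrame | None = None,
    stratum: str = "",
) -> Bodygram:
    """Per-axis mean bodygram over the participants a predicate selects.

    ``stratum_filter`` is either a boolean Series aligned to the
    participants or a callable evaluated on ``covariates`` (e.g.
    ``lambda cov: cov["gender"] == "F"``).
    """
    if callable(stratum_filter):
        if covariates is None:
            raise AtlasError("a callable stratum_filter requires covariates")
        mask = stratum_filter(covariates.reindex(meta_values.index))
    else:
        mask = stratum_filter
    mask = pd.Series(mask).reindex(meta_values.index).fillna(False).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise AtlasError(f"empty stratum: {stratum or stratum_filter!r}")
    sub = meta_values.loc[mask]
    return Bodygram(
        axis_order=tuple(meta_values.columns),
        radii=sub.mean(axis=0).to_numpy(dtype=float),
        stratum=stratum or "stratum",
        n=n,
    )


@dataclass
class MapOverlay:
    """Per-unit aggregated characteristic on the body-map lattice.

    ``values`` is an (H, W) float grid, NaN on units with no mapped
    participant; ``counts`` holds the per-unit occupancy.
    """

    values: np.ndarray
    counts: np.ndarray
    characteristic: str
    statistic: str

    def to_frame(self) -> pd.DataFrame:
        """Long-format (row, col, value, n) table of occupied units."""
        rr, cc = np.nonzero(self.counts > 0)
        return pd.DataFrame(
            {"row": rr, "col": cc, "value": self.values[rr, cc], "n": self.counts[rr, cc]}
        )


def stain_map(
    bmu: np.ndarray,
    characteristic: np.ndarray | pd.Series,
    shape: tuple,
    statistic: str = "mean",
    name: str = "characteristic",
) -> MapOverlay:
    """Aggregate a per-participant value over each body-map unit.

    ``statistic`` is ``"mean"``, ``"mode"`` (ties -> smallest value) or
    ``"tertile_class"`` (classes the values into cohort-wide tertiles
    first, then takes the per-unit modal class).
    """
    bmu = np.asarray(bmu, dtype=int)
    vals = np.asarray(characteristic, dtype=float)
    if vals.shape[0] != bmu.shape[0]:
        raise AtlasError("characteristic must align with the BMU array")
    if np.any(np.isnan(vals)):
        raise AtlasError("characteristic contains missing values")
    h, w = shape
    if statistic == "tertile_class":
        vals = _tertile_classes(vals).astype(float)
        agg = "mode"
    elif statistic in ("mean", "mode"):
        agg = statistic
    else:
        raise AtlasError(f"unknown statistic: {statistic}")

    counts = np.zeros((h, w), dtype=int)
    np.add.at(counts, (bmu[:, 0], bmu[:, 1]), 1)
    out = np.full((h, w), np.nan)
    if agg == "mean":
        totals = np.zeros((h, w))
        np.add.at(totals, (bmu[:, 0], bmu[:, 1]), vals)
        occ = counts > 0
        out[occ] = totals[occ] / counts[occ]
    else:
        groups: dict[tuple, list] = {}
        for (r, c), v in zip(map(tuple, bmu), vals):
            groups.setdefault((r, c), []).append(v)
        for (r, c), vs in groups.items():
            uniq, cnt = np.unique(vs, return_counts=True)
            out[r, c] = uniq[cnt.argmax()]  # ties -> smallest value
    return MapOverlay(values=out, counts=counts, characteristic=name, statistic=statistic)


def _tertile_classes(values: np.ndarray) -> np.ndarray:
    """Class 0/1/2 at the empirical 1/3 and 2/3 quantiles (midpoint
    interpolation); ties on a boundary go to the lower class."""
    q1, q2 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0], method="midpoint")
    return np.where(values <= q1, 0, np.where(values <= q2, 1, 2))


def tertile_map(
    meta_values: pd.DataFrame,
    meta_name: str,
    bmu: np.ndarray,
    shape: tuple,
) -> MapOverlay:
    """Modal cohort-tertile class of one meta-measure per body-map unit."""
    if meta_name not in meta_values.columns:
        raise AtlasError(f"unknown meta-measure: {meta_name}")
    overlay = stain_map(
        bmu,
        meta_values[meta_name].to_numpy(dtype=float),
        shape,
        statistic="tertile_class",
        name=f"tertile[{meta_name}]",
    )
    return overlay


# ---------------------------------------------------------------------------
# optional rendering (thin layer; nothing below is load-bearing for analysis)
# ---------------------------------------------------------------------------

def plot_bodygram(bg: Bodygram, ax=None, offset: float = 3.0, **line_kw):
    """Draw a bodygram as a closed polygon over the Z = 0 reference circle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    verts = bg.vertices(offset=offset)
    closed = np.vstack([verts, verts[:1]])
    theta = np.linspace(0, 2 * math.pi, 200)
    ax.plot(offset * np.sin(theta), offset * np.cos(theta), color="black", lw=1)
    ax.plot(closed[:, 0], closed[:, 1], **{"lw": 1.5, **line_kw})
    for (x, y), label in zip(verts, bg.axis_order):
        ax.annotate(label, (x, y), fontsize=8, ha="center")
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(f"{bg.stratum} (n={bg.n})", fontsize=9)
    return ax


def plot_overlay(overlay: MapOverlay, ax=None, cmap: str = "viridis"):
    """Render a map overlay as an image; empty units stay blank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(overlay.values, cmap=cmap, interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"{overlay.characteristic} ({overlay.statistic})", fontsize=9)
    return ax
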