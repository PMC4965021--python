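"""Body-type detection on the participant map.

A second, larger SOM (the *body map*) is trained on the row-Z-normalized
meta-measure vectors so that each unit collects participants of similar
body shape.  Separated basins of its U-matrix define *body types*; only
clusters holding at least a minimum share of the cohort (default 1%,
generalizing an absolute floor of 85 participants in an ~8,500-person
cohort) are kept, the rest of the participants stay unassigned.  Types
are labelled by gender composition — F* mostly female, M* mostly male,
B* mixed — and numbered by descending size within each letter group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    UNASSIGNED,
    ClusterAssignment,
    MetaMeasureTable,
    detect_clusters,
)
from .som import SomGrid, TrainingSchedule, best_matching_units, distance_map, train_som

__all__ = ["BodyTypeAssignment", "assign_body_types", "label_by_gender", "summarize_body_types"]


class BodyTypeError(ValueError):
    pass


@dataclass
class BodyTypeAssignment:
    """Per-participant body-type labels plus the map they came from."""

    participants: pd.Index
    cluster_ids: np.ndarray          # int id per participant, -1 unassigned
    bmu: np.ndarray                  # (n, 2) body-map coordinates
    som: SomGrid
    dmap: np.ndarray
    assignment: ClusterAssignment
    min_size: int
    type_names: dict = field(default_factory=dict)  # cluster id -> "F1"/"M2"/"B1"...

    @property
    def n_types(self) -> int:
        return int(len(np.unique(self.cluster_ids[self.cluster_ids != UNASSIGNED])))

    @property
    def n_unassigned(self) -> int:
        return int((self.cluster_ids == UNASSIGNED).sum())

    @property
    def type_sizes(self) -> dict:
        ids, counts = np.unique(
            self.cluster_ids[self.cluster_ids != UNASSIGNED], return_counts=True
        )
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def labels(self) -> pd.Series:
        """Per-participant type name ("F1", ...; "unassigned" sentinel)."""
        names = [
            self.type_names.get(int(c), "unassigned") if c != UNASSIGNED else "unassigned"
            for c in self.cluster_ids
        ]
        return pd.Series(names, index=self.participants, name="body_type")


def assign_body_types(
    meta: MetaMeasureTable,
    grid: tuple = (130, 130),
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    min_fraction: float = 0.01,
    min_count: int | None = None,
    theta: float = 0.30,
    smooth_sigma: float = 2.0,
) -> BodyTypeAssignment:
    """Train the body map and cut it into body types.

    ``meta`` must be the row-Z-normalized meta-measure table.  Cluster
    detection runs on the body-map U-matrix; clusters smaller than
    ``ceil(min_fraction * N)`` participants (or ``min_count``, whichever
    is larger, when an absolute floor is given) are dissolved into the
    unassigned pool.  Deterministic given ``seed``.
    """
    if not meta.row_normalized:
        raise BodyTypeError(
            "assign_body_types expects a row-Z-normalized meta table "
            "(apply z_normalize_rows first)"
        )
    data = meta.values.to_numpy(dtype=float)
    n = data.shape[0]
    width, height = int(grid[0]), int(grid[1])
    som = train_som(data, width=width, height=height, schedule=schedule, seed=seed)
    dmap = distance_map(som)
    bmu = best_matching_units(som, data)
    assignment = detect_clusters(dmap, bmu, theta=theta, smooth_sigma=smooth_sigma)

    min_size = math.ceil(min_fraction * n)
    if min_count is not None:
        min_size = max(min_size, int(min_count))
    sizes = assignment.cluster_sizes
    keep = sorted(k for k, c in sizes.items() if c >= min_size)
    if not keep:
        raise BodyTypeError(
            f"no body-type cluster reaches the minimum size {min_size} "
            f"(largest cluster: {max(sizes.values()) if sizes else 0})"
        )
    relabel = {old: new for new, old in enumerate(keep)}
    cluster_ids = np.array(
        [relabel.get(int(c), UNASSIGNED) for c in assignment.item_labels], dtype=int
    )
    unit_labels = np.full_like(assignment.unit_labels, UNASSIGNED)
    for old, new in relabel.items():
        unit_labels[assignment.unit_labels == old] = new
    pruned = ClusterAssignment(unit_labels=unit_labels, item_labels=cluster_ids, bmu=bmu)
    return BodyTypeAssignment(
        participants=meta.values.index,
        cluster_ids=cluster_ids,
        bmu=bmu,
        som=som,
        dmap=dmap,
        assignment=pruned,
        min_size=min_size,
    )


def label_by_gender(
    assignment: BodyTypeAssignment,
    gender: pd.Series,
    majority_threshold: float = 0.8,
) -> BodyTypeAssignment:
    """Name each type F*/M*/B* by its gender composition.

    A type is F* when its female fraction reaches ``majority_threshold``,
    M* when its male fraction does, otherwise B* (mixed).  Within each
    letter, numbering runs by descending type size (ties by cluster id).
    The assignment is updated in place and returned.
    """
    gender = gender.reindex(assignment.participants)
    assigned = assignment.cluster_ids != UNASSIGNED
    if gender[assigned].isna().any():
        missing = assignment.participants[assigned & gender.isna().to_numpy()]
        raise BodyTypeError(f"gender missing for assigned participants: {list(missing)[:5]}")

    sizes = assignment.type_sizes
    letters = {}
    for k in sizes:
        members = gender[assignment.cluster_ids == k]
        f_frac = float((members == "F").mean())
        if f_frac >= majority_threshold:
            letters[k] = "F"
        elif (1.0 - f_frac) >= majority_threshold:
            letters[k] = "M"
        else:
            letters[k] = "B"
    names = {}
    for letter in ("F", "M", "B"):
        group = [k for k, l in letters.items() if l == letter]
        group.sort(key=lambda k: (-sizes[k], k))
        for i, k in enumerate(group, start=1):
            names[k] = f"{letter}{i}"
    assignment.type_names = names
    return assignment


#: banded distributions reported per body type
BMI_BANDS = ((-np.inf, 18.5), (18.5, 25.0), (25.0, 30.0), (30.0, np.inf))
WHTR_BANDS = ((-np.inf, 0.4), (0.4, 0.5), (0.5, 0.6), (0.6, np.inf))


def _band_counts(values: np.ndarray, bands) -> list:
    return [int(((values > lo) & (values <= hi)).sum()) for lo, hi in bands]


def summarize_body_types(
    assignment: BodyTypeAssignment,
    covariates: pd.DataFrame,
    indices: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-type summary: size, gender split, age/height, index bands.

    ``indices`` optionally supplies per-participant ``bmi``, ``whr``,
    ``whtr``, ``absi`` columns; WHR and ABSI are banded into cohort-wide
    tertiles, BMI and WHtR into their conventional clinical bands.
    """
    cov = covariates.reindex(assignment.participants)
    n_total = len(assignment.participants)
    rows = []
    tertiles = {}
    if indices is not None:
        indices = indices.reindex(assignment.participants)
        for col in ("whr", "absi"):
            if col in indices.columns:
                v = indices[col].to_numpy(float)
                tertiles[col] = np.quantile(v, [1 / 3, 2 / 3], method="midpoint")
    for k, size in sorted(assignment.type_sizes.items()):
        sel = assignment.cluster_ids == k
        members = cov[sel]
        row = {
            "type": assignment.type_names.get(k, f"T{k}"),
            "cluster_id": k,
            "n": size,
            "pct_cohort": 100.0 * size / n_total,
            "n_female": int((members["gender"] == "F").sum()),
            "n_male": int((members["gender"] == "M").sum()),
            "age_mean": float(members["age"].mean()),
            "age_sd": float(members["age"].std(ddof=1)) if size > 1 else 0.0,
            "height_mean": float(members["height"].mean()),
            "height_sd": float(members["height"].std(ddof=1)) if size > 1 else 0.0,
        }
        if indices is not None:
            sub = indices[sel]
            if "bmi" in sub.columns:
                for (lo, hi), c in zip(BMI_BANDS, _band_counts(sub["bmi"].to_numpy(float), BMI_BANDS)):
                    row[f"bmi_{lo:g}_{hi:g}"] = c
                row["bmi_mean"] = float(sub["bmi"].mean())
            if "whtr" in sub.columns:
                for (lo, hi), c in zip(WHTR_BANDS, _band_counts(sub["whtr"].to_numpy(float), WHTR_BANDS)):
                    row[f"whtr_{lo:g}_{hi:g}"] = c
                row["whtr_mean"] = float(sub["whtr"].mean())
            for col, cuts in tertiles.items():
                v = sub[col].to_numpy(float)
                row[f"{col}_t1"] = int((v <= cuts[0]).sum())
                row[f"{col}_t2"] = int(((v > cuts[0]) & (v <= cuts[1])).sum())
                row[f"{col}_t3"] = int((v > cuts[1]).sum())
                row[f"{col}_mean"] = float(np.mean(v))
        rows.append(row)
    return pd.DataFrame(rows).set_index("type")
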