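"""Preprocessing of raw anthropometric measure tables.

The raw input is a participants x measures table of body-scanner readings
(lengths and girths in cm, angles in degrees, weight in kg) together with
per-participant covariates (gender, age, body height).  Before any map
training the table passes through three steps, in this order:

1. a three-stage missing-value filter (participants, then measures, then
   the remaining incomplete participants),
2. division of every measure by the participant's body height, which
   removes overall body-size scaling and leaves shape information,
3. Z-normalization of every measure column to zero mean and unit standard
   deviation, putting all measures on a common scale for Euclidean
   distances.

The classical body indices BMI, WHR, WHtR and ABSI are computed here as
well; by convention they may be appended to the measure table and treated
like any other column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasureTable",
    "PreprocessReport",
    "IndexSet",
    "filter_missing",
    "height_normalize",
    "z_normalize_columns",
    "compute_indices",
]

#: recognised measure kinds
MEASURE_KINDS = ("length", "girth", "angle", "weight", "index")


class PreprocessError(ValueError):
    """Raised when a preprocessing contract is violated."""


@dataclass
class MeasureTable:
    """Participants x measures matrix with covariates and measure metadata.

    Parameters
    ----------
    values
        DataFrame indexed by participant id, one column per measure.
        Missing readings are ``NaN``.
    covariates
        DataFrame aligned on the same index.  Must contain at least
        ``gender`` (``"F"``/``"M"``), ``age`` (years) and ``height`` (cm).
    measure_kind
        Series mapping measure name to one of :data:`MEASURE_KINDS`.
        Missing entries default to ``"length"``.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    measure_kind: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.measure_kind is None:
            self.measure_kind = pd.Series("length", index=self.values.columns)
        else:
            self.measure_kind = self.measure_kind.reindex(
                self.values.columns, fill_value="length"
            )
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise PreprocessError(f"duplicate measure names: {dupes}")
        if not self.values.index.equals(self.covariates.index):
            raise PreprocessError("values and covariates must share the participant index")
        bad_kind = set(self.measure_kind) - set(MEASURE_KINDS)
        if bad_kind:
            raise PreprocessError(f"unknown measure kinds: {sorted(bad_kind)}")

    # -- convenience views -------------------------------------------------
    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where a reading is missing."""
        return self.values.isna()

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_measures(self) -> int:
        return self.values.shape[1]

    @property
    def measure_names(self) -> list[str]:
        return list(self.values.columns)

    def require_complete(self, op: str) -> None:
        n_missing = int(self.values.isna().to_numpy().sum())
        if n_missing:
            raise PreprocessError(
                f"{op} requires a complete table; {n_missing} missing cells present "
                "(run filter_missing first)"
            )


@dataclass(frozen=True)
class PreprocessReport:
    """Book-keeping of the three-stage missing-value filter."""

    n_participants_removed_stage1: int
    n_measures_removed_stage2: int
    n_participants_removed_stage3: int
    remaining_P: int  # measures
    remaining_N: int  # participants
    total_missing_cells: int
    removed_participants_stage1: tuple = ()
    removed_measures_stage2: tuple = ()
    removed_participants_stage3: tuple = ()

    def to_dict(self) -> dict:
        return {
            "n_participants_removed_stage1": self.n_participants_removed_stage1,
            "n_measures_removed_stage2": self.n_measures_removed_stage2,
            "n_participants_removed_stage3": self.n_participants_removed_stage3,
            "remaining_P": self.remaining_P,
            "remaining_N": self.remaining_N,
            "total_missing_cells": self.total_missing_cells,
        }


@dataclass(frozen=True)
class IndexSet:
    """The four classical body indices.

    bmi : kg/m^2, weight / height^2
    whr : waist / hip (dimensionless)
    whtr : waist / height (dimensionless)
    absi : waist / (bmi^(2/3) * height^(1/2)), units m^(11/6) kg^(-2/3)
    """

    bmi: float
    whr: float
    whtr: float
    absi: float


# ---------------------------------------------------------------------------
# stage 1-3 missing-value filter
# ---------------------------------------------------------------------------

def filter_missing(
    table: MeasureTable,
    participant_threshold: float = 0.5,
    measure_threshold: float = 0.05,
) -> tuple[MeasureTable, PreprocessReport]:
    """Remove missing values in three ordered stages.

    Stage 1 removes participants missing more than ``participant_threshold``
    of their measures.  Stage 2 removes measures missing in more than
    ``measure_threshold`` of the *remaining* participants.  Stage 3 removes
    every remaining participant that still has at least one missing value.
    The output table is complete (no NaN).

    The stage order matters and is part of the contract: measure missing
    fractions are evaluated only after grossly incomplete participants are
    gone, so a handful of near-empty rows cannot drag many measures over
    the 5% line.
    """
    if not (0 < participant_threshold < 1) or not (0 < measure_threshold < 1):
        raise PreprocessError("thresholds must lie strictly between 0 and 1")

    mask = table.values.isna()
    total_missing = int(mask.to_numpy().sum())

    # stage 1: participants with > threshold missing measures
    frac_by_participant = mask.mean(axis=1)
    drop1 = frac_by_participant.index[frac_by_participant > participant_threshold]
    vals = table.values.drop(index=drop1)
    if vals.shape[0] == 0:
        raise PreprocessError("stage 1 (participant filter) removed every participant")

    # stage 2: measures with > threshold missing among remaining participants
    frac_by_measure = vals.isna().mean(axis=0)
    drop2 = frac_by_measure.index[frac_by_measure > measure_threshold]
    vals = vals.drop(columns=drop2)
    if vals.shape[1] == 0:
        raise PreprocessError("stage 2 (measure filter) removed every measure")

    # stage 3: remaining participants with any missing value
    has_missing = vals.isna().any(axis=1)
    drop3 = vals.index[has_missing]
    vals = vals.drop(index=drop3)
    if vals.shape[0] == 0:
        raise PreprocessError("stage 3 (complete-case filter) removed every participant")

    out = MeasureTable(
        values=vals,
        covariates=table.covariates.loc[vals.index],
        measure_kind=table.measure_kind.reindex(vals.columns),
    )
    report = PreprocessReport(
        n_participants_removed_stage1=len(drop1),
        n_measures_removed_stage2=len(drop2),
        n_participants_removed_stage3=len(drop3),
        remaining_P=out.n_measures,
        remaining_N=out.n_participants,
        total_missing_cells=total_missing,
        removed_participants_stage1=tuple(drop1),
        removed_measures_stage2=tuple(drop2),
        removed_participants_stage3=tuple(drop3),
    )
    return out, report


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def height_normalize(
    table: MeasureTable, exempt_kinds: Iterable[str] = ()
) -> MeasureTable:
    """Divide every measure by the participant's body height.

    Height is taken from the covariates in the same length unit as the
    measures (cm over cm), so normalized lengths and girths become
    dimensionless shape measures.  All kinds are normalized by default;
    ``exempt_kinds`` (e.g. ``("angle",)``) skips kinds for which division
    by a length is physically meaningless.
    """
    table.require_complete("height_normalize")
    height = table.covariates["height"].astype(float)
    if (height <= 0).any() or height.isna().any():
        bad = height.index[(height <= 0) | height.isna()].tolist()
        raise PreprocessError(f"non-positive or missing height for participants: {bad}")

    exempt = set(exempt_kinds)
    out = table.values.astype(float).copy()
    norm_cols = [m for m in out.columns if table.measure_kind[m] not in exempt]
    out[norm_cols] = out[norm_cols].div(height, axis=0)
    return replace(table, values=out)


def z_normalize_columns(table: MeasureTable, ddof: int = 1) -> MeasureTable:
    """Z-normalize each measure column to mean 0 and SD 1.

    Sample standard deviation (``ddof=1``) is used; at cohort scale the
    choice is numerically immaterial but it is fixed for reproducibility.
    """
    table.require_complete("z_normalize_columns")
    if table.n_participants < 2:
        raise PreprocessError("z_normalize_columns needs at least 2 participants")
    vals = table.values.astype(float)
    sd = vals.std(axis=0, ddof=ddof)
    zero_var = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero_var:
        raise PreprocessError(f"zero-variance measure columns: {zero_var}")
    out = (vals - vals.mean(axis=0)) / sd
    return replace(table, values=out)


# ---------------------------------------------------------------------------
# classical body indices
# ---------------------------------------------------------------------------

def compute_indices(weight: float, height: float, waist: float, hip: float) -> IndexSet:
    """Compute BMI, WHR, WHtR and ABSI from basal measures.

    Parameters are in SI units: ``weight`` kg, ``height``/``waist``/``hip``
    metres.  Accepts scalars or aligned numpy arrays.

    ABSI = waist / (BMI^(2/3) * height^(1/2)), the allometric waist index
    whose mortality association motivated its inclusion among the classical
    indices.
    """
    w, h, wa, hi = (np.asarray(x, dtype=float) for x in (weight, height, waist, hip))
    if np.any(w <= 0) or np.any(h <= 0) or np.any(wa <= 0) or np.any(hi <= 0):
        raise PreprocessError("compute_indices requires strictly positive inputs")
    bmi = w / h**2
    whr = wa / hi
    whtr = wa / h
    absi = wa / (bmi ** (2.0 / 3.0) * h**0.5)
    if bmi.ndim == 0:
        return IndexSet(float(bmi), float(whr), float(whtr), float(absi))
    return IndexSet(bmi, whr, whtr, absi)  # type: ignore[arg-type]


def append_indices(table: MeasureTable) -> MeasureTable:
    """Append BMI/WHR/WHtR/ABSI as ``index``-kind measure columns.

    Requires ``weight``, ``waist`` and ``hip`` covariates (kg / cm / cm);
    heights are covariate cm and converted to metres internally.
    """
    cov = table.covariates
    for col in ("weight", "waist", "hip"):
        if col not in cov.columns:
            raise PreprocessError(f"append_indices requires covariate '{col}'")
    idx = compute_indices(
        cov["weight"].to_numpy(float),
        cov["height"].to_numpy(float) / 100.0,
        cov["waist"].to_numpy(float) / 100.0,
        cov["hip"].to_numpy(float) / 100.0,
    )
    vals = table.values.copy()
    vals["bmi"] = idx.bmi
    vals["whr"] = idx.whr
    vals["whtr"] = idx.whtr
    vals["absi"] = idx.absi
    kind = pd.concat(
        [table.measure_kind, pd.Series("index", index=["bmi", "whr", "whtr", "absi"])]
    )
    return MeasureTable(values=vals, covariates=table.covariates, measure_kind=kind)
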