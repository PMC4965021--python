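"""File formats, pipeline configuration and end-to-end orchestration.

All tables are plain delimited text with a header row.  Measure tables
keep one participant per row; covariate columns carry a ``cov_`` prefix
and missing readings are empty fields.  ``run_pipeline`` chains
simulate/ingest -> preprocess -> feature map -> meta-measures -> body map
-> consensus -> atlas and writes a JSON manifest (inputs, derived seeds,
stage timings, record counts, output hashes) that makes a rerun
bit-checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import bodytypes as bt
from . import consensus as cons
from . import features as ft
from . import preprocess as pp
from . import som as som_mod
from . import synthetic as syn

__all__ = [
    "read_measure_table",
    "write_measure_table",
    "read_s2_table",
    "PipelineConfig",
    "run_pipeline",
    "stage_seed",
]

log = logging.getLogger("bodyatlas")


class IoError(ValueError):
    pass


# ---------------------------------------------------------------------------
# measure-table round trip
# ---------------------------------------------------------------------------

def _detect_sep(path: Path) -> str:
    head = path.open("r").readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_measure_table(
    path: str | Path,
    sep: str | None = None,
    measure_kind: pd.Series | None = None,
) -> pp.MeasureTable:
    """Parse a delimited measure table into a :class:`MeasureTable`.

    The delimiter is auto-detected (comma vs tab) unless ``sep`` is given.
    Columns prefixed ``cov_`` become covariates (``cov_gender`` stays a
    string); everything else must be numeric, with empty fields read as
    missing.  Parse problems are reported with row/column coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such file: {path}")
    sep = sep or _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].tolist()
        raise IoError(f"duplicate column names: {dupes}")
    cov_cols = [c for c in raw.columns if c.startswith("cov_")]
    meas_cols = [c for c in raw.columns if not c.startswith("cov_")]
    if "cov_height" not in cov_cols:
        raise IoError(f"missing required covariate column 'cov_height' in {path}")

    def to_numeric(frame: pd.DataFrame, what: str) -> pd.DataFrame:
        cells = frame.where(frame != "", np.nan)
        out = cells.apply(pd.to_numeric, errors="coerce")
        bad = cells.notna() & out.isna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise IoError(
                f"malformed numeric cell in {what} at row {frame.index[r]!r}, "
                f"column {frame.columns[c]!r}: {cells.iat[r, c]!r}"
            )
        return out

    values = to_numeric(raw[meas_cols], "measures")
    cov = pd.DataFrame(index=raw.index)
    for c in cov_cols:
        name = c[len("cov_"):]
        if name == "gender":
            cov[name] = raw[c]
        else:
            cov[name] = to_numeric(raw[[c]], "covariates")[c]
    return pp.MeasureTable(values=values, covariates=cov, measure_kind=measure_kind)


def write_measure_table(table: pp.MeasureTable, path: str | Path, sep: str = ",") -> None:
    """Write a measure table; covariates prefixed ``cov_``, NaN -> empty."""
    out = table.values.copy()
    for c in table.covariates.columns:
        out[f"cov_{c}"] = table.covariates[c]
    out.to_csv(Path(path), sep=sep, na_rep="")


def read_s2_table(path: str | Path) -> tuple[ft.MetaMeasureTable, pd.DataFrame]:
    """Ingest a deposited processed-data workbook (xlsx).

    Expects one sheet with per-participant rows carrying (case-insensitive)
    ``age``, ``gender``, ``bmi`` and ``body type`` columns plus one column
    per meta-measure (single upper-case letters).  Returns the meta table
    (not row-normalized) and a covariate frame with the body-type labels.
    """
    df = pd.read_excel(Path(path))
    colmap = {c: str(c).strip().lower() for c in df.columns}
    meta_cols = [c for c in df.columns if len(str(c).strip()) <= 2 and str(c).strip().isalpha()
                 and str(c).strip().isupper()]
    wanted = {"age", "gender", "bmi", "body type", "body_type"}
    cov_cols = [c for c in df.columns if colmap[c] in wanted]
    if not meta_cols:
        raise IoError("no meta-measure columns (single capital letters) found")
    cov = df[cov_cols].rename(columns=lambda c: colmap[c].replace(" ", "_"))
    meta = ft.MetaMeasureTable(
        values=df[meta_cols].astype(float),
        members={str(c): [] for c in meta_cols},
        singletons_excluded=[],
    )
    return meta, cov


# ---------------------------------------------------------------------------
# configuration and seeds
# ---------------------------------------------------------------------------

def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (below 2^31)."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2_654_435_761)) % 2**31


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with its default."""

    # input: either a cohort file, or a synthetic-cohort config to simulate
    input_path: str | None = None
    cohort: syn.CohortConfig = field(default_factory=syn.CohortConfig)
    # preprocessing
    participant_threshold: float = 0.5
    measure_threshold: float = 0.05
    exempt_kinds: tuple = ()
    include_indices: bool = True
    # feature map
    feature_grid: tuple = (50, 50)
    feature_epochs: int = 100
    theta: float = 0.30
    min_cluster_members: int = 2
    # body map
    body_grid: tuple = (130, 130)
    body_epochs: int = 100
    body_smooth_sigma: float = 2.0
    min_fraction: float = 0.01
    min_count: int | None = None
    gender_threshold: float = 0.8
    # consensus
    consensus_iters: int = 100
    consensus_subsample_fraction: float = 0.5
    stability_sizes: tuple = ()
    # global
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = syn.CohortConfig(**raw.pop("cohort", {}))
        cfg = cls(cohort=cohort, **raw)
        for name in ("feature_grid", "body_grid", "stability_sizes", "exempt_kinds"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        return d


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write all artifacts plus a manifest.

    Stages: simulate/ingest -> preprocess -> feature map -> meta-measures
    -> body map -> consensus (+ optional stability curve) -> atlas.  Any
    stage error propagates wrapped with the stage name.  Returns the
    manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
        "counts": {},
    }
    t_all = time.time()

    def record(stage: str, t0: float) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3),
                                     "seed": stage_seed(config.seed, stage)}
        log.info("stage %s done in %.2fs", stage, time.time() - t0)

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path.name), "sha256": _sha256(path)}

    try:
        # --- ingest / simulate -------------------------------------------
        t0 = time.time()
        stage = "ingest"
        truth_types = None
        if config.input_path:
            table = read_measure_table(config.input_path)
        else:
            cohort_cfg = dataclasses.replace(
                config.cohort, seed=stage_seed(config.seed, "simulate")
            )
            cohort = syn.generate_cohort(cohort_cfg)
            table = cohort.to_measure_table()
            truth_types = cohort.truth_body_type
            path = outdir / "cohort.csv"
            write_measure_table(table, path)
            emit("cohort", path)
            truth = pd.DataFrame({
                "body_type": cohort.truth_body_type,
            })
            truth.to_csv(outdir / "truth_body_type.csv")
            cohort.truth_block_of_measure.rename("block").to_csv(outdir / "truth_blocks.csv")
            emit("truth_body_type", outdir / "truth_body_type.csv")
            emit("truth_blocks", outdir / "truth_blocks.csv")
        manifest["counts"]["raw_participants"] = table.n_participants
        manifest["counts"]["raw_measures"] = table.n_measures
        record(stage, t0)

        # --- preprocess ---------------------------------------------------
        t0 = time.time(); stage = "preprocess"
        clean, report = pp.filter_missing(
            table, config.participant_threshold, config.measure_threshold
        )
        if config.include_indices and {"weight", "waist", "hip"} <= set(
            clean.covariates.columns
        ):
            clean = pp.append_indices(clean)
        normed = pp.z_normalize_columns(
            pp.height_normalize(clean, exempt_kinds=config.exempt_kinds)
        )
        (outdir / "preprocess_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        emit("preprocess_report", outdir / "preprocess_report.json")
        write_measure_table(normed, outdir / "clean.csv")
        emit("clean", outdir / "clean.csv")
        manifest["counts"].update(report.to_dict())
        record(stage, t0)

        # --- feature map --------------------------------------------------
        t0 = time.time(); stage = "feature-map"
        fw, fh = config.feature_grid
        fsched = som_mod.TrainingSchedule(n_epochs=config.feature_epochs)
        fdata = normed.values.to_numpy(dtype=float).T  # measures as items
        fsom = som_mod.train_som(fdata, int(fw), int(fh), fsched,
                                 seed=stage_seed(config.seed, stage))
        fdmap = som_mod.distance_map(fsom)
        fbmu = som_mod.best_matching_units(fsom, fdata)
        raw_assign = ft.detect_clusters(fdmap, fbmu, theta=config.theta)
        assign = ft.prune_singletons(raw_assign, config.min_cluster_members)
        np.savetxt(outdir / "feature_dmap.csv", fdmap, delimiter=",")
        emit("feature_dmap", outdir / "feature_dmap.csv")
        manifest["counts"]["n_meta_measures"] = assign.n_clusters
        manifest["counts"]["n_singleton_measures"] = int(
            (assign.item_labels == ft.UNASSIGNED).sum()
        )
        record(stage, t0)

        # --- meta-measures ------------------------------------------------
        t0 = time.time(); stage = "meta-measures"
        meta = ft.aggregate_meta_measures(normed, assign)
        meta_z = ft.z_normalize_rows(meta)
        meta.values.to_csv(outdir / "meta_measures.csv")
        emit("meta_measures", outdir / "meta_measures.csv")
        membership = pd.DataFrame(
            [(m, name) for name, ms in meta.members.items() for m in ms],
            columns=["measure", "meta_name"],
        )
        membership.to_csv(outdir / "meta_membership.csv", index=False)
        emit("meta_membership", outdir / "meta_membership.csv")
        record(stage, t0)

        # --- body map -----------------------------------------------------
        t0 = time.time(); stage = "body-map"
        bsched = som_mod.TrainingSchedule(n_epochs=config.body_epochs)
        bodytypes = bt.assign_body_types(
            meta_z,
            grid=tuple(int(g) for g in config.body_grid),
            schedule=bsched,
            seed=stage_seed(config.seed, stage),
            min_fraction=config.min_fraction,
            min_count=config.min_count,
            theta=config.theta,
            smooth_sigma=config.body_smooth_sigma,
        )
        bt.label_by_gender(bodytypes, normed.covariates["gender"], config.gender_threshold)
        idx_frame = None
        if {"weight", "waist", "hip"} <= set(normed.covariates.columns):
            cov = normed.covariates
            iset = pp.compute_indices(
                cov["weight"].to_numpy(float), cov["height"].to_numpy(float) / 100.0,
                cov["waist"].to_numpy(float) / 100.0, cov["hip"].to_numpy(float) / 100.0,
            )
            idx_frame = pd.DataFrame(
                {"bmi": iset.bmi, "whr": iset.whr, "whtr": iset.whtr, "absi": iset.absi},
                index=cov.index,
            )
        summary = bt.summarize_body_types(bodytypes, normed.covariates, idx_frame)
        out_assign = pd.DataFrame(
            {
                "bmu_row": bodytypes.bmu[:, 0],
                "bmu_col": bodytypes.bmu[:, 1],
                "body_type": bodytypes.labels(),
            },
            index=bodytypes.participants,
        )
        out_assign.to_csv(outdir / "body_types.csv")
        emit("body_types", outdir / "body_types.csv")
        summary.to_csv(outdir / "body_type_summary.csv")
        emit("body_type_summary", outdir / "body_type_summary.csv")
        manifest["counts"]["n_body_types"] = bodytypes.n_types
        manifest["counts"]["n_unassigned_participants"] = bodytypes.n_unassigned
        if truth_types is not None:
            from sklearn.metrics import adjusted_rand_score

            manifest["counts"]["body_type_ari_vs_truth"] = float(
                adjusted_rand_score(
                    truth_types.reindex(bodytypes.participants).to_numpy(),
                    bodytypes.cluster_ids,
                )
            )
        record(stage, t0)

        # --- consensus ----------------------------------------------------
        t0 = time.time(); stage = "consensus"
        bdata = meta_z.values.to_numpy(dtype=float)
        sub = max(2, int(round(config.consensus_subsample_fraction * bdata.shape[0])))
        body_grid = tuple(int(g) for g in config.body_grid)

        def body_proc(d: np.ndarray, s: int) -> np.ndarray:
            g = som_mod.train_som(d, body_grid[0], body_grid[1], bsched, seed=s)
            dm = som_mod.distance_map(g)
            bm = som_mod.best_matching_units(g, d)
            a = ft.detect_clusters(dm, bm, theta=config.theta,
                                   smooth_sigma=config.body_smooth_sigma)
            labels = a.item_labels.copy()
            min_sz = max(1, int(np.ceil(config.min_fraction * d.shape[0])))
            for k, c in a.cluster_sizes.items():
                if c < min_sz:
                    labels[labels == k] = ft.UNASSIGNED
            return labels

        cmat = cons.subsampled_consensus(
            bdata, sub, body_proc, n_iter=config.consensus_iters,
            seed=stage_seed(config.seed, stage),
        )
        stats = cons.consensus_stats(cmat, bodytypes.cluster_ids)
        link = cons.consensus_dendrogram(stats) if len(stats.cluster_ids) > 1 else None
        pd.DataFrame(
            stats.inter,
            index=[bodytypes.type_names.get(k, str(k)) for k in stats.cluster_ids],
            columns=[bodytypes.type_names.get(k, str(k)) for k in stats.cluster_ids],
        ).to_csv(outdir / "inter_cluster_consensus.csv")
        emit("inter_cluster_consensus", outdir / "inter_cluster_consensus.csv")
        if link is not None:
            np.savetxt(outdir / "dendrogram.csv", link, delimiter=",")
            emit("dendrogram", outdir / "dendrogram.csv")
        manifest["counts"]["mean_intra_consensus"] = stats.mean_intra
        if config.stability_sizes:
            curve = cons.stability_vs_size(
                bdata, sorted(config.stability_sizes), body_proc,
                n_iter=config.consensus_iters,
                seed=stage_seed(config.seed, "stability"),
                reference_labels=bodytypes.cluster_ids,
            )
            curve.to_frame().to_csv(outdir / "stability_curve.csv", index=False)
            emit("stability_curve", outdir / "stability_curve.csv")
        record(stage, t0)

        # --- atlas --------------------------------------------------------
        t0 = time.time(); stage = "atlas"
        shape = (bodytypes.som.height, bodytypes.som.width)
        grams = []
        for g, label in (("F", "women"), ("M", "men")):
            mask = (normed.covariates["gender"] == g).reindex(meta.values.index, fill_value=False)
            if mask.any():
                bg = atlas_mod.mean_bodygram(meta.values, mask, stratum=label)
                grams.extend(
                    {"stratum": bg.stratum, "axis": a, "radius": r, "n": bg.n}
                    for a, r in zip(bg.axis_order, bg.radii)
                )
        pd.DataFrame(grams).to_csv(outdir / "bodygrams.csv", index=False)
        emit("bodygrams", outdir / "bodygrams.csv")
        overlays = {"age": normed.covariates["age"].to_numpy(float)}
        if idx_frame is not None:
            overlays.update({c: idx_frame[c].to_numpy(float) for c in idx_frame.columns})
        rows = []
        for name, vals in overlays.items():
            ov = atlas_mod.stain_map(bodytypes.bmu, vals, shape, "mean", name)
            f = ov.to_frame()
            f.insert(0, "characteristic", name)
            rows.append(f)
        pd.concat(rows, ignore_index=True).to_csv(outdir / "map_overlays.csv", index=False)
        emit("map_overlays", outdir / "map_overlays.csv")
        record(stage, t0)

    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
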