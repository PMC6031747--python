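"""File formats, run configuration and end-to-end orchestration.

CSV dialect: UTF-8, comma separated, header row, dot decimal.  Well
coordinates are 0-based (row, col) with row 0 at the chip top.  The layout
is a headerless TSV grid with a JSON sidecar carrying the geometry
metadata.  Every output directory receives a provenance.json sufficient to
reproduce it bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from topochip import topo_design as td
from topochip import synthetic_screen as synth_mod
from topochip import screen_pipeline as sp
from topochip import ml_models as ml
from topochip.errors import SchemaError
from topochip.synthetic_screen import SynthConfig

log = logging.getLogger("topochip")

REQUIRED_CELL_COLUMNS = synth_mod.CELL_COLUMNS


# ---------------------------------------------------------------------------
# tabular round-trips


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in REQUIRED_CELL_COLUMNS if c in cells.columns]
    extra = [c for c in cells.columns if c not in cols]
    cells[cols + extra].to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: cells table lacks column(s) {missing}")
    numeric = [c for c in REQUIRED_CELL_COLUMNS
               if c not in ("chip_id", "row", "col", "unit_id", "cell_id")]
    for col in numeric:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}")
        df[col] = pd.to_numeric(df[col])
    return df


def write_controls(controls: pd.DataFrame, path: str | Path) -> None:
    controls.to_csv(path, index=False)


def read_controls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("condition", "cell_id", "icam1_median_intensity"):
        if col not in df.columns:
            raise SchemaError(f"{path}: controls table lacks column {col!r}")
    return df


def write_layout(layout: td.ChipLayout, path: str | Path) -> None:
    path = Path(path)
    grid = layout.grid.astype(str)
    path.write_text("\n".join("\t".join(row) for row in grid) + "\n")
    sidecar = {
        "n_unique": layout.n_unique,
        "n_flat_wells": layout.n_flat_wells,
        "well_pitch_um": layout.well_pitch_um,
        "well_side_um": layout.well_side_um,
        "wall_width_um": layout.wall_width_um,
        "flat_id": layout.flat_id,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_layout(path: str | Path) -> td.ChipLayout:
    path = Path(path)
    rows = [line.split("\t") for line in path.read_text().strip().split("\n")]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise SchemaError(f"{path}: ragged layout grid (row widths {sorted(widths)})")
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    grid = np.array(rows, dtype=object)
    flat_id = meta.get("flat_id", td.FLAT_ID)
    n_unique = meta.get("n_unique")
    if n_unique is None:
        n_unique = len({u for u in grid.ravel() if u != flat_id})
    return td.ChipLayout(
        grid=grid,
        n_unique=int(n_unique),
        n_flat_wells=int(meta.get("n_flat_wells", int((grid == flat_id).sum()))),
        well_pitch_um=float(meta.get("well_pitch_um", 300.0)),
        well_side_um=float(meta.get("well_side_um", 300.0)),
        wall_width_um=float(meta.get("wall_width_um", 10.0)),
        flat_id=flat_id,
    )


def write_hit_table(table: pd.DataFrame, path: str | Path) -> None:
    table[sp.HIT_TABLE_COLUMNS].to_csv(path, index=False)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in sp.HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: hit table lacks column(s) {missing}")
    return df


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "unit_id" not in df.columns:
        raise SchemaError(f"{path}: feature table lacks column 'unit_id'")
    return df


# ---------------------------------------------------------------------------
# run configuration


class RunConfig(BaseModel):
    """Everything an end-to-end run needs; validates before any stage runs."""

    out_dir: str = "topochip_out"
    simulate: bool = True
    cells_path: str | None = None
    controls_path: str | None = None
    layout_path: str | None = None
    features_path: str | None = None

    n_unique: int = 2176
    grid_rows: int = 66
    grid_cols: int = 66
    n_flat_wells: int = 4
    resolution_um: float = 1.0

    synth: SynthConfig = Field(default_factory=SynthConfig)

    qc_multiplier: float = 1.5
    threshold_method: str = "control_intersection"  # or "fixed_percentile"
    fixed_percentile: float = 93.0
    alpha: float = 0.05
    adjusted: bool = False
    reference: str = "control"  # "control" (off-chip) or "flat_wells" (on-chip)

    ml_feature_set: str = "design"  # "design" | "shape" | "none"
    ml_repeats: int = 100
    ml_holdout: float = 0.25
    ml_cv_folds: int = 10

    master_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def json_schema_text(cls) -> str:
        return json.dumps(cls.model_json_schema(), indent=2, sort_keys=True)


def _stage_hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate? -> qc -> threshold -> hits -> classify -> report.

    Each stage writes its artifact into ``out_dir`` and logs counts.  A
    stage is skipped (its artifact reloaded) when the stage hash recorded in
    provenance.json matches the current configuration.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov_path = out / "provenance.json"
    prev = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    prov: dict = {"config": config.model_dump(mode="json"), "stages": {}}
    seed = config.master_seed

    def fresh(stage: str, *artifacts: Path) -> bool:
        h = _stage_hash(stage, config.model_dump(mode="json"))
        prov["stages"][stage] = h
        cached = prev.get("stages", {}).get(stage) == h and all(a.exists() for a in artifacts)
        return not cached

    # --- inputs -----------------------------------------------------------
    cfg_synth = config.synth.model_copy(update={"master_seed": seed})
    if config.simulate:
        layout_path = out / "layout.tsv"
        cells_path = out / "cells.csv"
        if fresh("simulate", cells_path, layout_path, out / "controls.csv",
                 out / "wells.csv", out / "design_features.csv"):
            designs, features = td.generate_catalog(
                config.n_unique, seed, resolution_um=config.resolution_um
            )
            layout = td.build_chip_layout(
                config.n_unique, seed, (config.grid_rows, config.grid_cols),
                config.n_flat_wells,
                unit_ids=[d.unit_id for d in designs if not d.is_flat],
            )
            ds = synth_mod.simulate_screen(cfg_synth, layout, features)
            synth_mod.write_dataset(ds, out)
            write_features(features, out / "design_features.csv")
            cells, controls, features_df = ds.cells, ds.controls, features
            wells = ds.wells
        else:
            log.info("simulate: cached, reloading artifacts")
            layout = read_layout(layout_path)
            cells = read_cells(cells_path)
            controls = read_controls(out / "controls.csv")
            features_df = read_features(out / "design_features.csv")
            wells = pd.read_csv(out / "wells.csv")
        log.info("simulate: %d cells on %d chips", len(cells), cells["chip_id"].nunique())
    else:
        if not (config.cells_path and config.controls_path and config.layout_path):
            raise SchemaError("without --simulate, cells/controls/layout paths are required")
        fresh("load")
        cells = read_cells(config.cells_path)
        controls = read_controls(config.controls_path)
        layout = read_layout(config.layout_path)
        features_df = read_features(config.features_path) if config.features_path else None
        wells = None
        log.info("load: %d cells", len(cells))

    # --- qc ---------------------------------------------------------------
    qc_report, cells_qc = sp.qc_filter(cells, multiplier=config.qc_multiplier)
    qc_out = qc_report.bounds.reset_index().rename(columns={"index": "unit_id"})
    qc_out.to_csv(out / "qc_report.csv", index=False)
    log.info("qc: %d cells in, %d excluded", qc_report.n_in, qc_report.n_excluded)

    # --- threshold --------------------------------------------------------
    if config.threshold_method == "control_intersection":
        cal = sp.calibrate_threshold(
            controls.loc[controls["condition"] == "neg", "icam1_median_intensity"].to_numpy(),
            controls.loc[controls["condition"] == "pos", "icam1_median_intensity"].to_numpy(),
        )
        percentile = cal.percentile
    else:
        percentile = config.fixed_percentile
    flagged, model = sp.apply_threshold(cells_qc, percentile, config.threshold_method)
    (out / "thresholds.json").write_text(
        json.dumps(
            {
                "calibration_percentile": model.calibration_percentile,
                "method": config.threshold_method,
                "per_chip_threshold": {str(k): v for k, v in model.per_chip_threshold.items()},
            },
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    log.info("threshold: percentile %.2f, %d/%d cells positive",
             percentile, int(flagged["icam1_positive"].sum()), len(flagged))

    # --- hits -------------------------------------------------------------
    if config.reference == "control":
        ref_counts = sp.control_reference_counts(
            controls.loc[controls["condition"] == "neg", "icam1_median_intensity"].to_numpy(),
            percentile,
        )
    else:
        ref_counts = None
    hits = sp.call_hits(flagged, layout, alpha=config.alpha, adjusted=config.adjusted,
                        reference_counts=ref_counts)
    write_hit_table(hits, out / "hit_table.csv")
    counts = hits["class"].value_counts().to_dict()
    log.info("hits: %d surfaces -> High %d / Low %d / NS %d", len(hits),
             counts.get("High", 0), counts.get("Low", 0), counts.get("NS", 0))

    # --- summary ----------------------------------------------------------
    summary = sp.summarize_screen(flagged, hits, layout, wells)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    # --- classify ---------------------------------------------------------
    report = None
    if config.ml_feature_set != "none":
        if config.ml_feature_set == "design":
            if features_df is None:
                raise SchemaError("design-feature classification needs a feature table")
            feats = features_df
            cols = [c for c in ml.DESIGN_FEATURE_COLUMNS if c in feats.columns]
        else:
            feats = flagged.groupby("unit_id")[ml.SHAPE_FEATURE_COLUMNS].median().reset_index()
            cols = ml.SHAPE_FEATURE_COLUMNS
        fm = ml.build_feature_matrix(hits, feats, cols)
        report = ml.repeat_split_classify(
            fm,
            n_repeats=config.ml_repeats,
            train_fraction=1.0 - config.ml_holdout,
            cv_folds=config.ml_cv_folds,
            master_seed=seed,
        )
        ml.report_model(report, out)
        log.info("classify: %s features, mean accuracy %.3f over %d repeats",
                 config.ml_feature_set, report.mean_accuracy, config.ml_repeats)

    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    return {
        "cells": cells, "cells_qc": flagged, "qc_report": qc_report,
        "threshold_model": model, "hit_table": hits, "summary": summary,
        "model_report": report, "out_dir": out,
    }
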