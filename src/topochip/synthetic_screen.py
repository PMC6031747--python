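"""Seeded synthetic screening data with the structure the analysis assumes.

The generator emulates an 8-chip TopoChip screen: per-well cell counts are
Poisson around the count implied by the seeding density (10,000 cells/cm^2 x
a 300 um well ~ 9 cells); each cell is marker-positive with a per-surface
probability (a baseline weight plus a planted effect on hit surfaces); the
per-cell median marker intensity is a two-component lognormal mixture whose
components are scaled by a per-chip multiplicative batch factor; cell-shape
features come from class-conditional Gaussians on transformed scales with
the orderings seen in screens of this kind (cells on flat wells spread and
round, marker-negative cells on topographies thinnest and most eccentric).

Off-chip controls (flat polystyrene with/without cytokine stimulation) are
drawn from the same mixture components with their own positive weights; the
negative control calibrates the screening threshold downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from topochip._seeds import stage_rng
from topochip.errors import ConfigurationError
from topochip.topo_design import ChipLayout

WELL_AREA_CM2_PER_UM_SIDE = 1e-8  # (1 um)^2 in cm^2

CELL_COLUMNS = [
    "chip_id", "row", "col", "unit_id", "cell_id",
    "area_um2", "perimeter_um", "form_factor", "solidity", "eccentricity",
    "median_radius_um", "icam1_median_intensity", "actin_intensity",
]


class ShapeProfile(BaseModel):
    """Latent-scale Gaussian for one cell population.

    Latent order: log area (um^2), log perimeter (um), logit solidity,
    logit form factor, eccentricity, log median radius (um).
    """

    mean: tuple[float, float, float, float, float, float]
    sd: tuple[float, float, float, float, float, float]


def _default_profiles() -> dict[str, ShapeProfile]:
    return {
        # spread, round cells on unpatterned wells: largest form factor
        "flat": ShapeProfile(mean=(7.8, 5.45, 2.4, 0.2, 0.60, 2.48),
                             sd=(0.35, 0.20, 0.4, 0.35, 0.10, 0.30)),
        # marker-positive cells on topographies: elongated
        "topo_pos": ShapeProfile(mean=(7.3, 5.35, 1.8, -0.85, 0.85, 1.80),
                                 sd=(0.35, 0.20, 0.4, 0.35, 0.06, 0.30)),
        # marker-negative cells on topographies: thinner, most eccentric
        "topo_neg": ShapeProfile(mean=(7.1, 5.40, 1.4, -1.40, 0.93, 1.40),
                                 sd=(0.35, 0.20, 0.4, 0.35, 0.04, 0.30)),
    }


#: latent correlation structure shared by all profiles; capped at |rho| <= 0.7
_LATENT_CORR = np.array(
    [
        # logA  logP   sol    ff     ecc   logR
        [1.00, 0.70, 0.00, 0.00, 0.00, 0.50],
        [0.70, 1.00, 0.00, -0.30, 0.20, 0.20],
        [0.00, 0.00, 1.00, 0.40, 0.00, 0.00],
        [0.00, -0.30, 0.40, 1.00, -0.40, 0.30],
        [0.00, 0.20, 0.00, -0.40, 1.00, -0.30],
        [0.50, 0.20, 0.00, 0.30, -0.30, 1.00],
    ]
)


class SynthConfig(BaseModel):
    """All knobs of the synthetic screen, JSON-serializable."""

    n_chips: int = 8
    seeding_density_cells_per_cm2: float | None = None  # derived from mean if None
    cells_per_well_mean: float = 9.0
    well_side_um: float = 300.0

    meanlog_neg: float = 4.0
    meanlog_pos: float = 5.18
    sdlog: float = 0.4
    baseline_positive_weight: float = 0.07
    #: the off-chip negative control is modeled as the pure low component:
    #: basal flat-polystyrene cultures sit at the bottom of the intensity
    #: range, and the control-intersection <-> 93rd-percentile calibration
    #: geometry holds only for a pure-component negative control
    neg_control_positive_weight: float = 0.0
    positive_control_weight: float = 0.70
    chip_scale_sd: float = 0.15

    n_planted_high: int = 112
    n_planted_low: int = 72
    planted_high_ids: tuple[str, ...] | None = None
    planted_low_ids: tuple[str, ...] | None = None
    effect_high: float = 0.20
    effect_low: float = -0.05
    weight_floor: float = 0.005

    actin_rho: float = 0.5
    actin_mean: float = 500.0
    actin_sd: float = 100.0
    #: the control culture has chip-scale area (~40k cells at the default
    #: seeding density); 5000 imaged cells per condition is conservative
    n_control_cells: int = 5000

    shape_profiles: dict[str, ShapeProfile] = Field(default_factory=_default_profiles)
    master_seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SynthConfig":
        for name in ("baseline_positive_weight", "positive_control_weight",
                     "neg_control_positive_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.cells_per_well_mean <= 0:
            raise ConfigurationError("cells_per_well_mean must be positive")
        if self.sdlog <= 0 or self.chip_scale_sd < 0:
            raise ConfigurationError("intensity scale parameters must be non-negative")
        if self.planted_high_ids and self.planted_low_ids:
            overlap = set(self.planted_high_ids) & set(self.planted_low_ids)
            if overlap:
                raise ConfigurationError(f"planted sets overlap: {sorted(overlap)[:5]}")
        if self.seeding_density_cells_per_cm2 is not None:
            implied = self.seeding_density_cells_per_cm2 * self.well_area_cm2
            if abs(implied - self.cells_per_well_mean) > 0.01 * self.cells_per_well_mean:
                raise ConfigurationError(
                    f"seeding density implies {implied:.3f} cells/well, which differs "
                    f"from cells_per_well_mean={self.cells_per_well_mean} by more than 1%"
                )
        if not -1.0 <= self.actin_rho <= 1.0:
            raise ConfigurationError("actin_rho must be in [-1, 1]")
        return self

    @property
    def well_area_cm2(self) -> float:
        return (self.well_side_um * 1e-4) ** 2

    @property
    def derived_seeding_density(self) -> float:
        if self.seeding_density_cells_per_cm2 is not None:
            return self.seeding_density_cells_per_cm2
        return self.cells_per_well_mean / self.well_area_cm2


@dataclass
class ScreenDataset:
    """One simulated screen: per-cell table, well index, off-chip controls."""

    layout: ChipLayout
    cells: pd.DataFrame
    wells: pd.DataFrame  # chip_id, row, col, unit_id, n_cells (zero-cell wells included)
    controls: pd.DataFrame  # condition in {neg, pos}, cell_id, icam1_median_intensity
    config: SynthConfig

    def validate(self) -> None:
        valid_ids = set(self.layout.grid.astype(str).ravel())
        if not set(self.cells["unit_id"]).issubset(valid_ids):
            raise ConfigurationError("cells reference unit ids absent from the layout")
        for cond in ("neg", "pos"):
            n = (self.controls["condition"] == cond).sum()
            if n < 500:
                raise ConfigurationError(f"{cond} control has {n} cells; need >= 500")
        counts = self.wells.groupby(["chip_id", "row", "col"]).size()
        if (counts != 1).any():
            raise ConfigurationError("well index has duplicate wells")


def choose_planted_ids(
    features: pd.DataFrame,
    n_high: int,
    n_low: int,
    rng: np.random.Generator,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Sample planted hit surfaces from the design archetype classes."""
    if "archetype" not in features.columns:
        raise ConfigurationError("feature table lacks an 'archetype' column")
    highs = features.loc[features["archetype"] == "high_like", "unit_id"].to_numpy()
    lows = features.loc[features["archetype"] == "low_like", "unit_id"].to_numpy()
    if len(highs) < n_high or len(lows) < n_low:
        raise ConfigurationError(
            f"catalog provides {len(highs)} high_like / {len(lows)} low_like designs; "
            f"need {n_high} / {n_low}"
        )
    high = tuple(sorted(rng.choice(highs, size=n_high, replace=False)))
    low = tuple(sorted(rng.choice(lows, size=n_low, replace=False)))
    return high, low


def _latent_cov(sd: np.ndarray) -> np.ndarray:
    return _LATENT_CORR * np.outer(sd, sd)


def _draw_shapes(profile: ShapeProfile, n: int, rng: np.random.Generator) -> pd.DataFrame:
    mean = np.asarray(profile.mean)
    cov = _latent_cov(np.asarray(profile.sd))
    z = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    return pd.DataFrame(
        {
            "area_um2": np.exp(z[:, 0]),
            "perimeter_um": np.exp(z[:, 1]),
            "solidity": expit(z[:, 2]),
            "form_factor": expit(z[:, 3]),
            "eccentricity": np.clip(z[:, 4], 0.0, 0.995),
            "median_radius_um": np.exp(z[:, 5]),
        }
    )


def positive_weights(config: SynthConfig, unit_ids: np.ndarray) -> np.ndarray:
    """Per-cell (or per-well) true positive-class probability."""
    w = np.full(len(unit_ids), config.baseline_positive_weight)
    if config.planted_high_ids:
        w[np.isin(unit_ids, config.planted_high_ids)] += config.effect_high
    if config.planted_low_ids:
        w[np.isin(unit_ids, config.planted_low_ids)] += config.effect_low
    return np.clip(w, config.weight_floor, 1.0)


def simulate_screen(
    config: SynthConfig,
    layout: ChipLayout,
    features: pd.DataFrame | None = None,
) -> ScreenDataset:
    """Simulate the full multi-chip screen.

    If planted ids are not given in the config but ``features`` (with an
    ``archetype`` column) is, the planted sets are drawn from the high_like /
    low_like archetypes.  With no features and no explicit ids, no effects
    are planted (a null screen).
    """
    cfg = config
    if cfg.planted_high_ids is None and cfg.planted_low_ids is None and features is not None:
        rng_plant = stage_rng(cfg.master_seed, "plant")
        high, low = choose_planted_ids(features, cfg.n_planted_high, cfg.n_planted_low, rng_plant)
        cfg = cfg.model_copy(update={"planted_high_ids": high, "planted_low_ids": low})
    valid = set(layout.grid.astype(str).ravel())
    for ids, name in ((cfg.planted_high_ids, "planted_high_ids"),
                      (cfg.planted_low_ids, "planted_low_ids")):
        if ids and not set(ids).issubset(valid):
            missing = sorted(set(ids) - valid)[:5]
            raise ConfigurationError(f"{name} not present in layout: {missing}")

    wells = layout.wells()
    n_wells = len(wells)
    rng_counts = stage_rng(cfg.master_seed, "counts")
    rng_class = stage_rng(cfg.master_seed, "class")
    rng_intens = stage_rng(cfg.master_seed, "intensity")
    rng_shape = stage_rng(cfg.master_seed, "shape")
    rng_actin = stage_rng(cfg.master_seed, "actin")

    chip_factors = np.exp(rng_intens.normal(0.0, cfg.chip_scale_sd, size=cfg.n_chips))

    well_frames = []
    cell_frames = []
    for chip in range(cfg.n_chips):
        counts = rng_counts.poisson(cfg.cells_per_well_mean, size=n_wells)
        wf = wells.copy()
        wf.insert(0, "chip_id", chip)
        wf["n_cells"] = counts
        well_frames.append(wf)

        idx = np.repeat(np.arange(n_wells), counts)
        n_cells = len(idx)
        unit_ids = wells["unit_id"].to_numpy()[idx]
        w = positive_weights(cfg, unit_ids)
        is_pos = rng_class.random(n_cells) < w
        meanlog = np.where(is_pos, cfg.meanlog_pos, cfg.meanlog_neg)
        intensity = np.exp(rng_intens.normal(meanlog, cfg.sdlog)) * chip_factors[chip]

        cf = pd.DataFrame(
            {
                "chip_id": chip,
                "row": wells["row"].to_numpy()[idx],
                "col": wells["col"].to_numpy()[idx],
                "unit_id": unit_ids,
                "icam1_median_intensity": intensity,
                "true_class": np.where(is_pos, "pos", "neg"),
            }
        )
        is_flat = unit_ids == layout.flat_id
        profile = np.where(is_flat, "flat", np.where(is_pos, "topo_pos", "topo_neg"))
        shapes = pd.DataFrame(index=np.arange(n_cells),
                              columns=["area_um2", "perimeter_um", "solidity",
                                       "form_factor", "eccentricity", "median_radius_um"],
                              dtype=float)
        for name in ("flat", "topo_pos", "topo_neg"):
            sel = profile == name
            if sel.any():
                shapes.loc[sel, :] = _draw_shapes(
                    cfg.shape_profiles[name], int(sel.sum()), rng_shape
                ).to_numpy()
        cf = pd.concat([cf, shapes], axis=1)
        cell_frames.append(cf)

    cells = pd.concat(cell_frames, ignore_index=True)
    # actin correlated with marker intensity on the measured scale: an affine
    # blend of the standardized intensity and independent noise gives a sample
    # Pearson correlation of actin_rho regardless of the mixture shape
    x = cells["icam1_median_intensity"].to_numpy()
    zx = (x - x.mean()) / x.std()
    eps = rng_actin.normal(size=len(x))
    latent = cfg.actin_rho * zx + np.sqrt(1.0 - cfg.actin_rho**2) * eps
    cells["actin_intensity"] = np.clip(cfg.actin_mean + cfg.actin_sd * latent, 1e-6, None)
    cells["cell_id"] = [f"c{i:07d}" for i in range(len(cells))]
    cells = cells[CELL_COLUMNS + ["true_class"]]

    controls = simulate_controls(cfg, cfg.n_control_cells)
    ds = ScreenDataset(
        layout=layout,
        cells=cells,
        wells=pd.concat(well_frames, ignore_index=True),
        controls=controls,
        config=cfg,
    )
    ds.validate()
    return ds


def simulate_controls(
    config: SynthConfig,
    n_cells: int,
    neg_positive_weight: float | None = None,
    pos_positive_weight: float | None = None,
) -> pd.DataFrame:
    """Off-chip flat-polystyrene controls, with and without stimulation.

    The negative condition defaults to the pure low component (basal
    cultures); the positive (cytokine-stimulated) condition to a high
    positive weight.  No chip batch factor applies: controls are a separate
    culture.
    """
    if n_cells < 100:
        raise ConfigurationError(
            f"need >= 100 control cells per condition for stable calibration, got {n_cells}"
        )
    w_neg = (config.neg_control_positive_weight if neg_positive_weight is None
             else neg_positive_weight)
    w_pos = config.positive_control_weight if pos_positive_weight is None else pos_positive_weight
    rng = stage_rng(config.master_seed, "controls")
    frames = []
    for cond, w in (("neg", w_neg), ("pos", w_pos)):
        is_pos = rng.random(n_cells) < w
        meanlog = np.where(is_pos, config.meanlog_pos, config.meanlog_neg)
        intensity = np.exp(rng.normal(meanlog, config.sdlog))
        frames.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "cell_id": [f"{cond}{i:06d}" for i in range(n_cells)],
                    "icam1_median_intensity": intensity,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_dataset(ds: ScreenDataset, path: str | Path) -> dict[str, Path]:
    """Write cells.csv, wells.csv, controls.csv, layout.tsv and provenance.json."""
    from topochip import io as tio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {
        "cells": path / "cells.csv",
        "wells": path / "wells.csv",
        "controls": path / "controls.csv",
        "layout": path / "layout.tsv",
        "provenance": path / "provenance.json",
    }
    tio.write_cells(ds.cells, out["cells"])
    ds.wells.to_csv(out["wells"], index=False)
    ds.controls.to_csv(out["controls"], index=False)
    tio.write_layout(ds.layout, out["layout"])
    out["provenance"].write_text(
        json.dumps({"synth_config": ds.config.model_dump(mode="json")},
                   indent=2, sort_keys=True)
        + "\n"
    )
    return out
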