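"""Screening statistics: QC, adaptive thresholding, chi-square hit calling.

The stages mirror a high-content marker screen:

1. QC: per unique surface (pooled over all replicas on all chips), cells
   whose area or perimeter lies strictly outside median +/- 1.5 x IQR are
   excluded as likely mis-segmentations.
2. Calibration: the positivity percentile is the rank, within the negative
   control, of the intersection of the positive- and negative-control
   per-cell median-intensity distributions (kernel density estimates on the
   log scale).  With the default mixture this lands at the 93rd percentile.
3. Adaptive threshold: per chip, the cutoff is that percentile of the
   chip's own post-QC intensity distribution, absorbing chip-level batch
   scaling; a cell is positive when its intensity exceeds the cutoff.
4. Hit calling: per unique surface, pooled positive/negative counts are
   tested against the pooled on-chip flat-well counts with a 2x2 chi-square
   (no continuity correction; Fisher's exact test when an expected count
   drops below 5).  Surfaces are classed High/Low/NS at raw p < alpha, with
   Benjamini-Hochberg adjusted p-values reported alongside, and ranked by
   positive fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from topochip.errors import CalibrationError, ConfigurationError, SchemaError
from topochip.topo_design import ChipLayout

HIT_TABLE_COLUMNS = [
    "unit_id", "n_cells", "n_pos", "pos_fraction",
    "chi2_stat", "p_value", "p_adj", "class", "rank",
]


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    n_in: int
    n_excluded: int
    bounds: pd.DataFrame  # per surface: area_lo/hi, perim_lo/hi, n_cells, filtered flag
    pass_flags: pd.Series  # index-aligned with the input cells
    multiplier: float = 1.5
    unfiltered_surfaces: list[str] = field(default_factory=list)


def qc_filter(
    cells: pd.DataFrame,
    multiplier: float = 1.5,
    min_cells: int = 4,
    area_col: str = "area_um2",
    perim_col: str = "perimeter_um",
) -> tuple[QCReport, pd.DataFrame]:
    """Exclude likely mis-segmented cells, per unique surface across replicas.

    A cell fails QC iff its area or perimeter lies strictly outside
    [median - m*IQR, median + m*IQR], both statistics computed over all cells
    of all replicas of that surface.  Boundary values are retained.  Surfaces
    with fewer than ``min_cells`` cells pass unfiltered (quartiles unstable)
    and are flagged.
    """
    for col in (area_col, perim_col, "unit_id"):
        if col not in cells.columns:
            raise SchemaError(f"cells table lacks required column {col!r}")
    for col in (area_col, perim_col):
        bad = cells.index[cells[col].isna()]
        if len(bad):
            raise SchemaError(f"cell {bad[0]} has missing {col!r}")

    def _bounds(g: pd.DataFrame) -> pd.Series:
        out = {}
        for col, tag in ((area_col, "area"), (perim_col, "perim")):
            med = g[col].median()
            iqr = g[col].quantile(0.75) - g[col].quantile(0.25)
            out[f"{tag}_lo"] = med - multiplier * iqr
            out[f"{tag}_hi"] = med + multiplier * iqr
        out["n_cells"] = len(g)
        return pd.Series(out)

    bounds = cells.groupby("unit_id", sort=True).apply(_bounds, include_groups=False)
    bounds["filtered"] = bounds["n_cells"] >= min_cells
    b = bounds.loc[cells["unit_id"]].set_axis(cells.index)
    ok = (
        (cells[area_col] >= b["area_lo"]) & (cells[area_col] <= b["area_hi"])
        & (cells[perim_col] >= b["perim_lo"]) & (cells[perim_col] <= b["perim_hi"])
    )
    ok |= ~b["filtered"]
    report = QCReport(
        n_in=len(cells),
        n_excluded=int((~ok).sum()),
        bounds=bounds,
        pass_flags=ok,
        multiplier=multiplier,
        unfiltered_surfaces=sorted(bounds.index[~bounds["filtered"]]),
    )
    return report, cells.loc[ok].copy()


# ---------------------------------------------------------------------------
# threshold calibration and application


@dataclass
class ThresholdModel:
    calibration_percentile: float
    per_chip_threshold: dict[int, float] = field(default_factory=dict)
    method: str = "fixed_percentile"  # or "control_intersection"

    def __post_init__(self) -> None:
        if not 0.0 < self.calibration_percentile < 100.0:
            raise ConfigurationError(
                f"percentile must lie in (0, 100), got {self.calibration_percentile}"
            )


@dataclass
class CalibrationResult:
    percentile: float
    crossing_intensity: float


def calibrate_threshold(
    neg_intensities: np.ndarray,
    pos_intensities: np.ndarray,
    grid_points: int = 1024,
) -> CalibrationResult:
    """Find the control-distribution intersection and its negative-control rank.

    Gaussian KDEs are fit to the log intensities of each control; the lowest
    crossing of the two densities inside the overlap region is located, and
    its percentile rank within the negative sample returned.
    """
    neg = np.asarray(neg_intensities, dtype=float)
    pos = np.asarray(pos_intensities, dtype=float)
    if len(neg) < 100 or len(pos) < 100:
        raise CalibrationError("need >= 100 cells per control condition")
    if np.any(neg <= 0) or np.any(pos <= 0):
        raise CalibrationError("intensities must be positive")
    ln, lp = np.log(neg), np.log(pos)
    lo, hi = max(ln.min(), lp.min()), min(ln.max(), lp.max())
    if lo >= hi:
        raise CalibrationError("no intersection in overlap: control supports are disjoint")
    kde_neg, kde_pos = stats.gaussian_kde(ln), stats.gaussian_kde(lp)
    grid = np.linspace(lo, hi, grid_points)
    dn, dp = kde_neg(grid), kde_pos(grid)
    diff = dn - dp
    signs = np.sign(diff)
    crossings = np.nonzero(np.diff(signs) != 0)[0]
    crossings = crossings[np.abs(diff[crossings]) + np.abs(diff[crossings + 1]) > 1e-12]
    # the decision boundary lies between the two density modes; sign flips
    # from kernel noise in the sparse tails outside that interval are not
    # population intersections
    i_neg_mode, i_pos_mode = int(np.argmax(dn)), int(np.argmax(dp))
    if i_neg_mode < i_pos_mode:
        crossings = crossings[(crossings >= i_neg_mode) & (crossings + 1 <= i_pos_mode)]
    if len(crossings) == 0:
        if np.max(np.abs(diff)) < 1e-3 * max(np.max(kde_neg(grid)), 1e-300):
            raise CalibrationError("no unique intersection: control samples are identical")
        raise CalibrationError("no intersection in overlap")
    i = crossings[0]  # lowest-intensity crossing
    # linear interpolation of the zero of the density difference
    x0, x1, d0, d1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
    log_cross = x0 if d0 == d1 else x0 - d0 * (x1 - x0) / (d1 - d0)
    crossing = float(np.exp(log_cross))
    percentile = 100.0 * float(np.mean(neg <= crossing))
    if percentile > 99.0:
        warnings.warn(
            f"control intersection at percentile {percentile:.2f} of the negative "
            "control; positivity calls will be extremely conservative",
            stacklevel=2,
        )
    return CalibrationResult(percentile=percentile, crossing_intensity=crossing)


def apply_threshold(
    cells: pd.DataFrame,
    percentile: float = 93.0,
    method: str = "fixed_percentile",
    intensity_col: str = "icam1_median_intensity",
    min_chip_cells: int = 50,
) -> tuple[pd.DataFrame, ThresholdModel]:
    """Flag positive cells per chip at the calibrated percentile.

    Each chip's cutoff is the ``percentile``-th linear-interpolation
    percentile of that chip's own intensity distribution; a cell is positive
    when strictly above the cutoff.  By construction each chip flags about
    (100 - percentile)% of its cells, absorbing chip-level batch scaling.
    """
    model = ThresholdModel(calibration_percentile=percentile, method=method)
    if intensity_col not in cells.columns or "chip_id" not in cells.columns:
        raise SchemaError(f"cells table needs columns 'chip_id' and {intensity_col!r}")
    out = cells.copy()
    out["icam1_positive"] = False
    for chip, g in out.groupby("chip_id"):
        if len(g) < min_chip_cells:
            raise ConfigurationError(
                f"chip {chip} has {len(g)} cells; percentile threshold unstable below "
                f"{min_chip_cells}"
            )
        cutoff = float(np.percentile(g[intensity_col], percentile))  # type-7 quantile
        model.per_chip_threshold[int(chip)] = cutoff
        out.loc[g.index, "icam1_positive"] = g[intensity_col] > cutoff
    return out, model


# ---------------------------------------------------------------------------
# hit calling


def chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Pearson chi-square (no continuity correction) for 2x2 tables [[a,b],[c,d]].

    Vectorized; returns (statistic, p, min expected count).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        expected_min = np.minimum.reduce([r1 * c1, r1 * c2, r2 * c1, r2 * c2]) / n
    stat = np.where(np.isfinite(stat), stat, 0.0)
    p = stats.chi2.sf(stat, df=1)
    return stat, p, expected_min


def control_reference_counts(
    neg_control_intensities: np.ndarray, percentile: float
) -> tuple[int, int]:
    """Positive/total counts of the off-chip negative control at the
    calibrated percentile of its own intensity distribution."""
    neg = np.asarray(neg_control_intensities, dtype=float)
    cutoff = float(np.percentile(neg, percentile))
    return int((neg > cutoff).sum()), len(neg)


def call_hits(
    cells: pd.DataFrame,
    layout: ChipLayout,
    alpha: float = 0.05,
    adjusted: bool = False,
    min_reference_cells: int = 30,
    per_replica: bool = False,
    reference_counts: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Classify every unique surface High / Low / NS against flat polystyrene.

    Counts are pooled over all replicas of a surface (set ``per_replica`` to
    average per-replica positive fractions for ranking instead; the test
    itself always uses pooled counts).  The reference is ``reference_counts``
    = (positive, total) from the large off-chip flat-polystyrene control when
    given (see :func:`control_reference_counts`); otherwise the pooled
    on-chip flat wells.  A small shared reference makes every test move
    together with its sampling noise, so the off-chip control is preferred.
    ``adjusted`` gates the class calls on BH-adjusted instead of raw
    p-values.
    """
    if "icam1_positive" not in cells.columns:
        raise SchemaError("cells lack the 'icam1_positive' flag; run apply_threshold first")
    flat_id = layout.flat_id
    if reference_counts is not None:
        ref_pos, ref_n = int(reference_counts[0]), int(reference_counts[1])
    else:
        ref = cells[cells["unit_id"] == flat_id]
        ref_pos = int(ref["icam1_positive"].sum())
        ref_n = len(ref)
    if ref_n < min_reference_cells:
        raise ConfigurationError(
            f"reference pools only {ref_n} cells; need >= {min_reference_cells}"
        )
    ref_frac = ref_pos / ref_n

    unit_ids = layout.unit_ids()
    grp = cells[cells["unit_id"] != flat_id].groupby("unit_id")["icam1_positive"]
    n_cells = grp.size().reindex(unit_ids, fill_value=0)
    n_pos = grp.sum().reindex(unit_ids, fill_value=0).astype(int)

    a = n_pos.to_numpy()
    b = (n_cells - n_pos).to_numpy()
    stat, p, e_min = chi2_2x2(a, b, ref_pos, ref_n - ref_pos)
    method = np.where(e_min < 5, "fisher", "chi2")
    # Fisher fallback for sparse tables
    for i in np.nonzero(e_min < 5)[0]:
        _, p[i] = stats.fisher_exact([[a[i], b[i]], [ref_pos, ref_n - ref_pos]])
        stat[i] = np.nan

    zero = n_cells.to_numpy() == 0
    p[zero] = 1.0
    stat[zero] = np.nan
    method[zero] = "none"

    with np.errstate(invalid="ignore", divide="ignore"):
        pos_fraction = np.where(zero, np.nan, a / np.maximum(n_cells.to_numpy(), 1))
    if per_replica:
        rep = cells[cells["unit_id"] != flat_id].groupby(["unit_id", "chip_id", "row", "col"])[
            "icam1_positive"
        ].mean()
        pf = rep.groupby("unit_id").mean().reindex(unit_ids).to_numpy()
        pos_fraction = np.where(zero, np.nan, pf)

    p_adj = np.ones_like(p)
    tested = ~zero
    if tested.any():
        p_adj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    p_gate = p_adj if adjusted else p
    cls = np.full(len(unit_ids), "NS", dtype=object)
    cls[(p_gate < alpha) & (pos_fraction > ref_frac)] = "High"
    cls[(p_gate < alpha) & (pos_fraction < ref_frac)] = "Low"
    cls[zero] = "NS"

    table = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "n_cells": n_cells.to_numpy(),
            "n_pos": a,
            "pos_fraction": pos_fraction,
            "chi2_stat": stat,
            "p_value": p,
            "p_adj": p_adj,
            "class": cls,
            "stat_method": method,
        }
    )
    # rank by positive fraction, ties by unit id, zero-cell surfaces last
    sort_key = table["pos_fraction"].fillna(-np.inf)
    order = np.lexsort((table["unit_id"].to_numpy(), -sort_key.to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[HIT_TABLE_COLUMNS + ["stat_method"]]


# ---------------------------------------------------------------------------
# summaries


def summarize_screen(
    cells: pd.DataFrame,
    hit_table: pd.DataFrame,
    layout: ChipLayout,
    wells: pd.DataFrame | None = None,
) -> dict:
    """Convenience screen-level summary.

    Includes per-chip median cells per well (from the complete well index
    when given, so empty wells count), the rank-sum comparison of topography
    vs flat per-cell intensities, and the actin / marker-intensity Pearson
    correlation when an actin column is present.
    """
    out: dict = {
        "n_cells": int(len(cells)),
        "n_surfaces": int(len(hit_table)),
        "class_counts": hit_table["class"].value_counts().to_dict(),
    }
    if wells is not None:
        out["per_chip_median_cells_per_well"] = {
            int(chip): float(g["n_cells"].median()) for chip, g in wells.groupby("chip_id")
        }
    pooled = hit_table["n_cells"]
    out["median_pooled_cells_per_surface"] = float(pooled.median())

    flat = cells.loc[cells["unit_id"] == layout.flat_id, "icam1_median_intensity"]
    topo = cells.loc[cells["unit_id"] != layout.flat_id, "icam1_median_intensity"]
    if len(flat) and len(topo):
        u = stats.mannwhitneyu(topo, flat, alternative="two-sided")
        out["topo_vs_flat_ranksum"] = {
            "statistic": float(u.statistic),
            "p_value": float(u.pvalue),
            "topo_median": float(topo.median()),
            "flat_median": float(flat.median()),
        }
    if "actin_intensity" in cells.columns:
        r = np.corrcoef(cells["icam1_median_intensity"], cells["actin_intensity"])[0, 1]
        out["actin_icam1_pearson_r"] = float(r)
    return out
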