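"""TopoChip design library: pattern synthesis, chip layout, design descriptors.

A TopoChip presents 2176 unique microtopographies, each in duplicate, plus 4
unpatterned (flat) wells on a 66x66 grid of 300x300 um wells (TopoUnits).
Each topography is a periodic tiling of a small square feature cell populated
with geometric primitives drawn from three shapes: circles, triangles and
rectangles.  Overlapping primitives merge into compound pillars.

Per-design descriptors summarize the pattern the way the screening analysis
uses them: mean pillar (pattern) area, mean background (space) area per
pillar, foreground fraction, pillar count, and wave-number descriptors WN_q
-- the fraction of non-DC spectral power of the binary mask at radial
spatial frequencies below q times the Nyquist frequency, which captures both
the density of structures and their size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from topochip.errors import ConfigurationError, LayoutError

SHAPES = ("circle", "triangle", "rectangle")

#: wave-number descriptor levels, as fractions of the Nyquist frequency
WN_LEVELS = (0.1, 0.25, 0.5)

FLAT_ID = "FLAT"


# ---------------------------------------------------------------------------
# primitives


@dataclass(frozen=True)
class PrimitiveSpec:
    """One geometric primitive inside a feature cell.

    ``size_um`` is the characteristic dimension: diameter for circles, side
    length for (square) rectangles and equilateral triangles.  ``offset_um``
    positions the primitive centroid relative to the feature-cell origin
    (top-left corner); ``rotation_deg`` rotates about the centroid.
    """

    shape: str
    size_um: float
    offset_um: tuple[float, float]
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ConfigurationError(
                f"unknown primitive shape {self.shape!r}; allowed: {SHAPES}"
            )
        if not self.size_um > 0:
            raise ConfigurationError(f"size_um must be positive, got {self.size_um}")

    @property
    def circumradius_um(self) -> float:
        """Radius of the smallest circle containing the primitive (any rotation)."""
        if self.shape == "circle":
            return self.size_um / 2.0
        if self.shape == "rectangle":
            return self.size_um * math.sqrt(2.0) / 2.0
        return self.size_um / math.sqrt(3.0)  # equilateral triangle

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-primitive test in feature-cell coordinates (um)."""
        ox, oy = self.offset_um
        dx, dy = x - ox, y - oy
        if self.rotation_deg:
            t = math.radians(self.rotation_deg)
            c, s = math.cos(t), math.sin(t)
            dx, dy = c * dx + s * dy, -s * dx + c * dy
        if self.shape == "circle":
            return dx * dx + dy * dy <= (self.size_um / 2.0) ** 2
        if self.shape == "rectangle":
            h = self.size_um / 2.0
            return (np.abs(dx) <= h) & (np.abs(dy) <= h)
        # equilateral triangle, one vertex pointing in +y, centroid at origin
        r = self.circumradius_um
        verts = [
            (r * math.cos(a), r * math.sin(a))
            for a in (math.pi / 2, math.pi / 2 + 2 * math.pi / 3, math.pi / 2 + 4 * math.pi / 3)
        ]
        inside = np.ones_like(dx, dtype=bool)
        for (x0, y0), (x1, y1) in zip(verts, verts[1:] + verts[:1]):
            inside &= (x1 - x0) * (dy - y0) - (y1 - y0) * (dx - x0) >= 0
        return inside

    def to_json_dict(self) -> dict:
        return {
            "shape": self.shape,
            "size_um": self.size_um,
            "offset_um": list(self.offset_um),
            "rotation_deg": self.rotation_deg,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PrimitiveSpec":
        return cls(
            shape=d["shape"],
            size_um=float(d["size_um"]),
            offset_um=(float(d["offset_um"][0]), float(d["offset_um"][1])),
            rotation_deg=float(d.get("rotation_deg", 0.0)),
        )


@dataclass(frozen=True)
class DesignParams:
    """Ranges the random pattern generator draws from.

    Primitive count and size are sampled uniformly; the feature-cell width is
    drawn from ``feature_cell_choices_um`` (each must divide the active well
    side so the tiling is exact).  Sizes are clipped so a primitive's bounding
    circle fits inside its feature cell at any rotation.
    """

    shapes: tuple[str, ...] = SHAPES
    n_primitives_range: tuple[int, int] = (1, 16)
    size_range_um: tuple[float, float] = (3.0, 30.0)
    feature_cell_choices_um: tuple[float, ...] = (10.0, 29.0, 58.0)

    def __post_init__(self) -> None:
        if not self.shapes:
            raise ConfigurationError("allowed-shape set must be non-empty")
        for s in self.shapes:
            if s not in SHAPES:
                raise ConfigurationError(f"unknown shape {s!r}")
        lo, hi = self.n_primitives_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("primitive count range must be non-empty and >= 1")
        if not (0 < self.size_range_um[0] <= self.size_range_um[1]):
            raise ConfigurationError("size range must be positive and non-empty")


# ---------------------------------------------------------------------------
# designs


def _check_grid(length_um: float, resolution_um: float, what: str) -> int:
    n = length_um / resolution_um
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(
            f"resolution {resolution_um} um does not divide the {what} ({length_um} um)"
        )
    return int(round(n))


@dataclass
class TopoUnitDesign:
    """One topography: a feature cell of primitives tiled over the active well.

    The binary mask is recomputed on demand from the primitive list (it is a
    pure function of the design), so a large catalog does not have to hold
    thousands of rasters in memory.
    """

    unit_id: str
    is_flat: bool
    feature_cell_um: float
    primitives: list[PrimitiveSpec]
    active_um: float = 290.0
    resolution_um: float = 0.5

    def __post_init__(self) -> None:
        if self.is_flat != (len(self.primitives) == 0):
            raise ConfigurationError("is_flat must hold exactly when there are no primitives")
        _check_grid(self.active_um, self.resolution_um, "active well side")
        _check_grid(self.feature_cell_um, self.resolution_um, "feature cell")
        n_tiles = self.active_um / self.feature_cell_um
        if abs(n_tiles - round(n_tiles)) > 1e-9:
            raise ConfigurationError(
                f"feature cell {self.feature_cell_um} um does not divide the "
                f"active well side {self.active_um} um"
            )
        for p in self.primitives:
            ox, oy = p.offset_um
            r = p.circumradius_um
            if not (r - 1e-9 <= ox <= self.feature_cell_um - r + 1e-9
                    and r - 1e-9 <= oy <= self.feature_cell_um - r + 1e-9):
                raise ConfigurationError(
                    f"primitive at offset {p.offset_um} extends past the "
                    f"{self.feature_cell_um} um feature cell of {self.unit_id}"
                )

    @property
    def n_tiles(self) -> int:
        return int(round(self.active_um / self.feature_cell_um))

    def tile_mask(self) -> np.ndarray:
        """Rasterize one feature cell (boolean, row-major, origin top-left)."""
        n = _check_grid(self.feature_cell_um, self.resolution_um, "feature cell")
        if self.is_flat:
            return np.zeros((n, n), dtype=bool)
        # sample at raster-cell centers
        coords = (np.arange(n) + 0.5) * self.resolution_um
        x, y = np.meshgrid(coords, coords)  # x: column axis, y: row axis
        out = np.zeros((n, n), dtype=bool)
        for p in self.primitives:
            out |= p.contains(x, y)
        return out

    def mask(self) -> np.ndarray:
        """Full active-area raster: the feature cell tiled periodically."""
        return np.tile(self.tile_mask(), (self.n_tiles, self.n_tiles))


def generate_unit(
    primitive_seed: int,
    design_params: DesignParams | None = None,
    feature_cell_um: float | None = None,
    resolution_um: float = 0.5,
    active_um: float = 290.0,
    unit_id: str | None = None,
    flat: bool = False,
) -> TopoUnitDesign:
    """Draw one random topography design, deterministically from its seed.

    Primitive count, shape, size, position and rotation are all sampled
    uniformly from ``design_params``; a primitive's position is constrained so
    its bounding circle stays inside the feature cell.
    """
    params = design_params or DesignParams()
    rng = np.random.default_rng(primitive_seed)
    uid = unit_id if unit_id is not None else f"U{primitive_seed:05d}"
    if flat:
        return TopoUnitDesign(uid, True, feature_cell_um or params.feature_cell_choices_um[0],
                              [], active_um, resolution_um)
    w = feature_cell_um if feature_cell_um is not None else float(
        rng.choice(params.feature_cell_choices_um)
    )
    k = int(rng.integers(params.n_primitives_range[0], params.n_primitives_range[1] + 1))
    prims: list[PrimitiveSpec] = []
    for _ in range(k):
        shape = str(rng.choice(params.shapes))
        size_hi = min(params.size_range_um[1], w * _max_size_factor(shape))
        size_lo = min(params.size_range_um[0], size_hi)
        size = float(rng.uniform(size_lo, size_hi))
        p = PrimitiveSpec(shape, size, (0.0, 0.0), float(rng.uniform(0.0, 360.0)))
        r = p.circumradius_um
        if w - 2 * r <= 0:
            offset = (w / 2.0, w / 2.0)
        else:
            offset = (float(rng.uniform(r, w - r)), float(rng.uniform(r, w - r)))
        prims.append(PrimitiveSpec(shape, size, offset, p.rotation_deg))
    return TopoUnitDesign(uid, False, w, prims, active_um, resolution_um)


def _max_size_factor(shape: str) -> float:
    # largest size (as fraction of cell width) whose bounding circle fits
    if shape == "circle":
        return 1.0
    if shape == "rectangle":
        return 1.0 / math.sqrt(2.0)
    return math.sqrt(3.0) / 2.0


# ---------------------------------------------------------------------------
# chip layout


@dataclass
class ChipLayout:
    """The 66x66 well grid: every unique design twice, the flat unit 4 times."""

    grid: np.ndarray  # 2D array of unit_id strings
    n_unique: int
    n_flat_wells: int = 4
    well_pitch_um: float = 300.0
    well_side_um: float = 300.0
    wall_width_um: float = 10.0
    flat_id: str = FLAT_ID

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=object)
        ids, counts = np.unique(self.grid.astype(str), return_counts=True)
        tally = dict(zip(ids, counts))
        n_flat = tally.pop(self.flat_id, 0)
        if n_flat != self.n_flat_wells:
            raise LayoutError(
                f"flat unit appears {n_flat} times, expected {self.n_flat_wells}"
            )
        if len(tally) != self.n_unique:
            raise LayoutError(
                f"grid holds {len(tally)} unique designs, expected {self.n_unique}"
            )
        bad = {k: v for k, v in tally.items() if v != 2}
        if bad:
            raise LayoutError(f"designs without exactly 2 replicas: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_wells(self) -> int:
        return self.grid.size

    def unit_ids(self) -> list[str]:
        """Unique non-flat unit ids in sorted order."""
        ids = sorted(set(self.grid.astype(str).ravel()))
        return [u for u in ids if u != self.flat_id]

    def wells(self) -> pd.DataFrame:
        """Long-format well table: row, col, unit_id (row 0 = chip top)."""
        nr, nc = self.grid.shape
        rows, cols = np.divmod(np.arange(self.grid.size), nc)
        return pd.DataFrame(
            {"row": rows, "col": cols, "unit_id": self.grid.astype(str).ravel()}
        )


def build_chip_layout(
    n_unique: int = 2176,
    seed: int = 0,
    grid_shape: tuple[int, int] = (66, 66),
    n_flat_wells: int = 4,
    unit_ids: list[str] | None = None,
    **layout_kwargs,
) -> ChipLayout:
    """Place ``n_unique`` designs (in duplicate) plus flat wells on the grid.

    Placement is a seeded shuffle.  All chip replicas of one screen share one
    layout: fabrication is deterministic, only the biology is random.
    """
    n_wells = grid_shape[0] * grid_shape[1]
    if 2 * n_unique + n_flat_wells != n_wells:
        raise LayoutError(
            f"2*{n_unique} duplicates + {n_flat_wells} flat wells != "
            f"{grid_shape[0]}x{grid_shape[1]} = {n_wells} wells"
        )
    if unit_ids is None:
        unit_ids = [f"U{i:05d}" for i in range(1, n_unique + 1)]
    if len(unit_ids) != n_unique:
        raise LayoutError(f"got {len(unit_ids)} unit ids for n_unique={n_unique}")
    slots = np.array(list(unit_ids) * 2 + [FLAT_ID] * n_flat_wells, dtype=object)
    rng = np.random.default_rng(seed)
    rng.shuffle(slots)
    return ChipLayout(
        grid=slots.reshape(grid_shape),
        n_unique=n_unique,
        n_flat_wells=n_flat_wells,
        **layout_kwargs,
    )


# ---------------------------------------------------------------------------
# design descriptors


@dataclass
class DesignFeatures:
    """Per-design surface descriptors used by the screening analysis."""

    unit_id: str
    pattern_area_um2: float  # mean area of one connected pillar
    space_area_um2: float    # mean background area per pillar
    foreground_fraction: float
    n_pillars: int
    wn: dict[float, float] = field(default_factory=dict)  # q -> cumulative power fraction

    def to_row(self) -> dict:
        row = {
            "unit_id": self.unit_id,
            "pattern_area_um2": self.pattern_area_um2,
            "space_area_um2": self.space_area_um2,
            "foreground_fraction": self.foreground_fraction,
            "n_pillars": self.n_pillars,
        }
        for q, v in self.wn.items():
            row[f"wn{q:g}"] = v
        return row


def _radial_freq(shape: tuple[int, int], resolution_um: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0], d=resolution_um)
    fx = np.fft.fftfreq(shape[1], d=resolution_um)
    return np.hypot.outer(fy, fx)


def spectral_power_partition(
    mask: np.ndarray, resolution_um: float, edges: tuple[float, ...] = (0.1, 0.25, 0.5)
) -> np.ndarray:
    """Non-DC power fractions in disjoint radial-frequency bins.

    Bin edges are fractions of the Nyquist frequency; a final bin up to
    sqrt(2) x Nyquist (the spectrum corner) completes the partition, so the
    returned fractions sum to exactly 1 for any non-empty, non-full mask.
    """
    m = mask.astype(float)
    power = np.abs(np.fft.fft2(m)) ** 2
    power[0, 0] = 0.0
    total = power.sum()
    if total <= 0:
        return np.zeros(len(edges) + 1)
    rf = _radial_freq(mask.shape, resolution_um)
    nyquist = 1.0 / (2.0 * resolution_um)
    full_edges = (0.0,) + tuple(edges) + (math.sqrt(2.0) * 1.0000001,)
    out = np.empty(len(full_edges) - 1)
    for i in range(len(full_edges) - 1):
        lo, hi = full_edges[i] * nyquist, full_edges[i + 1] * nyquist
        out[i] = power[(rf > lo) & (rf <= hi)].sum() / total
    return out


def features_from_mask(
    mask: np.ndarray, resolution_um: float, unit_id: str = "", is_flat: bool | None = None
) -> DesignFeatures:
    """Compute descriptors directly from a binary raster."""
    area_per_cell = resolution_um**2
    active_area = mask.size * area_per_cell
    fg = int(mask.sum())
    if is_flat is None:
        is_flat = fg == 0
    if is_flat or fg == 0:
        return DesignFeatures(unit_id, 0.0, 0.0, 0.0, 0, {q: 0.0 for q in WN_LEVELS})
    # 4-connected pillars
    _, n_pillars = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    fg_area = fg * area_per_cell
    parts = spectral_power_partition(mask, resolution_um, WN_LEVELS)
    cumulative = np.cumsum(parts)
    wn = {q: float(cumulative[i]) for i, q in enumerate(WN_LEVELS)}
    return DesignFeatures(
        unit_id=unit_id,
        pattern_area_um2=fg_area / n_pillars,
        space_area_um2=(active_area - fg_area) / n_pillars,
        foreground_fraction=fg_area / active_area,
        n_pillars=int(n_pillars),
        wn=wn,
    )


def compute_design_features(design: TopoUnitDesign) -> DesignFeatures:
    """Descriptors of one design, from its rasterized mask."""
    return features_from_mask(design.mask(), design.resolution_um, design.unit_id,
                              design.is_flat)


# ---------------------------------------------------------------------------
# archetypes (used by the synthetic generator to plant plausible effects)

HIGH_AREA_RANGE_UM2 = (100.0, 400.0)
LOW_AREA_MAX_UM2 = 100.0
DENSE_FRACTION_CUTOFF = 0.25


def classify_design_archetype(
    features: DesignFeatures,
    high_area_range: tuple[float, float] = HIGH_AREA_RANGE_UM2,
    low_area_max: float = LOW_AREA_MAX_UM2,
    dense_fraction: float = DENSE_FRACTION_CUTOFF,
) -> str:
    """Label a design ``high_like``, ``low_like`` or ``other``.

    Marker-inducing surfaces tend to carry pillars of 100-400 um^2 with
    moderate spacing; suppressing surfaces tend to carry densely packed
    pillars under 100 um^2.  Density is summarized by foreground fraction.
    """
    if features.n_pillars == 0:
        return "other"
    a = features.pattern_area_um2
    if high_area_range[0] <= a <= high_area_range[1] and features.foreground_fraction <= dense_fraction:
        return "high_like"
    if a < low_area_max and features.foreground_fraction > dense_fraction:
        return "low_like"
    return "other"


# ---------------------------------------------------------------------------
# catalog helpers


def generate_design_list(
    n_unique: int = 2176,
    seed: int = 0,
    design_params: DesignParams | None = None,
    resolution_um: float = 0.5,
    active_um: float = 290.0,
) -> list[TopoUnitDesign]:
    """Draw the design library (flat control appended, id ``FLAT``)."""
    ss = np.random.SeedSequence([int(seed), 0x70D0])
    prim_seeds = np.random.default_rng(ss).integers(0, 2**31 - 1, size=n_unique)
    designs = [
        generate_unit(int(s), design_params, resolution_um=resolution_um,
                      active_um=active_um, unit_id=f"U{i + 1:05d}")
        for i, s in enumerate(prim_seeds)
    ]
    designs.append(
        generate_unit(0, design_params, resolution_um=resolution_um,
                      active_um=active_um, unit_id=FLAT_ID, flat=True)
    )
    return designs


def generate_catalog(
    n_unique: int = 2176,
    seed: int = 0,
    design_params: DesignParams | None = None,
    resolution_um: float = 0.5,
    active_um: float = 290.0,
) -> tuple[list[TopoUnitDesign], pd.DataFrame]:
    """Generate the design library plus a feature/archetype table.

    Returns the designs (flat control included, id ``FLAT``) and a DataFrame
    of descriptors with an ``archetype`` column.
    """
    designs = generate_design_list(n_unique, seed, design_params, resolution_um, active_um)
    rows = []
    for d in designs:
        f = compute_design_features(d)
        row = f.to_row()
        row["archetype"] = classify_design_archetype(f)
        rows.append(row)
    return designs, pd.DataFrame(rows)


def catalog_to_frame(designs: list[TopoUnitDesign]) -> pd.DataFrame:
    """Serializable catalog table (primitives as canonical JSON)."""
    return pd.DataFrame(
        {
            "unit_id": [d.unit_id for d in designs],
            "is_flat": [d.is_flat for d in designs],
            "feature_cell_um": [d.feature_cell_um for d in designs],
            "primitives_json": [
                json.dumps([p.to_json_dict() for p in d.primitives], sort_keys=True)
                for d in designs
            ],
        }
    )


def catalog_from_frame(
    frame: pd.DataFrame, active_um: float = 290.0, resolution_um: float = 0.5
) -> list[TopoUnitDesign]:
    designs = []
    for rec in frame.itertuples(index=False):
        prims = [PrimitiveSpec.from_json_dict(d) for d in json.loads(rec.primitives_json)]
        designs.append(
            TopoUnitDesign(str(rec.unit_id), bool(rec.is_flat), float(rec.feature_cell_um),
                           prims, active_um, resolution_um)
        )
    return designs
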