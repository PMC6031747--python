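"""Design generation, chip layout and surface-descriptor tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topochip.errors import ConfigurationError, LayoutError
from topochip.topo_design import (
    DesignFeatures,
    DesignParams,
    PrimitiveSpec,
    TopoUnitDesign,
    build_chip_layout,
    catalog_from_frame,
    catalog_to_frame,
    classify_design_archetype,
    compute_design_features,
    features_from_mask,
    generate_unit,
    spectral_power_partition,
)


def unit_with(primitives, cell=58.0, res=1.0, active=290.0, uid="t"):
    return TopoUnitDesign(uid, False, cell, primitives, active, res)


class TestPrimitives:
    def test_unknown_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            PrimitiveSpec("hexagon", 10.0, (5.0, 5.0))

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ConfigurationError):
            PrimitiveSpec("circle", 0.0, (5.0, 5.0))

    @pytest.mark.parametrize(
        "shape,expected",
        [("circle", 5.0), ("rectangle", 5.0 * math.sqrt(2)), ("triangle", 10.0 / math.sqrt(3))],
    )
    def test_circumradius(self, shape, expected):
        assert PrimitiveSpec(shape, 10.0, (20.0, 20.0)).circumradius_um == pytest.approx(expected)

    def test_primitive_escaping_cell_rejected(self):
        prim = PrimitiveSpec("circle", 20.0, (5.0, 29.0))  # radius 10 at x=5
        with pytest.raises(ConfigurationError):
            unit_with([prim])


class TestRasterization:
    def test_flat_unit_all_background(self):
        d = generate_unit(0, unit_id="FLAT", flat=True, resolution_um=1.0)
        assert d.is_flat and d.primitives == []
        assert not d.mask().any()

    def test_square_tiling_area_exact(self):
        # a 10x10 um square in a 58 um cell tiles 5x5 over 290 um: 2500 um^2
        d = unit_with([PrimitiveSpec("rectangle", 10.0, (29.0, 29.0))])
        assert d.mask().sum() * d.resolution_um**2 == pytest.approx(2500.0)

    def test_circle_area_within_rasterization_tolerance(self):
        d = unit_with([PrimitiveSpec("circle", 10.0, (29.0, 29.0))], res=0.5)
        per_tile = d.tile_mask().sum() * 0.25
        assert per_tile == pytest.approx(math.pi * 25.0, rel=0.05)

    @pytest.mark.parametrize(
        "shape,size,rotation,analytic",
        [
            ("circle", 10.0, 0.0, math.pi * 25.0),
            ("triangle", 12.0, 20.0, math.sqrt(3) / 4 * 144.0),
            ("rectangle", 10.0, 0.0, 100.0),
        ],
    )
    def test_area_error_shrinks_with_resolution(self, shape, size, rotation, analytic):
        errs = []
        for res in (2.0, 1.0, 0.5, 0.25):
            d = unit_with([PrimitiveSpec(shape, size, (29.0, 29.0), rotation)], res=res)
            errs.append(abs(d.tile_mask().sum() * res**2 - analytic))
        for coarse, fine in zip(errs, errs[1:]):
            assert fine <= coarse + 1e-9

    def test_mask_is_periodic_tiling(self):
        d = unit_with([PrimitiveSpec("triangle", 15.0, (30.0, 25.0), 40.0)])
        m = d.mask()
        period = int(round(d.feature_cell_um / d.resolution_um))
        np.testing.assert_array_equal(m, np.roll(m, period, axis=0))
        np.testing.assert_array_equal(m, np.roll(m, period, axis=1))

    def test_resolution_must_divide_geometry(self):
        with pytest.raises(ConfigurationError):
            unit_with([PrimitiveSpec("circle", 10.0, (29.0, 29.0))], res=0.3)


class TestGenerateUnit:
    def test_deterministic_per_seed(self):
        a = generate_unit(123)
        b = generate_unit(123)
        assert a.primitives == b.primitives and a.feature_cell_um == b.feature_cell_um

    def test_empty_shape_set_rejected(self):
        with pytest.raises(ConfigurationError):
            DesignParams(shapes=())

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_primitives_always_inside_cell(self, seed):
        d = generate_unit(seed)
        for p in d.primitives:
            r = p.circumradius_um
            assert r - 1e-9 <= p.offset_um[0] <= d.feature_cell_um - r + 1e-9
            assert r - 1e-9 <= p.offset_um[1] <= d.feature_cell_um - r + 1e-9


class TestChipLayout:
    def test_default_arithmetic(self):
        lay = build_chip_layout(seed=1)
        assert lay.n_wells == 4356 and lay.shape == (66, 66)
        assert lay.n_unique == 2176 and lay.n_flat_wells == 4
        ids, counts = np.unique(lay.grid.astype(str), return_counts=True)
        tally = dict(zip(ids, counts))
        assert tally.pop("FLAT") == 4
        assert set(tally.values()) == {2}

    def test_same_seed_identical(self):
        np.testing.assert_array_equal(build_chip_layout(seed=3).grid,
                                      build_chip_layout(seed=3).grid)

    def test_arithmetic_mismatch_raises(self):
        with pytest.raises(LayoutError):
            build_chip_layout(n_unique=2175)

    @pytest.mark.parametrize("n_unique,grid", [(48, (10, 10)), (16, (6, 6))])
    def test_small_grids_conserve_multiplicities(self, n_unique, grid):
        lay = build_chip_layout(n_unique, seed=0, grid_shape=grid)
        wells = lay.wells()
        tally = wells["unit_id"].value_counts()
        assert tally["FLAT"] == 4
        assert (tally.drop("FLAT") == 2).all()
        assert tally.sum() == grid[0] * grid[1]


class TestDesignFeatures:
    def test_flat_design_zeroed(self):
        d = generate_unit(0, flat=True, resolution_um=1.0)
        f = compute_design_features(d)
        assert f.pattern_area_um2 == 0 and f.n_pillars == 0 and f.foreground_fraction == 0

    def test_square_grid_counts(self):
        # 5x5 tiling of 100 um^2 squares in 290x290 um
        d = unit_with([PrimitiveSpec("rectangle", 10.0, (29.0, 29.0))])
        f = compute_design_features(d)
        assert f.n_pillars == 25
        assert f.pattern_area_um2 == pytest.approx(100.0)
        assert f.foreground_fraction == pytest.approx(2500.0 / 84100.0)
        assert f.space_area_um2 == pytest.approx((84100.0 - 2500.0) / 25.0)

    def test_wn_low_freq_larger_for_coarser_pattern(self):
        # identical foreground fraction, pillar side 10 vs 20 um
        fine = unit_with([PrimitiveSpec("rectangle", 10.0, (14.5, 14.5))], cell=29.0, res=0.5)
        coarse = unit_with([PrimitiveSpec("rectangle", 20.0, (29.0, 29.0))], cell=58.0, res=0.5)
        ff_fine = compute_design_features(fine)
        ff_coarse = compute_design_features(coarse)
        assert ff_fine.foreground_fraction == pytest.approx(ff_coarse.foreground_fraction)
        assert ff_coarse.wn[0.1] > ff_fine.wn[0.1]

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_wn_partition_sums_to_one(self, seed):
        d = generate_unit(seed, resolution_um=1.0)
        parts = spectral_power_partition(d.mask(), 1.0)
        assert parts.sum() == pytest.approx(1.0, abs=1e-9)

    def test_wn_cumulative_monotone_in_unit_interval(self):
        d = generate_unit(9, resolution_um=1.0)
        f = compute_design_features(d)
        vals = [f.wn[q] for q in sorted(f.wn)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert vals == sorted(vals)

    def test_tiling_origin_shift_leaves_features_unchanged(self):
        d = unit_with([PrimitiveSpec("circle", 12.0, (20.0, 35.0))])
        m = d.mask()
        period = int(round(d.feature_cell_um / d.resolution_um))
        f0 = features_from_mask(m, 1.0)
        f1 = features_from_mask(np.roll(np.roll(m, period, axis=0), period, axis=1), 1.0)
        assert f0.pattern_area_um2 == pytest.approx(f1.pattern_area_um2)
        assert f0.n_pillars == f1.n_pillars
        assert f0.wn[0.1] == pytest.approx(f1.wn[0.1], abs=1e-12)


class TestArchetypes:
    def make(self, area, fraction, n_pillars=10):
        return DesignFeatures("x", area, 100.0, fraction, n_pillars, {0.1: 0.5})

    def test_moderate_pillars_are_high_like(self):
        assert classify_design_archetype(self.make(250.0, 0.15)) == "high_like"

    def test_small_dense_pillars_are_low_like(self):
        assert classify_design_archetype(self.make(60.0, 0.40)) == "low_like"

    def test_flat_is_other(self):
        assert classify_design_archetype(DesignFeatures("f", 0.0, 0.0, 0.0, 0, {})) == "other"


class TestCatalogRoundTrip:
    def test_primitive_lists_survive_serialization(self, small_catalog):
        designs, _ = small_catalog
        frame = catalog_to_frame(designs)
        back = catalog_from_frame(frame, resolution_um=1.0)
        assert [d.unit_id for d in back] == [d.unit_id for d in designs]
        for a, b in zip(designs, back):
            assert a.primitives == b.primitives
            assert a.feature_cell_um == b.feature_cell_um
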