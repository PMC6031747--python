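"""QC, threshold calibration/application, chi-square hit calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from topochip.errors import CalibrationError, ConfigurationError, SchemaError
from topochip.screen_pipeline import (
    apply_threshold,
    calibrate_threshold,
    call_hits,
    chi2_2x2,
    control_reference_counts,
    qc_filter,
    summarize_screen,
)
from topochip.synthetic_screen import SynthConfig, simulate_screen


def cells_frame(areas, perims=None, unit="U1", chip=0):
    n = len(areas)
    return pd.DataFrame(
        {
            "chip_id": chip,
            "unit_id": unit,
            "area_um2": areas,
            "perimeter_um": perims if perims is not None else np.full(n, 50.0),
            "icam1_median_intensity": np.linspace(10, 20, n),
        }
    )


class TestQC:
    def test_identical_cells_never_excluded(self):
        cells = cells_frame([100.0] * 12)
        report, kept = qc_filter(cells)
        assert report.n_excluded == 0 and len(kept) == 12

    def test_single_outlier_excluded(self):
        # 15 cells near 100 plus one at 1000; bounds computed by direct
        # enumeration of the same 16 values
        areas = [99, 100, 101] * 5 + [1000]
        cells = cells_frame(areas)
        med = np.median(areas)
        iqr = np.quantile(areas, 0.75) - np.quantile(areas, 0.25)
        assert 1000 > med + 1.5 * iqr  # the construction is an outlier
        report, kept = qc_filter(cells)
        assert report.n_excluded == 1
        assert 1000 not in kept["area_um2"].values

    def test_boundary_value_retained(self):
        # [99]*5 + [100]*5 + [101]*5 + candidate: median 100, IQR 2, hi bound 103
        base = [99.0] * 5 + [100.0] * 5 + [101.0] * 5
        for candidate, kept_expected in ((103.0, True), (103.1, False)):
            sample = base + [candidate]
            med = np.median(sample)
            iqr = np.quantile(sample, 0.75) - np.quantile(sample, 0.25)
            assert med + 1.5 * iqr == pytest.approx(103.0)
            _, kept = qc_filter(cells_frame(sample))
            assert (candidate in kept["area_um2"].values) is kept_expected

    def test_small_surfaces_pass_unfiltered(self):
        cells = cells_frame([1.0, 1.0, 1e6])  # wild outlier but n < 4
        report, kept = qc_filter(cells)
        assert report.n_excluded == 0
        assert report.unfiltered_surfaces == ["U1"]

    def test_missing_feature_raises(self):
        cells = cells_frame([1.0] * 5).drop(columns=["perimeter_um"])
        with pytest.raises(SchemaError, match="perimeter_um"):
            qc_filter(cells)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_refiltering(self, seed):
        rng = np.random.default_rng(seed)
        cells = pd.concat(
            [
                cells_frame(rng.lognormal(5, 0.6, 40), rng.lognormal(4, 0.4, 40), unit=f"U{k}")
                for k in range(5)
            ],
            ignore_index=True,
        )
        r1, kept1 = qc_filter(cells)
        r2, kept2 = qc_filter(kept1)
        assert r2.n_excluded <= r1.n_excluded
        assert len(kept2) <= len(kept1)


class TestCalibration:
    def test_equal_variance_crossing_at_midpoint(self, rng):
        neg = np.exp(rng.normal(4.0, 0.4, 5000))
        pos = np.exp(rng.normal(6.0, 0.4, 5000))
        cal = calibrate_threshold(neg, pos)
        assert cal.crossing_intensity == pytest.approx(np.exp(5.0), rel=0.10)

    def test_default_mixture_lands_at_93rd_percentile(self, rng):
        neg = np.exp(rng.normal(4.0, 0.4, 5000))
        pos = np.exp(rng.normal(5.18, 0.4, 5000))
        cal = calibrate_threshold(neg, pos)
        assert cal.percentile == pytest.approx(93.0, abs=2.0)

    def test_disjoint_supports_raise(self, rng):
        neg = np.exp(rng.normal(1.0, 0.1, 500))
        pos = np.exp(rng.normal(9.0, 0.1, 500))
        with pytest.raises(CalibrationError, match="disjoint"):
            calibrate_threshold(neg, pos)

    def test_identical_samples_raise(self, rng):
        x = np.exp(rng.normal(4.0, 0.4, 1000))
        with pytest.raises(CalibrationError, match="identical"):
            calibrate_threshold(x, x)

    def test_far_right_positive_warns(self, rng):
        neg = np.exp(rng.normal(4.0, 0.4, 2000))
        pos = np.exp(rng.normal(6.0, 0.4, 2000))
        with pytest.warns(UserWarning, match="conservative"):
            cal = calibrate_threshold(neg, pos)
        assert cal.percentile > 99.0

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(CalibrationError):
            calibrate_threshold(np.ones(50), np.ones(200))


class TestApplyThreshold:
    def test_enumerated_percentile_cutoff(self):
        cells = pd.DataFrame(
            {"chip_id": 0, "icam1_median_intensity": np.arange(1.0, 101.0)}
        )
        flagged, model = apply_threshold(cells, 93.0)
        cutoff = model.per_chip_threshold[0]
        assert 93.0 < cutoff < 94.0  # between the 93rd and 94th order statistics
        assert int(flagged["icam1_positive"].sum()) == 7

    def test_scale_invariance(self, rng):
        base = pd.DataFrame({"chip_id": 0, "icam1_median_intensity": rng.lognormal(4, 0.4, 500)})
        f1, _ = apply_threshold(base, 93.0)
        scaled = base.assign(icam1_median_intensity=base["icam1_median_intensity"] * 37.0)
        f2, _ = apply_threshold(scaled, 93.0)
        np.testing.assert_array_equal(f1["icam1_positive"], f2["icam1_positive"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_per_chip_flagged_fraction_contract(self, seed):
        rng = np.random.default_rng(seed)
        cells = pd.DataFrame(
            {
                "chip_id": np.repeat([0, 1], 2000),
                "icam1_median_intensity": np.concatenate(
                    [rng.lognormal(4.0, 0.4, 2000), rng.lognormal(4.6, 0.4, 2000)]
                ),
            }
        )
        flagged, _ = apply_threshold(cells, 93.0)
        for _, g in flagged.groupby("chip_id"):
            assert g["icam1_positive"].mean() == pytest.approx(0.07, abs=1.0 / len(g) + 1e-9)

    def test_small_chip_rejected(self):
        cells = pd.DataFrame({"chip_id": 0, "icam1_median_intensity": np.arange(10.0)})
        with pytest.raises(ConfigurationError):
            apply_threshold(cells, 93.0)


class TestChiSquare:
    def test_statistic_matches_scipy_on_random_tables(self, rng):
        tables = rng.integers(1, 400, size=(1000, 4))
        stat, p, e_min = chi2_2x2(*tables.T)
        for i in range(1000):
            s, pp, _, expected = stats.chi2_contingency(tables[i].reshape(2, 2),
                                                        correction=False)
            assert abs(stat[i] - s) < 1e-9
            assert abs(p[i] - pp) < 1e-9
            assert abs(e_min[i] - expected.min()) < 1e-9

    def test_identical_rows_give_zero(self):
        stat, p, _ = chi2_2x2(30, 70, 30, 70)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)


def flagged_frame(spec, layout):
    """spec: unit_id -> (n_pos, n_neg); cells placed on chip 0 at well (0, 0)."""
    rows = []
    for unit, (npos, nneg) in spec.items():
        for flag in [True] * npos + [False] * nneg:
            rows.append({"chip_id": 0, "row": 0, "col": 0, "unit_id": unit,
                         "icam1_positive": flag})
    return pd.DataFrame(rows)


class TestCallHits:
    def test_surface_equal_to_reference_is_ns(self, small_layout):
        units = small_layout.unit_ids()
        spec = {u: (5, 45) for u in units}
        spec["FLAT"] = (5, 45)
        table = call_hits(flagged_frame(spec, small_layout), small_layout,
                          reference_counts=(50, 500))
        first = table.set_index("unit_id").loc[units[0]]
        assert first["class"] == "NS"
        assert first["chi2_stat"] == pytest.approx(0.0, abs=1e-12)
        assert first["p_value"] == pytest.approx(1.0)

    def test_worked_example_matches_oracle(self, small_layout):
        units = small_layout.unit_ids()
        spec = {u: (5, 45) for u in units}
        spec[units[0]] = (40, 120)
        table = call_hits(flagged_frame(spec, small_layout), small_layout,
                          reference_counts=(22, 320))
        row = table.set_index("unit_id").loc[units[0]]
        s, p, _, _ = stats.chi2_contingency([[40, 120], [22, 298]], correction=False)
        assert row["chi2_stat"] == pytest.approx(s, abs=1e-9)
        assert row["p_value"] == pytest.approx(p, abs=1e-9)
        assert row["class"] == "High"

    def test_fisher_fallback_exactly_when_expected_below_five(self, small_layout):
        units = small_layout.unit_ids()
        spec = {u: (5, 45) for u in units}
        spec[units[0]] = (1, 3)  # tiny surface -> min expected < 5
        table = call_hits(flagged_frame(spec, small_layout), small_layout,
                          reference_counts=(50, 500)).set_index("unit_id")
        assert table.loc[units[0], "stat_method"] == "fisher"
        assert np.isnan(table.loc[units[0], "chi2_stat"])
        _, p_fisher = stats.fisher_exact([[1, 3], [50, 450]])
        assert table.loc[units[0], "p_value"] == pytest.approx(p_fisher, abs=1e-12)
        big = table.loc[units[1]]
        assert big["stat_method"] == "chi2"

    def test_zero_cell_surface_is_ns_and_ranked_last(self, small_layout):
        units = small_layout.unit_ids()
        spec = {u: (5, 45) for u in units if u != units[0]}
        table = call_hits(flagged_frame(spec, small_layout), small_layout,
                          reference_counts=(50, 500))
        row = table[table["unit_id"] == units[0]].iloc[0]
        assert row["class"] == "NS" and row["p_value"] == 1.0
        assert row["rank"] == len(units)

    def test_ranks_are_permutation_with_unit_id_ties(self, small_layout):
        units = small_layout.unit_ids()
        spec = {u: (5, 45) for u in units}
        table = call_hits(flagged_frame(spec, small_layout), small_layout,
                          reference_counts=(50, 500))
        assert sorted(table["rank"]) == list(range(1, len(units) + 1))
        # all fractions tie -> order is lexicographic by unit_id
        assert list(table["unit_id"]) == sorted(units)

    def test_small_reference_rejected(self, small_layout):
        spec = {u: (5, 45) for u in small_layout.unit_ids()}
        with pytest.raises(ConfigurationError):
            call_hits(flagged_frame(spec, small_layout), small_layout,
                      reference_counts=(1, 10))

    def test_missing_flags_rejected(self, small_layout):
        with pytest.raises(SchemaError):
            call_hits(pd.DataFrame({"unit_id": ["U1"]}), small_layout)


class TestControlReference:
    def test_counts_at_own_percentile(self, rng):
        neg = rng.lognormal(4.0, 0.4, 5000)
        npos, ntot = control_reference_counts(neg, 93.0)
        assert ntot == 5000
        assert npos / ntot == pytest.approx(0.07, abs=1.0 / 5000 + 1e-9)


class TestSummarize:
    def test_summary_recovers_generator_structure(self, small_layout):
        cfg = SynthConfig(n_chips=8, master_seed=13, effect_high=0.0, effect_low=0.0)
        ds = simulate_screen(cfg, small_layout)
        flagged, _ = apply_threshold(ds.cells, 93.0)
        neg = ds.controls.query("condition == 'neg'")["icam1_median_intensity"].to_numpy()
        table = call_hits(flagged, small_layout,
                          reference_counts=control_reference_counts(neg, 93.0))
        summary = summarize_screen(flagged, table, small_layout, ds.wells)
        # ~7200 cells: the configured actin correlation is recovered
        assert summary["actin_icam1_pearson_r"] == pytest.approx(0.5, abs=0.05)
        meds = summary["per_chip_median_cells_per_well"]
        assert all(7 <= m <= 12 for m in meds.values())
        assert summary["n_surfaces"] == 48
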