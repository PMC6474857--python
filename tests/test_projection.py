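"""Projection bookkeeping, MPA thresholding, masking, dispersal, range change."""

import numpy as np
import pytest

import viperarisk as v
from viperarisk.errors import AlignmentError, ConfigurationError, ThresholdingError


def grid(vals, **kw):
    return v.RasterGrid(np.asarray(vals, dtype=float), **kw)


class TestEnumerateProjections:
    def test_full_factorial_study_design(self):
        plan = v.ScenarioPlan(["GLM", "GBM", "SRE", "MAXENT"], 10,
                              ["CCSM4", "CNRM-CM5", "HadGEM2-ES", "MIROC5"],
                              ["RCP4.5", "RCP8.5"], ["2050", "2070"])
        tasks = v.enumerate_projections(plan)
        assert len(tasks) == 640
        assert plan.n_projections == 640
        assert len(set(tasks)) == 640  # all distinct

    def test_single_cell_plan(self):
        plan = v.ScenarioPlan(["GLM"], 1, ["g"], ["r"], ["p"])
        assert len(v.enumerate_projections(plan)) == 1

    def test_multiplicative_in_each_component(self):
        base = dict(algorithms=["a"], replicates=2, gcms=["g"], rcps=["r"],
                    periods=["p"])
        n0 = v.ScenarioPlan(**base).n_projections
        doubled = dict(base, gcms=["g1", "g2"])
        assert v.ScenarioPlan(**doubled).n_projections == 2 * n0

    def test_empty_component_rejected(self):
        with pytest.raises(ConfigurationError):
            v.ScenarioPlan([], 1, ["g"], ["r"], ["p"])


class TestMpaThreshold:
    def test_minimum_over_occurrences(self):
        suit = grid([[0.31, 0.74], [0.90, 0.10]])
        occs = v.OccurrenceSet.from_records([
            ("a", "x", *suit.cell_center(0, 0)),
            ("b", "x", *suit.cell_center(0, 1)),
            ("c", "x", *suit.cell_center(1, 0)),
        ])
        assert v.mpa_threshold(suit, occs) == pytest.approx(0.31)

    def test_single_occurrence(self):
        suit = grid([[0.42, 0.9]])
        occs = v.OccurrenceSet.from_records([("a", "x", *suit.cell_center(0, 0))])
        assert v.mpa_threshold(suit, occs) == pytest.approx(0.42)

    def test_all_occurrence_cells_suitable_after_binarizing(self, small_suitability):
        occs = v.sample_occurrences(small_suitability, 80, seed=5)
        thr = v.mpa_threshold(small_suitability, occs)
        binary = v.binarize(small_suitability, thr)
        for lon, lat in occs.lonlat:
            r, c = small_suitability.cell_of(lon, lat)
            assert binary.values[r, c]

    def test_all_on_nodata_rejected(self):
        suit = grid([[0.5]], nodata_mask=np.array([[True]]))
        occs = v.OccurrenceSet.from_records([("a", "x", *suit.cell_center(0, 0))])
        with pytest.raises(ThresholdingError):
            v.mpa_threshold(suit, occs)


class TestBinarize:
    def test_threshold_zero_keeps_all_valid(self):
        suit = grid([[0.0, 0.4], [0.9, 0.2]])
        assert v.binarize(suit, 0.0).n_suitable == 4

    def test_threshold_above_max_keeps_none(self):
        suit = grid([[0.0, 0.4], [0.9, 0.2]])
        assert v.binarize(suit, 0.95).n_suitable == 0

    def test_exact_threshold_is_suitable(self):
        suit = grid([[0.5, 0.49]])
        binary = v.binarize(suit, 0.5)
        assert binary.values[0, 0] and not binary.values[0, 1]

    def test_nodata_never_suitable(self):
        mask = np.array([[True, False]])
        binary = v.binarize(grid([[0.9, 0.9]], nodata_mask=mask), 0.5)
        assert not binary.values[0, 0] and binary.values[0, 1]


class TestFootprintMask:
    def test_zero_footprint_no_change(self, make_binary):
        b = make_binary([[1, 1], [0, 1]])
        out = v.apply_footprint_mask(b, grid([[0, 0], [0, 0]]))
        np.testing.assert_array_equal(out.values, b.values)

    def test_fully_developed_empties_range(self, make_binary):
        b = make_binary([[1, 1], [1, 1]])
        out = v.apply_footprint_mask(b, grid([[100, 100], [100, 100]]))
        assert out.n_suitable == 0

    def test_cutoff_is_strict_inequality(self, make_binary):
        b = make_binary([[1, 1]])
        out = v.apply_footprint_mask(b, grid([[50, 51]]))
        assert out.values[0, 0] and not out.values[0, 1]

    def test_misaligned_rejected(self, make_binary):
        with pytest.raises(AlignmentError):
            v.apply_footprint_mask(make_binary([[1]]), grid([[0, 0]]))


class TestAverageOverGcms:
    def test_mean_of_two(self):
        a, b = grid([[0.2]]), grid([[0.6]])
        assert v.average_over_gcms([a, b]).values[0, 0] == pytest.approx(0.4)

    def test_identical_maps_unchanged(self):
        a = grid([[0.3, 0.8]])
        np.testing.assert_array_equal(v.average_over_gcms([a, a]).values, a.values)

    def test_bounded_by_cellwise_extremes(self):
        rng = np.random.default_rng(0)
        maps = [grid(rng.uniform(size=(5, 5))) for _ in range(4)]
        avg = v.average_over_gcms(maps).values
        stackv = np.stack([m.values for m in maps])
        assert (avg >= stackv.min(axis=0) - 1e-12).all()
        assert (avg <= stackv.max(axis=0) + 1e-12).all()


class TestDispersal:
    def test_no_dispersal_removes_gains(self, make_binary):
        current = make_binary([[1, 1, 0, 0]])
        future = make_binary([[0, 1, 1, 1]])
        out = v.apply_dispersal(current, future, "none")
        np.testing.assert_array_equal(out.values, [[False, True, False, False]])
        assert (out.values <= current.values).all()

    def test_unlimited_is_identity(self, make_binary):
        current = make_binary([[1, 0]])
        future = make_binary([[0, 1]])
        out = v.apply_dispersal(current, future, "unlimited")
        np.testing.assert_array_equal(out.values, future.values)

    def test_unknown_scenario_rejected(self, make_binary):
        with pytest.raises(ConfigurationError):
            v.apply_dispersal(make_binary([[1]]), make_binary([[1]]), "partial")


class TestRangeChange:
    def test_identical_maps(self, make_binary):
        cur = make_binary(np.ones((3, 3)))
        s = v.range_change(cur, cur)
        assert (s.stable_pct, s.loss_pct, s.gain_pct) == (100.0, 0.0, 0.0)

    def test_eighty_percent_loss(self, make_binary):
        vals = np.zeros((10, 10))
        vals.ravel()[:100] = 1  # 100 current cells
        cur = make_binary(vals.reshape(10, 10))
        fut_vals = np.zeros(100)
        fut_vals[:20] = 1
        fut = make_binary(fut_vals.reshape(10, 10))
        s = v.range_change(cur, fut)
        assert s.loss_pct == 80.0 and s.stable_pct == 20.0 and s.gain_pct == 0.0

    def test_mixed_loss_and_gain(self, make_binary):
        cur = np.zeros(200, dtype=bool)
        cur[:100] = True
        fut = np.zeros(200, dtype=bool)
        fut[50:110] = True  # keeps 50, adds 10
        s = v.range_change(make_binary(cur.reshape(10, 20)),
                           make_binary(fut.reshape(10, 20)))
        assert (s.stable_pct, s.loss_pct, s.gain_pct) == (50.0, 50.0, 10.0)
        assert s.net_change_pct == pytest.approx(-40.0)

    def test_invariants_on_random_maps(self, make_binary):
        rng = np.random.default_rng(2)
        for _ in range(20):
            cur = make_binary(rng.uniform(size=(8, 8)) < 0.4)
            fut = make_binary(rng.uniform(size=(8, 8)) < 0.4)
            if cur.n_suitable == 0:
                continue
            s = v.range_change(cur, fut)
            assert s.stable_pct + s.loss_pct == pytest.approx(100.0)
            assert s.net_change_pct == pytest.approx(s.gain_pct - s.loss_pct)

    def test_empty_current_rejected(self, make_binary):
        with pytest.raises(ConfigurationError):
            v.range_change(make_binary([[0]]), make_binary([[1]]))


class TestMeanAltitude:
    def test_single_cell(self, make_binary):
        assert v.mean_range_altitude(make_binary([[1, 0]]),
                                     grid([[1746.0, 99.0]])) == 1746.0

    def test_two_cells_average(self, make_binary):
        assert v.mean_range_altitude(make_binary([[1, 1]]),
                                     grid([[1000.0, 2000.0]])) == 1500.0

    def test_uphill_shift_increases_mean(self, make_binary):
        dem = grid(np.arange(100.0).reshape(10, 10))
        low = np.zeros((10, 10)); low[:5] = 1
        high = np.zeros((10, 10)); high[5:] = 1
        assert (v.mean_range_altitude(make_binary(high), dem)
                > v.mean_range_altitude(make_binary(low), dem))


class TestSummarizeOverGcms:
    def test_identical_gcms_have_zero_sd(self):
        base = dict(clade="c", rcp="r", period="p", dispersal="none",
                    stable_pct=60.0, loss_pct=40.0, gain_pct=0.0,
                    net_change_pct=-40.0, current_cells=10, future_cells=6,
                    mean_altitude_m=1500.0)
        summaries = [v.RangeChangeSummary(gcm=g, **base) for g in "abcd"]
        out = v.summarize_over_gcms(summaries)
        assert len(out) == 1
        assert out["loss_pct_mean"].iloc[0] == pytest.approx(40.0)
        assert out["loss_pct_std"].iloc[0] == 0.0
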