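"""Interval detection, rates, persistence classes, filters, pixel areas."""

import numpy as np
import pytest

from foresttraj import analyze_cell, generate_mosaic, random_cell_specs
from foresttraj.trajectory import (
    CellRecord,
    ChangeInterval,
    ForestSeries,
    amount_of_change,
    apply_filters,
    change_interval,
    classify_trajectory,
    initial_state,
    pixel_area,
    rate_of_change,
    scale_min_change,
)


def fs(counts, cell_size=324):
    return ForestSeries(np.array(counts), cell_size=cell_size)


class TestChangeInterval:
    def test_constant_series_has_no_interval(self):
        assert change_interval(fs([100] * 5)) is None

    def test_even_decline_spans_whole_series(self):
        series = fs(list(range(100, 70, -1)))  # 30 values, -1/year
        iv = change_interval(series)
        assert (iv.start, iv.end, iv.duration) == (0, 29, 29)

    def test_single_step_drop(self):
        iv = change_interval(fs([100, 100, 70, 70]))
        assert (iv.start, iv.end, iv.duration) == (1, 2, 1)

    def test_counts_constant_outside_interval(self):
        c = [50, 50, 48, 45, 45, 40, 40, 40]
        iv = change_interval(fs(c))
        assert all(v == c[0] for v in c[: iv.start + 1])
        assert all(v == c[-1] for v in c[iv.end:])


class TestRate:
    def test_thirty_year_decline_rate(self):
        assert rate_of_change(ChangeInterval(0, 30)) == pytest.approx(1 / 30)

    def test_single_year_drop_rate_is_one(self):
        assert rate_of_change(ChangeInterval(3, 4)) == 1.0

    def test_longest_interval_of_29_annual_maps(self):
        assert rate_of_change(ChangeInterval(0, 28)) == pytest.approx(1 / 28)


class TestClassification:
    def test_strict_decline_is_persistent_loss(self):
        s = fs([100, 90, 80, 70])
        assert classify_trajectory(s, change_interval(s)) == "persistent_loss"

    def test_decrease_then_increase_is_non_persistent(self):
        s = fs([100, 80, 90, 90])
        assert classify_trajectory(s, change_interval(s)) == "non_persistent"

    def test_plateau_inside_interval_keeps_persistence(self):
        s = fs([100, 90, 90, 90, 80, 80])
        assert classify_trajectory(s, change_interval(s)) == "persistent_loss"

    def test_increase_is_persistent_gain(self):
        s = fs([10, 20, 20, 30])
        assert classify_trajectory(s, change_interval(s)) == "persistent_gain"

    def test_constant_is_no_change(self):
        s = fs([5, 5, 5])
        assert classify_trajectory(s, None) == "no_change"


class TestAmount:
    def test_thirty_pixels_on_default_cell(self):
        s = fs([100, 100, 70, 70])
        assert amount_of_change(s, change_interval(s)) == pytest.approx(30 / 324)

    def test_full_grid_swing(self):
        s = fs([0, 324])
        assert amount_of_change(s, change_interval(s)) == 1.0


class TestFilters:
    def _rec(self, **kw):
        base = dict(cell_id="c", involves_forest=True,
                    trajectory_class="persistent_loss", change_pixels=30,
                    initial_lci=0.4)
        base.update(kw)
        return CellRecord(**base)

    def test_sixteen_pixel_change_is_at_most_five_percent_and_excluded(self):
        assert 16 / 324 <= 0.05 < 17 / 324
        _, excluded = apply_filters([self._rec(change_pixels=16)])
        assert excluded and "min_change" in excluded[0].filter_flags

    def test_degenerate_lci_excluded(self):
        _, excluded = apply_filters([self._rec(initial_lci=None)])
        assert "degenerate_lci" in excluded[0].filter_flags

    def test_non_persistent_excluded(self):
        _, excluded = apply_filters([self._rec(trajectory_class="non_persistent")])
        assert "non_persistent" in excluded[0].filter_flags

    def test_non_forest_transition_excluded(self):
        _, excluded = apply_filters([self._rec(involves_forest=False)])
        assert "no_forest_transition" in excluded[0].filter_flags

    def test_valid_record_retained_and_partition_holds(self):
        recs = [self._rec(), self._rec(change_pixels=5), self._rec(initial_lci=None)]
        retained, excluded = apply_filters(recs)
        assert len(retained) == 1 and len(retained) + len(excluded) == len(recs)

    def test_threshold_scales_with_cell_size(self):
        assert scale_min_change(324) == 17
        assert scale_min_change(324 * 4) == 68  # 6 arc-minute analogue


class TestRecovery:
    def test_pipeline_recovers_generating_specs_exactly(self):
        specs = random_cell_specs(60, seed=17)
        mosaic = generate_mosaic(specs, seed=17)
        want = {"loss": "persistent_loss", "gain": "persistent_gain",
                "non_persistent": "non_persistent"}
        for sp in specs:
            r = analyze_cell(mosaic[sp.cell_id])
            t = sp.trajectory
            assert r.trajectory_class == want[t.direction]
            assert r.interval_start == t.start_step
            assert r.duration == t.duration_years
            assert r.rate_of_change == pytest.approx(1 / t.duration_years)
            if t.direction != "non_persistent":
                assert r.change_pixels == t.change_pixels
            assert r.initial_transition_amount == pytest.approx(
                sp.initial_transition_amount / 324)

    def test_rates_come_from_integer_durations(self):
        specs = random_cell_specs(30, seed=23)
        mosaic = generate_mosaic(specs, seed=23)
        allowed = {1 / d for d in range(1, 29)}
        for s in mosaic.values():
            r = analyze_cell(s)
            assert any(abs(r.rate_of_change - a) < 1e-12 for a in allowed)


class TestInitialState:
    def test_absent_transition_lc_flags_degenerate(self, loss_cell):
        spec, series = loss_cell
        # pick a class absent from the grid
        from foresttraj.categories import WATER
        iv = change_interval(ForestSeries.from_series(series, spec.forest_class))
        amount, lci_val = initial_state(series, iv, WATER)
        assert amount == 0.0 and lci_val is None

    def test_amount_is_pixel_share_at_interval_start(self, loss_cell):
        spec, series = loss_cell
        iv = change_interval(ForestSeries.from_series(series, spec.forest_class))
        amount, lci_val = initial_state(series, iv, spec.transition_class)
        assert amount == pytest.approx(80 / 324)
        assert 0.0 <= lci_val <= 1.0


class TestPixelArea:
    def test_equatorial_3arcmin_cell(self):
        # 0.05 degree cell at the equator: edge ~5.56 km, pixel ~0.095 km^2
        area = pixel_area((0.0, 0.0, 0.05, 0.05), 18, 18)
        assert area == pytest.approx((5.56 / 18) ** 2, rel=0.01)

    def test_width_halves_at_sixty_degrees(self):
        eq = pixel_area((0.0, -0.025, 0.05, 0.025), 18, 18)
        north = pixel_area((0.0, 59.975, 0.05, 60.025), 18, 18)
        assert north / eq == pytest.approx(0.5, rel=0.01)

    def test_degenerate_bounds_raise(self):
        with pytest.raises(ValueError):
            pixel_area((0.0, 0.0, 0.0, 0.05), 18, 18)
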