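"""CPP, rolling reactivity indices, episodes and ICP dose."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerebroflux import (
    LPRX,
    MLPRX,
    ConfigurationError,
    Group,
    IndexSeries,
    PRxSpec,
    PhaseSchedule,
    SimulationConfig,
    ValidationError,
    classify_reactivity,
    cpp_series,
    delta_from_baseline,
    detect_episodes,
    icp_dose,
    rolling_prx,
    simulate_animal,
)
from conftest import make_record
from oracles import pearson_oracle

# Frozen oracle value: pearson_oracle([90,95,100,98,102,105], [17,18,20,19,21,22])
FROZEN_WINDOW_R = 0.9852688551766631


class TestCpp:
    def test_cpp_is_map_minus_icp(self):
        rec = make_record([94.0, 163.0], [17.0, 34.0])
        s = cpp_series(rec)
        assert s.values[0] == pytest.approx(77.0)
        assert s.values[1] == pytest.approx(129.0)

    def test_missing_input_propagates(self):
        rec = make_record([None, 90.0], [20.0, None])
        s = cpp_series(rec)
        assert list(s.status) == ["missing", "missing"]

    def test_cpp_plus_icp_reconstructs_pmap(self, gridded_record):
        s = cpp_series(gridded_record)
        icp = gridded_record.channel("icp")
        pmap = gridded_record.channel("pmap")
        np.testing.assert_allclose(s.values + icp, pmap, rtol=0, atol=1e-12)


class TestRollingPrx:
    def test_colinear_channels_give_plus_one(self):
        pmap = [90.0, 95.0, 100.0, 98.0, 102.0, 105.0]
        rec = make_record(pmap, [p - 73 for p in pmap])
        s = rolling_prx(rec, MLPRX)
        assert s.values[0] == pytest.approx(1.0)

    def test_anti_colinear_channels_give_minus_one(self):
        pmap = [90.0, 95.0, 100.0, 98.0, 102.0, 105.0]
        rec = make_record(pmap, [120 - p for p in pmap])
        s = rolling_prx(rec, MLPRX)
        assert s.values[0] == pytest.approx(-1.0)

    def test_matches_frozen_brute_force_value(self):
        rec = make_record(
            [90.0, 95.0, 100.0, 98.0, 102.0, 105.0],
            [17.0, 18.0, 20.0, 19.0, 21.0, 22.0],
        )
        s = rolling_prx(rec, MLPRX)
        assert abs(s.values[0] - FROZEN_WINDOW_R) < 1e-12

    def test_constant_icp_window_is_undefined(self):
        rec = make_record([90.0, 95.0, 100.0, 98.0, 102.0, 105.0], [20.0] * 6)
        s = rolling_prx(rec, MLPRX)
        assert s.status[0] == "undefined"

    def test_window_count_and_end_assignment(self, gridded_record):
        s = rolling_prx(gridded_record, MLPRX)
        assert len(s.values) == 46 - 6 + 1
        assert s.times[0] == gridded_record.times()[5]  # causal: window end
        center = rolling_prx(
            gridded_record, PRxSpec(n_points=6, interval=5.0, assignment="window_center")
        )
        assert center.times[0] == pytest.approx(
            0.5 * (gridded_record.times()[0] + gridded_record.times()[5])
        )

    def test_missing_sample_knocks_out_its_windows(self, gridded_record):
        samples = [
            type(s)(s.time, None if i == 20 else s.pmap, s.icp)
            for i, s in enumerate(gridded_record.samples)
        ]
        rec = type(gridded_record)("pigx", Group.NICPG, 47.5, samples)
        s = rolling_prx(rec, MLPRX)
        assert (s.status == "missing").sum() == 6  # interior sample: n_points windows
        assert s.status[15] == "missing" and s.status[20] == "missing"
        assert s.status[14] == "ok" and s.status[21] == "ok"

    def test_grid_step_mismatch_is_configuration_error(self, gridded_record):
        with pytest.raises(ConfigurationError):
            rolling_prx(gridded_record, LPRX)  # 1-min spec on a 5-min grid

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        pmap = rng.normal(90, 10, n).tolist()
        icp = rng.normal(20, 3, n).tolist()
        rec = make_record(pmap, icp)
        s = rolling_prx(rec, MLPRX)
        for w in range(n - 6 + 1):
            expected = pearson_oracle(pmap[w : w + 6], icp[w : w + 6])
            assert abs(s.values[w] - expected) < 1e-12

    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=-50.0, max_value=50.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance_and_sign_flip(self, scale, shift):
        rng = np.random.default_rng(1234)
        pmap = rng.normal(90, 10, 8).tolist()
        icp = rng.normal(20, 3, 8).tolist()
        base = rolling_prx(make_record(pmap, icp), MLPRX).values
        scaled = rolling_prx(
            make_record(pmap, [scale * v + shift for v in icp]), MLPRX
        ).values
        flipped = rolling_prx(
            make_record(pmap, [-scale * v + shift for v in icp]), MLPRX
        ).values
        np.testing.assert_allclose(scaled, base, atol=1e-9)
        np.testing.assert_allclose(flipped, -base, atol=1e-9)

    def test_phase_censoring_blanks_boundary_windows(self, gridded_record, schedule):
        s = rolling_prx(gridded_record, MLPRX, censor_schedule=schedule)
        # the window ending at T0 spans bleeding and occlusion
        i = list(s.times).index(0.0)
        assert s.status[i] == "missing"
        i_late = list(s.times).index(115.0)  # fully inside occlusion
        assert s.status[i_late] == "ok"


class TestClassifyAndEpisodes:
    @pytest.mark.parametrize(
        "value,label",
        [(0.0, "preserved"), (0.01, "impaired"), (-0.5, "preserved"), (float("nan"), "undefined")],
    )
    def test_threshold_is_inclusive_for_preserved(self, value, label):
        assert classify_reactivity(value, MLPRX) == label

    def test_no_impairment_no_episodes(self):
        s = IndexSeries("a", "mL-PRx", [25.0, 30.0, 35.0], [-0.1, 0.0, -0.4], ["ok"] * 3)
        assert detect_episodes(s, MLPRX) == []

    def test_single_run_with_min_windows(self):
        s = IndexSeries(
            "a", "mL-PRx", [25.0, 30.0, 35.0, 40.0], [-0.1, 0.3, 0.4, -0.2], ["ok"] * 4
        )
        eps = detect_episodes(s, MLPRX, min_windows=2)
        assert len(eps) == 1
        ep = eps[0]
        # start = first impaired window's data onset (assigned time - span)
        assert ep.start == 30.0 - MLPRX.span
        assert ep.end == 35.0
        assert ep.duration == ep.end - ep.start
        assert ep.mean_index == pytest.approx(0.35)
        assert ep.peak_index == pytest.approx(0.4)

    def test_short_runs_discarded_and_missing_breaks_runs(self):
        s = IndexSeries(
            "a", "mL-PRx",
            [25.0, 30.0, 35.0, 40.0, 45.0],
            [0.3, float("nan"), 0.4, 0.5, -0.1],
            ["ok", "missing", "ok", "ok", "ok"],
        )
        eps = detect_episodes(s, MLPRX, min_windows=2)
        assert len(eps) == 1 and eps[0].end == 40.0  # the isolated 0.3 is dropped


class TestIcpDose:
    def test_constant_excess_closed_form(self):
        rec = make_record([90.0] * 13, [30.0] * 13)  # 0..60 min at 5-min steps
        assert icp_dose(rec, threshold=20.0, window=(0.0, 60.0)) == pytest.approx(600.0)

    def test_below_threshold_gives_zero(self):
        rec = make_record([90.0] * 13, [15.0] * 13)
        assert icp_dose(rec, threshold=20.0) == 0.0

    def test_additive_over_partitions_and_monotone_in_threshold(self, gridded_record):
        whole = icp_dose(gridded_record, 17.0, (-90.0, 135.0))
        left = icp_dose(gridded_record, 17.0, (-90.0, 0.0))
        right = icp_dose(gridded_record, 17.0, (0.0, 135.0))
        assert left + right == pytest.approx(whole, rel=1e-12)
        assert icp_dose(gridded_record, 18.0) <= icp_dose(gridded_record, 17.0)

    def test_window_outside_record_is_error(self, gridded_record):
        with pytest.raises(ValidationError):
            icp_dose(gridded_record, 20.0, (-200.0, 0.0))


class TestDeltaFromBaseline:
    def _series(self, times, values, name="pMAP"):
        return IndexSeries("a", name, times, values, ["ok"] * len(times))

    def test_printed_eicpg_worked_example(self):
        # group-median trajectory: baseline 99 at T-30, occlusion maximum 163 at T15
        s = self._series([-30.0, 0.0, 15.0, 90.0], [99.0, 41.0, 163.0, 124.0])
        assert delta_from_baseline(s, -30.0, "max") == pytest.approx(64.0)

    def test_printed_nicpg_counterpart(self):
        s = self._series([-30.0, 0.0, 15.0, 90.0], [94.0, 45.0, 125.0, 85.0])
        assert delta_from_baseline(s, -30.0, "max") == pytest.approx(31.0)

    def test_constant_series_gives_zero(self):
        s = self._series([-30.0, 10.0, 50.0], [80.0, 80.0, 80.0])
        assert delta_from_baseline(s, -30.0, "max") == 0.0

    def test_missing_baseline_is_error(self):
        s = IndexSeries("a", "pMAP", [-30.0, 10.0], [99.0, 120.0], ["missing", "ok"])
        with pytest.raises(ValidationError):
            delta_from_baseline(s, -30.0, "max")

    def test_at_time_stat(self):
        s = self._series([-30.0, 90.0], [99.0, 124.0])
        assert delta_from_baseline(s, -30.0, "at_time", at=90.0) == pytest.approx(25.0)


class TestEpisodeRecoveryFromSimulation:
    def test_scheduled_impairment_is_recovered_within_one_window_span(self):
        """Forced impairment on [20, 40] min is found with <= 25-min boundary
        error (normal-ICP arm: MAP inside the plateau, so the schedule is the
        only impairment source)."""
        cfg = SimulationConfig(
            seed=1, impairment_schedule={Group.NICPG: ((20.0, 40.0),), Group.EICPG: ()}
        )
        hits = 0
        for k in range(5):
            rec = simulate_animal(cfg, Group.NICPG, 1 + k)
            s = rolling_prx(rec, MLPRX, censor_schedule=cfg.schedule)
            eps = detect_episodes(s, MLPRX, min_windows=2)
            hits += any(
                e.overlaps(20.0, 40.0) and abs(e.start - 20.0) <= 25.0 and abs(e.end - 40.0) <= 25.0
                for e in eps
            )
        assert hits >= 4
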