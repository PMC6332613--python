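"""MAC summation, z-scoring, windowing, TVI computation, and proportions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tvindex.tvi_core import (
    FitError,
    Window,
    add_zscores,
    assemble_profile,
    build_profiles,
    build_windows,
    compute_total_mac,
    compute_tvi,
    fit_population_stats,
    prepare_streams,
    summed_mac_frame,
    temporal_proportion,
    window_proportion,
    windows_frame,
    zscore,
)

from .conftest import MICRO_EXPECTED_TVIS, toy_measurements


class TestComputeTotalMac:
    @pytest.mark.parametrize(
        "agents,expected",
        [
            ({"sevoflurane": 1.8}, 1.0),
            ({"isoflurane": 1.17, "nitrous_oxide": 105.0}, 2.0),
            ({"desflurane": 3.3}, 0.5),
            ({"isoflurane": 1.17}, 1.0),
        ],
    )
    def test_equivalent_identities(self, agents, expected):
        mac, negligible = compute_total_mac(agents)
        assert mac == pytest.approx(expected, abs=1e-12)
        assert not negligible

    def test_all_zero_is_negligible(self):
        mac, negligible = compute_total_mac(
            {"isoflurane": 0.0, "desflurane": 0.0, "sevoflurane": 0.0, "nitrous_oxide": 0.0}
        )
        assert mac == 0.0 and negligible

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_total_mac({"sevoflurane": -0.1})

    def test_unknown_agent_rejected(self):
        with pytest.raises(KeyError):
            compute_total_mac({"xenon": 1.0})


class TestSummedMacFrame:
    def test_sums_simultaneous_agents_and_filters(self):
        frame = toy_measurements(
            [
                ("c1", 0.0, "ISOFLURANE", 1.17, "NA"),
                ("c1", 0.0, "NITROUS_OXIDE", 105.0, "NA"),
                ("c1", 5.0, "SEVOFLURANE", 6.3, "NA"),   # 3.5 MAC -> artifact
                ("c1", 10.0, "SEVOFLURANE", 0.0, "NA"),  # negligible
            ]
        )
        mac, removed = summed_mac_frame(frame)
        assert mac["value"].tolist() == [pytest.approx(2.0)]
        assert sorted(removed["reason"]) == ["MAC_above_limit", "MAC_negligible"]

    def test_mac_boundary_retained(self):
        frame = toy_measurements([("c1", 0.0, "SEVOFLURANE", 3.0 * 1.8, "NA")])
        mac, removed = summed_mac_frame(frame)
        assert len(mac) == 1 and len(removed) == 0


class TestPopulationStats:
    def test_hand_computed_mean_and_sample_sd(self):
        frame = toy_measurements(
            [("c1", float(i), "MAP", v, "ARTERIAL") for i, v in enumerate((70, 80, 90))]
        )
        stats = fit_population_stats(frame, variables=("MAP",))
        assert stats.mean("MAP") == pytest.approx(80.0)
        assert stats.sd("MAP") == pytest.approx(10.0)  # divisor n-1
        assert stats.n("MAP") == 3

    def test_pooling_is_case_agnostic(self):
        values = [72.0, 81.0, 95.0, 88.0]
        one_case = toy_measurements(
            [("c1", float(i), "MAP", v, "ARTERIAL") for i, v in enumerate(values)]
        )
        two_cases = toy_measurements(
            [
                (f"c{1 + i % 2}", float(i), "MAP", v, "ARTERIAL")
                for i, v in enumerate(values)
            ]
        )
        a = fit_population_stats(one_case, variables=("MAP",))
        b = fit_population_stats(two_cases, variables=("MAP",))
        assert a.mean("MAP") == b.mean("MAP") and a.sd("MAP") == b.sd("MAP")

    def test_constant_variable_is_fit_error(self):
        frame = toy_measurements(
            [("c1", float(i), "BIS", 47.0, "NA") for i in range(5)]
        )
        with pytest.raises(FitError, match="BIS"):
            fit_population_stats(frame, variables=("BIS",))

    def test_single_value_is_fit_error(self):
        frame = toy_measurements([("c1", 0.0, "MAP", 80.0, "ARTERIAL")])
        with pytest.raises(FitError, match="at least 2"):
            fit_population_stats(frame, variables=("MAP",))


class TestZscore:
    @pytest.fixture()
    def stats(self):
        frame = toy_measurements(
            [("c1", float(i), "MAP", v, "ARTERIAL") for i, v in enumerate((70, 80, 90))]
        )
        return fit_population_stats(frame, variables=("MAP",))

    def test_population_mean_maps_to_zero(self, stats):
        assert zscore(80.0, "MAP", stats) == 0.0

    def test_direct_formula(self, stats):
        assert zscore(90.0, "MAP", stats) == pytest.approx(1.0)

    @given(d=st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_about_mean(self, d):
        frame = toy_measurements(
            [("c1", float(i), "MAP", v, "ARTERIAL") for i, v in enumerate((70, 80, 90))]
        )
        stats = fit_population_stats(frame, variables=("MAP",))
        assert zscore(80.0 + d, "MAP", stats) == pytest.approx(
            -zscore(80.0 - d, "MAP", stats), abs=1e-12
        )

    def test_unknown_variable_rejected(self, stats):
        with pytest.raises(KeyError):
            zscore(1.0, "HR", stats)


class TestWindowing:
    def test_micro_case_window_sizes_and_tvis(self, micro_case):
        streams, audit = prepare_streams(micro_case)
        assert audit.empty
        stats = fit_population_stats(streams)
        windows = build_windows(streams, stats)
        assert [w.n_timepoints for w in windows] == [5, 5, 2]
        for w, expected in zip(windows, MICRO_EXPECTED_TVIS):
            assert w.tvi == pytest.approx(expected, abs=1e-12)

    def test_three_timepoints_single_remainder_window(self):
        rows = []
        for i in range(3):
            rows += [
                ("c1", float(i), "MAP", 70.0 + 10 * i, "ARTERIAL"),
                ("c1", float(i), "BIS", 40.0 + i, "NA"),
            ]
        frame = toy_measurements(rows)
        stats = fit_population_stats(frame, variables=("MAP", "BIS"))
        windows = build_windows(frame, stats)
        assert len(windows) == 1 and windows[0].n_timepoints == 3

    def test_map_only_window_has_no_tvi(self):
        frame = toy_measurements(
            [("c1", float(i), "MAP", 70.0 + i, "ARTERIAL") for i in range(5)]
        )
        stats = fit_population_stats(frame, variables=("MAP",))
        windows = build_windows(frame, stats)
        assert len(windows) == 1
        w = windows[0]
        assert w.map_mean_z is not None
        assert w.bis_mean_z is None and w.mac_mean_z is None
        assert w.tvi is None

    def test_empty_case_rejected(self):
        frame = toy_measurements([]).astype({"t_min": float, "value": float})
        stats_frame = toy_measurements(
            [("c1", float(i), "MAP", 70.0 + i, "ARTERIAL") for i in range(3)]
        )
        stats = fit_population_stats(stats_frame, variables=("MAP",))
        with pytest.raises(ValueError, match="empty"):
            build_windows(frame, stats)

    def test_simultaneous_variables_share_a_timepoint(self):
        # 5 timepoints each carrying MAP+BIS: one full window, not two
        rows = []
        for i in range(5):
            rows += [
                ("c1", float(i), "MAP", 70.0 + i, "ARTERIAL"),
                ("c1", float(i), "BIS", 40.0 + i, "NA"),
            ]
        frame = toy_measurements(rows)
        stats = fit_population_stats(frame, variables=("MAP", "BIS"))
        windows = build_windows(frame, stats)
        assert len(windows) == 1 and windows[0].n_timepoints == 5

    def test_timepoint_conservation_random_cases(self, rng):
        for _ in range(20):
            n_t = int(rng.integers(1, 40))
            rows = []
            for i in range(n_t):
                for var in ("MAP", "BIS", "MAC"):
                    if rng.random() < 0.7:
                        rows.append(
                            (
                                "c1",
                                float(i),
                                var,
                                float(rng.uniform(30, 90)),
                                "ARTERIAL" if var == "MAP" else "NA",
                            )
                        )
            if not rows:
                continue
            frame = toy_measurements(rows)
            z = frame.assign(z=0.0)
            wins = windows_frame(z)
            n_distinct = frame["t_min"].nunique()
            assert wins["n_timepoints"].sum() == n_distinct
            assert (wins["n_timepoints"].iloc[:-1] == 5).all()


class TestComputeTvi:
    def test_sum_of_three_means(self):
        w = Window(0, (0.0,), map_mean_z=0.5, bis_mean_z=-0.2, mac_mean_z=0.1)
        assert compute_tvi(w) == pytest.approx(0.4)

    def test_zero_at_population_means(self):
        w = Window(0, (0.0,), map_mean_z=0.0, bis_mean_z=0.0, mac_mean_z=0.0)
        assert compute_tvi(w) == 0.0

    def test_absent_mac_yields_no_tvi(self):
        w = Window(0, (0.0,), map_mean_z=0.5, bis_mean_z=-0.2, mac_mean_z=None)
        assert compute_tvi(w) is None


class TestAssembleProfile:
    def _window(self, i, tvi):
        return Window(
            i, (float(i),), map_mean_z=0.0, bis_mean_z=0.0,
            mac_mean_z=0.0 if tvi is not None else None, tvi=tvi,
        )

    def test_profile_keeps_missing_middle_window(self):
        windows = [self._window(0, 0.1), self._window(1, None), self._window(2, -0.2)]
        profile = assemble_profile("c1", windows, (0.0, 10.0))
        assert profile is not None and profile.n_windows == 3
        assert profile.windows[1].tvi is None
        assert profile.n_tvi_values == 2

    def test_all_missing_is_excluded(self):
        windows = [self._window(0, None), self._window(1, None)]
        assert assemble_profile("c1", windows, (0.0, 10.0)) is None

    def test_map_only_case_excluded_with_reason(self):
        frame = toy_measurements(
            [("c1", float(i), "MAP", 70.0 + i, "ARTERIAL") for i in range(6)]
            + [
                ("c2", float(i), var, v, "ARTERIAL" if var == "MAP" else "NA")
                for i in range(6)
                for var, v in (("MAP", 80.0 + i), ("BIS", 40.0 + i), ("SEVOFLURANE", 1.4 + 0.1 * i))
            ]
        )
        result = build_profiles(frame)
        assert set(result.profiles) == {"c2"}
        assert result.exclusions["case_id"].tolist() == ["c1"]
        assert result.exclusions["reason"].tolist() == ["no_tvi_windows"]


class TestAlgebraicIdentities:
    def test_window_mean_z_equals_z_of_raw_mean(self, small_profiles):
        """Averaging z-scores inside a window must equal z-scoring the raw
        window mean — an exact algebraic identity under one set of
        population statistics."""
        stats = small_profiles.stats
        w = small_profiles.windows
        for var in ("map", "bis", "mac"):
            present = w[w[f"{var}_mean"].notna()]
            expected = (
                present[f"{var}_mean"] - stats.mean(var.upper())
            ) / stats.sd(var.upper())
            assert np.allclose(present[f"{var}_mean_z"], expected, atol=1e-9)

    def test_pooled_zscores_standardized(self, small_profiles):
        z = add_zscores(small_profiles.streams, small_profiles.stats)
        for var in ("MAP", "BIS", "MAC"):
            vals = z.loc[z["variable"] == var, "z"].to_numpy()
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std(ddof=1) - 1.0) < 1e-9

    def test_tvi_equals_sum_of_means_exactly(self, small_profiles):
        w = small_profiles.windows
        complete = w[w["tvi"].notna()]
        total = (
            complete["map_mean_z"] + complete["bis_mean_z"] + complete["mac_mean_z"]
        )
        assert (complete["tvi"] == total).all()


class TestProportions:
    def test_minute_six_of_sixty_is_one_tenth(self):
        assert temporal_proportion(6.0, (0.0, 60.0)) == pytest.approx(0.10)

    def test_span_endpoints(self):
        assert temporal_proportion(0.0, (0.0, 60.0)) == 0.0
        assert temporal_proportion(60.0, (0.0, 60.0)) == 1.0

    def test_zero_length_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            temporal_proportion(5.0, (5.0, 5.0))

    @given(
        data=st.tuples(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            st.floats(min_value=0, max_value=100, allow_nan=False),
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_t(self, data):
        t1, t2 = sorted(data)
        span = (-1.0, 101.0)
        assert temporal_proportion(t1, span) <= temporal_proportion(t2, span)

    @pytest.mark.parametrize(
        "i,w,expected",
        [(0, 11, 0.0), (10, 11, 1.0), (5, 11, 0.5), (0, 1, 0.0)],
    )
    def test_window_proportion_convention(self, i, w, expected):
        assert window_proportion(i, w) == pytest.approx(expected)

    def test_window_proportion_bounds_validated(self):
        with pytest.raises(ValueError):
            window_proportion(3, 3)
        with pytest.raises(ValueError):
            window_proportion(0, 0)
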