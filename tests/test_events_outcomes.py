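"""Event detection, mortality windows, and cluster characterization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tvindex.events_outcomes import (
    EventFlags,
    MortalityClass,
    TripleLowCriteria,
    classify_mortality,
    compute_correlations,
    detect_ioh,
    detect_tls,
    event_flags_frame,
    patient_level_sensitivity,
)
from tvindex.patterns import ClusterModel, FeaturizationParams
from tvindex.tvi_core import TVIProfile, Window


def profile_with_means(case_id, triples):
    """Profile whose windows carry the given raw (map, bis, mac) means."""
    windows = []
    for i, triple in enumerate(triples):
        if triple is None:
            windows.append(Window(i, (float(i),)))
            continue
        m, b, a = triple
        windows.append(
            Window(
                i, (float(i),),
                map_mean_z=0.0, bis_mean_z=0.0, mac_mean_z=0.0,
                map_mean=m, bis_mean=b, mac_mean=a, tvi=0.1,
            )
        )
    return TVIProfile(case_id=case_id, windows=tuple(windows), monitoring_span=(0.0, 60.0))


class TestDetectIoh:
    @pytest.mark.parametrize(
        "values,expected",
        [([80.0, 54.0, 90.0], True), ([55.0, 80.0], False), ([80.0, 80.0], False)],
    )
    def test_strict_threshold(self, values, expected):
        assert detect_ioh(values) is expected

    def test_empty_case_rejected(self):
        with pytest.raises(ValueError, match="no MAP"):
            detect_ioh([])


class TestDetectTls:
    def test_boundary_window_means(self):
        qualifies = profile_with_means("c", [(74.0, 44.0, 0.79)])
        assert detect_tls(qualifies) == (True, 1)
        boundary = profile_with_means("c", [(75.0, 44.0, 0.79)])
        assert detect_tls(boundary) == (False, 0)

    def test_counts_over_mixed_windows(self):
        p = profile_with_means(
            "c", [(70.0, 40.0, 0.5), None, (70.0, 40.0, 0.5)]
        )
        assert detect_tls(p) == (True, 2)

    def test_window_missing_one_variable_never_qualifies(self):
        w = Window(
            0, (0.0,), map_mean_z=0.0, bis_mean_z=0.0,
            map_mean=60.0, bis_mean=30.0, mac_mean=None,
        )
        p = TVIProfile("c", (w,), (0.0, 10.0))
        assert detect_tls(p) == (False, 0)

    def test_custom_criteria(self):
        p = profile_with_means("c", [(74.0, 44.0, 0.79)])
        assert detect_tls(p, TripleLowCriteria(map_thresh=70.0)) == (False, 0)


class TestEventFlags:
    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            EventFlags("c", ioh=False, tls_any=True, tls_window_count=0)

    def test_frame_from_profiles_and_streams(self, small_cohort, small_profiles):
        flags = event_flags_frame(small_profiles.profiles, small_profiles.streams)
        assert set(flags.columns) == {"case_id", "ioh", "tls_any", "tls_window_count"}
        assert len(flags) == len(small_profiles.profiles)
        assert (flags["tls_any"] == (flags["tls_window_count"] >= 1)).all()
        # TLS windows require a computable window, bounded by TVI windows
        counts = {
            c: small_profiles.profiles[c].n_tvi_values for c in small_profiles.profiles
        }
        assert all(
            row.tls_window_count <= counts[row.case_id] for row in flags.itertuples()
        )


class TestClassifyMortality:
    @pytest.mark.parametrize(
        "day,expected",
        [
            (0, MortalityClass.D30),
            (30, MortalityClass.D30),
            (31, MortalityClass.D31_365),
            (365, MortalityClass.D31_365),
            (366, MortalityClass.D366_730),
            (730, MortalityClass.D366_730),
            (731, MortalityClass.SURVIVED_BEYOND_730),
        ],
    )
    def test_window_boundaries(self, day, expected):
        assert classify_mortality(day) is expected

    def test_absent_death_day_uses_follow_up(self):
        assert classify_mortality(None, 800) is MortalityClass.SURVIVED_BEYOND_730
        assert classify_mortality(None, 400) is MortalityClass.UNKNOWN
        assert classify_mortality(None, None) is MortalityClass.UNKNOWN

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            classify_mortality(-1)


def tiny_model(assignments: dict[str, int], k=3) -> ClusterModel:
    return ClusterModel(
        k=k,
        params=FeaturizationParams(),
        centroids=np.zeros((k, 2)),
        assignments=assignments,
        seed=0,
        labels={0: "elevated", 1: "mixed", 2: "depressed"},
    )


class TestPatientLevelSensitivity:
    def _cases(self, rows):
        return pd.DataFrame(
            rows,
            columns=["case_id", "patient_id", "days_to_death", "follow_up_days"],
        )

    def test_repeat_patient_counted_once_per_cluster(self):
        model = tiny_model({"s1": 2, "s2": 2})
        cases = self._cases([("s1", "p1", 10, 800), ("s2", "p1", 10, 800)])
        out = patient_level_sensitivity(model, cases)
        d30 = out[(out["cluster_label"] == "depressed") & (out["metric"] == "pct_mortality_30d")]
        assert d30["value"].iloc[0] == 1.0
        assert d30["n"].iloc[0] == 1  # one distinct patient

    def test_patient_in_two_clusters_counted_in_each(self):
        model = tiny_model({"s1": 0, "s2": 2})
        cases = self._cases([("s1", "p1", 10, 800), ("s2", "p1", 10, 800)])
        out = patient_level_sensitivity(model, cases)
        for label in ("elevated", "depressed"):
            d30 = out[(out["cluster_label"] == label) & (out["metric"] == "pct_mortality_30d")]
            assert d30["value"].iloc[0] == 1.0

    def test_unique_patients_match_profile_level(self):
        model = tiny_model({"s1": 0, "s2": 0, "s3": 0})
        cases = self._cases(
            [("s1", "p1", 10, 800), ("s2", "p2", pd.NA, 800), ("s3", "p3", pd.NA, 800)]
        )
        out = patient_level_sensitivity(model, cases)
        d30 = out[(out["cluster_label"] == "elevated") & (out["metric"] == "pct_mortality_30d")]
        assert d30["value"].iloc[0] == pytest.approx(1 / 3)


class TestCorrelations:
    def test_perfect_linear_pair(self):
        w = pd.DataFrame(
            {
                "case_id": ["c"] * 5,
                "map_mean": [70, 75, 80, 85, 90.0],
                "bis_mean": [35, 40, 45, 50, 55.0],
                "mac_mean": [0.6, 0.7, 0.8, 0.9, 1.0],
            }
        )
        out = compute_correlations(w)
        assert np.allclose(out["r"], 1.0)

    def test_independent_pair_near_zero(self, rng):
        n = 10000
        w = pd.DataFrame(
            {
                "case_id": ["c"] * n,
                "map_mean": rng.normal(80, 10, n),
                "bis_mean": rng.normal(45, 5, n),
                "mac_mean": rng.normal(0.8, 0.2, n),
            }
        )
        out = compute_correlations(w)
        assert (out["r"].abs() < 0.05).all()

    def test_generator_coupling_gives_negative_bis_mac(self, small_profiles):
        out = compute_correlations(small_profiles.windows)
        r = out.loc[out["pair"] == "BIS_MAC", "r"].iloc[0]
        assert r < 0

    def test_constant_series_reported_na(self):
        w = pd.DataFrame(
            {
                "case_id": ["c"] * 4,
                "map_mean": [80.0] * 4,
                "bis_mean": [35, 40, 45, 50.0],
                "mac_mean": [0.6, 0.7, 0.8, 0.9],
            }
        )
        out = compute_correlations(w)
        assert np.isnan(out.loc[out["pair"] == "MAP_BIS", "r"]).all()

    def test_too_few_windows_rejected(self):
        w = pd.DataFrame(
            {"case_id": ["c"] * 2, "map_mean": [1.0, 2.0], "bis_mean": [1.0, 2.0], "mac_mean": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            compute_correlations(w)
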