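"""Intraoperative event detection, mortality windows, and cluster characterization.

Two threshold-based events, evaluated at deliberately different
granularities mirroring their clinical definitions: intraoperative
hypotension (IOH) is any RAW recorded MAP below 55 mmHg, while triple low
state (TLS) exposure is judged on profile-window MEANS — a window qualifies
when its mean MAP, BIS, and MAC are all present and strictly below
75 mmHg / 45 / 0.8. Postoperative deaths are classed into the 30-day,
31–365-day, and 366–730-day windows. Cluster characterization aggregates
patient, procedure, physiology, event, and mortality summaries per TVI
pattern, with Wilson intervals for proportions, t-intervals for means, and
bootstrap intervals for medians.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .patterns import ClusterModel
from .stats import BootstrapMedianParams, bootstrap_median_ci, mean_t_ci, wilson_ci
from .tvi_core import TVIProfile

__all__ = [
    "TripleLowCriteria",
    "EventFlags",
    "MortalityClass",
    "detect_ioh",
    "detect_tls",
    "classify_mortality",
    "event_flags_frame",
    "characterize_clusters",
    "patient_level_sensitivity",
    "compute_correlations",
]


@dataclass(frozen=True)
class TripleLowCriteria:
    """Triple-low-state thresholds; all comparisons are strict less-than."""

    map_thresh: float = 75.0
    bis_thresh: float = 45.0
    mac_thresh: float = 0.8

    def __post_init__(self) -> None:
        if min(self.map_thresh, self.bis_thresh, self.mac_thresh) <= 0:
            raise ValueError("triple-low thresholds must be positive")


@dataclass(frozen=True)
class EventFlags:
    """Per-case intraoperative event summary."""

    case_id: str
    ioh: bool
    tls_any: bool
    tls_window_count: int

    def __post_init__(self) -> None:
        if self.tls_any != (self.tls_window_count >= 1):
            raise ValueError("tls_any must equal tls_window_count >= 1")


class MortalityClass(str, enum.Enum):
    D30 = "d30"
    D31_365 = "d31_365"
    D366_730 = "d366_730"
    SURVIVED_BEYOND_730 = "survived_beyond_730"
    UNKNOWN = "unknown"


MORTALITY_WINDOWS = (MortalityClass.D30, MortalityClass.D31_365, MortalityClass.D366_730)


def detect_ioh(map_values) -> bool:
    """True iff any raw recorded MAP value is below 55 mmHg (strict)."""
    v = np.asarray(map_values, float)
    if v.size == 0:
        raise ValueError("case has no MAP values")
    return bool(np.min(v) < 55.0)


def detect_tls(
    profile: TVIProfile, criteria: TripleLowCriteria | None = None
) -> tuple[bool, int]:
    """Count profile windows meeting triple-low-state criteria.

    A window qualifies iff its raw-scale MAP, BIS, and MAC means are all
    present and each strictly below its threshold. Returns
    ``(tls_any, tls_window_count)``.
    """
    criteria = criteria or TripleLowCriteria()
    count = 0
    for w in profile.windows:
        if w.map_mean is None or w.bis_mean is None or w.mac_mean is None:
            continue
        if (
            w.map_mean < criteria.map_thresh
            and w.bis_mean < criteria.bis_thresh
            and w.mac_mean < criteria.mac_thresh
        ):
            count += 1
    return count >= 1, count


def classify_mortality(
    days_to_death: Optional[int], follow_up_days: Optional[int] = None
) -> MortalityClass:
    """Map a death day to its postoperative mortality window.

    Day ``d`` (counted from surgery) maps to the 30-day window iff
    ``d <= 30``, to 31–365 iff ``31 <= d <= 365``, to 366–730 iff
    ``366 <= d <= 730``; later deaths fall outside every window and count
    as survival beyond 730 days. An absent death day means survival beyond
    730 days when follow-up reaches at least 730 days, otherwise unknown.
    """
    if days_to_death is None or (isinstance(days_to_death, float) and np.isnan(days_to_death)):
        if follow_up_days is not None and follow_up_days >= 730:
            return MortalityClass.SURVIVED_BEYOND_730
        return MortalityClass.UNKNOWN
    d = int(days_to_death)
    if d < 0:
        raise ValueError(f"days_to_death must be non-negative, got {d}")
    if d <= 30:
        return MortalityClass.D30
    if d <= 365:
        return MortalityClass.D31_365
    if d <= 730:
        return MortalityClass.D366_730
    return MortalityClass.SURVIVED_BEYOND_730


def event_flags_frame(
    profiles: Mapping[str, TVIProfile],
    streams: pd.DataFrame,
    criteria: TripleLowCriteria | None = None,
) -> pd.DataFrame:
    """Per-case event flags: IOH from raw MAP rows, TLS from window means.

    ``streams`` is the retained tidy MAP/BIS/MAC frame the profiles were
    built from. Returns columns ``case_id, ioh, tls_any, tls_window_count``.
    """
    criteria = criteria or TripleLowCriteria()
    map_rows = streams[streams["variable"] == "MAP"]
    map_by_case = map_rows.groupby("case_id")["value"]
    min_map = map_by_case.min()
    rows = []
    for case_id in sorted(profiles):
        if case_id not in min_map.index:
            raise ValueError(f"case {case_id} has no MAP values")
        tls_any, count = detect_tls(profiles[case_id], criteria)
        rows.append(
            {
                "case_id": case_id,
                "ioh": bool(min_map.loc[case_id] < 55.0),
                "tls_any": tls_any,
                "tls_window_count": count,
            }
        )
    return pd.DataFrame(rows, columns=["case_id", "ioh", "tls_any", "tls_window_count"])


def _mortality_class_column(cases: pd.DataFrame) -> pd.Series:
    follow = cases["follow_up_days"] if "follow_up_days" in cases.columns else None
    out = []
    for i, row in cases.iterrows():
        d = row["days_to_death"]
        d = None if pd.isna(d) else int(d)
        f = None
        if follow is not None and not pd.isna(follow.loc[i]):
            f = int(follow.loc[i])
        out.append(classify_mortality(d, f).value)
    return pd.Series(out, index=cases.index, name="mortality_class")


def _proportion_row(label, metric, count, nobs, detail=None) -> dict:
    lo, hi = wilson_ci(count, nobs)
    return {
        "cluster_label": label,
        "metric": metric,
        "value": count / nobs,
        "ci_low": lo,
        "ci_high": hi,
        "n": nobs,
        "detail": detail,
    }


def _mean_row(label, metric, values, detail=None) -> dict:
    m, lo, hi = mean_t_ci(np.asarray(values, float))
    return {
        "cluster_label": label,
        "metric": metric,
        "value": m,
        "ci_low": lo,
        "ci_high": hi,
        "n": len(values),
        "detail": detail,
    }


def _median_row(label, metric, values, boot_params, detail=None) -> dict:
    med, lo, hi = bootstrap_median_ci(np.asarray(values, float), boot_params)
    return {
        "cluster_label": label,
        "metric": metric,
        "value": med,
        "ci_low": lo,
        "ci_high": hi,
        "n": len(values),
        "detail": detail,
    }


def characterize_clusters(
    model: ClusterModel,
    profiles: Mapping[str, TVIProfile],
    cases: pd.DataFrame,
    flags: pd.DataFrame,
    boot_params: BootstrapMedianParams | None = None,
) -> pd.DataFrame:
    """Build the per-cluster characterization table.

    One row per (cluster, metric) in long format with columns
    ``cluster_label, metric, value, ci_low, ci_high, n, detail``.
    Proportions get Wilson 95% CIs, means t-intervals, medians seeded
    bootstrap intervals (default: 1000 resamples at the data's own size;
    pass full-scale :class:`BootstrapMedianParams` to reproduce the
    original procedure exactly).
    """
    boot_params = boot_params or BootstrapMedianParams(
        n_boot=1000, sample_size=None, seed=0
    )
    cases = cases.set_index("case_id", drop=False)
    flags = flags.set_index("case_id", drop=False)
    mort = _mortality_class_column(cases)

    rows: list[dict] = []
    by_label: dict[str, list[str]] = {}
    for case_id in model.assignments:
        by_label.setdefault(model.label_of(case_id), []).append(case_id)

    for label in sorted(by_label):
        members = sorted(by_label[label])
        if not members:
            raise ValueError(f"cluster {label} is empty")
        sub_cases = cases.loc[members]
        sub_flags = flags.loc[members]
        n = len(members)
        n_patients = int(sub_cases["patient_id"].nunique())
        rows.append(
            {
                "cluster_label": label, "metric": "n_profiles", "value": n,
                "ci_low": np.nan, "ci_high": np.nan, "n": n, "detail": None,
            }
        )
        rows.append(
            {
                "cluster_label": label, "metric": "n_patients", "value": n_patients,
                "ci_low": np.nan, "ci_high": np.nan, "n": n, "detail": None,
            }
        )
        rows.append(
            _proportion_row(label, "pct_repeat_surgery", int(sub_cases["repeat_surgery"].sum()), n)
        )
        for asa in range(1, 6):
            rows.append(
                _proportion_row(
                    label, f"pct_asa_{asa}", int((sub_cases["asa_status"] == asa).sum()), n
                )
            )
        rows.append(_proportion_row(label, "pct_emergent", int(sub_cases["emergent"].sum()), n))
        rows.append(_mean_row(label, "mean_age_years", sub_cases["age_years"].to_numpy()))
        rows.append(
            _proportion_row(label, "pct_male", int((sub_cases["sex"] == "M").sum()), n)
        )
        for rank, (name, count) in enumerate(
            sub_cases["specialty"].value_counts().head(3).items(), start=1
        ):
            rows.append(
                _proportion_row(label, f"top_specialty_{rank}", int(count), n, detail=name)
            )
        for rank, (name, count) in enumerate(
            sub_cases["procedure"].value_counts().head(3).items(), start=1
        ):
            rows.append(
                _proportion_row(label, f"top_procedure_{rank}", int(count), n, detail=name)
            )

        spans_hr = np.array(
            [
                (profiles[c].monitoring_span[1] - profiles[c].monitoring_span[0]) / 60.0
                for c in members
            ]
        )
        rows.append(_median_row(label, "median_procedure_length_hr", spans_hr, boot_params))

        pooled: dict[str, list[float]] = {
            "map_mean": [], "bis_mean": [], "mac_mean": [],
            "map_mean_z": [], "bis_mean_z": [], "mac_mean_z": [], "tvi": [],
        }
        tvi_counts = []
        tvi_per_hr = []
        maps_per_hr = []
        for c in members:
            p = profiles[c]
            for w in p.windows:
                for attr in pooled:
                    v = getattr(w, attr)
                    if v is not None:
                        pooled[attr].append(v)
            tvi_counts.append(p.n_tvi_values)
            span_hr = max((p.monitoring_span[1] - p.monitoring_span[0]) / 60.0, 1e-9)
            tvi_per_hr.append(p.n_tvi_values / span_hr)
        for attr, metric in [
            ("map_mean", "mean_map"), ("bis_mean", "mean_bis"), ("mac_mean", "mean_mac"),
            ("map_mean_z", "mean_map_z"), ("bis_mean_z", "mean_bis_z"),
            ("mac_mean_z", "mean_mac_z"), ("tvi", "mean_tvi"),
        ]:
            rows.append(_mean_row(label, metric, pooled[attr]))
        rows.append(_median_row(label, "median_tvi_values_per_profile", tvi_counts, boot_params))
        rows.append(_median_row(label, "median_tvis_per_hr", tvi_per_hr, boot_params))
        rows.append(
            _proportion_row(label, "pct_ioh", int(sub_flags["ioh"].sum()), n)
        )
        rows.append(
            _proportion_row(label, "pct_tls", int(sub_flags["tls_any"].sum()), n)
        )
        sub_mort = mort.loc[members]
        for mc, metric in [
            (MortalityClass.D30, "pct_mortality_30d"),
            (MortalityClass.D31_365, "pct_mortality_31_365d"),
            (MortalityClass.D366_730, "pct_mortality_366_730d"),
        ]:
            rows.append(_proportion_row(label, metric, int((sub_mort == mc.value).sum()), n))
    return pd.DataFrame(rows)


def add_map_rate_metric(
    table: pd.DataFrame,
    model: ClusterModel,
    profiles: Mapping[str, TVIProfile],
    streams: pd.DataFrame,
    boot_params: BootstrapMedianParams | None = None,
) -> pd.DataFrame:
    """Append the median MAP-measurements-per-hour metric per cluster.

    Computed as each case's count of retained MAP rows divided by its
    monitoring span in hours, then the (bootstrap-CI'd) median across the
    cluster's cases.
    """
    boot_params = boot_params or BootstrapMedianParams(n_boot=1000, sample_size=None, seed=0)
    map_counts = streams[streams["variable"] == "MAP"].groupby("case_id").size()
    by_label: dict[str, list[str]] = {}
    for case_id in model.assignments:
        by_label.setdefault(model.label_of(case_id), []).append(case_id)
    rows = []
    for label in sorted(by_label):
        rates = []
        for c in by_label[label]:
            span_hr = max(
                (profiles[c].monitoring_span[1] - profiles[c].monitoring_span[0]) / 60.0,
                1e-9,
            )
            rates.append(float(map_counts.get(c, 0)) / span_hr)
        rows.append(_median_row(label, "median_maps_per_hr", rates, boot_params))
    return pd.concat([table, pd.DataFrame(rows)], ignore_index=True)


def patient_level_sensitivity(
    model: ClusterModel, cases: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster mortality proportions over distinct patients.

    Within each cluster every patient counts once (a patient with several
    member profiles contributes a single unit); a patient whose profiles
    fall in multiple clusters counts once in each such cluster. Mirrors the
    repeat-surgery sensitivity recalculation of the profile-level table.
    """
    cases = cases.set_index("case_id", drop=False)
    mort = _mortality_class_column(cases)
    per_cluster: dict[str, dict[str, str]] = {}
    for case_id in model.assignments:
        label = model.label_of(case_id)
        pid = cases.loc[case_id, "patient_id"]
        cls = mort.loc[case_id]
        bucket = per_cluster.setdefault(label, {})
        # a patient who died keeps the death class across their profiles
        prev = bucket.get(pid)
        if prev is None or _class_priority(cls) < _class_priority(prev):
            bucket[pid] = cls
    rows = []
    for label in sorted(per_cluster):
        classes = pd.Series(list(per_cluster[label].values()))
        n = len(classes)
        for mc, metric in [
            (MortalityClass.D30, "pct_mortality_30d"),
            (MortalityClass.D31_365, "pct_mortality_31_365d"),
            (MortalityClass.D366_730, "pct_mortality_366_730d"),
        ]:
            rows.append(_proportion_row(label, metric, int((classes == mc.value).sum()), n))
    return pd.DataFrame(rows)


def _class_priority(cls: str) -> int:
    order = [
        MortalityClass.D30.value,
        MortalityClass.D31_365.value,
        MortalityClass.D366_730.value,
        MortalityClass.SURVIVED_BEYOND_730.value,
        MortalityClass.UNKNOWN.value,
    ]
    return order.index(cls)


_PAIRS = (("map", "bis"), ("map", "mac"), ("bis", "mac"))


def compute_correlations(
    windows: pd.DataFrame, groups: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Pearson correlations between window-level variable means.

    For each group (``groups`` maps case_id → label; ``None`` pools all
    cases as group ``"all"``) and each variable pair, computes Pearson r
    over windows where both means are present. Requires at least 3 complete
    windows per pair; a constant series yields NA.
    """
    w = windows.copy()
    if groups is None:
        w["_group"] = "all"
    else:
        w["_group"] = w["case_id"].map(groups)
        w = w[w["_group"].notna()]
    rows = []
    for group, sub in w.groupby("_group", sort=True):
        for va, vb in _PAIRS:
            pair = sub[[f"{va}_mean", f"{vb}_mean"]].dropna()
            name = f"{va}_{vb}".upper()
            if len(pair) < 3:
                raise ValueError(f"group {group}: fewer than 3 complete windows for {name}")
            x = pair.iloc[:, 0].to_numpy(float)
            y = pair.iloc[:, 1].to_numpy(float)
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"group": group, "pair": name, "r": r, "n_windows": len(pair)})
    return pd.DataFrame(rows)
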