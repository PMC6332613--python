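"""MAC summation, population z-scoring, windowing, and TVI profile assembly.

The Triple Variable Index (TVI) condenses three concurrently monitored
variables — mean arterial pressure (MAP, mmHg), bispectral index (BIS,
unitless 0–100), and total minimum alveolar concentration (MAC, summed
agent equivalents) — into one composite number per window of time:

    TVI(window) = mean z(MAP) + mean z(BIS) + mean z(MAC)

where z-scores are taken against the pooled mean and SD of each variable
over the entire study population (not per case). Windows are formed from
five consecutive distinct measurement timepoints (any variable, alone or in
combination); the final window of a case holds the 1–4 remaining
timepoints. A window lacking data for any of the three variables has, by
definition, no TVI value; no interpolation or carry-forward is ever
performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    AGENT_VARIABLES,
    ArtifactLimits,
    Variable,
    remove_artifacts,
    resolve_map_source,
)

__all__ = [
    "MacEquivalents",
    "PopulationStats",
    "Window",
    "TVIProfile",
    "FitError",
    "compute_total_mac",
    "summed_mac_frame",
    "prepare_streams",
    "fit_population_stats",
    "zscore",
    "add_zscores",
    "windows_frame",
    "build_windows",
    "compute_tvi",
    "assemble_profile",
    "assemble_profiles",
    "build_profiles",
    "profiles_to_frame",
    "temporal_proportion",
    "window_proportion",
    "ProfileResult",
]

#: The three z-scored variables entering the index.
TVI_VARIABLES = ("MAP", "BIS", "MAC")

DEFAULT_WINDOW_SIZE = 5


@dataclass(frozen=True)
class MacEquivalents:
    """Standard 1-MAC end-tidal concentrations (volume %) per inhaled agent.

    Total MAC at a timepoint is the sum over agents of concentration
    divided by that agent's 1-MAC equivalent. Summed MAC at or below
    ``negligible_threshold`` is treated as anesthetic-not-in-use. MAC is
    deliberately not age-adjusted.
    """

    isoflurane: float = 1.17
    desflurane: float = 6.6
    sevoflurane: float = 1.8
    nitrous_oxide: float = 105.0
    negligible_threshold: float = 0.001

    def __post_init__(self) -> None:
        for name in ("isoflurane", "desflurane", "sevoflurane", "nitrous_oxide"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MAC equivalent for {name} must be positive")

    def equivalent_for(self, agent: str) -> float:
        key = agent.lower()
        if not hasattr(self, key):
            raise KeyError(f"unknown inhaled agent {agent!r}")
        return float(getattr(self, key))


class FitError(ValueError):
    """Population statistics could not be fitted for a variable."""


@dataclass(frozen=True)
class VariableStats:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class PopulationStats:
    """Pooled per-variable mean/SD over the whole study population.

    The z-scoring reference: fitted once on the pooled, post-artifact-removal
    values of the entire dataset, never per case. SDs use the sample
    convention (divisor n−1).
    """

    per_variable: Mapping[str, VariableStats]

    def mean(self, variable: str) -> float:
        return self._get(variable).mean

    def sd(self, variable: str) -> float:
        return self._get(variable).sd

    def n(self, variable: str) -> int:
        return self._get(variable).n

    def _get(self, variable: str) -> VariableStats:
        try:
            return self.per_variable[variable]
        except KeyError:
            raise KeyError(f"no population stats for variable {variable!r}") from None


@dataclass(frozen=True)
class Window:
    """One profile window: up to five consecutive distinct timepoints.

    Carries both z-scale means (entering the TVI sum) and raw-scale means
    (used for threshold-based event criteria such as the triple low state).
    A variable's means are ``None`` when it has no value at any of the
    window's timepoints; ``tvi`` is present iff all three z-means are.
    """

    index: int
    timepoints: tuple[float, ...]
    map_mean_z: Optional[float] = None
    bis_mean_z: Optional[float] = None
    mac_mean_z: Optional[float] = None
    map_mean: Optional[float] = None
    bis_mean: Optional[float] = None
    mac_mean: Optional[float] = None
    tvi: Optional[float] = None

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)


@dataclass(frozen=True)
class TVIProfile:
    """A case's ordered sequence of windows across the monitoring period."""

    case_id: str
    windows: tuple[Window, ...]
    monitoring_span: tuple[float, float]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def tvi_values(self) -> np.ndarray:
        """Present TVI values in window order (missing windows skipped)."""
        return np.array([w.tvi for w in self.windows if w.tvi is not None], float)

    @property
    def n_tvi_values(self) -> int:
        return sum(1 for w in self.windows if w.tvi is not None)


def compute_total_mac(
    agent_values: Mapping[str, float], equivalents: MacEquivalents | None = None
) -> tuple[float, bool]:
    """Sum inhaled-agent concentrations into a total MAC value.

    Parameters
    ----------
    agent_values
        Mapping of agent name (``isoflurane``/``desflurane``/``sevoflurane``/
        ``nitrous_oxide``, case-insensitive; the measurement-variable
        spellings are accepted too) to end-tidal volume %.

    Returns
    -------
    ``(mac, negligible)`` where ``mac = Σ value_i / equivalent_i`` and
    ``negligible`` is True iff the sum does not exceed the threshold below
    which inhaled anesthetics are considered not in use.
    """
    equivalents = equivalents or MacEquivalents()
    total = 0.0
    for agent, value in agent_values.items():
        if value < 0:
            raise ValueError(f"negative concentration for {agent}: {value}")
        total += value / equivalents.equivalent_for(agent)
    return total, total <= equivalents.negligible_threshold


def summed_mac_frame(
    measurements: pd.DataFrame,
    equivalents: MacEquivalents | None = None,
    limits: ArtifactLimits | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert per-agent concentration rows into summed ``MAC`` rows.

    Agent concentrations recorded at the same ``(case_id, t_min)`` are
    summed in MAC-equivalent units. Summed values above the MAC artifact
    limit are removed; values at or below the negligible threshold are
    dropped as anesthetic-not-in-use. Returns ``(mac_rows, removed)`` where
    ``mac_rows`` has columns ``case_id,t_min,variable,value,source`` with
    ``variable == "MAC"`` and ``removed`` carries a ``reason`` column.
    """
    equivalents = equivalents or MacEquivalents()
    limits = limits or ArtifactLimits()
    agent_rows = measurements[measurements["variable"].isin(AGENT_VARIABLES)]
    if (agent_rows["value"] < 0).any():
        bad = agent_rows[agent_rows["value"] < 0].iloc[0]
        raise ValueError(
            f"negative agent concentration in case {bad['case_id']} at t={bad['t_min']}"
        )
    if agent_rows.empty:
        empty = pd.DataFrame(columns=["case_id", "t_min", "variable", "value", "source"])
        return empty, empty.assign(reason=pd.Series(dtype=object))

    equiv = agent_rows["variable"].map(
        {
            Variable.ISOFLURANE.value: equivalents.isoflurane,
            Variable.DESFLURANE.value: equivalents.desflurane,
            Variable.SEVOFLURANE.value: equivalents.sevoflurane,
            Variable.NITROUS_OXIDE.value: equivalents.nitrous_oxide,
        }
    )
    fractions = agent_rows.assign(frac=agent_rows["value"] / equiv)
    mac = (
        fractions.groupby(["case_id", "t_min"], sort=True)["frac"]
        .sum()
        .reset_index()
        .rename(columns={"frac": "value"})
    )
    mac["variable"] = "MAC"
    mac["source"] = "NA"
    mac = mac[["case_id", "t_min", "variable", "value", "source"]]

    negligible = mac["value"] <= equivalents.negligible_threshold
    too_high = mac["value"] > limits.mac_high
    removed = mac[negligible | too_high].reset_index(drop=True)
    removed["reason"] = np.where(
        removed["value"] > limits.mac_high, "MAC_above_limit", "MAC_negligible"
    )
    retained = mac[~(negligible | too_high)].reset_index(drop=True)
    return retained, removed


def prepare_streams(
    measurements: pd.DataFrame,
    limits: ArtifactLimits | None = None,
    equivalents: MacEquivalents | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pre-TVI filtering: source precedence, artifact removal, MAC summation.

    Returns ``(streams, audit)``: ``streams`` is the tidy frame of retained
    MAP/BIS/MAC rows sorted by ``(case_id, t_min)``, ``audit`` the removed
    rows with reasons.
    """
    limits = limits or ArtifactLimits()
    equivalents = equivalents or MacEquivalents()
    resolved = resolve_map_source(measurements)
    retained, removed = remove_artifacts(resolved, limits)
    mac_rows, mac_removed = summed_mac_frame(retained, equivalents, limits)
    base = retained[retained["variable"].isin({"MAP", "BIS"})]
    parts = [f for f in (base, mac_rows) if not f.empty]
    combined = pd.concat(parts, ignore_index=True) if parts else base
    streams = combined.sort_values(
        ["case_id", "t_min", "variable"], kind="mergesort"
    ).reset_index(drop=True)
    audit = pd.concat([removed, mac_removed], ignore_index=True)
    return streams, audit


def fit_population_stats(
    streams: pd.DataFrame, variables: Sequence[str] = TVI_VARIABLES
) -> PopulationStats:
    """Fit pooled mean/SD per variable over the entire dataset.

    Pooling is case-agnostic: every retained value of a variable, from every
    case, enters one mean and one sample SD (divisor n−1). Raises
    :class:`FitError` for a variable with fewer than two values or zero
    variance.
    """
    per: dict[str, VariableStats] = {}
    for var in variables:
        values = streams.loc[streams["variable"] == var, "value"].to_numpy(float)
        if values.size < 2:
            raise FitError(f"variable {var}: need at least 2 values, got {values.size}")
        sd = float(np.std(values, ddof=1))
        if sd == 0.0:
            raise FitError(f"variable {var}: zero variance, cannot z-score")
        per[var] = VariableStats(mean=float(np.mean(values)), sd=sd, n=int(values.size))
    return PopulationStats(per_variable=per)


def zscore(value, variable: str, stats: PopulationStats):
    """Z-score a value (or array) of one variable against population stats."""
    vs = stats.per_variable.get(variable)
    if vs is None:
        raise KeyError(f"no population stats for variable {variable!r}")
    return (np.asarray(value, float) - vs.mean) / vs.sd if np.ndim(value) else (
        float(value) - vs.mean
    ) / vs.sd


def add_zscores(streams: pd.DataFrame, stats: PopulationStats) -> pd.DataFrame:
    """Attach a ``z`` column to a tidy MAP/BIS/MAC frame."""
    out = streams.copy()
    z = np.full(len(out), np.nan)
    values = out["value"].to_numpy(float)
    for var, vs in stats.per_variable.items():
        mask = (out["variable"] == var).to_numpy()
        z[mask] = (values[mask] - vs.mean) / vs.sd
    out["z"] = z
    return out


def windows_frame(
    streams_z: pd.DataFrame, window_size: int = DEFAULT_WINDOW_SIZE
) -> pd.DataFrame:
    """Aggregate z-scored streams into non-overlapping windows, all cases at once.

    A timepoint is a distinct ``t_min`` within a case at which at least one
    of MAP/BIS/MAC exists; timepoints are grouped ``window_size`` at a time
    in chronological order, the final window holding the remainder.
    Per-variable window means are simple means over all of that variable's
    values at the window's timepoints (duplicates included).

    Returns one row per ``(case_id, window_index)`` with columns
    ``n_timepoints, t_start, t_end, {map,bis,mac}_mean_z, {map,bis,mac}_mean,
    tvi`` (NaN for absent values).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if streams_z.empty:
        raise ValueError("no measurements to window")
    d = streams_z.sort_values(["case_id", "t_min"], kind="mergesort").reset_index(
        drop=True
    )
    new_case = d["case_id"].ne(d["case_id"].shift())
    new_tp = new_case | d["t_min"].ne(d["t_min"].shift())
    tp_global = new_tp.cumsum()
    case_first_tp = tp_global.where(new_case).ffill()
    tp_index = (tp_global - case_first_tp).astype(int)
    d["window_index"] = tp_index // window_size
    d["_tp"] = tp_index

    per_var = (
        d.groupby(["case_id", "window_index", "variable"], sort=True)
        .agg(z_mean=("z", "mean"), raw_mean=("value", "mean"))
        .unstack("variable")
    )
    meta = d.groupby(["case_id", "window_index"], sort=True).agg(
        n_timepoints=("_tp", "nunique"), t_start=("t_min", "min"), t_end=("t_min", "max")
    )
    out = meta.copy()
    for var in TVI_VARIABLES:
        lo = var.lower()
        col_z = ("z_mean", var)
        col_r = ("raw_mean", var)
        out[f"{lo}_mean_z"] = per_var[col_z] if col_z in per_var.columns else np.nan
        out[f"{lo}_mean"] = per_var[col_r] if col_r in per_var.columns else np.nan
    zcols = [f"{v.lower()}_mean_z" for v in TVI_VARIABLES]
    complete = out[zcols].notna().all(axis=1)
    out["tvi"] = np.where(complete, out[zcols].sum(axis=1), np.nan)
    return out.reset_index()


def compute_tvi(window: Window) -> Optional[float]:
    """TVI of a window: the sum of its three per-variable z-means, if all present."""
    parts = (window.map_mean_z, window.bis_mean_z, window.mac_mean_z)
    if any(p is None for p in parts):
        return None
    return float(sum(parts))  # type: ignore[arg-type]


def _timepoints_by_window(
    streams: pd.DataFrame, window_size: int
) -> pd.Series:
    """Distinct timepoints of each (case, window), as tuples, all cases at once."""
    d = (
        streams[["case_id", "t_min"]]
        .drop_duplicates()
        .sort_values(["case_id", "t_min"], kind="mergesort")
    )
    window_index = d.groupby("case_id").cumcount() // window_size
    return d.groupby([d["case_id"], window_index.rename("window_index")])["t_min"].agg(
        tuple
    )


def _opt(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def _window_from_row(row, timepoints: tuple[float, ...]) -> Window:
    return Window(
        index=int(row.window_index),
        timepoints=timepoints,
        map_mean_z=_opt(row.map_mean_z),
        bis_mean_z=_opt(row.bis_mean_z),
        mac_mean_z=_opt(row.mac_mean_z),
        map_mean=_opt(row.map_mean),
        bis_mean=_opt(row.bis_mean),
        mac_mean=_opt(row.mac_mean),
        tvi=_opt(row.tvi),
    )


def build_windows(
    case_streams: pd.DataFrame,
    stats: PopulationStats,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> list[Window]:
    """Window one case's retained, MAC-summed streams.

    ``case_streams`` must hold a single case's tidy MAP/BIS/MAC rows (after
    artifact removal and MAC summation). Raises on an empty case.
    """
    if case_streams.empty:
        raise ValueError("cannot window an empty case")
    if case_streams["case_id"].nunique() != 1:
        raise ValueError("build_windows expects a single case")
    z = add_zscores(case_streams, stats)
    rows = windows_frame(z, window_size)
    tp_map = _timepoints_by_window(case_streams, window_size)
    return [
        _window_from_row(row, tp_map.loc[(row.case_id, row.window_index)])
        for row in rows.sort_values("window_index").itertuples()
    ]


def assemble_profile(
    case_id: str, windows: Sequence[Window], span: tuple[float, float]
) -> Optional[TVIProfile]:
    """Assemble a case's profile; ``None`` when no window has a TVI value.

    Mirrors the study-inclusion requirement of concurrent MAP/BIS/MAC
    monitoring: a case whose every window lacks a TVI value (for instance
    MAP-only monitoring) is excluded from the study set.
    """
    if not windows:
        return None
    if any(w.tvi is not None for w in windows):
        return TVIProfile(case_id=case_id, windows=tuple(windows), monitoring_span=span)
    return None


def assemble_profiles(
    windows: pd.DataFrame,
    streams: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> tuple[dict[str, TVIProfile], pd.DataFrame]:
    """Build profile objects for every case in a windows frame.

    Returns ``(profiles, exclusions)`` where ``exclusions`` lists cases
    dropped for lacking any computable TVI window (reason logged).
    """
    profiles: dict[str, TVIProfile] = {}
    excluded: list[dict] = []
    spans = streams.groupby("case_id")["t_min"].agg(["min", "max"])
    tp_map = _timepoints_by_window(streams, window_size)
    ordered = windows.sort_values(["case_id", "window_index"], kind="mergesort")
    for case_id, rows in ordered.groupby("case_id", sort=True):
        span = (float(spans.loc[case_id, "min"]), float(spans.loc[case_id, "max"]))
        wins = [
            _window_from_row(row, tp_map.loc[(case_id, row.window_index)])
            for row in rows.itertuples()
        ]
        profile = assemble_profile(str(case_id), wins, span)
        if profile is None:
            excluded.append({"case_id": case_id, "reason": "no_tvi_windows"})
        else:
            profiles[str(case_id)] = profile
    return profiles, pd.DataFrame(excluded, columns=["case_id", "reason"])


@dataclass
class ProfileResult:
    """Everything produced by the ingest-to-profiles pipeline stage."""

    profiles: dict[str, TVIProfile]
    windows: pd.DataFrame
    stats: PopulationStats
    streams: pd.DataFrame
    audit: pd.DataFrame
    exclusions: pd.DataFrame


def build_profiles(
    measurements: pd.DataFrame,
    limits: ArtifactLimits | None = None,
    equivalents: MacEquivalents | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
    stats: PopulationStats | None = None,
) -> ProfileResult:
    """Run the full measurement→profile pipeline over a cohort.

    Filtering (MAP source precedence, artifact limits), MAC summation,
    population z-scoring (fitted over the pooled retained values unless
    ``stats`` is supplied), windowing, and profile assembly.
    """
    streams, audit = prepare_streams(measurements, limits, equivalents)
    if streams.empty:
        raise ValueError("no retained measurements after filtering")
    if stats is None:
        # z-score only variables the cohort actually carries; a variable
        # absent everywhere simply yields no TVI windows, and the affected
        # cases fall out at assembly with a logged reason
        present = [
            v
            for v in TVI_VARIABLES
            if (streams["variable"] == v).sum() >= 2
            and streams.loc[streams["variable"] == v, "value"].nunique() > 1
        ]
        if not present:
            raise FitError("no variable has enough values to z-score")
        fitted = fit_population_stats(streams, variables=present)
    else:
        fitted = stats
    z = add_zscores(streams, fitted)
    wins = windows_frame(z, window_size)
    profiles, exclusions = assemble_profiles(wins, streams, window_size)
    keep = wins["case_id"].isin(profiles.keys())
    return ProfileResult(
        profiles=profiles,
        windows=wins[keep].reset_index(drop=True),
        stats=fitted,
        streams=streams,
        audit=audit,
        exclusions=exclusions,
    )


def profiles_to_frame(profiles: Mapping[str, TVIProfile]) -> pd.DataFrame:
    """Export profiles as the tidy profile-matrix CSV layout.

    Columns: ``case_id, window_index, n_timepoints, t_start, t_end,
    map_mean_z, bis_mean_z, mac_mean_z, map_mean, bis_mean, mac_mean, tvi``
    with empty cells for absent values.
    """
    rows = []
    for case_id in sorted(profiles):
        p = profiles[case_id]
        for w in p.windows:
            rows.append(
                {
                    "case_id": case_id,
                    "window_index": w.index,
                    "n_timepoints": w.n_timepoints,
                    "t_start": w.timepoints[0],
                    "t_end": w.timepoints[-1],
                    "map_mean_z": w.map_mean_z,
                    "bis_mean_z": w.bis_mean_z,
                    "mac_mean_z": w.mac_mean_z,
                    "map_mean": w.map_mean,
                    "bis_mean": w.bis_mean,
                    "mac_mean": w.mac_mean,
                    "tvi": w.tvi,
                }
            )
    return pd.DataFrame(rows)


def temporal_proportion(t: float, span: tuple[float, float]) -> float:
    """Position of time ``t`` as a proportion of the monitoring period.

    With a span of ``[t_first, t_last]``, returns
    ``(t − t_first) / (t_last − t_first)`` — e.g. minute 6 of a 60-minute
    monitoring period maps to 0.10. Monotone increasing in ``t``.
    """
    t_first, t_last = span
    if not t_last > t_first:
        raise ValueError(f"zero- or negative-length span {span}")
    if t < t_first or t > t_last:
        raise ValueError(f"t={t} outside span {span}")
    return (t - t_first) / (t_last - t_first)


def window_proportion(index: int, n_windows: int) -> float:
    """Position of window ``index`` as a proportion of a profile's windows.

    Uses ``index / (n_windows − 1)`` so the first window maps to 0.0 and the
    last to 1.0, matching the endpoints of the measurement-level convention;
    a single-window profile maps to 0.0.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if not 0 <= index < n_windows:
        raise ValueError(f"window index {index} outside [0, {n_windows})")
    if n_windows == 1:
        return 0.0
    return index / (n_windows - 1)
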