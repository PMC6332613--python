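"""Domain types, CSV ingest, and artifact filtering for intraoperative monitoring data.

The ingest dialect is long-format CSV: one row per recorded value of one
monitored variable (mean arterial pressure, bispectral index, or an inhaled
anesthetic's end-tidal concentration) in one surgical case. Timestamps are
minutes from the case's first recorded measurement. All downstream
computation (MAC summation, z-scoring, windowing) consumes the tidy frames
produced here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Variable",
    "Source",
    "Measurement",
    "ArtifactLimits",
    "SchemaError",
    "RowParseError",
    "AGENT_VARIABLES",
    "MEASUREMENT_COLUMNS",
    "CASE_COLUMNS",
    "read_measurements",
    "read_cases",
    "read_medications",
    "resolve_map_source",
    "remove_artifacts",
    "write_audit_log",
]

#: Reader rounding precision for timestamps: one second, in minutes.
DEFAULT_TIME_PRECISION_MIN = 1.0 / 60.0


class Variable(str, enum.Enum):
    """Monitored variables accepted in the measurements CSV."""

    MAP = "MAP"
    BIS = "BIS"
    ISOFLURANE = "ISOFLURANE"
    DESFLURANE = "DESFLURANE"
    SEVOFLURANE = "SEVOFLURANE"
    NITROUS_OXIDE = "NITROUS_OXIDE"


#: Inhaled-agent variables, whose values are end-tidal volume percent.
AGENT_VARIABLES = frozenset(
    {
        Variable.ISOFLURANE.value,
        Variable.DESFLURANE.value,
        Variable.SEVOFLURANE.value,
        Variable.NITROUS_OXIDE.value,
    }
)


class Source(str, enum.Enum):
    """Provenance of a MAP value; ``NA`` for every non-MAP variable."""

    NONINVASIVE = "NONINVASIVE"
    ARTERIAL = "ARTERIAL"
    NA = "NA"


@dataclass(frozen=True)
class Measurement:
    """One timestamped value of one monitored variable in one case."""

    case_id: str
    t_min: float
    variable: Variable
    value: float
    source: Source = Source.NA

    def __post_init__(self) -> None:
        if self.t_min < 0:
            raise ValueError(f"t_min must be non-negative, got {self.t_min}")
        if not np.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value}")
        is_map = self.variable == Variable.MAP
        if is_map and self.source == Source.NA:
            raise ValueError("MAP measurements require a NONINVASIVE or ARTERIAL source")
        if not is_map and self.source != Source.NA:
            raise ValueError(f"source is meaningful only for MAP, got {self.source}")


@dataclass(frozen=True)
class ArtifactLimits:
    """Physiologic plausibility limits; values strictly outside are artifacts.

    Boundary values (e.g. MAP exactly 10 or 250 mmHg) are retained: the
    limits express strict exclusion (greater-than / less-than).
    """

    map_low: float = 10.0
    map_high: float = 250.0
    bis_low: float = 1.0
    bis_high: float = 100.0
    mac_high: float = 3.0

    def __post_init__(self) -> None:
        for name in ("map_low", "map_high", "bis_low", "bis_high", "mac_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.map_low >= self.map_high:
            raise ValueError("map_low must be below map_high")
        if self.bis_low >= self.bis_high:
            raise ValueError("bis_low must be below bis_high")


class SchemaError(ValueError):
    """A CSV is missing required columns or has an unusable layout."""


class RowParseError(ValueError):
    """A CSV row could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


MEASUREMENT_COLUMNS = ["case_id", "t_min", "variable", "value", "source"]
CASE_COLUMNS = [
    "case_id",
    "patient_id",
    "age_years",
    "sex",
    "asa_status",
    "emergent",
    "specialty",
    "procedure",
    "cpb_used",
    "cpb_start_min",
    "cpb_end_min",
    "repeat_surgery",
    "days_to_death",
]
MEDICATION_COLUMNS = ["case_id", "drug", "total_dose"]

_VALID_VARIABLES = frozenset(v.value for v in Variable)
_VALID_SOURCES = frozenset(s.value for s in Source)


def _require_columns(frame: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} CSV is missing required column(s): {missing}")


def read_measurements(
    path, time_precision_min: float = DEFAULT_TIME_PRECISION_MIN
) -> pd.DataFrame:
    """Read a long-format measurements CSV into a validated tidy frame.

    Parameters
    ----------
    path
        CSV with header columns ``case_id,t_min,variable,value,source``
        (``source`` may be empty for non-MAP rows).
    time_precision_min
        Timestamps are rounded to this precision (default: one second) so
        that "simultaneous" recordings compare equal.

    Returns
    -------
    DataFrame sorted by ``(case_id, t_min)`` with string ``case_id``,
    float ``t_min``/``value``, and categorical-checked ``variable``/``source``.
    """
    frame = pd.read_csv(path, dtype={"case_id": str, "variable": str, "source": str})
    _require_columns(frame, MEASUREMENT_COLUMNS, "measurements")
    frame = frame[MEASUREMENT_COLUMNS].copy()

    bad_var = ~frame["variable"].isin(_VALID_VARIABLES)
    if bad_var.any():
        row = int(frame.index[bad_var][0])
        raise RowParseError(
            f"unknown variable {frame.loc[row, 'variable']!r}", row
        )

    values = pd.to_numeric(frame["value"], errors="coerce")
    bad_val = values.isna() | ~np.isfinite(values)
    if bad_val.any():
        row = int(frame.index[bad_val][0])
        raise RowParseError(f"non-numeric value {frame.loc[row, 'value']!r}", row)
    frame["value"] = values.astype(float)

    t = pd.to_numeric(frame["t_min"], errors="coerce")
    bad_t = t.isna() | (t < 0)
    if bad_t.any():
        row = int(frame.index[bad_t][0])
        raise RowParseError(f"invalid t_min {frame.loc[row, 't_min']!r}", row)
    if time_precision_min and time_precision_min > 0:
        t = np.round(t / time_precision_min) * time_precision_min
    frame["t_min"] = t.astype(float)

    frame["source"] = frame["source"].fillna(Source.NA.value)
    bad_src = ~frame["source"].isin(_VALID_SOURCES)
    if bad_src.any():
        row = int(frame.index[bad_src][0])
        raise RowParseError(f"unknown source {frame.loc[row, 'source']!r}", row)
    is_map = frame["variable"] == Variable.MAP.value
    if ((frame["source"] == Source.NA.value) & is_map).any():
        row = int(frame.index[(frame["source"] == Source.NA.value) & is_map][0])
        raise RowParseError("MAP row lacks a source", row)
    if ((frame["source"] != Source.NA.value) & ~is_map).any():
        row = int(frame.index[(frame["source"] != Source.NA.value) & ~is_map][0])
        raise RowParseError("non-MAP row carries a MAP source", row)

    return frame.sort_values(["case_id", "t_min"], kind="mergesort").reset_index(
        drop=True
    )


def read_cases(path) -> pd.DataFrame:
    """Read the per-case metadata CSV.

    ``days_to_death`` and the CPB interval are nullable; an optional
    ``follow_up_days`` column (days of post-surgical follow-up for
    survivors) is carried through when present.
    """
    frame = pd.read_csv(path, dtype={"case_id": str, "patient_id": str})
    _require_columns(frame, CASE_COLUMNS, "cases")
    for col in ("emergent", "cpb_used", "repeat_surgery"):
        frame[col] = frame[col].astype(bool)
    frame["days_to_death"] = pd.to_numeric(
        frame["days_to_death"], errors="coerce"
    ).astype("Int64")
    if "follow_up_days" in frame.columns:
        frame["follow_up_days"] = pd.to_numeric(
            frame["follow_up_days"], errors="coerce"
        ).astype("Int64")
    else:
        frame["follow_up_days"] = pd.array([pd.NA] * len(frame), dtype="Int64")
    bad_cpb = frame["cpb_used"] & (
        frame["cpb_start_min"].isna() | frame["cpb_end_min"].isna()
    )
    if bad_cpb.any():
        raise SchemaError(
            f"cases with cpb_used but no interval: {list(frame.loc[bad_cpb, 'case_id'])}"
        )
    orphan = ~frame["cpb_used"] & (
        frame["cpb_start_min"].notna() | frame["cpb_end_min"].notna()
    )
    if orphan.any():
        raise SchemaError(
            f"cases with a CPB interval but cpb_used=False: {list(frame.loc[orphan, 'case_id'])}"
        )
    return frame.reset_index(drop=True)


def read_medications(path) -> pd.DataFrame:
    """Read the per-case medication totals CSV (``case_id,drug,total_dose``)."""
    frame = pd.read_csv(path, dtype={"case_id": str, "drug": str})
    _require_columns(frame, MEDICATION_COLUMNS, "medications")
    frame["total_dose"] = pd.to_numeric(frame["total_dose"], errors="coerce")
    if frame["total_dose"].isna().any() or (frame["total_dose"] < 0).any():
        raise SchemaError("medication total_dose must be numeric and non-negative")
    return frame.reset_index(drop=True)


def resolve_map_source(measurements: pd.DataFrame) -> pd.DataFrame:
    """Prefer arterial-line MAP over noninvasive cuff MAP at shared timestamps.

    At any ``(case_id, t_min)`` where both an ARTERIAL and a NONINVASIVE MAP
    value exist, only the arterial value(s) are retained. Lone values of
    either source pass through, as do duplicate same-source values. Never
    increases the number of rows.
    """
    is_map = measurements["variable"] == Variable.MAP.value
    if not is_map.any():
        return measurements
    map_rows = measurements[is_map]
    has_arterial = (
        map_rows["source"]
        .eq(Source.ARTERIAL.value)
        .groupby([map_rows["case_id"], map_rows["t_min"]])
        .transform("any")
    )
    drop = is_map.copy()
    drop.loc[is_map] = has_arterial & (map_rows["source"] == Source.NONINVASIVE.value)
    return measurements[~drop].reset_index(drop=True)


def remove_artifacts(
    measurements: pd.DataFrame, limits: ArtifactLimits | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split measurements into physiologically plausible and artifactual rows.

    MAP is retained iff ``map_low <= value <= map_high``; BIS iff
    ``bis_low <= value <= bis_high`` (a BIS of zero, a monitor on/off
    artifact, falls below ``bis_low`` and is removed). Rows of a summed
    ``MAC`` variable, when present, are retained iff ``value <= mac_high``;
    per-agent concentrations are never bounded here — the MAC limit applies
    to the summed value after MAC calculation.

    Returns ``(retained, removed)``; ``removed`` carries a ``reason``
    column for audit logging. The operation is a partition (conservation)
    and is idempotent.
    """
    limits = limits or ArtifactLimits()
    var = measurements["variable"]
    value = measurements["value"]
    reason = pd.Series("", index=measurements.index, dtype=object)

    bad_map = (var == Variable.MAP.value) & (
        (value < limits.map_low) | (value > limits.map_high)
    )
    reason[bad_map] = "MAP_out_of_range"
    bad_bis = (var == Variable.BIS.value) & (
        (value < limits.bis_low) | (value > limits.bis_high)
    )
    reason[bad_bis] = "BIS_out_of_range"
    bad_mac = (var == "MAC") & (value > limits.mac_high)
    reason[bad_mac] = "MAC_above_limit"

    removed_mask = bad_map | bad_bis | bad_mac
    retained = measurements[~removed_mask].reset_index(drop=True)
    removed = measurements[removed_mask].reset_index(drop=True)
    removed["reason"] = reason[removed_mask].to_numpy()
    return retained, removed


def write_audit_log(removed: pd.DataFrame, path) -> None:
    """Write removed-artifact rows (with their ``reason``) as CSV."""
    removed.to_csv(path, index=False)
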