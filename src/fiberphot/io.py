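"""Readers, writers and validated in-memory containers.

Traces travel as CSV (``time_s``, ``fluorescence_au``) with a JSON sidecar
carrying the sampling rate and session metadata; event schedules as CSV
(``time_s``, ``event_type``, ``value``); cohort summary tables as long-format
CSV. All text files are UTF-8 with "." as the decimal separator. Readers
validate eagerly and never silently coerce missing values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "GROUPS",
    "TIMEPOINTS",
    "TraceMeta",
    "RawTrace",
    "Event",
    "EventSchedule",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "write_results",
]

#: Closed vocabulary of event types understood by the pipeline.
EVENT_TYPES = frozenset(
    {
        "stimulus_onset",
        "infusion_start",
        "infusion_end",
        "injection",
        "door_open",
        "pellet_delivery",
        "pellet_removal",
    }
)

#: Closed vocabularies for cohort factors; validated at read time so that a
#: typo in a factor level fails loudly instead of becoming a spurious ANOVA cell.
GROUPS = ("lean", "DIO")
TIMEPOINTS = ("baseline", "wk6", "wk10")

# Relative tolerance on sample spacing vs 1/sample_rate.
_SPACING_RTOL = 1e-4


@dataclass
class TraceMeta:
    """Session metadata attached to every trace."""

    mouse_id: str = "m00"
    session_id: str = "s00"
    stimulus: str = "sensory"
    trial: int = 0
    group: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )


@dataclass
class RawTrace:
    """Uniformly sampled fluorescence time series.

    Attributes
    ----------
    time : array of float
        Sample times in seconds, strictly increasing, uniform spacing.
    fluorescence : array of float
        Fluorescence in arbitrary units, same length as ``time``.
    sample_rate : float
        Sampling rate in Hz; spacing must agree with ``1/sample_rate``
        to within 1 part in 10^4.
    meta : TraceMeta
    """

    time: np.ndarray
    fluorescence: np.ndarray
    sample_rate: float
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.fluorescence.ndim != 1:
            raise ValueError("time and fluorescence must be 1-D")
        if self.time.size != self.fluorescence.size:
            raise ValueError("time and fluorescence lengths differ")
        if self.time.size < 2:
            raise ValueError("trace must contain at least 2 samples")
        if not np.all(np.isfinite(self.time)) or not np.all(
            np.isfinite(self.fluorescence)
        ):
            raise ValueError("trace contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        _check_uniform(self.time, self.sample_rate)

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def _check_uniform(time: np.ndarray, sample_rate: float) -> None:
    dt_nominal = 1.0 / sample_rate
    dt = np.diff(time)
    bad = np.flatnonzero(np.abs(dt - dt_nominal) > _SPACING_RTOL * dt_nominal)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"nonuniform sampling at index {i}: interval {dt[i]:.6g} s vs "
            f"nominal {dt_nominal:.6g} s (tolerance {_SPACING_RTOL:g} relative)"
        )


@dataclass(frozen=True)
class Event:
    time_s: float
    event_type: str
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"unknown event_type {self.event_type!r}; expected one of "
                f"{sorted(EVENT_TYPES)}"
            )


@dataclass
class EventSchedule:
    """Ordered, typed event log for one session.

    ``drop_count`` records the number of pellets found dropped at the end of
    the session (used by behavioral scoring).
    """

    events: list[Event] = field(default_factory=list)
    drop_count: int = 0

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be nondecreasing")
        if self.drop_count < 0:
            raise ValueError("drop_count must be >= 0")
        starts = [e.time_s for e in self.events if e.event_type == "infusion_start"]
        ends = [e.time_s for e in self.events if e.event_type == "infusion_end"]
        for s, e in zip(starts, ends):
            if e <= s:
                raise ValueError("infusion_start must precede infusion_end")

    def of_type(self, event_type: str) -> list[Event]:
        if event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {event_type!r}")
        return [e for e in self.events if e.event_type == event_type]

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# traces


def _default_sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: RawTrace, path, sidecar=None, overwrite: bool = False) -> None:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _default_sidecar(path)
    for p in (path, sidecar):
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
    df = pd.DataFrame({"time_s": trace.time, "fluorescence_au": trace.fluorescence})
    df.to_csv(path, index=False)
    meta = {"sample_rate": trace.sample_rate, "meta": asdict(trace.meta)}
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_trace(path, sidecar=None) -> RawTrace:
    """Read a trace CSV plus its JSON sidecar and validate uniform sampling."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _default_sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} not found (carries sample_rate)")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trace file") from None
    for col in ("time_s", "fluorescence_au"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ValueError(f"{path}: no samples")
    if df[["time_s", "fluorescence_au"]].isna().any().any():
        raise ValueError(f"{path}: missing values present; refusing to coerce")
    info = json.loads(sidecar.read_text())
    meta = TraceMeta(**info.get("meta", {}))
    return RawTrace(
        time=df["time_s"].to_numpy(),
        fluorescence=df["fluorescence_au"].to_numpy(),
        sample_rate=float(info["sample_rate"]),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# events

_DROP_SENTINEL = "drop_count"


def write_events(schedule: EventSchedule, path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    rows = [(e.time_s, e.event_type, e.value) for e in schedule.events]
    # end-of-session drop count stored as a sentinel row
    last_t = rows[-1][0] if rows else 0.0
    rows.append((last_t, _DROP_SENTINEL, float(schedule.drop_count)))
    pd.DataFrame(rows, columns=["time_s", "event_type", "value"]).to_csv(
        path, index=False
    )


def read_events(path) -> EventSchedule:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty event file") from None
    for col in ("time_s", "event_type", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df[["time_s", "event_type"]].isna().any().any():
        raise ValueError(f"{path}: missing values present; refusing to coerce")
    drop_count = 0
    events = []
    for row in df.itertuples(index=False):
        if row.event_type == _DROP_SENTINEL:
            drop_count = int(row.value)
        else:
            events.append(Event(float(row.time_s), str(row.event_type), float(row.value)))
    return EventSchedule(events=events, drop_count=drop_count)


# ---------------------------------------------------------------------------
# cohort tables

_COHORT_COLUMNS = ["mouse_id", "group", "timepoint", "measure", "value"]


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format cohort table (one row per mouse x timepoint x measure)."""
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if df.empty:
        raise ValueError("cohort table is empty")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}")
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoint labels {sorted(bad_tp)}")
    values = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cohort values must be finite")
    dup = df.duplicated(subset=["mouse_id", "timepoint", "measure"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate cohort row (trials must be averaged first): "
            f"mouse {first['mouse_id']!r}, timepoint {first['timepoint']!r}, "
            f"measure {first['measure']!r}"
        )
    return df[_COHORT_COLUMNS].copy()


def write_cohort(df: pd.DataFrame, path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    out = validate_cohort(df)
    out = out.sort_values(["measure", "group", "mouse_id", "timepoint"], kind="stable")
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty cohort file") from None
    if df[[c for c in _COHORT_COLUMNS if c in df.columns]].isna().any().any():
        raise ValueError(f"{path}: missing values present; refusing to coerce")
    return validate_cohort(df)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_results(cohort: pd.DataFrame, stats: dict, out_dir, overwrite: bool = False):
    """Write the cohort CSV and a JSON file of inference results.

    ``stats`` may contain result objects exposing ``to_dict`` (AnovaResult,
    ComparisonSet, ...) or plain JSON-serializable values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_path = out_dir / "cohort.csv"
    stats_path = out_dir / "stats.json"
    if not stats:
        raise ValueError("no statistics results to write")
    write_cohort(cohort, cohort_path, overwrite=overwrite)
    if stats_path.exists() and not overwrite:
        raise FileExistsError(f"{stats_path} exists; pass overwrite=True to replace")
    stats_path.write_text(json.dumps(_jsonable(stats), indent=1, sort_keys=True))
    return cohort_path, stats_path
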