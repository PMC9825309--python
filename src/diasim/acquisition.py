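"""DIA windowing schemes and scan-event scheduling.

A duty cycle is an ordered list of scan-event templates (one or more MS1
surveys plus a set of MS2 isolation windows, each with its own duration).
The default scheme is a single MS1 event followed by contiguous fixed-width,
non-overlapping windows; arbitrary schemes — variable-width, overlapping, or
staggered (expressed as two offset window sets in one long cycle) — can be
read from a 4-column CSV acquisition-schema file.

Isolation windows are half-open ``[lower, upper)`` so that in the default
scheme every precursor m/z falls in exactly one window.
"""

from __future__ import annotations

import csv
import gzip
import math
from dataclasses import dataclass
from pathlib import Path

from .chromatography import ElutionProfile, profile_support

__all__ = [
    "IsolationWindow",
    "ScanEventTemplate",
    "AcquisitionSchema",
    "ScanEvent",
    "default_schema",
    "read_schema",
    "schedule_run",
    "expected_points_per_peak",
]


class SchemaError(ValueError):
    """Raised for invalid window definitions or schema files."""


@dataclass(frozen=True)
class IsolationWindow:
    lower_mz: float
    upper_mz: float

    def __post_init__(self) -> None:
        if self.lower_mz >= self.upper_mz:
            raise SchemaError(
                f"isolation window lower {self.lower_mz} >= upper {self.upper_mz}"
            )

    @property
    def target_mz(self) -> float:
        return 0.5 * (self.lower_mz + self.upper_mz)

    def contains(self, mz: float) -> bool:
        """Half-open containment: lower <= mz < upper."""
        return self.lower_mz <= mz < self.upper_mz


@dataclass(frozen=True)
class ScanEventTemplate:
    ms_level: int
    duration: float
    window: IsolationWindow | None = None

    def __post_init__(self) -> None:
        if self.ms_level not in (1, 2):
            raise SchemaError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.duration <= 0:
            raise SchemaError(f"event duration must be > 0, got {self.duration}")
        if self.ms_level == 2 and self.window is None:
            raise SchemaError("MS2 event requires an isolation window")
        if self.ms_level == 1 and self.window is not None:
            raise SchemaError("MS1 event must not carry an isolation window")


@dataclass(frozen=True)
class AcquisitionSchema:
    """One duty cycle: the ordered scan events repeated through the run."""

    events: tuple[ScanEventTemplate, ...]

    def __post_init__(self) -> None:
        if not any(e.ms_level == 1 for e in self.events):
            raise SchemaError("schema must contain at least one MS1 event")

    @property
    def cycle_time(self) -> float:
        return sum(e.duration for e in self.events)

    @property
    def windows(self) -> list[IsolationWindow]:
        return [e.window for e in self.events if e.ms_level == 2]

    def n_events(self, ms_level: int) -> int:
        return sum(1 for e in self.events if e.ms_level == ms_level)


@dataclass(frozen=True)
class ScanEvent:
    """One concrete scan in the scheduled run."""

    index: int
    start_time: float
    ms_level: int
    window: IsolationWindow | None = None


def default_schema(
    mz_min: float,
    mz_max: float,
    window_width: float,
    ms1_duration: float = 0.05,
    ms2_duration: float = 0.02,
) -> AcquisitionSchema:
    """Fixed-width, non-overlapping DIA windows covering [mz_min, mz_max].

    One MS1 survey scan is followed by ``ceil((mz_max - mz_min) / width)``
    contiguous windows; the last window is truncated at ``mz_max``.
    """
    if mz_max <= mz_min:
        raise SchemaError(f"mz_max {mz_max} must exceed mz_min {mz_min}")
    if window_width <= 0:
        raise SchemaError(f"window_width must be > 0, got {window_width}")
    events: list[ScanEventTemplate] = [ScanEventTemplate(1, ms1_duration)]
    n_windows = math.ceil((mz_max - mz_min) / window_width)
    # one shared edge sequence so adjacent windows share boundaries exactly
    edges = [min(mz_min + i * window_width, mz_max) for i in range(n_windows)]
    edges.append(mz_max)
    for lower, upper in zip(edges, edges[1:]):
        if lower >= upper:  # last edge already clamped at mz_max
            continue
        events.append(
            ScanEventTemplate(2, ms2_duration, IsolationWindow(lower, upper))
        )
    return AcquisitionSchema(tuple(events))


def read_schema(path: str | Path) -> AcquisitionSchema:
    """Read a duty cycle from a CSV acquisition-schema file.

    Columns: ``ms_level, mz_lower, mz_upper, duration_s``; the m/z fields are
    left empty on MS1 rows.  Rows become scan events in file order, so
    overlapping, variable-width and staggered window sets are expressed
    directly.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    events: list[ScanEventTemplate] = []
    with opener(path, "rt", newline="") as handle:
        reader = csv.DictReader(handle)
        required = {"ms_level", "mz_lower", "mz_upper", "duration_s"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"schema file missing columns: {sorted(missing)}")
        for row_number, row in enumerate(reader, start=2):
            level = int(row["ms_level"])
            duration = float(row["duration_s"])
            if level == 1:
                events.append(ScanEventTemplate(1, duration))
                continue
            try:
                lower = float(row["mz_lower"])
                upper = float(row["mz_upper"])
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"row {row_number}: invalid m/z bounds") from exc
            if lower >= upper:
                raise SchemaError(
                    f"row {row_number}: mz_lower {lower} >= mz_upper {upper}"
                )
            events.append(ScanEventTemplate(2, duration, IsolationWindow(lower, upper)))
    if not events:
        raise SchemaError(f"empty acquisition schema file: {path}")
    return AcquisitionSchema(tuple(events))


def schedule_run(schema: AcquisitionSchema, run_length: float) -> list[ScanEvent]:
    """Repeat the duty cycle from t=0, keeping every event that finishes by
    ``run_length`` (with a 1 ns float tolerance)."""
    if run_length < schema.cycle_time:
        raise SchemaError(
            f"run_length {run_length} shorter than one duty cycle "
            f"({schema.cycle_time})"
        )
    offsets = []
    acc = 0.0
    for event in schema.events:
        offsets.append(acc)
        acc += event.duration
    cycle = schema.cycle_time
    events: list[ScanEvent] = []
    index = 0
    cycle_index = 0
    tol = 1e-9
    while True:
        cycle_start = cycle_index * cycle
        if cycle_start + cycle <= run_length + tol:
            for template, offset in zip(schema.events, offsets):
                events.append(
                    ScanEvent(index, cycle_start + offset, template.ms_level, template.window)
                )
                index += 1
            cycle_index += 1
        else:
            for template, offset in zip(schema.events, offsets):
                start = cycle_start + offset
                if start + template.duration > run_length + tol:
                    return events
                events.append(ScanEvent(index, start, template.ms_level, template.window))
                index += 1
            return events


def expected_points_per_peak(
    schema: AcquisitionSchema, profile: ElutionProfile
) -> dict[int, float]:
    """FWHM-based points-per-peak estimate, per MS level.

    A chromatographic peak of full width at half maximum ``w`` sampled once
    per duty cycle yields ``w / cycle_time`` points above half height.  MS1
    is sampled ``n_ms1`` times per cycle; each MS2 window is normally
    sampled once per cycle (staggered schemes listing a window twice per
    cycle double its rate — use the per-window repeat count accordingly).
    """
    t_start, t_end = profile_support(profile, 0.5)
    fwhm = t_end - t_start
    cycle = schema.cycle_time
    ppp = {1: fwhm * schema.n_events(1) / cycle}
    if schema.n_events(2):
        repeats: dict[tuple[float, float], int] = {}
        for window in schema.windows:
            key = (window.lower_mz, window.upper_mz)
            repeats[key] = repeats.get(key, 0) + 1
        ppp[2] = fwhm * max(repeats.values()) / cycle
    return ppp
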