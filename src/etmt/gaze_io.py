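"""Gaze-recording data model and I/O.

A trial is one participant viewing one trail-making stimulus while an eye
tracker samples gaze position (here at 60 Hz).  Raw samples are grouped per
(participant, stimulus) into :class:`TrialRecord` objects; fixations — periods
of stable gaze — are either supplied in a pre-detected table or derived with
the dispersion-threshold (I-DT) detector in :func:`detect_fixations`.

Timestamps are milliseconds from trial start; coordinates are screen pixels
with the origin at the top-left and y increasing downward.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

# Default gaze-log dialect.  Vendor exports vary; the column map is
# overridable through GazeDialect.
GAZE_COLUMNS = ("participant", "stimulus", "timestamp_ms", "x_px", "y_px",
                "pupil_mm", "valid")
REQUIRED_GAZE_COLUMNS = ("participant", "stimulus", "timestamp_ms", "x_px", "y_px")

DEFAULT_DISPERSION_PX = 50.0
DEFAULT_MIN_DURATION_MS = 100.0


class GazeFormatError(ValueError):
    """Raised for malformed gaze logs (missing columns, bad rows)."""


@dataclass(frozen=True)
class GazeSample:
    """One timestamped gaze coordinate.

    ``pupil_diameter`` is in millimeters and may be ``None``; ``valid`` is the
    tracker's quality flag — invalid samples are retained but never contribute
    to fixations.
    """

    timestamp: float          # ms from trial start
    stimulus_id: str
    x: float
    y: float
    pupil_diameter: float | None = None
    valid: bool = True


@dataclass(frozen=True)
class Fixation:
    """A stable-gaze event: onset/duration in ms, centroid in pixels."""

    onset: float
    duration: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")
        if self.onset < 0:
            raise ValueError("fixation onset must be non-negative")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class TrialRecord:
    """All samples (and optionally fixations) of one participant on one stimulus."""

    participant_id: str
    stimulus_id: str
    samples: list[GazeSample] = field(default_factory=list)
    fixations: list[Fixation] = field(default_factory=list)
    trial_start: float = 0.0
    trial_end: float = 0.0

    @property
    def duration(self) -> float:
        return self.trial_end - self.trial_start


@dataclass(frozen=True)
class GazeDialect:
    """Delimiter and column naming of a gaze-log export."""

    delimiter: str = ","
    columns: dict[str, str] = field(default_factory=dict)  # canonical -> file header

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def read_gaze_log(path: str | Path, dialect: GazeDialect | None = None) -> list[TrialRecord]:
    """Parse a delimited gaze log into one :class:`TrialRecord` per
    (participant, stimulus) group, samples sorted by timestamp.

    Raises :class:`GazeFormatError` naming the column if a required column is
    missing, or naming the line if a valid row has a non-numeric coordinate.
    """
    dialect = dialect or GazeDialect()
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for canonical in REQUIRED_GAZE_COLUMNS:
        if dialect.resolve(canonical) not in df.columns:
            raise GazeFormatError(
                f"{path}: missing required column {dialect.resolve(canonical)!r}")

    col = dialect.resolve
    has_pupil = col("pupil_mm") in df.columns
    has_valid = col("valid") in df.columns

    trials: dict[tuple[str, str], TrialRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        valid = _parse_bool(rec[col("valid")]) if has_valid else True
        try:
            ts = float(rec[col("timestamp_ms")])
            x = float(rec[col("x_px")]) if rec[col("x_px")] != "" else math.nan
            y = float(rec[col("y_px")]) if rec[col("y_px")] != "" else math.nan
        except ValueError as exc:
            raise GazeFormatError(f"{path}: line {i + 2}: non-numeric value ({exc})") from exc
        if valid and not (math.isfinite(x) and math.isfinite(y)):
            raise GazeFormatError(f"{path}: line {i + 2}: non-finite coordinate on valid row")
        pupil = None
        if has_pupil and rec[col("pupil_mm")] not in ("", "NA", "nan"):
            pupil = float(rec[col("pupil_mm")])
        key = (str(rec[col("participant")]), str(rec[col("stimulus")]))
        trial = trials.setdefault(key, TrialRecord(participant_id=key[0], stimulus_id=key[1]))
        trial.samples.append(GazeSample(ts, key[1], x, y, pupil, valid))

    out = []
    for trial in trials.values():
        trial.samples.sort(key=lambda s: s.timestamp)
        trial.trial_start = trial.samples[0].timestamp
        trial.trial_end = trial.samples[-1].timestamp
        out.append(trial)
    return out


def write_gaze_log(trials: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trials in the default CSV dialect (round-trips with the reader)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(GAZE_COLUMNS)
        for t in trials:
            for s in t.samples:
                w.writerow([t.participant_id, t.stimulus_id, _fmt(s.timestamp),
                            _fmt(s.x), _fmt(s.y),
                            "" if s.pupil_diameter is None else _fmt(s.pupil_diameter),
                            int(s.valid)])


def read_fixation_table(path: str | Path) -> dict[tuple[str, str], list[Fixation]]:
    """Read a pre-detected fixation CSV keyed by (participant, stimulus)."""
    df = pd.read_csv(path)
    needed = {"participant", "stimulus", "onset_ms", "duration_ms", "cx_px", "cy_px"}
    missing = needed - set(df.columns)
    if missing:
        raise GazeFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    out: dict[tuple[str, str], list[Fixation]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.participant), str(row.stimulus))
        out.setdefault(key, []).append(
            Fixation(float(row.onset_ms), float(row.duration_ms),
                     float(row.cx_px), float(row.cy_px)))
    for fx in out.values():
        fx.sort(key=lambda f: f.onset)
    return out


def write_fixation_table(fixations: dict[tuple[str, str], Sequence[Fixation]],
                         path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["participant", "stimulus", "onset_ms", "duration_ms", "cx_px", "cy_px"])
        for (pid, stim), fx in fixations.items():
            for f in fx:
                w.writerow([pid, stim, _fmt(f.onset), _fmt(f.duration), _fmt(f.cx), _fmt(f.cy)])


def detect_fixations(samples: Sequence[GazeSample],
                     dispersion_px: float = DEFAULT_DISPERSION_PX,
                     min_duration_ms: float = DEFAULT_MIN_DURATION_MS) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    A fixation is a maximal run of consecutive *valid* samples whose bounding
    box satisfies width + height <= ``dispersion_px`` and whose time span is
    at least ``min_duration_ms``.  Invalid samples break runs; the centroid is
    the mean of the member coordinates.  Deterministic, no smoothing.
    """
    if dispersion_px <= 0 or min_duration_ms <= 0:
        raise ValueError("dispersion_px and min_duration_ms must be positive")
    fixations: list[Fixation] = []
    n = len(samples)
    i = 0
    while i < n:
        if not samples[i].valid:
            i += 1
            continue
        # grow window while dispersion stays within threshold
        j = i
        xmin = xmax = samples[i].x
        ymin = ymax = samples[i].y
        while j + 1 < n and samples[j + 1].valid:
            nx, ny = samples[j + 1].x, samples[j + 1].y
            w = max(xmax, nx) - min(xmin, nx)
            h = max(ymax, ny) - min(ymin, ny)
            if w + h > dispersion_px:
                break
            j += 1
            xmin, xmax = min(xmin, nx), max(xmax, nx)
            ymin, ymax = min(ymin, ny), max(ymax, ny)
        span = samples[j].timestamp - samples[i].timestamp
        if span >= min_duration_ms and j > i:
            members = samples[i:j + 1]
            cx = sum(s.x for s in members) / len(members)
            cy = sum(s.y for s in members) / len(members)
            fixations.append(Fixation(samples[i].timestamp, span, cx, cy))
            i = j + 1
        else:
            i += 1
    return fixations


# ---------------------------------------------------------------------------
# Score reports

def write_scores(reports: Sequence[dict], path: str | Path, fmt: str = "json") -> None:
    """Persist score reports as nested JSON (default) or flat CSV.

    JSON round-trips bit-exactly through :func:`read_scores`.
    """
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(list(reports), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        rows = [_flatten(r) for r in reports]
        keys: list[str] = []
        for r in rows:
            for k in r:
                if k not in keys:
                    keys.append(k)
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys)
            w.writeheader()
            w.writerows(rows)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_scores(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def _flatten(d: dict, prefix: str = "") -> dict:
    out: dict = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def _parse_bool(token: str) -> bool:
    return str(token).strip().lower() in ("1", "true", "t", "yes")


def _fmt(x: float) -> str:
    """Render floats without trailing .0 noise for integral values."""
    f = float(x)
    return str(int(f)) if f.is_integer() else repr(f)
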