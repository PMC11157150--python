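"""Delimited-text IO for collar bursts, behaviour labels and weather series.

A *burst* is one short continuous tri-axial recording (typically 3.3 s at
33.3 Hz, i.e. 110 samples per axis, taken every 5 min).  Counts are 12-bit
(0–4095).  Two file dialects are supported and must be declared, never
sniffed:

- ``interleaved`` — one whitespace-separated column holding
  ``x y z x y z ...`` (Movebank e-obs style);
- ``per_axis`` — three whitespace-separated columns, one per axis.

Readers validate every row and report failures with row numbers instead of
silently dropping or passing malformed data downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import IO, Iterable

import numpy as np
import pandas as pd

COUNT_MIN = 0
COUNT_MAX = 4095


class ValidationError(ValueError):
    """Structural invariant violated in an input file."""


@dataclass(frozen=True)
class AccBurst:
    """One fixed-length tri-axial accelerometer recording.

    Counts are raw 12-bit values in [0, 4095]; ``timestamp`` is the UTC
    start of the burst; ``fs`` the per-axis sampling frequency in Hz.
    """

    individual_id: str
    timestamp: pd.Timestamp
    fs: float
    x_raw: np.ndarray
    y_raw: np.ndarray
    z_raw: np.ndarray

    def __post_init__(self):
        for axis in ("x_raw", "y_raw", "z_raw"):
            arr = np.asarray(getattr(self, axis), dtype=np.int64)
            object.__setattr__(self, axis, arr)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.x_raw)

    def validate(self) -> None:
        if not (len(self.x_raw) == len(self.y_raw) == len(self.z_raw)):
            raise ValidationError(
                f"axis length mismatch: x={len(self.x_raw)} y={len(self.y_raw)} "
                f"z={len(self.z_raw)}"
            )
        if self.fs <= 0:
            raise ValidationError(f"sampling frequency must be positive, got {self.fs}")
        for name, arr in (("x", self.x_raw), ("y", self.y_raw), ("z", self.z_raw)):
            if arr.size and (arr.min() < COUNT_MIN or arr.max() > COUNT_MAX):
                raise ValidationError(
                    f"{name}-axis count outside [{COUNT_MIN}, {COUNT_MAX}]"
                )


@dataclass(frozen=True)
class LabeledBurst:
    """A burst paired with its video-observed ethogram behaviour."""

    burst: AccBurst
    behaviour: str

    def __post_init__(self):
        from .ethogram import ETHOGRAM_LABELS

        if self.behaviour not in ETHOGRAM_LABELS:
            raise ValidationError(f"behaviour {self.behaviour!r} not in ethogram")


@dataclass(frozen=True)
class ParseIssue:
    """A row that failed validation, reported with its 0-based data row index."""

    row: int
    reason: str


@dataclass(frozen=True)
class BurstDialect:
    """Declared file layout for burst tables (never sniffed).

    ``kind`` is ``"interleaved"`` (single whitespace-separated xyz column)
    or ``"per_axis"`` (three whitespace-separated per-axis columns).
    ``fs_col`` names a per-row sampling-frequency column; if None, ``fs``
    applies to every row.
    """

    kind: str = "per_axis"
    id_col: str = "individual_id"
    time_col: str = "timestamp"
    fs_col: str | None = None
    fs: float = 33.3
    acc_col: str = "accelerations"
    x_col: str = "acc_x"
    y_col: str = "acc_y"
    z_col: str = "acc_z"
    label_col: str | None = None

    def __post_init__(self):
        if self.kind not in ("interleaved", "per_axis"):
            raise ValueError(f"unknown dialect kind {self.kind!r}")


def _parse_counts(text: str) -> np.ndarray:
    return np.array(str(text).split(), dtype=np.int64)


def _row_axes(row: pd.Series, dialect: BurstDialect) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if dialect.kind == "interleaved":
        flat = _parse_counts(row[dialect.acc_col])
        if flat.size % 3:
            raise ValidationError(
                f"interleaved count length {flat.size} not divisible by 3"
            )
        return flat[0::3], flat[1::3], flat[2::3]
    return (
        _parse_counts(row[dialect.x_col]),
        _parse_counts(row[dialect.y_col]),
        _parse_counts(row[dialect.z_col]),
    )


def read_bursts(
    source: str | IO[str], dialect: BurstDialect
) -> tuple[list[AccBurst], list[ParseIssue]]:
    """Read a burst table, returning validated bursts and per-row issues.

    Rows failing validation (counts out of range, axis-length mismatch,
    unparseable fields) are reported in the issue list with their 0-based
    data row index; surviving rows are returned as :class:`AccBurst`.
    """
    try:
        frame = pd.read_csv(source, dtype=str)
    except pd.errors.EmptyDataError:
        return [], []
    required = {dialect.id_col, dialect.time_col}
    required |= {dialect.acc_col} if dialect.kind == "interleaved" else {
        dialect.x_col,
        dialect.y_col,
        dialect.z_col,
    }
    if dialect.fs_col:
        required.add(dialect.fs_col)
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")

    bursts: list[AccBurst] = []
    issues: list[ParseIssue] = []
    for i, row in frame.iterrows():
        try:
            fs = float(row[dialect.fs_col]) if dialect.fs_col else dialect.fs
            x, y, z = _row_axes(row, dialect)
            bursts.append(
                AccBurst(
                    individual_id=str(row[dialect.id_col]),
                    timestamp=pd.Timestamp(row[dialect.time_col], tz="UTC")
                    if pd.Timestamp(row[dialect.time_col]).tzinfo is None
                    else pd.Timestamp(row[dialect.time_col]).tz_convert("UTC"),
                    fs=fs,
                    x_raw=x,
                    y_raw=y,
                    z_raw=z,
                )
            )
        except (ValidationError, ValueError) as exc:
            issues.append(ParseIssue(row=int(i), reason=str(exc)))
    return bursts, issues


def read_labelled_bursts(
    source: str | IO[str], dialect: BurstDialect
) -> tuple[list[LabeledBurst], list[ParseIssue]]:
    """Read bursts with a behaviour-label column (``dialect.label_col``)."""
    if dialect.label_col is None:
        raise ValueError("dialect.label_col must name the behaviour column")
    frame = pd.read_csv(source, dtype=str)
    labels = frame[dialect.label_col].tolist()
    import io as _io

    buf = _io.StringIO()
    frame.to_csv(buf, index=False)
    buf.seek(0)
    bursts, issues = read_bursts(buf, dialect)
    bad_rows = {iss.row for iss in issues}
    surviving_labels = [lab for i, lab in enumerate(labels) if i not in bad_rows]
    out: list[LabeledBurst] = []
    for b, lab, row in zip(
        bursts, surviving_labels, [i for i in range(len(labels)) if i not in bad_rows]
    ):
        try:
            out.append(LabeledBurst(burst=b, behaviour=lab))
        except ValidationError as exc:
            issues.append(ParseIssue(row=row, reason=str(exc)))
    return out, sorted(issues, key=lambda s: s.row)


def write_bursts(
    bursts: Iterable[AccBurst | LabeledBurst],
    path: str | IO[str],
    dialect: BurstDialect,
) -> None:
    """Write bursts in the declared dialect (exact count round-trip)."""
    rows = []
    for item in bursts:
        labelled = isinstance(item, LabeledBurst)
        b = item.burst if labelled else item
        row: dict[str, object] = {
            dialect.id_col: b.individual_id,
            dialect.time_col: b.timestamp.isoformat(),
        }
        if dialect.fs_col:
            row[dialect.fs_col] = b.fs
        if dialect.kind == "interleaved":
            flat = np.empty(3 * b.n, dtype=np.int64)
            flat[0::3], flat[1::3], flat[2::3] = b.x_raw, b.y_raw, b.z_raw
            row[dialect.acc_col] = " ".join(map(str, flat))
        else:
            row[dialect.x_col] = " ".join(map(str, b.x_raw))
            row[dialect.y_col] = " ".join(map(str, b.y_raw))
            row[dialect.z_col] = " ".join(map(str, b.z_raw))
        if dialect.label_col:
            row[dialect.label_col] = item.behaviour if labelled else ""
        rows.append(row)
    columns = [dialect.id_col, dialect.time_col]
    if dialect.fs_col:
        columns.append(dialect.fs_col)
    columns += (
        [dialect.acc_col]
        if dialect.kind == "interleaved"
        else [dialect.x_col, dialect.y_col, dialect.z_col]
    )
    if dialect.label_col:
        columns.append(dialect.label_col)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def split_long_bursts(burst: AccBurst, parts: int) -> list[AccBurst]:
    """Divide one long recording into ``parts`` equal consecutive bursts.

    Used for the 6.6-s labelling recordings, which are split in two 110
    sample halves; part ``j`` starts ``j * (n/parts)/fs`` seconds after the
    original timestamp.
    """
    if parts < 1:
        raise ValueError("parts must be >= 1")
    if burst.n % parts:
        raise ValueError(f"burst of {burst.n} samples not divisible into {parts} parts")
    m = burst.n // parts
    out = []
    for j in range(parts):
        sl = slice(j * m, (j + 1) * m)
        out.append(
            replace(
                burst,
                timestamp=burst.timestamp + pd.Timedelta(seconds=j * m / burst.fs),
                x_raw=burst.x_raw[sl],
                y_raw=burst.y_raw[sl],
                z_raw=burst.z_raw[sl],
            )
        )
    return out


WEATHER_COLUMNS = ("timestamp", "air_temp", "solar", "rh")


def read_weather(source: str | IO[str]) -> pd.DataFrame:
    """Read a weather-station series (timestamp, air_temp °C, solar W/m², rh %).

    Raises :class:`ValidationError` on missing columns, relative humidity
    outside [0, 100], or non-strictly-increasing timestamps.
    """
    frame = pd.read_csv(source)
    missing = set(WEATHER_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"missing weather columns: {sorted(missing)}")
    frame = frame[list(WEATHER_COLUMNS)].copy()
    ts = pd.to_datetime(frame["timestamp"], utc=True)
    frame["timestamp"] = ts
    if len(frame):
        bad_rh = frame[(frame["rh"] < 0) | (frame["rh"] > 100)]
        if len(bad_rh):
            raise ValidationError(
                f"relative humidity outside [0, 100] at rows {bad_rh.index.tolist()}"
            )
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValidationError("weather timestamps must be strictly increasing")
    return frame


def write_weather(frame: pd.DataFrame, path: str | IO[str]) -> None:
    out = frame.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    out.to_csv(path, index=False)
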