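"""Readers, writers and configuration shared across the package.

Covers: NMEA-0183-style ASCII sensor datagrams with XOR checksum, daily raw
files named ``YYYYMMDD.<instrument>``, frame loading with timestamp parsing
from filenames, census/count CSV tables, tidy hourly exports, and a flat
key-value configuration file.  All writers are deterministic: fixed column
order and fixed float formatting (6 significant digits), so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .census_evaluation import CountPair
from .frame_pipeline import FrameCensus
from .habitat_timeseries import HabitatSeries, SampleStream, ValidationError

FLOAT_FMT = "%.6g"

DATAGRAM_TALKER = "OBSEA"
_DATAGRAM_RE = re.compile(
    r"^\$(?P<payload>" + DATAGRAM_TALKER + r",[^*]*)\*(?P<checksum>[0-9A-Fa-f]{2})\s*$"
)
DAILY_NAME_RE = re.compile(r"^(?P<date>\d{8})\.(?P<instrument>[A-Za-z0-9_-]+)$")
FRAME_TS_PATTERN = r"(?P<ts>\d{8}_\d{6})"


class ChecksumError(ValueError):
    pass


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class Datagram:
    """One ASCII sensor sentence: ``$OBSEA,<instr>,<iso-ts>,<var>,<value>*hh``."""

    instrument: str
    timestamp: pd.Timestamp
    variable: str
    value: float


def _xor_checksum(payload: str) -> str:
    acc = 0
    for ch in payload.encode("ascii"):
        acc ^= ch
    return f"{acc:02X}"


def emit_datagram(d: Datagram) -> str:
    ts = d.timestamp.tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%S.%f").rstrip("0").rstrip(".")
    payload = f"{DATAGRAM_TALKER},{d.instrument},{ts}Z,{d.variable},{FLOAT_FMT % d.value}"
    return f"${payload}*{_xor_checksum(payload)}"


def parse_datagram(line: str) -> Datagram:
    """Parse and checksum-verify one sensor sentence."""
    m = _DATAGRAM_RE.match(line)
    if not m:
        star = line.find("*")
        raise ParseError(f"malformed datagram (near column {star if star >= 0 else 0}): {line!r}")
    payload = m.group("payload")
    expected = _xor_checksum(payload)
    found = m.group("checksum").upper()
    if expected != found:
        raise ChecksumError(f"checksum mismatch: expected {expected}, found {found}")
    parts = payload.split(",")
    if len(parts) != 5:
        raise ParseError(f"expected 5 comma fields, got {len(parts)}")
    _, instrument, ts, variable, value = parts
    try:
        stamp = pd.Timestamp(ts)
        if stamp.tz is None:
            stamp = stamp.tz_localize("UTC")
        return Datagram(instrument, stamp, variable, float(value))
    except (ValueError, TypeError) as exc:
        raise ParseError(f"bad field in datagram: {exc}") from exc


# --------------------------------------------------------------------------
# daily raw files

def write_daily_files(stream: SampleStream, directory: Path) -> list[Path]:
    """Split a stream into ``YYYYMMDD.<instrument>`` CSV files, one per day."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    s = stream.samples
    for day, chunk in s.groupby(s.index.floor("D")):
        path = directory / f"{day.strftime('%Y%m%d')}.{stream.instrument}"
        df = pd.DataFrame(
            {
                "timestamp": chunk.index.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                "variable": stream.variable,
                "value": [FLOAT_FMT % v for v in chunk.to_numpy()],
            }
        )
        df.to_csv(path, index=False)
        written.append(path)
    return written


def read_daily_files(
    directory: Path,
    instrument: str,
    variable: Optional[str] = None,
    nominal_interval: float = 10.0,
) -> SampleStream:
    """Concatenate a directory of daily files into one validated stream.

    Files are matched by the ``YYYYMMDD.<instrument>`` convention and read in
    date order; timestamps must be strictly increasing within and across
    files, and overlapping files are an error naming the offenders.
    """
    directory = Path(directory)
    matched = []
    for p in sorted(directory.iterdir()):
        m = DAILY_NAME_RE.match(p.name)
        if m and m.group("instrument") == instrument:
            matched.append((m.group("date"), p))
    matched.sort()

    pieces = []
    prev_end: Optional[pd.Timestamp] = None
    prev_path: Optional[Path] = None
    for _, path in matched:
        df = pd.read_csv(path, parse_dates=["timestamp"])
        if variable is not None:
            df = df[df["variable"] == variable]
        if df.empty:
            continue
        idx = pd.DatetimeIndex(df["timestamp"])
        if idx.tz is None:
            idx = idx.tz_localize("UTC")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValidationError(f"timestamps not strictly increasing in {path.name}")
        if prev_end is not None and idx[0] <= prev_end:
            raise ValidationError(
                f"overlapping timestamps between {prev_path.name} and {path.name}"
            )
        prev_end, prev_path = idx[-1], path
        pieces.append(pd.Series(df["value"].to_numpy(dtype=float), index=idx))

    samples = (
        pd.concat(pieces)
        if pieces
        else pd.Series([], index=pd.DatetimeIndex([], tz="UTC"), dtype=float)
    )
    return SampleStream(
        instrument=instrument,
        variable=variable or "mixed",
        samples=samples,
        nominal_interval=nominal_interval,
    )


# --------------------------------------------------------------------------
# frames

def load_frame(path: Path) -> np.ndarray:
    """Load a JPEG/PNG frame as 8-bit RGB, promoting grey/alpha inputs."""
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        warnings.warn(f"{path}: greyscale input promoted to RGB", stacklevel=2)
        arr = np.repeat(arr[..., None], 3, axis=2)
    elif arr.shape[2] == 4:
        warnings.warn(f"{path}: alpha channel dropped", stacklevel=2)
        arr = arr[..., :3]
    return arr


def parse_frame_timestamp(name: str, pattern: str = FRAME_TS_PATTERN) -> Optional[pd.Timestamp]:
    """Extract a UTC timestamp from a filename (default ``YYYYMMDD_HHMMSS``)."""
    m = re.search(pattern, name)
    if not m:
        return None
    from datetime import datetime

    return pd.Timestamp(datetime.strptime(m.group("ts"), "%Y%m%d_%H%M%S")).tz_localize("UTC")


def write_census_csv(censuses: Iterable[FrameCensus], path: Path) -> None:
    rows = []
    for c in censuses:
        rows.append(
            {
                "timestamp": "" if c.timestamp is None else str(c.timestamp),
                "count": "" if c.error else c.count,
                "cumulative_area": "" if c.error else c.cumulative_area,
                "flag": c.error or "ok",
            }
        )
    pd.DataFrame(rows, columns=["timestamp", "count", "cumulative_area", "flag"]).to_csv(
        path, index=False
    )


def read_count_pairs_csv(path: Path) -> list[CountPair]:
    """Read ``image_id,manual_count,auto_count`` rows into count pairs."""
    df = pd.read_csv(path)
    return [
        CountPair(str(r.image_id), int(r.manual_count), int(r.auto_count))
        for r in df.itertuples()
    ]


def write_tidy_hourly(series_list: Iterable[HabitatSeries], path: Path) -> None:
    from .habitat_timeseries import habitat_to_tidy

    frames = [habitat_to_tidy(s) for s in series_list]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["hour_start", "variable", "value", "n_samples", "flag"]
    )
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_tidy_hourly(path: Path, variable: str) -> HabitatSeries:
    df = pd.read_csv(path, parse_dates=["hour_start"])
    df = df[df["variable"] == variable]
    idx = pd.DatetimeIndex(df["hour_start"])
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    data = pd.DataFrame(
        {"value": df["value"].to_numpy(), "n_samples": df["n_samples"].to_numpy(dtype=int)},
        index=idx,
    )
    data.index.name = "hour_start"
    return HabitatSeries(variable=variable, data=data)


# --------------------------------------------------------------------------
# configuration

@dataclass
class Config:
    """Flat run configuration; unknown keys in a config file are rejected."""

    min_area: int = 10
    max_area: int = 5000
    sobel_threshold_mode: str = "auto"
    sobel_threshold: Optional[float] = None
    connectivity: int = 8
    school_threshold: int = 20
    low_threshold: int = 10
    coverage_min: float = 0.5
    seed: int = 0


def load_config(path: Path) -> Config:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"config {path} must be a flat key: value mapping")
    known = {f.name for f in fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    return Config(**raw)
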