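"""Gap-aware hourly habitat series from raw sensor streams, QC alarms,
and coupling of visual fish counts with habitat variables.

Raw instrument output arrives as timestamped sample streams: a CTD emits one
multivariable record every 10 s; an ADCP-class instrument delivers 10-min
products obtained by averaging 1-min bursts sampled at 1 Hz.  Streams are
reduced to hourly means over [t, t+1h) bins labelled at the bin start (UTC).
A bin whose sample count falls below a coverage fraction of the nominal
expectation is marked missing rather than interpolated, so sensor outages
stay visible downstream.  Current direction is averaged circularly; all
other variables linearly.

Quality control mimics an observatory watchdog: a ``no_data`` alarm for
every maximal run of missing bins, and a ``trend_deviation`` alarm whenever
a value departs from the rolling median by more than ``k`` robust standard
deviations (MAD with a floor at the instrument resolution).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Nominal sampling intervals in seconds.
CTD_INTERVAL = 10.0
ADCP_PRODUCT_INTERVAL = 600.0

#: Variables averaged on the circle (degrees) instead of the line.
CIRCULAR_VARIABLES = frozenset({"current_direction", "wave_direction", "direction"})


class ValidationError(ValueError):
    pass


@dataclass
class SampleStream:
    """Raw timestamped samples of one variable from one instrument."""

    instrument: str
    variable: str
    samples: pd.Series  # tz-aware DatetimeIndex -> float
    nominal_interval: float  # seconds
    units: str = ""

    def __post_init__(self) -> None:
        if self.nominal_interval <= 0:
            raise ValidationError(f"nominal_interval must be > 0, got {self.nominal_interval}")
        s = self.samples
        if not isinstance(s.index, pd.DatetimeIndex):
            raise ValidationError("samples must be indexed by timestamps")
        if s.index.tz is None:
            self.samples = s.tz_localize("UTC")
        if len(s) > 1 and not s.index.is_monotonic_increasing:
            raise ValidationError("sample timestamps must be increasing")


@dataclass
class HabitatSeries:
    """Hourly-binned series: value (NaN = missing) and per-bin sample count."""

    variable: str
    data: pd.DataFrame  # index hour_start (UTC), columns: value, n_samples
    units: str = ""

    @property
    def values(self) -> pd.Series:
        return self.data["value"]

    @property
    def n_samples(self) -> pd.Series:
        return self.data["n_samples"]


@dataclass(frozen=True)
class Alarm:
    timestamp: pd.Timestamp
    type: str  # "no_data" | "trend_deviation"
    detail: str


@dataclass
class QCReport:
    alarms: list[Alarm]


@dataclass
class CoupledSeries:
    """Fish counts and habitat variables on one shared hourly grid."""

    data: pd.DataFrame  # index hour_start; columns: fish_count, <variables...>


def _circular_mean_deg(values: np.ndarray) -> float:
    rad = np.deg2rad(values)
    ang = math.atan2(np.sin(rad).mean(), np.cos(rad).mean())
    deg = math.degrees(ang) % 360.0
    return 0.0 if deg >= 360.0 else deg


def hourly_average(stream: SampleStream, coverage_min: float = 0.5) -> HabitatSeries:
    """Reduce a raw stream to hourly means with explicit gaps.

    Bins are [t, t+1h), labelled at the start.  A bin is missing (NaN) when
    its sample count is below ``coverage_min`` times the nominal expectation
    ``3600 / nominal_interval``.  Direction variables use the circular
    (vector) mean in degrees.  An empty stream yields an empty series.
    """
    if len(stream.samples) == 0:
        empty = pd.DataFrame(columns=["value", "n_samples"], index=pd.DatetimeIndex([], tz="UTC"))
        return HabitatSeries(variable=stream.variable, data=empty, units=stream.units)

    s = stream.samples
    grouped = s.groupby(s.index.floor("h"))
    circular = stream.variable in CIRCULAR_VARIABLES
    if circular:
        means = grouped.apply(lambda v: _circular_mean_deg(v.to_numpy()))
    else:
        means = grouped.mean()
    counts = grouped.size()

    grid = pd.date_range(s.index.min().floor("h"), s.index.max().floor("h"), freq="h")
    df = pd.DataFrame(index=grid)
    df["value"] = means.reindex(grid)
    df["n_samples"] = counts.reindex(grid).fillna(0).astype(int)
    expected = 3600.0 / stream.nominal_interval
    df.loc[df["n_samples"] < coverage_min * expected, "value"] = np.nan
    df.index.name = "hour_start"
    return HabitatSeries(variable=stream.variable, data=df, units=stream.units)


def burst_average(
    raw: SampleStream,
    burst_len: float = 60.0,
    rate: float = 1.0,
    cadence: float = 600.0,
) -> SampleStream:
    """Collapse burst-sampled raw data to one mean value per cadence window.

    Each window [k*cadence, (k+1)*cadence) contributes the mean of its burst
    samples, timestamped at the burst start (the window's first sample).
    Windows with no samples are skipped with a warning.
    """
    s = raw.samples
    if len(s) == 0:
        return SampleStream(raw.instrument, raw.variable, s.copy(), cadence, raw.units)
    epoch = s.index[0].floor("D")
    offset = (s.index - epoch).total_seconds()
    window = (offset // cadence).astype(int)
    out_times, out_vals = [], []
    n_windows = int(window.max()) + 1
    by_window = pd.Series(s.to_numpy(), index=window)
    groups = by_window.groupby(level=0)
    starts = s.index.to_series().groupby(window.to_numpy()).first()
    for w, grp in groups:
        out_times.append(starts.loc[w])
        out_vals.append(grp.mean())
    skipped = n_windows - int(window.min()) - len(out_times)
    if skipped > 0:
        logger.warning("burst_average: %d cadence windows had no samples", skipped)
    series = pd.Series(out_vals, index=pd.DatetimeIndex(out_times, tz="UTC"))
    return SampleStream(raw.instrument, raw.variable, series, cadence, raw.units)


def qc_alarms(
    series: HabitatSeries,
    window: int = 24,
    k_mad: float = 5.0,
    mad_floor: float = 1e-4,
) -> QCReport:
    """Watchdog alarms for a binned series.

    ``no_data``: one alarm per maximal run of missing bins, stamped at the
    run start.  ``trend_deviation``: one alarm per bin whose value deviates
    from the centred rolling median over ``window`` bins by more than
    ``k_mad`` times the rolling MAD (floored at ``mad_floor``, typically the
    instrument resolution, so a perfectly constant stretch cannot divide by
    zero).
    """
    alarms: list[Alarm] = []
    vals = series.values
    if len(vals) == 0:
        return QCReport(alarms=[])

    missing = vals.isna()
    run_start: Optional[pd.Timestamp] = None
    run_len = 0
    for ts, is_gap in missing.items():
        if is_gap:
            if run_start is None:
                run_start, run_len = ts, 0
            run_len += 1
        elif run_start is not None:
            alarms.append(Alarm(run_start, "no_data", f"{run_len} missing hourly bins"))
            run_start = None
    if run_start is not None:
        alarms.append(Alarm(run_start, "no_data", f"{run_len} missing hourly bins"))

    med = vals.rolling(window, center=True, min_periods=max(3, window // 2)).median()
    mad = (vals - med).abs().rolling(window, center=True, min_periods=max(3, window // 2)).median()
    limit = k_mad * mad.clip(lower=mad_floor)
    deviant = (vals - med).abs() > limit
    for ts in vals.index[deviant.fillna(False)]:
        alarms.append(
            Alarm(
                ts,
                "trend_deviation",
                f"value {vals.loc[ts]:.6g} departs from rolling median {med.loc[ts]:.6g}",
            )
        )
    alarms.sort(key=lambda a: (a.timestamp, a.type))
    return QCReport(alarms=alarms)


def couple(counts: HabitatSeries, habitat: Sequence[HabitatSeries]) -> CoupledSeries:
    """Align hourly fish counts with habitat variables on a shared grid.

    The output grid is the hourly union over the overlapping span of all
    inputs.  Missing bins stay missing — counts from a daylight-only camera
    leave night rows with habitat values and no count.  Disjoint spans are an
    error.
    """
    all_series = [("fish_count", counts)] + [(h.variable, h) for h in habitat]
    spans = []
    for name, h in all_series:
        if len(h.data) == 0:
            raise ValidationError(f"series {name!r} is empty")
        spans.append((h.data.index.min(), h.data.index.max()))
    lo = max(s[0] for s in spans)
    hi = min(s[1] for s in spans)
    if lo > hi:
        detail = "; ".join(
            f"{name}: [{s[0]}, {s[1]}]" for (name, _), s in zip(all_series, spans)
        )
        raise ValidationError(f"series spans do not overlap: {detail}")
    grid = pd.date_range(lo, hi, freq="h")
    df = pd.DataFrame(index=grid)
    for name, h in all_series:
        df[name] = h.values.reindex(grid)
    df.index.name = "hour_start"
    return CoupledSeries(data=df)


def habitat_to_tidy(series: HabitatSeries) -> pd.DataFrame:
    """Long-format export: hour_start, variable, value, n_samples, flag."""
    df = series.data.reset_index()
    df["variable"] = series.variable
    df["flag"] = np.where(df["value"].isna(), "missing", "ok")
    return df[["hour_start", "variable", "value", "n_samples", "flag"]]
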