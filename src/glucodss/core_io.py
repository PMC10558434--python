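"""Canonical data model, file I/O and time-grid alignment.

Everything downstream (simulation, feature filters, predictors, replay)
consumes a :class:`GlucoseTimeSeries`: three channels — CGM (mg/dl),
insulin delivery (U/min) and carbohydrate intake (g/min) — on a uniform
time grid (default 5 minutes), plus a boolean mask marking bins where the
CGM reading is absent.  Diary events (meals in grams, boluses in units,
basal-rate segments) travel separately in an :class:`EventList` until they
are rasterized onto the grid.

Conventions
-----------
* A bolus of ``U`` units delivered in one bin becomes ``U/step`` U/min in
  that bin; a meal of ``G`` grams becomes ``G/step`` g/min.  Totals are
  conserved exactly: ``sum(channel) * step`` equals delivered units/grams.
* CGM gaps strictly shorter than 30 minutes are linearly interpolated on
  *training* data only; the test set is never imputed.
* Timestamps are timezone-naive local time.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("glucodss")

#: canonical CSV schema; the last three columns are optional event carriers
CSV_COLUMNS = ("timestamp", "cgm_mgdl", "insulin_Umin", "cho_gmin")
CSV_EVENT_COLUMNS = ("bolus_U", "meal_g", "meal_announced")

DEFAULT_STEP_MIN = 5
#: CGM gaps strictly shorter than this (minutes) are interpolated (training only)
MAX_INTERP_GAP_MIN = 30


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid: sample ``k`` is at ``start + k * step`` minutes."""

    start: pd.Timestamp
    step: int = DEFAULT_STEP_MIN
    n: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.n < 0:
            raise ValueError("sample count must be non-negative")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n,
                             freq=pd.Timedelta(minutes=self.step))

    @property
    def minutes(self) -> np.ndarray:
        """Elapsed minutes of each sample relative to ``start``."""
        return np.arange(self.n) * float(self.step)

    def index_of(self, ts: pd.Timestamp) -> int:
        """Nearest grid index for a timestamp; exact halves snap earlier."""
        offset = (pd.Timestamp(ts) - self.start) / pd.Timedelta(minutes=self.step)
        return int(math.ceil(offset - 0.5))


@dataclass
class GlucoseTimeSeries:
    """CGM / insulin / CHO channels on a shared grid.

    ``cgm`` holds NaN wherever ``missing_mask`` is True.  Insulin and CHO
    channels are complete by construction (pump records and diary entries
    have no sensor dropout).
    """

    grid: TimeGrid
    cgm: np.ndarray          # mg/dl, NaN where missing
    insulin: np.ndarray      # U/min
    cho: np.ndarray          # g/min
    missing_mask: np.ndarray  # True -> CGM absent

    def __post_init__(self) -> None:
        self.cgm = np.asarray(self.cgm, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        self.cho = np.asarray(self.cho, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = self.grid.n
        for name in ("cgm", "insulin", "cho", "missing_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length != grid.n ({n})")
        if np.any(self.insulin < 0):
            raise ValueError("insulin channel must be non-negative")
        if np.any(self.cho < 0):
            raise ValueError("cho channel must be non-negative")
        present = ~self.missing_mask
        if np.any(~np.isfinite(self.cgm[present])) or np.any(self.cgm[present] <= 0):
            raise ValueError("present CGM values must be finite and positive")
        self.cgm = self.cgm.copy()
        self.cgm[self.missing_mask] = np.nan

    @property
    def n(self) -> int:
        return self.grid.n

    def copy(self) -> "GlucoseTimeSeries":
        return GlucoseTimeSeries(self.grid, self.cgm.copy(), self.insulin.copy(),
                                 self.cho.copy(), self.missing_mask.copy())

    def slice(self, start: int, stop: int) -> "GlucoseTimeSeries":
        """Sub-series of samples ``[start, stop)`` with a rebased grid."""
        if not (0 <= start < stop <= self.n):
            raise ValueError("slice bounds out of range")
        grid = TimeGrid(self.grid.timestamps[start], self.grid.step, stop - start)
        return GlucoseTimeSeries(grid, self.cgm[start:stop],
                                 self.insulin[start:stop], self.cho[start:stop],
                                 self.missing_mask[start:stop])


@dataclass(frozen=True)
class Meal:
    time: pd.Timestamp
    grams: float
    announced: bool = True


@dataclass(frozen=True)
class Bolus:
    time: pd.Timestamp
    units: float


@dataclass(frozen=True)
class BasalSegment:
    start: pd.Timestamp
    end: pd.Timestamp
    rate: float  # U/min


@dataclass
class EventList:
    """Raw diary events prior to (or recovered after) gridding."""

    meals: list[Meal] = field(default_factory=list)
    boluses: list[Bolus] = field(default_factory=list)
    basal_segments: list[BasalSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.meals:
            if m.grams <= 0:
                raise ValueError("meal grams must be positive")
        for b in self.boluses:
            if b.units < 0:
                raise ValueError("bolus units must be non-negative")


@dataclass
class DataSplit:
    """Chronological train/test partition (train strictly precedes test)."""

    train: GlucoseTimeSeries
    test: GlucoseTimeSeries

    def __post_init__(self) -> None:
        t_end = self.train.grid.timestamps[-1]
        if self.test.grid.start <= t_end:
            raise ValueError("test split must start after the training split ends")


# ---------------------------------------------------------------------------
# grid alignment
# ---------------------------------------------------------------------------

def align_to_grid(events: EventList, samples: pd.Series,
                  step: int = DEFAULT_STEP_MIN) -> GlucoseTimeSeries:
    """Snap raw CGM readings and diary events onto a uniform grid.

    Parameters
    ----------
    events:
        Diary events; bolus/meal amounts are spread over exactly one bin
        (``amount / step`` as a per-minute rate), basal segments are
        prorated over the bins they overlap so totals are conserved.
    samples:
        Raw CGM readings as a pandas Series indexed by timestamp (mg/dl).
    step:
        Grid step in minutes; must divide 60.

    Returns
    -------
    GlucoseTimeSeries with ``missing_mask`` set on bins that received no
    CGM reading.  If two readings snap to the same bin the nearer-in-time
    one is kept and a warning logged.
    """
    if 60 % step != 0:
        raise ValueError("grid step must divide 60 minutes")
    if len(samples) == 0:
        raise ValueError("no CGM samples provided")
    idx = pd.DatetimeIndex(samples.index)
    if idx.is_monotonic_increasing is False:
        order = np.argsort(idx.asi8, kind="stable")
        idx, samples = idx[order], samples.iloc[order]

    all_times = list(idx)
    all_times += [m.time for m in events.meals]
    all_times += [b.time for b in events.boluses]
    for seg in events.basal_segments:
        all_times += [seg.start, seg.end]
    t0 = min(all_times).floor(f"{step}min")
    t_last = max(all_times)
    n = int(math.ceil((t_last - t0) / pd.Timedelta(minutes=step))) + 1
    grid = TimeGrid(t0, step, n)

    cgm = np.full(n, np.nan)
    dist = np.full(n, np.inf)  # minutes from bin time of the kept reading
    for ts, value in zip(idx, np.asarray(samples, dtype=float)):
        k = grid.index_of(ts)
        d = abs((ts - t0).total_seconds() / 60.0 - k * step)
        if np.isfinite(dist[k]):
            logger.warning("two CGM readings snap to bin %d (%s); keeping nearer",
                           k, grid.timestamps[k])
            if d >= dist[k]:
                continue
        cgm[k] = value
        dist[k] = d

    insulin = np.zeros(n)
    cho = np.zeros(n)
    for seg in events.basal_segments:
        _add_basal(insulin, grid, seg)
    for b in events.boluses:
        k = grid.index_of(b.time)
        if not 0 <= k < n:
            raise ValueError(f"bolus at {b.time} outside grid span")
        insulin[k] += b.units / step
    for m in events.meals:
        k = grid.index_of(m.time)
        if not 0 <= k < n:
            raise ValueError(f"meal at {m.time} outside grid span")
        cho[k] += m.grams / step

    return GlucoseTimeSeries(grid, cgm, insulin, cho, np.isnan(cgm))


def _add_basal(insulin: np.ndarray, grid: TimeGrid, seg: BasalSegment) -> None:
    """Add a basal segment, prorating partial bin overlap (conserves units)."""
    step = float(grid.step)
    a = (seg.start - grid.start) / pd.Timedelta(minutes=1)
    b = (seg.end - grid.start) / pd.Timedelta(minutes=1)
    if b <= a:
        return
    k0 = max(int(math.floor(a / step)), 0)
    k1 = min(int(math.ceil(b / step)), grid.n)
    for k in range(k0, k1):
        lo, hi = k * step, (k + 1) * step
        overlap = min(hi, b) - max(lo, a)
        if overlap > 0:
            insulin[k] += seg.rate * overlap / step


# ---------------------------------------------------------------------------
# gap interpolation (training data only, by pipeline convention)
# ---------------------------------------------------------------------------

def interpolate_short_gaps(s: GlucoseTimeSeries,
                           max_gap: int = MAX_INTERP_GAP_MIN) -> GlucoseTimeSeries:
    """Linearly fill CGM gaps strictly shorter than ``max_gap`` minutes.

    A gap is a maximal run of missing bins with present readings on both
    flanks; boundary gaps (no flank) and gaps of ``max_gap`` minutes or
    longer are left untouched.  Insulin/CHO channels are never modified.
    """
    if max_gap % s.grid.step != 0:
        raise ValueError("max_gap must be a multiple of the grid step")
    out = s.copy()
    mask = out.missing_mask
    n = out.n
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        run = j - i  # bins missing
        has_flanks = i > 0 and j < n
        if has_flanks and run * s.grid.step < max_gap:
            x0, x1 = i - 1, j
            w = np.arange(1, run + 1) / (run + 1)
            out.cgm[i:j] = out.cgm[x0] * (1 - w) + out.cgm[x1] * w
            out.missing_mask[i:j] = False
        i = j
    return out


# ---------------------------------------------------------------------------
# canonical CSV
# ---------------------------------------------------------------------------

def write_csv(s: GlucoseTimeSeries, events: EventList | None, path) -> None:
    """Write a series (and optionally its events) to the canonical CSV."""
    df = pd.DataFrame({
        "timestamp": s.grid.timestamps,
        "cgm_mgdl": s.cgm,
        "insulin_Umin": s.insulin,
        "cho_gmin": s.cho,
    })
    if events is not None:
        bolus = np.zeros(s.n)
        meal = np.zeros(s.n)
        announced = np.zeros(s.n, dtype=bool)
        for b in events.boluses:
            k = s.grid.index_of(b.time)
            if 0 <= k < s.n:  # events outside this slice are dropped
                bolus[k] += b.units
        for m in events.meals:
            k = s.grid.index_of(m.time)
            if 0 <= k < s.n:
                meal[k] += m.grams
                announced[k] = m.announced
        df["bolus_U"] = np.where(bolus > 0, bolus, np.nan)
        df["meal_g"] = np.where(meal > 0, meal, np.nan)
        df["meal_announced"] = np.where(meal > 0, announced.astype(float), np.nan)
    df.to_csv(path, index=False, float_format="%.10g")


def read_csv(path) -> tuple[GlucoseTimeSeries, EventList]:
    """Read the canonical CSV back into a series and recovered event list.

    Basal segments are reconstructed as the insulin channel minus bolus
    impulses, compressed into constant-rate runs.
    """
    df = pd.read_csv(path)
    unknown = [c for c in df.columns
               if c not in CSV_COLUMNS and c not in CSV_EVENT_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns in canonical CSV: {unknown}")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"canonical CSV is missing columns: {missing}")
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    if len(ts) == 0:
        raise ValueError("empty canonical CSV")
    deltas = np.diff(ts.asi8)
    if len(deltas) and (np.any(deltas <= 0) or len(set(deltas)) != 1):
        raise ValueError("timestamps must be strictly increasing on a uniform grid")
    step = int(deltas[0] / 60e9) if len(deltas) else DEFAULT_STEP_MIN
    grid = TimeGrid(ts[0], step, len(ts))

    cgm = df["cgm_mgdl"].to_numpy(dtype=float)
    series = GlucoseTimeSeries(grid, cgm, df["insulin_Umin"].to_numpy(dtype=float),
                               df["cho_gmin"].to_numpy(dtype=float), np.isnan(cgm))

    events = EventList()
    bolus_col = df["bolus_U"].to_numpy(dtype=float) if "bolus_U" in df else np.full(len(ts), np.nan)
    meal_col = df["meal_g"].to_numpy(dtype=float) if "meal_g" in df else np.full(len(ts), np.nan)
    ann_col = df["meal_announced"].to_numpy(dtype=float) if "meal_announced" in df else np.full(len(ts), np.nan)
    for k in range(len(ts)):
        if np.isfinite(bolus_col[k]) and bolus_col[k] > 0:
            events.boluses.append(Bolus(ts[k], float(bolus_col[k])))
        if np.isfinite(meal_col[k]) and meal_col[k] > 0:
            announced = bool(ann_col[k]) if np.isfinite(ann_col[k]) else True
            events.meals.append(Meal(ts[k], float(meal_col[k]), announced))

    basal = series.insulin.copy()
    for b in events.boluses:
        basal[grid.index_of(b.time)] -= b.units / step
    basal = np.clip(basal, 0.0, None)
    events.basal_segments = _compress_segments(basal, grid)
    return series, events


def _compress_segments(rate: np.ndarray, grid: TimeGrid) -> list[BasalSegment]:
    segs: list[BasalSegment] = []
    if len(rate) == 0:
        return segs
    start = 0
    for k in range(1, len(rate) + 1):
        if k == len(rate) or not math.isclose(rate[k], rate[start], abs_tol=1e-12):
            segs.append(BasalSegment(grid.timestamps[start],
                                     grid.start + pd.Timedelta(minutes=k * grid.step),
                                     float(rate[start])))
            start = k
    return segs


# ---------------------------------------------------------------------------
# OhioT1DM-style XML adapter (read-only)
# ---------------------------------------------------------------------------

_OHIO_TS = "%d-%m-%Y %H:%M:%S"


def read_ohio_xml(path, step: int = DEFAULT_STEP_MIN) -> tuple[GlucoseTimeSeries, EventList]:
    """Read an OhioT1DM-layout XML file and align it to the grid.

    Expects ``glucose_level``, ``bolus``, ``meal`` and ``basal`` elements;
    basal rates are recorded in U/hr and converted to U/min.
    """
    try:
        root = ET.parse(Path(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed OhioT1DM XML: {exc}") from exc
    glucose = root.find(".//glucose_level")
    if glucose is None:
        raise ValueError("missing required element: glucose_level")

    times, values = [], []
    for ev in glucose.findall("event"):
        times.append(pd.to_datetime(ev.get("ts"), format=_OHIO_TS))
        values.append(float(ev.get("value")))
    if not times:
        raise ValueError("glucose_level element contains no events")
    samples = pd.Series(values, index=pd.DatetimeIndex(times))

    events = EventList()
    bolus_el = root.find(".//bolus")
    if bolus_el is not None:
        for ev in bolus_el.findall("event"):
            ts = pd.to_datetime(ev.get("ts_begin") or ev.get("ts"), format=_OHIO_TS)
            events.boluses.append(Bolus(ts, float(ev.get("dose"))))
    meal_el = root.find(".//meal")
    if meal_el is not None:
        for ev in meal_el.findall("event"):
            ts = pd.to_datetime(ev.get("ts"), format=_OHIO_TS)
            events.meals.append(Meal(ts, float(ev.get("carbs")), True))
    basal_el = root.find(".//basal")
    if basal_el is not None:
        entries = [(pd.to_datetime(ev.get("ts"), format=_OHIO_TS),
                    float(ev.get("value")) / 60.0)  # U/hr -> U/min
                   for ev in basal_el.findall("event")]
        entries.sort(key=lambda e: e[0])
        end_of_data = max([samples.index.max()]
                          + [b.time for b in events.boluses]
                          + [m.time for m in events.meals])
        for i, (t_start, rate) in enumerate(entries):
            t_end = entries[i + 1][0] if i + 1 < len(entries) else end_of_data
            if t_end > t_start:
                events.basal_segments.append(BasalSegment(t_start, t_end, rate))

    return align_to_grid(events, samples, step=step), events
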