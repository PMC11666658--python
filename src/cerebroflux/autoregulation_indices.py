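"""Per-animal derived series: CPP, pressure-reactivity indices, episodes, ICP dose.

The central quantity is a moving Pearson correlation between proximal MAP and
ICP.  With 5-minute manual sampling the practical variant correlates six
consecutive samples (a 25-minute window) and advances one sample at a time
("mL-PRx"); the classical long variant (20 samples at 1-minute intervals,
"L-PRx") is available as a preset for higher-resolution grids.  A value at or
below zero is read as preserved cerebrovascular reactivity: intact vessels
constrict when pressure rises, so ICP moves against MAP.  Positive values mark
pressure-passive vessels; a run of consecutive positive windows is an
impairment episode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .experiment_model import (
    AnimalRecord,
    ConfigurationError,
    PhaseSchedule,
    ValidationError,
    phase_of,
)

__all__ = [
    "PRxSpec",
    "MLPRX",
    "LPRX",
    "IndexSeries",
    "Episode",
    "cpp_series",
    "rolling_prx",
    "classify_reactivity",
    "detect_episodes",
    "icp_dose",
    "delta_from_baseline",
]

OK = "ok"
MISSING = "missing"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class PRxSpec:
    """Definition of a reactivity index.

    ``n_points`` consecutive samples at ``interval`` minutes enter each
    Pearson window; the result is assigned to the window's end (causal
    convention) or centre.  Values above ``impairment_threshold`` count as
    impaired reactivity; ``secondary_threshold`` is the conventional
    mortality-associated level (0.2), carried for reporting only.
    """

    n_points: int = 6
    interval: float = 5.0
    assignment: str = "window_end"
    impairment_threshold: float = 0.0
    secondary_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError(
                f"a Pearson window needs at least 3 points, got {self.n_points}"
            )
        if self.interval <= 0:
            raise ValidationError(f"interval must be positive, got {self.interval}")
        if self.assignment not in ("window_end", "window_center"):
            raise ValidationError(f"unknown assignment rule {self.assignment!r}")

    @property
    def span(self) -> float:
        """Window span in minutes: (n_points - 1) * interval."""
        return (self.n_points - 1) * self.interval


MLPRX = PRxSpec(n_points=6, interval=5.0)
LPRX = PRxSpec(n_points=20, interval=1.0)


@dataclass
class IndexSeries:
    """A named, time-indexed derived series for one animal.

    ``status`` flags each value: ``ok``, ``missing`` (an input was absent or
    the window was censored) or ``undefined`` (a correlation window with zero
    variance in a channel carries no reactivity information).
    """

    animal_id: str
    name: str
    times: np.ndarray
    values: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.status = np.asarray(self.status, dtype=object)
        if not (len(self.times) == len(self.values) == len(self.status)):
            raise ValidationError("times, values and status must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("index times must strictly increase")

    @property
    def ok_mask(self) -> np.ndarray:
        return self.status == OK

    def value_at(self, time: float) -> float:
        idx = np.flatnonzero(np.isclose(self.times, time))
        if idx.size == 0:
            raise ValidationError(f"{self.name}: no value at time {time}")
        if self.status[idx[0]] != OK:
            raise ValidationError(f"{self.name}: value at time {time} is {self.status[idx[0]]}")
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class Episode:
    """A maximal contiguous run of impaired-reactivity windows."""

    start: float
    end: float
    duration: float
    mean_index: float
    peak_index: float

    def overlaps(self, start: float, end: float) -> bool:
        return self.start < end and start < self.end


def cpp_series(record: AnimalRecord) -> IndexSeries:
    """Cerebral perfusion pressure: CPP = MAP - ICP, per sample.

    No zero-level correction is applied (with the pressure transducers zeroed
    at the same level, none is needed).  A missing input makes the CPP value
    missing.
    """
    times = record.times()
    pmap = record.channel("pmap")
    icp = record.channel("icp")
    values = pmap - icp
    status = np.where(np.isnan(values), MISSING, OK).astype(object)
    values = np.where(np.isnan(values), np.nan, values)
    return IndexSeries(record.animal_id, "CPP", times, values, status)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def rolling_prx(
    record: AnimalRecord,
    spec: PRxSpec = MLPRX,
    censor_schedule: Optional[PhaseSchedule] = None,
) -> IndexSeries:
    """Moving Pearson correlation of (pMAP, ICP) windows.

    Each fully overlapping window of ``spec.n_points`` consecutive samples
    yields one value; the window advances one sample at a time, so a gapless
    series of N samples yields ``N - n_points + 1`` values.  Windows
    containing a missing sample are flagged ``missing``; windows with zero
    variance in either channel are ``undefined``.  If ``censor_schedule`` is
    given, windows whose samples straddle a phase boundary are censored
    (flagged ``missing``) so an index value never mixes physiological regimes.

    The record must be sampled on a uniform grid whose step equals
    ``spec.interval``; anything else raises :class:`ConfigurationError`.
    """
    times = record.times()
    if len(times) >= 2:
        steps = np.diff(times)
        if not np.allclose(steps, spec.interval, atol=1e-9):
            raise ConfigurationError(
                f"record grid step(s) {sorted(set(np.round(steps, 6)))} do not match "
                f"the index interval {spec.interval} min"
            )
    pmap = record.channel("pmap")
    icp = record.channel("icp")
    n = spec.n_points
    n_windows = max(0, len(times) - n + 1)
    out_t = np.empty(n_windows)
    out_v = np.full(n_windows, np.nan)
    out_s = np.empty(n_windows, dtype=object)
    name = "mL-PRx" if (n, spec.interval) == (6, 5.0) else f"PRx[{n}x{spec.interval:g}min]"
    for w in range(n_windows):
        sl = slice(w, w + n)
        t_last = times[w + n - 1]
        out_t[w] = t_last if spec.assignment == "window_end" else 0.5 * (times[w] + t_last)
        if censor_schedule is not None:
            phases = {phase_of(censor_schedule, t) for t in times[sl]}
            if len(phases) > 1:
                out_s[w] = MISSING
                continue
        xp, yp = pmap[sl], icp[sl]
        if np.isnan(xp).any() or np.isnan(yp).any():
            out_s[w] = MISSING
        elif np.ptp(xp) == 0.0 or np.ptp(yp) == 0.0:
            out_s[w] = UNDEFINED
        else:
            out_v[w] = _pearson(xp, yp)
            out_s[w] = OK
    return IndexSeries(record.animal_id, name, out_t, out_v, out_s)


def classify_reactivity(value: float, spec: PRxSpec = MLPRX) -> str:
    """Label one index value: at or below the threshold reactivity is preserved."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return UNDEFINED
    return "preserved" if value <= spec.impairment_threshold else "impaired"


def detect_episodes(
    series: IndexSeries,
    spec: PRxSpec = MLPRX,
    min_windows: int = 2,
) -> list[Episode]:
    """Maximal runs of consecutive impaired windows.

    Runs shorter than ``min_windows`` are discarded (the default of two
    consecutive windows suppresses single-window noise while retaining the
    15-25-minute episodes of interest).  Missing and undefined values break
    runs.  An episode's start is the first impaired window's data onset
    (assigned time minus the window span); its end is the last impaired
    window's assigned time.
    """
    if min_windows < 1:
        raise ValidationError(f"min_windows must be >= 1, got {min_windows}")
    episodes: list[Episode] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_windows:
            vals = series.values[run]
            start = float(series.times[run[0]] - spec.span)
            end = float(series.times[run[-1]])
            episodes.append(
                Episode(
                    start=start,
                    end=end,
                    duration=end - start,
                    mean_index=float(vals.mean()),
                    peak_index=float(vals.max()),
                )
            )
        run.clear()

    for i in range(len(series.times)):
        impaired = (
            series.status[i] == OK and series.values[i] > spec.impairment_threshold
        )
        if impaired:
            run.append(i)
        else:
            flush()
    flush()
    return episodes


def icp_dose(
    record: AnimalRecord,
    threshold: float = 20.0,
    window: Optional[tuple[float, float]] = None,
) -> float:
    """Cumulative ICP burden above a threshold, in mmHg*min.

    Trapezoidal integral of ``max(0, ICP - threshold)`` over the requested
    window (default: the whole record).  Window endpoints may fall between
    samples; the rectified trace is interpolated linearly there.  Missing ICP
    samples are excluded from the integration grid.
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    times = record.times()
    icp = record.channel("icp")
    keep = ~np.isnan(icp)
    times, icp = times[keep], icp[keep]
    if len(times) < 2:
        raise ValidationError("icp_dose needs at least two non-missing ICP samples")
    a, b = window if window is not None else (times[0], times[-1])
    if a >= b:
        raise ValidationError(f"window must satisfy start < end, got ({a}, {b})")
    if a < times[0] - 1e-9 or b > times[-1] + 1e-9:
        raise ValidationError(
            f"window ({a}, {b}) lies outside the record span ({times[0]}, {times[-1]})"
        )
    excess = np.maximum(0.0, icp - threshold)
    inner = (times > a) & (times < b)
    grid = np.concatenate(([a], times[inner], [b]))
    vals = np.interp(grid, times, excess)
    return float(np.trapezoid(vals, grid))


def delta_from_baseline(
    series: IndexSeries,
    baseline_time: float,
    stat: str = "max",
    schedule: Optional[PhaseSchedule] = None,
    at: Optional[float] = None,
) -> float:
    """Change of a series from its baseline value, summarised over occlusion.

    ``stat`` selects the summary of ``value(t) - value(baseline_time)`` taken
    over the occlusion phase: ``max``, ``min`` or ``at_time`` (which requires
    ``at``).  The baseline sample must be present, otherwise an error is
    raised.
    """
    schedule = schedule or PhaseSchedule()
    baseline = series.value_at(baseline_time)  # raises if absent/missing
    if stat == "at_time":
        if at is None:
            raise ValidationError("stat='at_time' requires the `at` argument")
        return series.value_at(at) - baseline
    in_occlusion = (
        (series.times >= schedule.occlusion_start)
        & (series.times < schedule.reperfusion_start)
        & series.ok_mask
    )
    if not in_occlusion.any():
        raise ValidationError("no usable values inside the occlusion phase")
    deltas = series.values[in_occlusion] - baseline
    if stat == "max":
        return float(deltas.max())
    if stat == "min":
        return float(deltas.min())
    raise ValidationError(f"unknown stat {stat!r}; expected max, min or at_time")
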