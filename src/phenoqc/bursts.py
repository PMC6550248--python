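"""Burst segmentation and daily coverage estimation.

The observed ping stream for a sensor is partitioned, day by day, into
*bursts*: maximal runs of pings in which the gap between consecutive
pings is no greater than the schedule's gap threshold.  A gap exactly
equal to the threshold therefore stays within a burst.  From the bursts
of day ``i`` we estimate

* ``b_hat_i``  — number of bursts,
* ``p_hat_ij`` — pings in burst ``j``; ``p_hat_i`` is their daily sum,
* ``d_hat_ij`` — burst duration (last ping minus first ping; a
  single-ping burst has duration 0),
* ``d_hat_i``  — mean burst duration,
* ``f_hat_i = p_hat_i / (b_hat_i * d_hat_i)`` — mean within-burst
  frequency, and
* ``C_hat_i = p_hat_i / p`` — total daily coverage relative to the
  design expectation ``p``.

These satisfy the identity
``(b_hat_i/b) * (d_hat_i/d) * (f_hat_i/f) = p_hat_i/p`` on every
non-degenerate day.

Days are half-open 86,400 s windows anchored at each subject's start
(enrollment or first observed ping); pings are assigned to exactly one
day, so a burst never spans a day boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import OrderingError
from .schedules import SECONDS_PER_DAY, SamplingSchedule


@dataclass
class BurstSet:
    """The bursts estimated for one day.

    ``starts``/``ends`` are first/last ping times of each burst (same
    clock as the input timestamps), ``counts`` the per-burst ping counts
    ``p_hat_ij``.  Bursts are ordered by start time and consecutive
    bursts are separated by a gap strictly greater than the threshold
    used to build the set.
    """

    day_index: int
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray
    threshold: float

    @property
    def b_hat(self) -> int:
        """Number of bursts on this day (b_hat_i)."""
        return len(self.counts)

    @property
    def p_hat(self) -> int:
        """Total pings on this day (p_hat_i)."""
        return int(self.counts.sum())

    @property
    def durations(self) -> np.ndarray:
        """Per-burst durations d_hat_ij in seconds."""
        return self.ends - self.starts

    @property
    def gaps(self) -> np.ndarray:
        """Inter-burst gaps: start of burst j+1 minus end of burst j."""
        return self.starts[1:] - self.ends[:-1]


@dataclass
class DailyCoverage:
    """Daily summary estimators for one sensor stream.

    Missing values (degenerate days) are represented as NaN:
    ``d_hat``, ``f_hat`` and ``gap_hat`` are NaN when no burst was
    observed, ``gap_hat`` additionally when fewer than two bursts were,
    and ``f_hat`` when the mean duration is zero (all bursts single-ping).
    """

    day_index: int
    b_hat: int
    p_hat: int
    d_hat: float
    f_hat: float
    gap_hat: float
    coverage: float


def segment_bursts(
    timestamps: np.ndarray, threshold: float, day_index: int = 1
) -> BurstSet:
    """Partition sorted ping times (seconds) of one day into bursts.

    A new burst begins whenever the gap to the previous ping exceeds
    ``threshold``; a gap equal to the threshold does not split.
    Duplicate timestamps are retained (gap 0).

    Raises
    ------
    OrderingError
        If the timestamps are not sorted non-decreasing.
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.ndim != 1:
        raise ValueError("timestamps must be one-dimensional")
    if ts.size == 0:
        empty = np.empty(0)
        return BurstSet(day_index, empty, empty, np.empty(0, dtype=np.int64), threshold)
    diffs = np.diff(ts)
    if diffs.size and diffs.min() < 0:
        raise OrderingError("ping timestamps must be sorted non-decreasing")
    # burst boundaries: positions where the gap strictly exceeds the threshold
    cut = np.flatnonzero(diffs > threshold) + 1
    edges = np.concatenate(([0], cut, [ts.size]))
    counts = np.diff(edges).astype(np.int64)
    starts = ts[edges[:-1]]
    ends = ts[edges[1:] - 1]
    return BurstSet(day_index, starts, ends, counts, threshold)


def daily_coverage(burst_set: BurstSet, schedule: SamplingSchedule) -> DailyCoverage:
    """Summarise a day's :class:`BurstSet` into the daily estimators."""
    exp = schedule.expected
    b_hat = burst_set.b_hat
    p_hat = burst_set.p_hat
    if b_hat == 0:
        return DailyCoverage(burst_set.day_index, 0, 0, math.nan, math.nan, math.nan, 0.0)
    d_hat = float(burst_set.durations.mean())
    f_hat = p_hat / (b_hat * d_hat) if d_hat > 0 else math.nan
    gap_hat = float(burst_set.gaps.mean()) if b_hat >= 2 else math.nan
    coverage = p_hat / exp.p
    return DailyCoverage(burst_set.day_index, b_hat, p_hat, d_hat, f_hat, gap_hat, coverage)


def partition_days(
    timestamps: np.ndarray,
    subject_start: float,
    n_days: int | None = None,
) -> tuple[list[np.ndarray], int]:
    """Split absolute ping times into per-day lists.

    Day ``i`` (1-based) is the half-open window
    ``[subject_start + (i-1)*86400, subject_start + i*86400)``.  Pings
    before ``subject_start`` are rejected with a warning; the rejected
    count is returned alongside the per-day arrays (index 0 is day 1,
    empty days included).
    """
    ts = np.sort(np.asarray(timestamps, dtype=float))
    rejected = int(np.searchsorted(ts, subject_start, side="left"))
    if rejected:
        warnings.warn(f"{rejected} ping(s) before subject start were rejected", stacklevel=2)
        ts = ts[rejected:]
    if n_days is None:
        if ts.size == 0:
            return [], rejected
        n_days = int((ts[-1] - subject_start) // SECONDS_PER_DAY) + 1
    bounds = subject_start + SECONDS_PER_DAY * np.arange(n_days + 1)
    ts = ts[ts < bounds[-1]]
    idx = np.searchsorted(ts, bounds)
    days = [ts[idx[i] : idx[i + 1]] for i in range(n_days)]
    return days, rejected


def daily_metrics(
    timestamps: np.ndarray,
    schedule: SamplingSchedule,
    subject_start: float,
    n_days: int | None = None,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """Full daily data-quality table for one subject/sensor stream.

    Returns one row per day (1..n_days) with columns ``day_index,
    b_hat, p_hat, d_hat_mean, f_hat_mean, gap_hat_mean, coverage``
    (plus ``subject_id`` and ``sensor`` when a subject id is given).
    """
    days, _ = partition_days(timestamps, subject_start, n_days)
    records = []
    for i, day_ts in enumerate(days, start=1):
        cov = daily_coverage(segment_bursts(day_ts, schedule.threshold, i), schedule)
        records.append(
            (i, cov.b_hat, cov.p_hat, cov.d_hat, cov.f_hat, cov.gap_hat, cov.coverage)
        )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "day_index",
            "b_hat",
            "p_hat",
            "d_hat_mean",
            "f_hat_mean",
            "gap_hat_mean",
            "coverage",
        ],
    )
    if subject_id is not None:
        df.insert(0, "sensor", schedule.sensor_name)
        df.insert(0, "subject_id", subject_id)
    return df
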