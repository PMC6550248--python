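"""Sampling schedules for periodically sampled smartphone sensors.

Battery-constrained sensors (accelerometer, GPS) are sampled on an
alternating on-cycle/off-cycle regime: during each on-cycle of duration
``d`` seconds the sensor records at a target frequency ``f`` pings per
second, followed by a rest period of ``r`` seconds with no collection.
The design implies an expected number of bursts per day ``b = S/(d+r)``
(with ``S`` = 86,400 s) and an expected number of pings per day
``p = f*d*b``, the denominators against which empirical coverage is
measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import InvalidScheduleError

#: Seconds in one day (S).
SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class SamplingSchedule:
    """The designed on/off-cycle sampling regime for one sensor.

    Parameters
    ----------
    sensor_name : str
        Label for the sensor (e.g. ``"accelerometer"``).
    f : float
        Target within-burst sampling frequency, pings per second.
    d : float
        Designed on-cycle (burst) duration, seconds.
    r : float
        Designed off-cycle (rest) duration between bursts, seconds.
    threshold : float
        Gap threshold used to split the observed ping stream into
        bursts: consecutive pings separated by more than ``threshold``
        seconds belong to different bursts.
    """

    sensor_name: str
    f: float
    d: float
    r: float
    threshold: float = 30.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise InvalidScheduleError(f"target frequency must be positive, got f={self.f}")
        if self.d <= 0:
            raise InvalidScheduleError(f"burst duration must be positive, got d={self.d}")
        if self.r < 0:
            raise InvalidScheduleError(f"rest duration must be non-negative, got r={self.r}")
        if self.threshold <= 0:
            raise InvalidScheduleError(f"gap threshold must be positive, got {self.threshold}")
        if self.r > 0 and self.threshold >= self.r:
            warnings.warn(
                f"threshold ({self.threshold}s) >= rest period ({self.r}s) for "
                f"{self.sensor_name}: distinct on-cycles may be merged into one burst",
                stacklevel=2,
            )

    @property
    def period(self) -> float:
        """Length of one on/off cycle, ``d + r`` seconds."""
        return self.d + self.r

    @property
    def expected(self) -> "ExpectedQuantities":
        return expected_quantities(self)


@dataclass(frozen=True)
class ExpectedQuantities:
    """Design expectations implied by a :class:`SamplingSchedule`.

    ``b`` is the expected number of bursts per day and ``p`` the
    expected number of pings per day; both may be non-integer when the
    cycle period does not divide the day.
    """

    S: float
    b: float
    p: float


def expected_quantities(schedule: SamplingSchedule) -> ExpectedQuantities:
    """Compute the expected bursts/day ``b = S/(d+r)`` and pings/day ``p = f*d*b``."""
    b = SECONDS_PER_DAY / (schedule.d + schedule.r)
    p = schedule.f * schedule.d * b
    return ExpectedQuantities(S=SECONDS_PER_DAY, b=b, p=p)


#: The accelerometer regime used throughout: 10 Hz for 60 s on, 60 s off,
#: 30 s burst-splitting threshold.
ACCELEROMETER = SamplingSchedule("accelerometer", f=10.0, d=60.0, r=60.0, threshold=30.0)

#: The GPS regime: 1 Hz for 60 s on, 600 s off, 30 s threshold.
GPS = SamplingSchedule("gps", f=1.0, d=60.0, r=600.0, threshold=30.0)

DEFAULT_SCHEDULES = {"accelerometer": ACCELEROMETER, "gps": GPS}
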