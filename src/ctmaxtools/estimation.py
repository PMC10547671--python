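"""Convert timed stop observations into CTmax estimates.

In a dynamic ramping assay, individuals sit in vials in a shared water bath
whose temperature rises slowly while an observer cycles through the vials
checking for responsiveness. The recorded stop time for an individual is the
latest moment it could have reached its critical thermal maximum (CTmax); the
earliest is its previous check. That interval -- the *uncertainty window* --
has length (vials remaining in the bath) x (seconds per check), and shrinks
as the trial progresses. CTmax is estimated as the mean temperature recorded
by the three bath sensors over the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SensorLog",
    "StopRecord",
    "UncertaintyWindow",
    "CTmaxEstimate",
    "ExclusionReport",
    "ValidationError",
    "build_window",
    "mean_temp_over_window",
    "estimate_ctmax",
    "estimate_trial",
]

DEFAULT_CHECK_SECONDS = 5.0


class ValidationError(ValueError):
    """Raised when input records violate the assay's structural invariants."""


@dataclass(frozen=True)
class SensorLog:
    """One temperature sensor's trace within a single trial.

    Parameters
    ----------
    sensor_id : str
        Label of the sensor (e.g. ``"s1"``).
    times : array-like of float
        Seconds since ramp start, strictly increasing, length >= 2.
    temps : array-like of float
        Temperature in degrees Celsius, same length as ``times``.
    """

    sensor_id: str
    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if times.ndim != 1 or temps.ndim != 1 or times.size != temps.size:
            raise ValidationError(
                f"sensor {self.sensor_id}: times and temps must be 1-d and equal length"
            )
        if times.size < 2:
            raise ValidationError(f"sensor {self.sensor_id}: need at least 2 samples")
        if not np.all(np.diff(times) > 0):
            raise ValidationError(f"sensor {self.sensor_id}: times must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(temps))):
            raise ValidationError(f"sensor {self.sensor_id}: non-finite values")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class StopRecord:
    """One individual's timed observation within a trial.

    ``vials_remaining`` counts the vials in the bath over the focal vial's
    final inter-check gap, the focal vial included, so that
    ``vials_remaining * check_seconds`` equals the time since the individual
    was last seen responsive. For the final individual this is 1.
    """

    individual_id: str
    stop_time: float
    vials_remaining: int
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.excluded:
            if not np.isfinite(self.stop_time) or self.stop_time < 0:
                raise ValidationError(
                    f"individual {self.individual_id}: stop_time must be >= 0, "
                    f"got {self.stop_time}"
                )
            if self.vials_remaining < 1:
                raise ValidationError(
                    f"individual {self.individual_id}: vials_remaining must be >= 1"
                )


@dataclass(frozen=True)
class UncertaintyWindow:
    """Time interval within which an individual could have reached CTmax.

    ``duration`` is the nominal length ``check_seconds * vials_remaining``;
    the realised interval ``[t_start, t_end]`` may be shorter when clamped at
    ramp start.
    """

    t_start: float
    t_end: float
    duration: float

    @property
    def effective_duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class CTmaxEstimate:
    """CTmax estimate with its audit trail.

    ``ctmax`` is the unweighted mean of the three per-sensor window means.
    ``sensor_spread`` (max minus min of the per-sensor means) is reported for
    quality control only and never alters the estimate.
    """

    individual_id: str
    ctmax: float
    window: UncertaintyWindow
    per_sensor_means: tuple[float, ...]
    n_sensors_used: int
    sensor_spread: float = field(default=0.0)


@dataclass(frozen=True)
class ExclusionReport:
    individual_id: str
    reason: str


def build_window(
    stop: StopRecord, check_seconds: float = DEFAULT_CHECK_SECONDS
) -> UncertaintyWindow:
    """Build the uncertainty window for a stop record.

    The window is anchored backward from the recorded stop time (the hard
    upper bound on when CTmax was reached) and extends back by
    ``check_seconds * vials_remaining`` seconds, clamped at ramp start (t=0).
    """
    if check_seconds <= 0:
        raise ValidationError(f"check_seconds must be > 0, got {check_seconds}")
    if stop.stop_time < 0 or not np.isfinite(stop.stop_time):
        raise ValidationError(
            f"individual {stop.individual_id}: stop_time must be >= 0"
        )
    duration = check_seconds * stop.vials_remaining
    t_end = float(stop.stop_time)
    t_start = max(0.0, t_end - duration)
    return UncertaintyWindow(t_start=t_start, t_end=t_end, duration=duration)


def mean_temp_over_window(log: SensorLog, window: UncertaintyWindow) -> float:
    """Time-weighted mean temperature of a sensor trace over a window.

    The trace is linearly interpolated between samples, so the mean is the
    exact integral of the piecewise-linear interpolant over
    ``[t_start, t_end]`` divided by the window length. A zero-length window
    returns the interpolated temperature at ``t_end``.
    """
    a, b = window.t_start, window.t_end
    lo, hi = log.span
    tol = 1e-9
    if b < lo - tol or a > hi + tol:
        raise ValidationError(
            f"sensor {log.sensor_id}: window [{a}, {b}] outside log span [{lo}, {hi}]"
        )
    if a < lo - tol or b > hi + tol:
        raise ValidationError(
            f"sensor {log.sensor_id}: window [{a}, {b}] not fully covered by "
            f"log span [{lo}, {hi}]"
        )
    if b - a <= tol:
        return float(np.interp(b, log.times, log.temps))
    inner = log.times[(log.times > a) & (log.times < b)]
    knots = np.concatenate(([a], inner, [b]))
    vals = np.interp(knots, log.times, log.temps)
    return float(np.trapezoid(vals, knots) / (b - a))


def estimate_ctmax(
    logs: Sequence[SensorLog],
    stop: StopRecord,
    check_seconds: float = DEFAULT_CHECK_SECONDS,
) -> CTmaxEstimate:
    """Estimate one individual's CTmax from its stop record and three sensors.

    CTmax is the average temperature recorded by all three sensors throughout
    the uncertainty window. Excluded individuals are refused: callers must
    filter them (see :func:`estimate_trial`). There is no silent two-sensor
    fallback -- a missing sensor is an error.
    """
    if stop.excluded:
        raise ValidationError(
            f"individual {stop.individual_id} is excluded "
            f"({stop.exclusion_reason or 'no reason recorded'}); cannot estimate"
        )
    if len(logs) != 3:
        raise ValidationError(
            f"individual {stop.individual_id}: need exactly 3 sensor logs, got {len(logs)}"
        )
    window = build_window(stop, check_seconds)
    means = tuple(mean_temp_over_window(log, window) for log in logs)
    return CTmaxEstimate(
        individual_id=stop.individual_id,
        ctmax=float(np.mean(means)),
        window=window,
        per_sensor_means=means,
        n_sensors_used=3,
        sensor_spread=float(max(means) - min(means)),
    )


def estimate_trial(
    logs: Sequence[SensorLog],
    stops: Sequence[StopRecord],
    check_seconds: float = DEFAULT_CHECK_SECONDS,
) -> tuple[list[CTmaxEstimate], list[ExclusionReport]]:
    """Estimate CTmax for every non-excluded individual in one trial.

    Stops must be sorted by stop time with a non-increasing
    ``vials_remaining`` sequence (vials only leave the bath). Excluded
    records produce :class:`ExclusionReport` entries instead of estimates, so
    ``len(estimates) + len(exclusions) == len(stops)``.
    """
    active = [s for s in stops if not s.excluded]
    times = [s.stop_time for s in active]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("stop records must be sorted by stop_time")
    offenders = [
        b.individual_id
        for a, b in zip(active, active[1:])
        if b.vials_remaining > a.vials_remaining
    ]
    if offenders:
        raise ValidationError(
            "vials_remaining must be non-increasing across removals; "
            f"offending records: {', '.join(offenders)}"
        )
    estimates = [estimate_ctmax(logs, s, check_seconds) for s in active]
    exclusions = [
        ExclusionReport(s.individual_id, s.exclusion_reason or "abnormal behavior")
        for s in stops
        if s.excluded
    ]
    return estimates, exclusions
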