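"""Subject records: demographics plus one graded-exercise-test trajectory.

A :class:`SubjectProfile` is the raw input unit of the pipeline — who the
subject is (age drives the age-predicted HRmax, body mass converts relative
to absolute oxygen uptake) and what their treadmill test looked like
(minute-by-minute speed, slope and heart rate). Optionally it carries the
anaerobic-threshold surrogate time and measured Wingate peak/mean power for
training and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError

__all__ = ["TrajectoryPoint", "SubjectProfile"]


@dataclass(frozen=True)
class TrajectoryPoint:
    """One sample of a treadmill test.

    Parameters
    ----------
    time : float
        Minutes from test start.
    speed : float
        Treadmill belt speed, km/h.
    slope : float
        Treadmill grade, percent (0-100 scale).
    hr : float
        Heart rate, beats/min.
    """

    time: float
    speed: float
    slope: float
    hr: float

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise InvalidInputError(f"speed must be >= 0, got {self.speed}")
        if self.slope < 0:
            raise InvalidInputError(f"slope must be >= 0, got {self.slope}")
        if self.hr <= 0:
            raise InvalidInputError(f"hr must be > 0, got {self.hr}")


@dataclass
class SubjectProfile:
    """Demographics and exercise-test trajectory for one subject.

    ``measured_pp`` / ``measured_mp`` are the Wingate peak and mean power in
    watts when available (training/evaluation); ``at_time`` is the minute at
    which the anaerobic-threshold surrogate occurs.
    """

    subject_id: str
    age: float
    sex: str
    body_mass: float
    trajectory: list[TrajectoryPoint] = field(default_factory=list)
    body_height: float | None = None
    at_time: float | None = None
    measured_pp: float | None = None
    measured_mp: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise InvalidInputError(f"age must be > 0, got {self.age}")
        if self.body_mass <= 0:
            raise InvalidInputError(f"body_mass must be > 0, got {self.body_mass}")
        if self.sex not in ("female", "male"):
            raise InvalidInputError(f"sex must be 'female' or 'male', got {self.sex!r}")
        times = [p.time for p in self.trajectory]
        if times:
            if times[0] < 0:
                raise InvalidInputError("trajectory must start at time >= 0")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise InvalidInputError(
                    f"trajectory times must be strictly increasing (subject {self.subject_id})"
                )
            if self.at_time is not None and not (times[0] <= self.at_time <= times[-1]):
                raise InvalidInputError(
                    f"at_time {self.at_time} outside trajectory span "
                    f"[{times[0]}, {times[-1]}] (subject {self.subject_id})"
                )
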