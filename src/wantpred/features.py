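"""GXT feature derivation at fractions of age-predicted maximal heart rate.

A clinical graded exercise test (GXT) records treadmill speed, slope and
heart rate but no gas exchange. The features derived here reconstruct, from
that limited signal, the candidate predictors of Wingate anaerobic power:

* age-predicted HRmax via the Tanaka formula, ``208 - 0.7 * age``;
* the treadmill state (time, speed, slope) at the first upward crossing of
  85%, 90% and 100% of HRmax, located by linear interpolation;
* predicted oxygen uptake at that state via the ACSM running equation
  ``VO2 = 0.2*speed + 0.9*speed*grade + 3.5`` (speed in m/min, grade as a
  fraction, VO2 in mL/kg/min), scaled by body mass for the absolute value;
* intensity composites slope*speed and slope*speed*time;
* predicted VO2 at the anaerobic-threshold surrogate (the minute the
  treadmill slope first increases, i.e. the protocol's RQ = 1 event),
  overridable by an explicit ``at_time``.

Eight feature families per level x three levels + age = 25 candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateFeatureError, InvalidInputError, LevelNotReachedError
from .profiles import SubjectProfile, TrajectoryPoint

__all__ = [
    "LEVELS",
    "FEATURE_FAMILIES",
    "GXTFeatureVector",
    "tanaka_hrmax",
    "acsm_running_vo2",
    "hr_at_fraction",
    "locate_hr_crossing",
    "at_surrogate_time",
    "derive_feature_vector",
    "feature_table",
    "candidate_matrix",
    "candidate_names",
    "Standardizer",
    "standardize",
]

#: Heart-rate levels at which features are derived, as fractions of HRmax.
LEVELS: tuple[float, ...] = (0.85, 0.90, 1.00)

#: Per-level feature families, in registry (tie-break) order.
FEATURE_FAMILIES: tuple[str, ...] = (
    "hr_at_level",
    "time_at_level",
    "vo2_abs",
    "vo2_rel",
    "slope_speed",
    "slope_speed_time",
    "vo2_at_at_abs",
    "vo2_at_at_rel",
)

KMH_TO_M_MIN = 1000.0 / 60.0


def tanaka_hrmax(age: float) -> float:
    """Age-predicted maximal heart rate, beats/min: ``208 - 0.7 * age``."""
    if age < 0:
        raise InvalidInputError(f"age must be >= 0, got {age}")
    return 208.0 - 0.7 * age


def acsm_running_vo2(speed: float, grade: float) -> float:
    """ACSM running equation for oxygen uptake, mL/kg/min.

    Parameters
    ----------
    speed : float
        Belt speed in m/min.
    grade : float
        Grade as a dimensionless fraction (e.g. 0.10 for a 10% incline).
    """
    if speed < 0:
        raise InvalidInputError(f"speed must be >= 0, got {speed}")
    if grade < 0 or grade >= 1:
        raise InvalidInputError(f"grade must be in [0, 1), got {grade}")
    return 0.2 * speed + 0.9 * speed * grade + 3.5


def hr_at_fraction(hr_max: float, fraction: float) -> float:
    """Heart rate at a fraction of maximum: ``fraction * hr_max``."""
    if not 0 < fraction <= 1:
        raise InvalidInputError(f"fraction must be in (0, 1], got {fraction}")
    return fraction * hr_max


def locate_hr_crossing(
    trajectory: list[TrajectoryPoint], target_hr: float, level: float | None = None
) -> tuple[float, float, float]:
    """Treadmill state at the first upward crossing of ``target_hr``.

    Returns ``(time, speed, slope)`` linearly interpolated between the two
    samples bracketing the crossing. If the target is at or below the first
    sample's HR the first point is returned; if it exceeds the trajectory
    maximum a :class:`LevelNotReachedError` is raised.
    """
    if not trajectory:
        raise InvalidInputError("trajectory is empty")
    hrs = [p.hr for p in trajectory]
    if target_hr <= hrs[0]:
        p = trajectory[0]
        return p.time, p.speed, p.slope
    if target_hr > max(hrs):
        raise LevelNotReachedError(target_hr, max(hrs), level)
    for i in range(1, len(trajectory)):
        if hrs[i] >= target_hr:
            lo, hi = trajectory[i - 1], trajectory[i]
            # hrs[i-1] < target <= hrs[i], so the denominator is positive
            w = (target_hr - lo.hr) / (hi.hr - lo.hr)
            return (
                lo.time + w * (hi.time - lo.time),
                lo.speed + w * (hi.speed - lo.speed),
                lo.slope + w * (hi.slope - lo.slope),
            )
    raise LevelNotReachedError(target_hr, max(hrs), level)  # pragma: no cover


def at_surrogate_time(subject: SubjectProfile) -> float | None:
    """Anaerobic-threshold surrogate: explicit ``at_time`` if given, else the
    time at which the treadmill slope first increases (the protocol raises
    the slope when RQ reaches 1). ``None`` when neither is available."""
    if subject.at_time is not None:
        return subject.at_time
    traj = subject.trajectory
    for prev, cur in zip(traj, traj[1:]):
        if cur.slope > prev.slope:
            return cur.time
    return None


def _state_at_time(trajectory: list[TrajectoryPoint], t: float) -> tuple[float, float]:
    """Linearly interpolated (speed, slope) at time ``t``."""
    times = np.array([p.time for p in trajectory])
    speed = float(np.interp(t, times, [p.speed for p in trajectory]))
    slope = float(np.interp(t, times, [p.slope for p in trajectory]))
    return speed, slope


@dataclass
class GXTFeatureVector:
    """Derived candidate predictors for one subject at one HR level.

    Units: HR in beats/min, time in minutes, speed in km/h, slope in percent,
    relative VO2 in mL/kg/min, absolute VO2 in mL/min. The intensity
    composites keep the raw trajectory units (percent * km/h [* min]).
    """

    subject_id: str
    level: float
    hr_max: float
    hr_at_level: float
    time_at_level: float
    speed_at_level: float
    slope_at_level: float
    vo2_rel: float
    vo2_abs: float
    slope_speed: float
    slope_speed_time: float
    age: float
    vo2_at_at_rel: float | None = None
    vo2_at_at_abs: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def derive_feature_vector(subject: SubjectProfile, level: float) -> GXTFeatureVector:
    """Compute the full feature vector for one subject at one HR level.

    Raises :class:`LevelNotReachedError` when the trajectory never reaches
    ``level * hrmax``. Anaerobic-threshold features are ``None`` when no
    surrogate is available.
    """
    hr_max = tanaka_hrmax(subject.age)
    target = hr_at_fraction(hr_max, level)
    t, speed_kmh, slope_pct = locate_hr_crossing(subject.trajectory, target, level)
    vo2_rel = acsm_running_vo2(speed_kmh * KMH_TO_M_MIN, slope_pct / 100.0)
    vo2_abs = vo2_rel * subject.body_mass

    at_t = at_surrogate_time(subject)
    vo2_at_rel = vo2_at_abs = None
    if at_t is not None:
        at_speed, at_slope = _state_at_time(subject.trajectory, at_t)
        vo2_at_rel = acsm_running_vo2(at_speed * KMH_TO_M_MIN, at_slope / 100.0)
        vo2_at_abs = vo2_at_rel * subject.body_mass

    slope_speed = slope_pct * speed_kmh
    return GXTFeatureVector(
        subject_id=subject.subject_id,
        level=level,
        hr_max=hr_max,
        hr_at_level=target,
        time_at_level=t,
        speed_at_level=speed_kmh,
        slope_at_level=slope_pct,
        vo2_rel=vo2_rel,
        vo2_abs=vo2_abs,
        slope_speed=slope_speed,
        slope_speed_time=slope_speed * t,
        age=subject.age,
        vo2_at_at_rel=vo2_at_rel,
        vo2_at_at_abs=vo2_at_abs,
    )


def feature_table(
    subjects: list[SubjectProfile], levels: tuple[float, ...] = LEVELS
) -> pd.DataFrame:
    """Long-format feature table: one row per subject x level."""
    rows = [derive_feature_vector(s, lvl).as_dict() for s in subjects for lvl in levels]
    return pd.DataFrame(rows)


def candidate_names(level: float) -> list[str]:
    """Registry-ordered candidate feature names for a fit at one level."""
    pct = int(round(level * 100))
    return [f"{fam}@{pct}" for fam in FEATURE_FAMILIES] + ["age"]


def candidate_matrix(
    subjects: list[SubjectProfile], level: float, table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Wide candidate matrix for a fit at one level.

    One row per subject (indexed by subject_id), columns the eight per-level
    families tagged ``family@<pct>`` plus ``age``, in registry order.
    """
    if table is None:
        table = feature_table(subjects, (level,))
    sub = table[np.isclose(table["level"], level)].set_index("subject_id")
    pct = int(round(level * 100))
    out = pd.DataFrame(index=sub.index)
    for fam in FEATURE_FAMILIES:
        out[f"{fam}@{pct}"] = sub[fam].astype(float)
    out["age"] = sub["age"].astype(float)
    return out


class GXTFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer from subject profiles to the long feature table."""

    def __init__(self, levels: tuple[float, ...] = LEVELS):
        self.levels = levels

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        return self

    def transform(self, X: list[SubjectProfile]) -> pd.DataFrame:
        return feature_table(list(X), tuple(self.levels))


class Standardizer(BaseEstimator, TransformerMixin):
    """Column z-scoring with the sample (n-1) SD convention.

    Stats are learned on the calibration set and reused unchanged on test
    and validation data so every prediction lives in the calibration frame.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "Standardizer":
        X = pd.DataFrame(X)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        for col, s in sd.items():
            if not math.isfinite(s) or s <= 0:
                raise DegenerateFeatureError(str(col))
        self.mean_ = mean
        self.sd_ = sd
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return (X - self.mean_) / self.sd_

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        Z = pd.DataFrame(Z)
        return Z * self.sd_ + self.mean_

    def stats(self) -> dict[str, dict[str, float]]:
        """Serializable per-column {mean, sd}."""
        return {
            str(c): {"mean": float(self.mean_[c]), "sd": float(self.sd_[c])}
            for c in self.mean_.index
        }

    @classmethod
    def from_stats(cls, stats: dict[str, dict[str, float]]) -> "Standardizer":
        obj = cls()
        obj.mean_ = pd.Series({c: v["mean"] for c, v in stats.items()})
        obj.sd_ = pd.Series({c: v["sd"] for c, v in stats.items()})
        obj.feature_names_in_ = np.asarray(list(stats), dtype=object)
        obj.n_features_in_ = len(stats)
        return obj


def standardize(
    table: pd.DataFrame, reference_stats: dict[str, dict[str, float]] | None = None
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Z-score columns; compute stats from the input when none are given.

    Returns the transformed table and the stats used, for reuse on held-out
    data.
    """
    if reference_stats is None:
        sc = Standardizer().fit(table)
    else:
        sc = Standardizer.from_stats(reference_stats)
    return sc.transform(table), sc.stats()
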