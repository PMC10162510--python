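"""CSV/JSON interchange.

Subjects CSV: ``subject_id, age_y, sex, mass_kg, height_cm, at_time_min,
pp_w, mp_w`` (last four optional; empty = missing). Trajectory CSV:
``subject_id, time_min, speed_kmh, slope_pct, hr_bpm``. Feature table CSV:
one row per subject x level with the feature-vector field names as columns.
"""

from __future__ import annotations

import csv

import pandas as pd

from .errors import InvalidInputError, SchemaError
from .profiles import SubjectProfile, TrajectoryPoint

__all__ = [
    "read_subjects_csv",
    "read_trajectories_csv",
    "read_cohort",
    "write_cohort",
    "write_feature_table",
    "read_feature_table",
]

SUBJECT_REQUIRED = ("subject_id", "age_y", "sex", "mass_kg")
SUBJECT_OPTIONAL = ("height_cm", "at_time_min", "pp_w", "mp_w")
TRAJECTORY_REQUIRED = ("subject_id", "time_min", "speed_kmh", "slope_pct", "hr_bpm")


def _check_header(path, header, required) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(header)}")


def _num(row: dict, col: str, path, line: int, optional: bool = False):
    raw = (row.get(col) or "").strip()
    if raw == "":
        if optional:
            return None
        raise SchemaError(f"{path}, line {line}: missing value for {col!r}")
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(f"{path}, line {line}: unparseable numeric {raw!r} in column {col!r}")


def read_trajectories_csv(path) -> dict[str, list[TrajectoryPoint]]:
    """Per-subject trajectories, keyed by subject_id, in file order."""
    out: dict[str, list[TrajectoryPoint]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        _check_header(path, reader.fieldnames, TRAJECTORY_REQUIRED)
        for line, row in enumerate(reader, start=2):
            sid = (row.get("subject_id") or "").strip()
            if not sid:
                raise SchemaError(f"{path}, line {line}: missing subject_id")
            try:
                pt = TrajectoryPoint(
                    time=_num(row, "time_min", path, line),
                    speed=_num(row, "speed_kmh", path, line),
                    slope=_num(row, "slope_pct", path, line),
                    hr=_num(row, "hr_bpm", path, line),
                )
            except InvalidInputError as exc:
                raise SchemaError(f"{path}, line {line}: {exc}") from exc
            out.setdefault(sid, []).append(pt)
    return out


def read_subjects_csv(
    path, trajectories: dict[str, list[TrajectoryPoint]] | None = None
) -> list[SubjectProfile]:
    """Typed subject records with row-level validation."""
    trajectories = trajectories or {}
    subjects = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        _check_header(path, reader.fieldnames, SUBJECT_REQUIRED)
        for line, row in enumerate(reader, start=2):
            sid = (row.get("subject_id") or "").strip()
            if not sid:
                raise SchemaError(f"{path}, line {line}: missing subject_id")
            sex = (row.get("sex") or "").strip().lower()
            try:
                subjects.append(
                    SubjectProfile(
                        subject_id=sid,
                        age=_num(row, "age_y", path, line),
                        sex=sex,
                        body_mass=_num(row, "mass_kg", path, line),
                        body_height=_num(row, "height_cm", path, line, optional=True),
                        at_time=_num(row, "at_time_min", path, line, optional=True),
                        measured_pp=_num(row, "pp_w", path, line, optional=True),
                        measured_mp=_num(row, "mp_w", path, line, optional=True),
                        trajectory=trajectories.get(sid, []),
                    )
                )
            except InvalidInputError as exc:
                raise SchemaError(f"{path}, line {line}: {exc}") from exc
    return subjects


def read_cohort(subjects_path, trajectories_path) -> list[SubjectProfile]:
    """Join the two input tables into full subject profiles."""
    traj = read_trajectories_csv(trajectories_path)
    subjects = read_subjects_csv(subjects_path, traj)
    orphans = [s.subject_id for s in subjects if not s.trajectory]
    if orphans:
        raise SchemaError(f"{trajectories_path}: no trajectory rows for subject(s) {orphans}")
    return subjects


def write_cohort(subjects: list[SubjectProfile], subjects_path, trajectories_path) -> None:
    with open(subjects_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SUBJECT_REQUIRED + SUBJECT_OPTIONAL)
        for s in subjects:
            w.writerow(
                [
                    s.subject_id,
                    repr(s.age),
                    s.sex,
                    repr(s.body_mass),
                    "" if s.body_height is None else repr(s.body_height),
                    "" if s.at_time is None else repr(s.at_time),
                    "" if s.measured_pp is None else repr(s.measured_pp),
                    "" if s.measured_mp is None else repr(s.measured_mp),
                ]
            )
    with open(trajectories_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRAJECTORY_REQUIRED)
        for s in subjects:
            for p in s.trajectory:
                w.writerow([s.subject_id, repr(p.time), repr(p.speed), repr(p.slope), repr(p.hr)])


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("subject_id", "level"):
        if col not in table.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return table
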