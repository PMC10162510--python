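"""Exception hierarchy.

CLI exit-code convention: 0 success, 2 schema/input-file errors,
3 numeric or degeneracy errors.
"""


class WantpredError(Exception):
    """Base class for all package errors."""


class InvalidInputError(WantpredError, ValueError):
    """A scalar argument violates its physical/numeric precondition."""


class LevelNotReachedError(WantpredError):
    """The trajectory never reaches the target heart-rate level."""

    def __init__(self, target_hr: float, max_hr: float, level: float | None = None):
        self.target_hr = target_hr
        self.max_hr = max_hr
        self.level = level
        lvl = f" (level {level:.0%})" if level is not None else ""
        super().__init__(
            f"target HR {target_hr:.1f} bpm{lvl} exceeds the trajectory maximum "
            f"of {max_hr:.1f} bpm: level not reached"
        )


class DegenerateFeatureError(WantpredError):
    """A feature column has zero variance and cannot be standardized."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"feature column {column!r} has zero standard deviation")


class SingularDesignError(WantpredError):
    """The regression design matrix is rank deficient."""


class DegenerateTargetError(WantpredError):
    """The regression target has zero variance."""


class SchemaError(WantpredError):
    """An input table is missing columns or contains unparseable rows."""
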