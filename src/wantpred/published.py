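"""The six published Wingate-power prediction equations.

One equation per (outcome, level) cell: peak power (PP) and mean power (MP)
at 85%, 90% and 100% of age-predicted HRmax. Each is a linear combination
of z-scored GXT features with the intercept in watts at the standardized
origin.

The coefficient magnitudes (hundreds of watts per unit of a predictor whose
raw scale is thousands of mL/min) are only dimensionally coherent for
z-scored predictors; applying an equation therefore requires
standardization statistics for a reference cohort. The original
calibration-set means/SDs were not published, so absolute predictions are
reference-frame dependent — see the methods note.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .features import FEATURE_FAMILIES, GXTFeatureVector, Standardizer

__all__ = ["PublishedEquation", "load_published_equation", "published_equations", "predict_power"]


@dataclass(frozen=True)
class PublishedEquation:
    """One published prediction equation as structured coefficients."""

    outcome: str
    level: float
    intercept: float
    terms: tuple[tuple[str, float], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 2 <= len(self.terms) <= 4:
            raise ValueError(f"expected 2-4 terms, got {len(self.terms)}")
        for name, _ in self.terms:
            fam = name.split("@")[0]
            if fam not in FEATURE_FAMILIES and fam != "age":
                raise ValueError(f"unknown feature family in term {name!r}")

    def feature_names(self) -> list[str]:
        return [name for name, _ in self.terms]

    def to_json(self) -> str:
        d = asdict(self)
        d["terms"] = [list(t) for t in self.terms]
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PublishedEquation":
        d = json.loads(text)
        d["terms"] = tuple((n, float(c)) for n, c in d["terms"])
        return cls(**d)


def _load_registry() -> list[PublishedEquation]:
    raw = json.loads(
        resources.files("wantpred").joinpath("data/published_equations.json").read_text()
    )
    return [
        PublishedEquation(
            outcome=e["outcome"],
            level=float(e["level"]),
            intercept=float(e["intercept"]),
            terms=tuple((n, float(c)) for n, c in e["terms"]),
            provenance=e.get("provenance", ""),
        )
        for e in raw["equations"]
    ]


def published_equations() -> list[PublishedEquation]:
    """All six shipped equations."""
    return _load_registry()


def load_published_equation(outcome: str, level: float) -> PublishedEquation:
    """Fetch the shipped equation for one (outcome, level) cell.

    ``outcome`` is ``"PP"`` or ``"MP"`` (case-insensitive); ``level`` one of
    0.85, 0.90, 1.00 (or 85/90/100).
    """
    lvl = float(level)
    if lvl > 1:
        lvl /= 100.0
    key = (str(outcome).upper(), round(lvl, 2))
    for eq in _load_registry():
        if (eq.outcome, round(eq.level, 2)) == key:
            return eq
    raise KeyError(f"no published equation for outcome={outcome!r}, level={level!r}")


def _feature_value(features, name: str):
    if isinstance(features, GXTFeatureVector):
        fam = name.split("@")[0]
        val = getattr(features, fam, None)
    elif isinstance(features, (dict, pd.Series)):
        val = features.get(name) if isinstance(features, dict) else features.get(name, None)
        if val is None and "@" in name:  # tolerate untagged keys
            fam = name.split("@")[0]
            val = features.get(fam) if isinstance(features, dict) else features.get(fam, None)
    else:
        raise TypeError(f"unsupported feature container {type(features)!r}")
    if val is None or (isinstance(val, float) and np.isnan(val)):
        raise KeyError(f"required feature {name!r} is missing")
    return float(val)


def predict_power(
    equation: PublishedEquation,
    features,
    stats: dict[str, dict[str, float]],
) -> float:
    """Evaluate a published equation on one subject's feature vector.

    ``features`` may be a :class:`GXTFeatureVector`, dict or Series holding
    raw (unstandardized) values; ``stats`` supplies the per-feature mean/SD
    of the reference frame. A warning (not an error) is emitted when the
    predicted power is non-positive.
    """
    sc = Standardizer.from_stats(stats)
    total = equation.intercept
    for name, coef in equation.terms:
        x = _feature_value(features, name)
        key = name if name in stats else name.split("@")[0]
        if key not in stats:
            raise KeyError(f"standardization stats missing for feature {name!r}")
        z = (x - float(sc.mean_[key])) / float(sc.sd_[key])
        total += coef * z
    if total <= 0:
        warnings.warn(
            f"non-positive predicted power ({total:.1f} W) for {equation.outcome} "
            f"at level {equation.level:.0%}",
            stacklevel=2,
        )
    return float(total)
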