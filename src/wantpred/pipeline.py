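"""End-to-end pipeline: derive features, split, fit, evaluate, report.

One run covers every requested (outcome, level) cell and emits a
machine-readable report mirroring the published result tables (Spearman
rho, RMSE, percent error mean +/- SD per cell) plus one model JSON per
cell. Every artifact embeds the root seed and a hash of the configuration
so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .errors import WantpredError
from .features import LEVELS, candidate_matrix, feature_table
from .profiles import SubjectProfile
from .rng import substream
from .selection import SelectionResult, train_model

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("wantpred")


@dataclass
class RunConfig:
    levels: tuple[float, ...] = LEVELS
    outcomes: tuple[str, ...] = ("PP", "MP")
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    seed: int = 0
    min_pct_improvement: float = 0.5
    max_features: int = 10
    n_bins: int = 4
    n_error_reps: int = 100
    error_frac: float = 0.3
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise WantpredError(f"split fractions must sum to 1, got {self.fractions}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _cell_key(outcome: str, level: float) -> str:
    return f"{outcome}@{int(round(level * 100))}"


def run_pipeline(
    subjects: list[SubjectProfile], config: RunConfig | None = None
) -> dict:
    """Run derive -> split -> fit -> evaluate for every (outcome, level).

    Returns the report dict; when ``config.out_dir`` is set also writes
    ``report.json``, ``report.txt``, one ``model_<cell>.json`` per cell and
    a ``predictions_<cell>.csv`` over the full cohort.
    """
    config = config or RunConfig()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    table = feature_table(subjects, tuple(config.levels))
    outcome_values = {
        "PP": pd.Series(
            {s.subject_id: s.measured_pp for s in subjects if s.measured_pp is not None}
        ),
        "MP": pd.Series(
            {s.subject_id: s.measured_mp for s in subjects if s.measured_mp is not None}
        ),
    }

    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": len(subjects),
        "cells": {},
    }
    results: dict[str, SelectionResult] = {}
    for level in config.levels:
        candidates = candidate_matrix(subjects, level, feature_table(subjects, (level,)))
        # drop candidate columns that are unavailable for part of the cohort
        # (e.g. no anaerobic-threshold surrogate)
        incomplete = [c for c in candidates.columns if candidates[c].isna().any()]
        if incomplete:
            log.info("level %.0f%%: dropping incomplete candidates %s", level * 100, incomplete)
            candidates = candidates.drop(columns=incomplete)
        for outcome in config.outcomes:
            y = outcome_values[outcome]
            if y.empty:
                raise WantpredError(
                    f"stage fit[{_cell_key(outcome, level)}]: no measured {outcome} values"
                )
            cell_seed = int(substream(config.seed, f"fit:{_cell_key(outcome, level)}").integers(2**31))
            try:
                res = train_model(
                    candidates.loc[y.index],
                    y,
                    outcome=outcome,
                    level=level,
                    seed=cell_seed,
                    fractions=config.fractions,
                    n_bins=config.n_bins,
                    min_pct_improvement=config.min_pct_improvement,
                    max_features=config.max_features,
                    n_error_reps=config.n_error_reps,
                    error_frac=config.error_frac,
                )
            except WantpredError as exc:
                raise WantpredError(f"stage fit[{_cell_key(outcome, level)}]: {exc}") from exc
            key = _cell_key(outcome, level)
            results[key] = res
            report["cells"][key] = {
                "selected_features": res.selected_features,
                "n_features": len(res.selected_features),
                "test_spearman_rho": res.test_spearman[0],
                "validation_spearman_rho": res.validation_spearman[0],
                "validation_spearman_p": res.validation_spearman[1],
                "validation_rmse_w": res.validation_rmse,
                "pct_error_mean": res.pct_error_mean,
                "pct_error_sd": res.pct_error_sd,
                "seed": cell_seed,
            }
            if out_dir:
                res.to_json(out_dir / f"model_{key}.json", config_hash=report["config_hash"])
                preds = pd.DataFrame(
                    {
                        "subject_id": candidates.loc[y.index].index,
                        "level": int(round(level * 100)),
                        "outcome": outcome,
                        "predicted_w": res.predict(candidates.loc[y.index]),
                        "measured_w": y.to_numpy(),
                    }
                )
                preds.to_csv(out_dir / f"predictions_{key}.csv", index=False)

    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out_dir / "report.txt", "w") as fh:
            fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Plain-text report, one row per (outcome, level) cell."""
    lines = [
        f"wantpred run  seed={report['seed']}  config={report['config_hash']}  "
        f"n={report['n_subjects']}",
        "",
        f"{'cell':<10}{'k':>3}{'rho(val)':>10}{'p(val)':>12}{'RMSE[W]':>9}{'%err':>12}",
    ]
    for key, cell in sorted(report["cells"].items()):
        lines.append(
            f"{key:<10}{cell['n_features']:>3}"
            f"{cell['validation_spearman_rho']:>10.3f}"
            f"{cell['validation_spearman_p']:>12.2e}"
            f"{cell['validation_rmse_w']:>9.1f}"
            f"{cell['pct_error_mean']:>7.1f} ± {cell['pct_error_sd']:.1f}"
        )
    return "\n".join(lines) + "\n"
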