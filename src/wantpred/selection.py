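"""Greedy forward feature selection by multiple linear regression.

The training algorithm: subjects are split into calibration (40%), test
(30%) and validation (30%) subsets, stratified on predicted VO2max so every
fitness level is represented in each subset. On the calibration set,
features are added one at a time — at each iteration every remaining
candidate is tried in a least-squares multiple regression and the one
minimizing the residual sum of squares is kept. Selection stops before
adding a feature whose relative adjusted-R² improvement is negative or
below a minimal threshold (0.5% by default). The fitted equation is scored
by Spearman rank correlation on the test and validation subsets, and the
percent-error distribution is estimated by applying the fixed model to 100
resampled validation subsets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DegenerateTargetError,
    InvalidInputError,
    SingularDesignError,
)
from .features import Standardizer, candidate_names
from .rng import substream

__all__ = [
    "SplitAssignment",
    "SelectionResult",
    "fit_ols",
    "adjusted_r2",
    "spearman_rho",
    "percent_error",
    "stratified_split",
    "GreedyForwardRegressor",
    "greedy_select",
    "validation_error_distribution",
    "train_model",
]


# ---------------------------------------------------------------------------
# elementary statistics


def fit_ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for a design matrix that already contains
    its intercept column. Raises :class:`SingularDesignError` on rank
    deficiency."""
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if design.ndim != 2:
        raise InvalidInputError("design must be 2-D")
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]} columns)"
        )
    return beta


def adjusted_r2(y: np.ndarray, y_hat: np.ndarray, p: int) -> float:
    """R² penalized for the number of predictors ``p``:
    ``1 - (1 - R²)(n - 1)/(n - p - 1)``; plain R² when ``p == 0``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = y.size
    if n <= p + 1:
        raise InvalidInputError(f"adjusted R² undefined for n={n}, p={p}")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DegenerateTargetError("target has zero variance")
    r2 = 1.0 - float(np.sum((y - y_hat) ** 2)) / sst
    if p == 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def spearman_rho(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size != a.size:
        raise InvalidInputError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateTargetError("Spearman correlation undefined for a constant vector")
    res = sps.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def percent_error(y_real, y_pred):
    """Absolute percent error ``|y_real - y_pred| / y_real * 100``.

    Elementwise for array input; scalar for scalar input.
    """
    y_real = np.asarray(y_real, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.any(y_real == 0):
        raise InvalidInputError("percent error undefined where y_real == 0")
    out = np.abs(y_real - y_pred) / y_real * 100.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# cohort splitting


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint calibration/test/validation subject-id sets."""

    calibration_ids: tuple
    test_ids: tuple
    validation_ids: tuple
    seed: int
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)

    def as_labels(self) -> dict:
        out = {i: "calibration" for i in self.calibration_ids}
        out.update({i: "test" for i in self.test_ids})
        out.update({i: "validation" for i in self.validation_ids})
        return out


def _largest_remainder(quota: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def stratified_split(
    strat_values: pd.Series,
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    n_bins: int = 4,
    seed: int = 0,
) -> SplitAssignment:
    """Stratified calibration/test/validation split.

    Subjects are ranked by ``strat_values`` (predicted VO2max), cut into
    ``n_bins`` equal-rank bins, and within each bin membership is drawn at
    the given fractions; global subset sizes match ``fraction * n`` to
    within rounding (+/-1). Deterministic given the seed.
    """
    strat_values = pd.Series(strat_values)
    n = len(strat_values)
    if n < 10:
        raise InvalidInputError(f"need at least 10 subjects to split, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidInputError(f"fractions must sum to 1, got {fractions}")
    ids = np.asarray(strat_values.index, dtype=object)
    rng = np.random.default_rng(seed)

    # global targets by largest remainder
    targets = _largest_remainder(np.asarray(fractions) * n, n)

    # rank-based bins (contiguous chunks of the sorted order)
    order = np.argsort(strat_values.to_numpy(), kind="stable")
    bins = np.array_split(order, max(1, n_bins))

    # per-bin quotas: floor of proportional share, then distribute each
    # bin's leftover slots to the groups with the largest fractional share
    # among those still short of their global target
    base = [np.floor(len(b) * np.asarray(fractions)).astype(int) for b in bins]
    frac_part = [len(b) * np.asarray(fractions) - bq for b, bq in zip(bins, base)]
    residual = targets - np.sum(base, axis=0)
    for b_idx, b in enumerate(bins):
        extras = len(b) - base[b_idx].sum()
        for _ in range(extras):
            pref = np.argsort(-frac_part[b_idx], kind="stable")
            k = next(k for k in pref if residual[k] > 0)
            base[b_idx][k] += 1
            frac_part[b_idx][k] = -1.0
            residual[k] -= 1

    groups: list[list] = [[], [], []]
    for b_idx, b in enumerate(bins):
        perm = rng.permutation(len(b))
        shuffled = ids[b[perm]]
        c0, c1, _ = base[b_idx]
        groups[0].extend(shuffled[:c0])
        groups[1].extend(shuffled[c0 : c0 + c1])
        groups[2].extend(shuffled[c0 + c1 :])

    cal, test, val = (tuple(g) for g in groups)
    if min(len(cal), len(test), len(val)) == 0:
        raise InvalidInputError("cohort too small to populate all three subsets")
    return SplitAssignment(cal, test, val, seed=seed, fractions=tuple(fractions))


# ---------------------------------------------------------------------------
# the greedy estimator


class GreedyForwardRegressor(BaseEstimator, RegressorMixin):
    """Forward-stepwise multiple linear regression.

    At each iteration the single remaining candidate whose inclusion
    minimizes the calibration residual sum of squares is added (ties broken
    by lowest column index). Selection stops before adding a feature whose
    relative adjusted-R² improvement is negative or below
    ``min_pct_improvement`` percent. Expects predictors already standardized
    with calibration-set statistics.

    Parameters
    ----------
    min_pct_improvement : float
        Minimal relative adjusted-R² improvement, in percent, required to
        keep adding features (default 0.5).
    max_features : int
        Safety cap on the number of selected features (default 10).

    Attributes
    ----------
    selected_idx_ : list of int
        Column indices in selection order.
    selected_features_ : list of str
        Column names in selection order (indices stringified for arrays).
    intercept_ : float
    coef_ : ndarray, aligned with ``selected_idx_``.
    adj_r2_path_ : list of float
        Calibration adjusted R² after each addition.
    """

    def __init__(self, min_pct_improvement: float = 0.5, max_features: int = 10):
        self.min_pct_improvement = min_pct_improvement
        self.max_features = max_features

    def _validate(self, X, y=None):
        names = None
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InvalidInputError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("X contains non-finite values")
        if y is not None:
            y = np.asarray(y, dtype=float).ravel()
            if y.size != X.shape[0]:
                raise InvalidInputError("X and y have inconsistent lengths")
            return X, y, names
        return X, names

    def fit(self, X, y) -> "GreedyForwardRegressor":
        X, y, names = self._validate(X, y)
        n, p_all = X.shape
        if np.ptp(y) == 0:
            raise DegenerateTargetError("target has zero variance")
        if n < 4:
            raise InvalidInputError("need at least 4 calibration rows")

        self.n_features_in_ = p_all
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)

        selected: list[int] = []
        path: list[float] = []
        sst = float(np.sum((y - y.mean()) ** 2))
        intercept = np.ones((n, 1))
        beta_best: np.ndarray = np.array([y.mean()])
        prev_adj: float | None = None
        cap = min(self.max_features, p_all, n - 2)

        while len(selected) < cap:
            best = None  # (sse, j, beta)
            for j in range(p_all):
                if j in selected:
                    continue
                design = np.column_stack([intercept, X[:, selected + [j]]])
                beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
                sse = float(np.sum((y - design @ beta) ** 2))
                if best is None or sse < best[0] - 1e-12 * sst:
                    best = (sse, j, beta)
            if best is None:  # pragma: no cover - cap handles this
                break
            sse, j, beta = best
            # adjusted R² directly from the winning SSE
            k = len(selected) + 1
            r2 = 1.0 - sse / sst
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)

            if prev_adj is None:
                if sse >= sst * (1 - 1e-12):
                    warnings.warn(
                        "no candidate improves on the intercept-only model; "
                        "keeping the single best feature",
                        stacklevel=2,
                    )
                selected.append(j)
                path.append(adj)
                beta_best = beta
                prev_adj = adj
                continue

            gain = adj - prev_adj
            if gain <= 0:
                break
            rel_pct = gain / abs(prev_adj) * 100.0 if prev_adj != 0 else np.inf
            if rel_pct < self.min_pct_improvement:
                break
            selected.append(j)
            path.append(adj)
            beta_best = beta
            prev_adj = adj

        self.selected_idx_ = selected
        self.selected_features_ = (
            [names[j] for j in selected] if names is not None else [str(j) for j in selected]
        )
        self.intercept_ = float(beta_best[0])
        self.coef_ = np.asarray(beta_best[1:], dtype=float)
        self.adj_r2_path_ = path
        return self

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            X = X[[c for c in self.feature_names_in_]]
        X, _ = self._validate(X)
        return self.intercept_ + X[:, self.selected_idx_] @ self.coef_


# ---------------------------------------------------------------------------
# result container and orchestration


@dataclass
class SelectionResult:
    """A fitted prediction equation with its diagnostics."""

    outcome: str
    level: float
    selected_features: list[str]
    intercept: float
    coefficients: dict[str, float]
    standardization_stats: dict[str, dict[str, float]]
    train_adj_r2_path: list[float]
    test_spearman: tuple[float, float]
    validation_spearman: tuple[float, float]
    validation_rmse: float
    pct_error_mean: float
    pct_error_sd: float
    seed: int = 0
    split: dict = field(default_factory=dict)

    def predict(self, candidates: pd.DataFrame) -> np.ndarray:
        """Predict watts from a raw (unstandardized) candidate matrix."""
        sc = Standardizer.from_stats(self.standardization_stats)
        z = sc.transform(candidates[list(self.standardization_stats)])
        yhat = np.full(len(z), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            yhat += coef * z[name].to_numpy()
        return yhat

    def to_dict(self) -> dict:
        d = asdict(self)
        d["test_spearman"] = {"rho": self.test_spearman[0], "p": self.test_spearman[1]}
        d["validation_spearman"] = {
            "rho": self.validation_spearman[0],
            "p": self.validation_spearman[1],
        }
        return d

    def to_json(self, path=None, **extra) -> str:
        payload = {**self.to_dict(), **extra}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        d = dict(d)
        for k in ("test_spearman", "validation_spearman"):
            v = d[k]
            d[k] = (v["rho"], v["p"]) if isinstance(v, dict) else tuple(v)
        # keep coefficients in selection order (JSON may have sorted them)
        d["coefficients"] = {
            name: d["coefficients"][name] for name in d["selected_features"]
        }
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def greedy_select(
    X_cal: pd.DataFrame,
    y_cal,
    X_test: pd.DataFrame,
    y_test,
    min_pct_improvement: float = 0.5,
    max_features: int = 10,
) -> GreedyForwardRegressor:
    """Fit the greedy model on (standardized) calibration data and attach the
    test-set Spearman diagnostic as ``model.test_spearman_``."""
    model = GreedyForwardRegressor(
        min_pct_improvement=min_pct_improvement, max_features=max_features
    ).fit(X_cal, y_cal)
    model.test_spearman_ = spearman_rho(np.asarray(y_test, float), model.predict(X_test))
    return model


def validation_error_distribution(
    model,
    X_pool: pd.DataFrame,
    y_pool,
    n_reps: int = 100,
    frac: float = 0.3,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of the per-subset mean percent error.

    The fitted model is held fixed; ``n_reps`` validation subsets of size
    ``frac * len(pool)`` are drawn without replacement and the mean
    per-subject percent error of each is recorded. Returns the mean and
    sample SD over the subsets.
    """
    if n_reps < 2:
        raise InvalidInputError("need n_reps >= 2 for an SD")
    y_pool = np.asarray(y_pool, dtype=float)
    n = len(y_pool)
    m = int(round(frac * n))
    if m < 3:
        raise InvalidInputError(f"subset size {m} too small (frac {frac} of pool {n})")
    y_hat = np.asarray(model.predict(X_pool), dtype=float)
    pe = percent_error(y_pool, y_hat)
    rng = np.random.default_rng(seed)
    rep_means = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        rep_means[r] = pe[idx].mean()
    return float(rep_means.mean()), float(rep_means.std(ddof=1))


def train_model(
    candidates: pd.DataFrame,
    y: pd.Series,
    outcome: str,
    level: float,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    n_bins: int = 4,
    min_pct_improvement: float = 0.5,
    max_features: int = 10,
    n_error_reps: int = 100,
    error_frac: float = 0.3,
    strat_values: pd.Series | None = None,
) -> SelectionResult:
    """Full training run for one (outcome, level) cell.

    ``candidates`` is the raw (unstandardized) candidate matrix indexed by
    subject id; ``y`` the measured power in watts on the same index. The
    split is stratified on the ACSM-predicted relative VO2max at the fit
    level unless ``strat_values`` overrides it.
    """
    candidates = pd.DataFrame(candidates)
    y = pd.Series(y).loc[candidates.index].astype(float)
    if strat_values is None:
        strat_col = f"vo2_rel@{int(round(level * 100))}"
        strat_values = (
            candidates[strat_col] if strat_col in candidates else candidates.iloc[:, 0]
        )

    split = stratified_split(
        strat_values,
        fractions=fractions,
        n_bins=n_bins,
        seed=int(substream(seed, "split").integers(2**31)),
    )
    cal, test, val = (
        list(split.calibration_ids),
        list(split.test_ids),
        list(split.validation_ids),
    )

    scaler = Standardizer().fit(candidates.loc[cal])
    Z = scaler.transform(candidates)

    model = greedy_select(
        Z.loc[cal],
        y.loc[cal],
        Z.loc[test],
        y.loc[test],
        min_pct_improvement=min_pct_improvement,
        max_features=max_features,
    )

    y_val = y.loc[val].to_numpy()
    yhat_val = model.predict(Z.loc[val])
    val_rho = spearman_rho(y_val, yhat_val)
    rmse = float(np.sqrt(np.mean((y_val - yhat_val) ** 2)))
    err_mean, err_sd = validation_error_distribution(
        model,
        Z.loc[val],
        y_val,
        n_reps=n_error_reps,
        frac=error_frac,
        seed=int(substream(seed, "error-reps").integers(2**31)),
    )

    return SelectionResult(
        outcome=outcome,
        level=level,
        selected_features=list(model.selected_features_),
        intercept=model.intercept_,
        coefficients=dict(zip(model.selected_features_, model.coef_.tolist())),
        standardization_stats=scaler.stats(),
        train_adj_r2_path=list(model.adj_r2_path_),
        test_spearman=model.test_spearman_,
        validation_spearman=val_rho,
        validation_rmse=rmse,
        pct_error_mean=err_mean,
        pct_error_sd=err_sd,
        seed=seed,
        split={"calibration": cal, "test": test, "validation": val},
    )
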