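"""Multivariate linear regression of CO2 affinity and model validation.

The affinity model is ordinary least squares on z-scored descriptors
(z-scoring always uses training-split statistics only, so no test
information leaks into the scaler).  Model search enumerates every
descriptor subset of a fixed size exhaustively and ranks candidates by
leave-one-out Q2, with test-set MAE as tiebreak.

A pre-screen classifies nucleophiles by their HOMO energy: only
candidates with epsilon_HOMO >= -0.140 Hartree (boundary inclusive)
proceed to the expensive affinity round; a higher HOMO indicates a more
easily donated electron pair and hence a more favorable electron
transfer to CO2.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression

from .errors import (
    CollinearityError,
    DegenerateInputError,
    FeatureError,
    ModelingError,
    SplitError,
)

__all__ = [
    "HOMO_THRESHOLD",
    "MLRModel",
    "ModelMetrics",
    "Prediction",
    "NucleophilicityRecord",
    "CorrelationResult",
    "fit_mlr",
    "evaluate",
    "loo_cv",
    "kfold_cv",
    "best_subset_search",
    "homo_filter",
    "predict",
    "make_split",
    "nucleophilicity_correlation",
]

#: HOMO-energy screening threshold, Hartree.  Inclusive: a candidate
#: sitting exactly on the threshold passes.
HOMO_THRESHOLD = -0.140


@dataclass
class MLRModel:
    """Ordinary-least-squares model in z-scored descriptor space.

    ``coefficients`` multiply z-scored features; ``scaler`` holds the
    per-feature (mean, stddev) of the training split.  Raw-space
    coefficients are derived for reporting.
    """

    feature_names: list[str]
    coefficients: np.ndarray  # standardized space
    intercept: float
    scaler: list[tuple[float, float]]  # (mean, stddev) per feature
    response_units: str = "kcal/mol"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, float)
        if not (
            len(self.feature_names) == len(self.coefficients) == len(self.scaler)
        ):
            raise ModelingError("feature/coefficient/scaler lengths disagree")
        if any(s <= 0 for _, s in self.scaler):
            raise ModelingError("scaler stddev must be > 0 for every feature")

    @property
    def raw_coefficients(self) -> np.ndarray:
        """Coefficients in original descriptor units."""
        stds = np.array([s for _, s in self.scaler])
        return self.coefficients / stds

    @property
    def raw_intercept(self) -> float:
        means = np.array([m for m, _ in self.scaler])
        return float(self.intercept - self.raw_coefficients @ means)

    def transform(self, x: np.ndarray) -> np.ndarray:
        means = np.array([m for m, _ in self.scaler])
        stds = np.array([s for _, s in self.scaler])
        return (np.asarray(x, float) - means) / stds

    def predict_matrix(self, x: np.ndarray) -> np.ndarray:
        return self.transform(x) @ self.coefficients + self.intercept

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in frame.columns]
        if missing:
            raise FeatureError(f"missing model features: {missing}")
        return self.predict_matrix(frame[self.feature_names].to_numpy(float))

    def save(self, path: str | Path) -> None:
        """Serialize as structured text (JSON)."""
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "coefficients": self.coefficients.tolist(),
                    "intercept": self.intercept,
                    "scaler": [list(s) for s in self.scaler],
                    "response_units": self.response_units,
                    "provenance": self.provenance,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "MLRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.array(d["coefficients"]),
            intercept=d["intercept"],
            scaler=[tuple(s) for s in d["scaler"]],
            response_units=d.get("response_units", "kcal/mol"),
            provenance=d.get("provenance", {}),
        )


@dataclass
class ModelMetrics:
    """Validation metrics; MAE in kcal/mol."""

    r2_train: float | None = None
    mae_train: float | None = None
    r2_test: float | None = None
    mae_test: float | None = None
    q2_loo: float | None = None
    kfold: dict | None = None  # {"k", "seed", "per_fold": [...], "pooled_r2"}


@dataclass(frozen=True)
class Prediction:
    """Screening outcome for one nucleophile."""

    id: str
    epsilon_homo: float
    passed_homo_filter: bool
    co2a_pred: float | None  # kcal/mol; present iff the filter passed
    stability_call: str  # "stable" | "unstable" | "screened-out"

    def __post_init__(self):
        if self.passed_homo_filter != (self.co2a_pred is not None):
            raise ModelingError("co2a_pred must be present iff the filter passed")
        expected = (
            "screened-out"
            if not self.passed_homo_filter
            else ("stable" if self.co2a_pred > 0 else "unstable")
        )
        if self.stability_call != expected:
            raise ModelingError(
                f"stability_call {self.stability_call!r} inconsistent, expected {expected!r}"
            )


@dataclass(frozen=True)
class NucleophilicityRecord:
    """Mayr nucleophilicity parameter N for one nucleophile."""

    id: str
    N: float

    def __post_init__(self):
        if not math.isfinite(self.N):
            raise ModelingError("nucleophilicity N must be finite")


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    slope: float
    intercept: float
    n: int


def _design(table: pd.DataFrame, features: Sequence[str], response: str):
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise FeatureError(f"features not in table: {missing}")
    if response not in table.columns:
        raise FeatureError(f"response column {response!r} not in table")
    x = table[list(features)].to_numpy(float)
    y = table[response].to_numpy(float)
    return x, y


def _check_collinearity(x: np.ndarray, features: Sequence[str]) -> None:
    stds = x.std(axis=0, ddof=0)
    dead = [f for f, s in zip(features, stds) if s <= 1e-12]
    if dead:
        raise CollinearityError(dead)
    z = (x - x.mean(axis=0)) / stds
    rank = np.linalg.matrix_rank(z, tol=1e-8 * max(z.shape))
    if rank < z.shape[1]:
        # name a minimal offending set: features linearly explained by the rest
        offenders = []
        for j, name in enumerate(features):
            others = np.delete(z, j, axis=1)
            if others.shape[1] == 0:
                continue
            resid = z[:, j] - others @ np.linalg.lstsq(others, z[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-6 * max(1.0, np.linalg.norm(z[:, j])):
                offenders.append(name)
        raise CollinearityError(offenders or list(features))


def fit_mlr(
    table: pd.DataFrame,
    features: Sequence[str],
    response: str = "co2a",
) -> MLRModel:
    """Fit OLS on z-scored features.

    Requires ``n_rows > n_features + 1``.  A rank-deficient design
    raises :class:`CollinearityError` naming the offending features.
    Noiseless linear data is reproduced exactly.
    """
    x, y = _design(table, features, response)
    n, p = x.shape
    if n <= p + 1:
        raise ModelingError(f"need more than {p + 1} rows to fit {p} features, got {n}")
    _check_collinearity(x, features)

    means = x.mean(axis=0)
    stds = x.std(axis=0, ddof=0)
    z = (x - means) / stds
    reg = LinearRegression().fit(z, y)
    return MLRModel(
        feature_names=list(features),
        coefficients=reg.coef_,
        intercept=float(reg.intercept_),
        scaler=[(float(m), float(s)) for m, s in zip(means, stds)],
        provenance={"n_train": n, "response": response},
    )


def _r2_mae(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - yhat) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return r2, float(np.abs(y - yhat).mean())


def make_split(
    table: pd.DataFrame, test_fraction: float = 0.25, seed: int = 0
) -> pd.Series:
    """Seeded random train/test assignment ("train"/"test" per row).

    The default 75/25 split; an explicit assignment (e.g. read from a
    file) can be passed anywhere a split is accepted, so a deposited
    split can be reproduced exactly.
    """
    rng = np.random.default_rng(seed)
    n = len(table)
    n_test = max(1, int(round(n * test_fraction)))
    labels = np.array(["train"] * n, dtype=object)
    labels[rng.permutation(n)[:n_test]] = "test"
    return pd.Series(labels, index=table.index)


def evaluate(
    model: MLRModel,
    table: pd.DataFrame,
    split: pd.Series | Sequence[str],
    response: str = "co2a",
) -> ModelMetrics:
    """R2 and MAE on the train and test partitions of ``split``."""
    split = pd.Series(np.asarray(split, dtype=object), index=table.index)
    labels = set(split.unique())
    if not labels <= {"train", "test"}:
        raise SplitError(f"split labels must be train/test, got {sorted(labels)}")
    if "test" not in labels:
        raise SplitError("empty test split")
    if "train" not in labels:
        raise SplitError("empty train split")
    metrics = ModelMetrics()
    for part in ("train", "test"):
        sub = table[split == part]
        y = sub[response].to_numpy(float)
        yhat = model.predict_frame(sub)
        r2, mae = _r2_mae(y, yhat)
        setattr(metrics, f"r2_{part}", r2)
        setattr(metrics, f"mae_{part}", mae)
    return metrics


def _loo_predictions(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Held-out OLS predictions: n refits, each excluding one row.

    Solved directly on the raw design (intercept column added); OLS
    predictions are invariant to the z-scoring applied in
    :func:`fit_mlr`, so this is the same model without the per-refit
    scaler bookkeeping.
    """
    n = len(y)
    design = np.column_stack([np.ones(n), x])
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        beta = np.linalg.lstsq(design[mask], y[mask], rcond=None)[0]
        preds[i] = design[i] @ beta
    return preds


def loo_cv(
    table: pd.DataFrame,
    features: Sequence[str],
    response: str = "co2a",
) -> float:
    """Leave-one-out Q2: n refits, each predicting its held-out row.

    Q2 = 1 - PRESS / SS_tot with SS_tot about the full-sample mean.
    """
    x, y = _design(table, features, response)
    n = len(y)
    if n < 3:
        raise ModelingError("need at least 3 rows for leave-one-out")
    _check_collinearity(x, features)
    preds = _loo_predictions(x, y)
    press = float(((y - preds) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateInputError("constant response; Q2 undefined")
    return 1.0 - press / ss_tot


def kfold_cv(
    table: pd.DataFrame,
    features: Sequence[str],
    k: int = 5,
    seed: int = 0,
    response: str = "co2a",
) -> ModelMetrics:
    """Seeded k-fold cross-validation (default k = 5).

    Folds differ in size by at most one; the aggregate R2 is the
    pooled-prediction R2 over all held-out predictions.
    """
    n = len(table)
    if k > n:
        raise SplitError(f"k = {k} exceeds {n} rows")
    if k < 2:
        raise SplitError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, extra = divmod(n, k)
    folds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(order[start : start + size])
        start += size

    y = table[response].to_numpy(float)
    pooled = np.empty(n)
    per_fold = []
    for i, fold in enumerate(folds):
        mask = np.ones(n, bool)
        mask[fold] = False
        model = fit_mlr(table.iloc[mask], features, response)
        yhat = model.predict_frame(table.iloc[fold])
        pooled[fold] = yhat
        r2, mae = _r2_mae(y[fold], yhat)
        per_fold.append({"fold": i, "n": len(fold), "r2": r2, "mae": mae})
    pooled_r2, pooled_mae = _r2_mae(y, pooled)
    return ModelMetrics(
        kfold={
            "k": k,
            "seed": seed,
            "fold_sizes": [len(f) for f in folds],
            "per_fold": per_fold,
            "pooled_r2": pooled_r2,
            "pooled_mae": pooled_mae,
        }
    )


def best_subset_search(
    table: pd.DataFrame,
    pool: Sequence[str],
    subset_size: int = 3,
    response: str = "co2a",
    split: pd.Series | None = None,
    max_candidates: int = 200_000,
) -> list[dict]:
    """Exhaustive best-subset model search.

    Evaluates every ``subset_size``-subset of ``pool``; collinear
    subsets are skipped with a reason.  The leaderboard is ranked by
    leave-one-out Q2 (primary) and test-set MAE (tiebreak, when a split
    is supplied).  The full leaderboard is returned for persistence.
    """
    pool = list(pool)
    if len(pool) < subset_size:
        raise ModelingError("pool smaller than subset size")
    n_candidates = math.comb(len(pool), subset_size)
    if n_candidates > max_candidates:
        raise ModelingError(
            f"{n_candidates} candidate subsets exceed the cap {max_candidates}; "
            "use a staged/greedy search (prune the pool or raise max_candidates)"
        )
    y_all = table[response].to_numpy(float)
    x_all = table[[*pool]].to_numpy(float)
    col = {name: j for j, name in enumerate(pool)}
    leaderboard: list[dict] = []
    for combo in itertools.combinations(pool, subset_size):
        entry: dict = {"features": list(combo)}
        x = x_all[:, [col[f] for f in combo]]
        try:
            _check_collinearity(x, combo)
        except CollinearityError as exc:
            entry.update({"skipped": f"collinear: {exc.features}"})
            leaderboard.append(entry)
            continue
        preds = _loo_predictions(x, y_all)
        ss_tot = float(((y_all - y_all.mean()) ** 2).sum())
        q2 = 1.0 - float(((y_all - preds) ** 2).sum()) / ss_tot
        design = np.column_stack([np.ones(len(y_all)), x])
        beta = np.linalg.lstsq(design, y_all, rcond=None)[0]
        r2, mae = _r2_mae(y_all, design @ beta)
        entry.update({"q2_loo": q2, "r2_train": r2, "mae_train": mae})
        if split is not None:
            train = table[np.asarray(split) == "train"]
            model_t = fit_mlr(train, combo, response)
            m = evaluate(model_t, table, split, response)
            entry.update({"r2_test": m.r2_test, "mae_test": m.mae_test})
        leaderboard.append(entry)

    def sort_key(e: dict):
        if "skipped" in e:
            return (1, 0.0, 0.0)
        return (0, -e["q2_loo"], e.get("mae_test", e["mae_train"]))

    leaderboard.sort(key=sort_key)
    return leaderboard


def homo_filter(epsilon_homo: float, threshold: float = HOMO_THRESHOLD) -> bool:
    """HOMO-energy pre-screen: True when the candidate proceeds.

    Inclusive comparison: ``epsilon_homo >= threshold``; a candidate
    exactly on the boundary passes.
    """
    if not math.isfinite(epsilon_homo):
        raise ModelingError("epsilon_homo must be finite")
    return epsilon_homo >= threshold


def predict(
    model: MLRModel,
    row: Mapping[str, float] | pd.Series,
    record_id: str = "",
    epsilon_homo: float | None = None,
    threshold: float = HOMO_THRESHOLD,
) -> Prediction:
    """Predict the screening outcome for one descriptor row.

    ``epsilon_homo`` defaults to the row's ``epsilon_homo_lowE`` column
    (the lowest-energy-conformer value the pre-screen uses).  Rows that
    fail the filter carry no affinity; otherwise the affinity sign sets
    the stability call.
    """
    row = pd.Series(dict(row), dtype=float)
    if epsilon_homo is None:
        if "epsilon_homo_lowE" not in row:
            raise FeatureError(
                "epsilon_homo not given and epsilon_homo_lowE missing from row"
            )
        epsilon_homo = float(row["epsilon_homo_lowE"])
    passed = homo_filter(epsilon_homo, threshold)
    if not passed:
        return Prediction(
            id=record_id,
            epsilon_homo=epsilon_homo,
            passed_homo_filter=False,
            co2a_pred=None,
            stability_call="screened-out",
        )
    missing = [f for f in model.feature_names if f not in row.index]
    if missing:
        raise FeatureError(f"missing model features: {missing}")
    co2a = float(
        model.predict_matrix(row[model.feature_names].to_numpy(float)[None, :])[0]
    )
    return Prediction(
        id=record_id,
        epsilon_homo=epsilon_homo,
        passed_homo_filter=True,
        co2a_pred=co2a,
        stability_call="stable" if co2a > 0 else "unstable",
    )


def nucleophilicity_correlation(
    affinities: Mapping[str, float],
    n_values: Sequence[NucleophilicityRecord] | Mapping[str, float],
) -> CorrelationResult:
    """Correlate CO2 affinity with the Mayr nucleophilicity parameter N.

    Simple linear regression of affinity on N over the paired ids;
    returns R2 with the slope (a positive slope means more nucleophilic
    carbanions bind CO2 more strongly).
    """
    if not isinstance(n_values, Mapping):
        n_values = {r.id: r.N for r in n_values}
    shared = sorted(set(affinities) & set(n_values))
    unpaired = sorted(set(affinities) ^ set(n_values))
    if len(shared) < 3:
        raise ModelingError(
            f"need >= 3 paired records, got {len(shared)} (unpaired: {unpaired})"
        )
    x = np.array([n_values[i] for i in shared], float)
    y = np.array([affinities[i] for i in shared], float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("nucleophilicity N is constant; slope undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(shared),
    )
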