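"""Tree-ensemble regressors mapping patient covariates to realized clearance.

Four algorithms are compared: a single decision tree (depth unconstrained,
so it interpolates unique training covariates), gradient-boosted trees,
extreme gradient boosting (xgboost) and extra trees. Features are the four
covariates (age, weight, serum creatinine, sex encoded male=1/female=0);
the label is the realized individual clearance in L/h. Hyperparameters are
library defaults; every stochastic fit is seeded.

Fit quality is reported as R², MSE, RMSE and MAE on both the training and
the test partition; model selection ranks by test-partition R² with
RMSE → MAE → fixed algorithm order as tie-breaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor, GradientBoostingRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .errors import ConfigurationError, DomainError, StateError

#: fixed algorithm order; also the final tie-break in model selection
ALGORITHMS = (
    "decision_tree",
    "gradient_boosting",
    "extreme_gradient_boosting",
    "extra_trees",
)

#: ordered feature schema; sex_male is the 0/1 encoded sex column
FEATURES = ("age_years", "weight_kg", "scr_umol_L", "sex_male")

#: floor applied to predictions — clearance is physically positive
PREDICTION_FLOOR = 1e-3


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test patient-id partition."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.train_ids, self.test_ids)
        if overlap.size:
            raise StateError(f"train/test overlap: {overlap[:5]}...")


@dataclass(frozen=True)
class PartitionMetrics:
    r2: float
    mse: float
    rmse: float
    mae: float


@dataclass(frozen=True)
class MetricsReport:
    """R²/MSE/RMSE/MAE on the training and test partitions."""

    train: PartitionMetrics
    test: PartitionMetrics

    def to_dict(self) -> dict:
        return {"train": asdict(self.train), "test": asdict(self.test)}


class FittedModel:
    """A trained regressor bound to the fixed feature schema."""

    def __init__(self, spec: ModelSpec, estimator) -> None:
        self.spec = spec
        self.features = FEATURES
        self._estimator = estimator

    def predict(self, patients: pd.DataFrame) -> np.ndarray:
        """Predict clearance (L/h), floored at ``PREDICTION_FLOOR``."""
        if self._estimator is None:
            raise StateError("model has not been fitted")
        X = feature_matrix(patients)
        pred = np.asarray(self._estimator.predict(X), dtype=float)
        return np.maximum(pred, PREDICTION_FLOOR)


# ---------------------------------------------------------------------------
# Features and splitting
# ---------------------------------------------------------------------------

def feature_matrix(patients: pd.DataFrame) -> np.ndarray:
    """Covariates as an (n, 4) float matrix in the fixed schema order."""
    sex_male = (patients["sex"].to_numpy() == "male").astype(float)
    return np.column_stack(
        [
            patients["age_years"].to_numpy(dtype=float),
            patients["weight_kg"].to_numpy(dtype=float),
            patients["scr_umol_L"].to_numpy(dtype=float),
            sex_male,
        ]
    )


def parse_ratio(ratio) -> float:
    """Test fraction from a ``"test:train"`` string or a float in (0, 1)."""
    if isinstance(ratio, str):
        try:
            test_part, train_part = (float(x) for x in ratio.split(":"))
        except ValueError as exc:
            raise ConfigurationError(f"cannot parse ratio {ratio!r}") from exc
        if test_part <= 0 or train_part <= 0:
            raise ConfigurationError(f"ratio parts must be positive: {ratio!r}")
        return test_part / (test_part + train_part)
    frac = float(ratio)
    if not 0.0 < frac < 1.0:
        raise ConfigurationError(f"test fraction must be in (0, 1), got {frac}")
    return frac


def split(cohort: pd.DataFrame, ratio="1:3", seed: int = 0) -> SplitPlan:
    """Random seeded train/test split of a cohort by patient id.

    The default 1:3 test:train ratio sends 250 of 1,000 patients to the test
    set. The test size is round(n · test_fraction); a split that would leave
    either partition empty is rejected.
    """
    if len(cohort) == 0:
        raise ConfigurationError("cannot split an empty cohort")
    frac = parse_ratio(ratio)
    n = len(cohort)
    n_test = int(round(n * frac))
    if n_test == 0 or n_test == n:
        raise ConfigurationError(
            f"ratio {ratio!r} leaves an empty partition for n={n}"
        )
    rng = np.random.default_rng(seed)
    ids = cohort["id"].to_numpy()
    perm = rng.permutation(n)
    return SplitPlan(
        train_ids=np.sort(ids[perm[n_test:]]),
        test_ids=np.sort(ids[perm[:n_test]]),
        test_fraction=frac,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "decision_tree":
        return DecisionTreeRegressor(random_state=spec.seed, **hp)
    if spec.algorithm == "gradient_boosting":
        return GradientBoostingRegressor(random_state=spec.seed, **hp)
    if spec.algorithm == "extreme_gradient_boosting":
        return XGBRegressor(random_state=spec.seed, **hp)
    return ExtraTreesRegressor(random_state=spec.seed, **hp)


def fit(spec: ModelSpec, train: pd.DataFrame) -> FittedModel:
    """Train one regressor on covariates → realized clearance."""
    if len(train) == 0:
        raise StateError("training set is empty")
    y = train["cl_true_L_h"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise StateError("training labels (cl_true_L_h) are missing")
    est = _make_estimator(spec)
    est.fit(feature_matrix(train), y)
    return FittedModel(spec, est)


# ---------------------------------------------------------------------------
# Metrics (Eqs. for R², MSE, RMSE, MAE implemented directly)
# ---------------------------------------------------------------------------

def r_squared(y, yhat) -> float:
    """Coefficient of determination R² = 1 − SSE/SST.

    SSE = Σ(yᵢ − ŷᵢ)², SST = Σ(yᵢ − ȳ)². Equals 1 iff ŷ = y elementwise;
    undefined (domain error) when all y are equal.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise StateError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise DomainError("R^2 requires at least two observations")
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DomainError("R^2 undefined: zero total sum of squares")
    return 1.0 - sse / sst


def error_metrics(y, yhat) -> tuple[float, float, float]:
    """(MSE, RMSE, MAE) of predictions against reference values."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise StateError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise DomainError("error metrics require at least one observation")
    diff = yhat - y
    mse = float(np.mean(diff**2))
    return mse, float(np.sqrt(mse)), float(np.mean(np.abs(diff)))


def _partition_metrics(y, yhat) -> PartitionMetrics:
    mse, rmse, mae = error_metrics(y, yhat)
    return PartitionMetrics(r2=r_squared(y, yhat), mse=mse, rmse=rmse, mae=mae)


def evaluate_fit(model: FittedModel, train: pd.DataFrame, test: pd.DataFrame) -> MetricsReport:
    """Metrics of a fitted model on its training and test partitions."""
    return MetricsReport(
        train=_partition_metrics(train["cl_true_L_h"].to_numpy(), model.predict(train)),
        test=_partition_metrics(test["cl_true_L_h"].to_numpy(), model.predict(test)),
    )


def cross_validate(
    spec: ModelSpec, data: pd.DataFrame, k: int = 5, seed: int = 0
) -> tuple[list[PartitionMetrics], PartitionMetrics]:
    """k-fold cross-validation: per-fold held-out metrics and their mean.

    Folds are a seeded shuffled partition of the data; each fold's metrics
    are computed on its held-out records.
    """
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if k > len(data):
        raise ConfigurationError(f"k={k} exceeds {len(data)} records")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[PartitionMetrics] = []
    for fold_idx, (tr, te) in enumerate(kf.split(data)):
        model = fit(
            ModelSpec(spec.algorithm, spec.hyperparameters, seed=spec.seed + fold_idx),
            data.iloc[tr],
        )
        y = data.iloc[te]["cl_true_L_h"].to_numpy()
        yhat = model.predict(data.iloc[te])
        mse, rmse, mae = error_metrics(y, yhat)
        r2 = r_squared(y, yhat) if np.unique(y).size > 1 else float("nan")
        folds.append(PartitionMetrics(r2=r2, mse=mse, rmse=rmse, mae=mae))
    mean = PartitionMetrics(
        r2=float(np.mean([f.r2 for f in folds])),
        mse=float(np.mean([f.mse for f in folds])),
        rmse=float(np.mean([f.rmse for f in folds])),
        mae=float(np.mean([f.mae for f in folds])),
    )
    return folds, mean


def select_model(reports: dict[str, MetricsReport], partition: str = "test") -> str:
    """Pick the best algorithm by R² on the comparison partition.

    Ties break by lower RMSE, then lower MAE, then fixed algorithm order.
    """
    if not reports:
        raise StateError("no metric reports to select from")
    for name in reports:
        if name not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm in reports: {name!r}")

    def key(name: str):
        m: PartitionMetrics = getattr(reports[name], partition)
        return (-m.r2, m.rmse, m.mae, ALGORITHMS.index(name))

    return min(reports, key=key)


def metrics_to_json(reports: dict[str, MetricsReport], path) -> None:
    """Write the algorithm × partition × metric table as JSON."""
    payload = {name: rep.to_dict() for name, rep in reports.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
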