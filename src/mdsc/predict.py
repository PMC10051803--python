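"""Predictor harness: the four model families behind the Medical Device
Score, holdout evaluation, and out-of-fold (cross-fitted) prediction.

The Medical Device Score (MDS) is a model's GMFM-66 prediction from device
indicators, age and CP subtype.  Random forest is the production family
(lowest holdout MAE); SVM, feed-forward net and XGBoost run in compare
mode.  All families receive the identical feature matrix, and predictions
are clipped to the GMFM-66 range [0, 100] with a per-pair flag.

Hyperparameters are the implementing libraries' defaults (no tuning
protocol is part of the method); the feed-forward net uses one hidden
layer sized to the feature count (capped at 32) on standardized inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from mdsc._rng import derived_seed
from mdsc.cohort import Cohort, FeatureMatrix, encode_features, holdout_split
from mdsc.errors import ConfigurationError
from mdsc.metrics import evaluate_agreement

FAMILIES = ("RF", "SVM", "FNN", "XGBoost")

SCORE_MIN, SCORE_MAX = 0.0, 100.0


class ConstantPredictor:
    """Fallback model returned when the training outcome has zero variance."""

    def __init__(self, value: float):
        self.value = float(value)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.value)


def _build_estimator(family: str, n_features: int, seed: int):
    if family == "RF":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if family == "XGBoost":
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)
    if family == "SVM":
        # kernel methods are scale sensitive; age is on another scale than
        # the binary indicators
        return make_pipeline(StandardScaler(), SVR())
    if family == "FNN":
        hidden = max(4, min(32, n_features))
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=(hidden,), random_state=seed, max_iter=2000
            ),
        )
    raise ConfigurationError(f"unknown family {family!r}; expected one of {FAMILIES}")


@dataclass
class FittedPredictor:
    """A trained model handle carrying its family tag and feature contract."""

    family: str
    estimator: Any
    feature_names: tuple[str, ...]
    seed: int


@dataclass
class PredictionResult:
    """Paired (true GMFM-66, Medical Device Score) on a set of patients.

    ``frame`` columns: patient_id, gmfm_true, mds, clipped.
    """

    frame: pd.DataFrame
    family: str

    @property
    def gmfm_true(self) -> np.ndarray:
        return self.frame["gmfm_true"].to_numpy(dtype=float)

    @property
    def mds(self) -> np.ndarray:
        return self.frame["mds"].to_numpy(dtype=float)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["patient_id"])

    def mds_by_id(self) -> pd.Series:
        return pd.Series(
            self.mds, index=pd.Index(self.frame["patient_id"], name="patient_id"),
            name="mds",
        )

    def __len__(self) -> int:
        return len(self.frame)


def train_predictor(
    features_train: pd.DataFrame, outcome_train, family: str, seed: int = 0
) -> FittedPredictor:
    """Fit one model family.  Deterministic given ``seed`` for the
    stochastic families (RF, XGBoost, FNN).

    A zero-variance outcome yields a warning and a constant predictor.
    """
    X = features_train
    y = np.asarray(outcome_train, dtype=float)
    if len(X) != len(y):
        raise ValueError(f"features ({len(X)}) and outcome ({len(y)}) misaligned")
    if len(X) == 0:
        raise ValueError("cannot train on an empty set")
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if np.ptp(y) == 0.0:
        warnings.warn(
            f"training outcome has zero variance; {family} replaced by a "
            f"constant predictor at {y[0]:.3f}",
            stacklevel=2,
        )
        est = ConstantPredictor(y[0])
    else:
        est = _build_estimator(family, X.shape[1], seed)
        with warnings.catch_warnings():
            # the FNN may stop at max_iter on hard problems; predictions
            # are still well defined and deterministic
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X.to_numpy(dtype=float), y)
    return FittedPredictor(
        family=family, estimator=est, feature_names=tuple(X.columns), seed=seed
    )


def predict_mds(model: FittedPredictor, features_test: FeatureMatrix) -> PredictionResult:
    """Predict the Medical Device Score on held-out patients.

    Feature columns must match the training columns exactly; predictions
    outside [0, 100] are clipped and flagged.
    """
    cols = tuple(features_test.X.columns)
    if cols != model.feature_names:
        missing = sorted(set(model.feature_names) - set(cols))
        extra = sorted(set(cols) - set(model.feature_names))
        raise ValueError(
            "feature columns do not match training columns "
            f"(missing: {missing or 'none'}; unexpected: {extra or 'none'}; "
            "note column order is part of the contract)"
        )
    if len(features_test) == 0:
        frame = pd.DataFrame(columns=["patient_id", "gmfm_true", "mds", "clipped"])
        return PredictionResult(frame=frame, family=model.family)
    raw = np.asarray(
        model.estimator.predict(features_test.X.to_numpy(dtype=float)), dtype=float
    )
    if not np.all(np.isfinite(raw)):
        raise ValueError("model produced non-finite predictions")
    clipped = (raw < SCORE_MIN) | (raw > SCORE_MAX)
    mds = np.clip(raw, SCORE_MIN, SCORE_MAX)
    frame = pd.DataFrame(
        {
            "patient_id": list(features_test.row_ids),
            "gmfm_true": features_test.y.to_numpy(dtype=float),
            "mds": mds,
            "clipped": clipped,
        }
    )
    return PredictionResult(frame=frame, family=model.family)


def crossfit_mds(
    cohort: Cohort,
    family: str = "RF",
    n_folds: int = 5,
    seed: int = 0,
    *,
    include_gmfcs: bool = False,
) -> PredictionResult:
    """Out-of-fold Medical Device Score for every patient in the cohort.

    Each patient's MDS comes from a model never trained on that patient,
    avoiding in-sample optimism when the scores feed the group-comparison
    power analysis.  Result rows follow cohort record order.
    """
    n = len(cohort)
    if n_folds < 2:
        raise ConfigurationError(f"n_folds must be >= 2, got {n_folds}")
    if n_folds > n:
        raise ConfigurationError(f"n_folds={n_folds} exceeds cohort size {n}")
    fm = encode_features(cohort, include_gmfcs=include_gmfcs)
    ids = np.array(fm.row_ids, dtype=object)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=derived_seed(seed, 0))
    parts = []
    for k, (train_idx, test_idx) in enumerate(kf.split(ids)):
        model = train_predictor(
            fm.X.iloc[train_idx], fm.y.iloc[train_idx], family,
            seed=derived_seed(seed, 1, k),
        )
        parts.append(predict_mds(model, fm.subset(ids[test_idx])).frame)
    frame = pd.concat(parts, ignore_index=True)
    order = {pid: i for i, pid in enumerate(cohort.ids)}
    frame = frame.sort_values("patient_id", key=lambda s: s.map(order), ignore_index=True)
    return PredictionResult(frame=frame, family=family)


def insample_mds(
    cohort: Cohort, family: str = "RF", seed: int = 0
) -> PredictionResult:
    """MDS for every patient from a single model trained on all of them.

    Optimistic by construction; exposed because whether a study uses
    in-sample or out-of-fold scores changes the measured attenuation.
    """
    fm = encode_features(cohort)
    model = train_predictor(fm.X, fm.y, family, seed=derived_seed(seed, 2))
    return predict_mds(model, fm)


def compare_families(
    cohort: Cohort,
    families=FAMILIES,
    fraction: float = 0.7,
    seed: int = 0,
    bootstrap_reps: int = 2000,
) -> tuple[pd.DataFrame, Mapping[str, PredictionResult]]:
    """Holdout comparison of model families (the model comparison report).

    The cohort is split once (same split for every family, per the shared
    input-data contract); each family is trained on the training fraction
    and scored on the holdout with CCC/MAE/RMSE and bootstrap CIs.

    Returns the report DataFrame (one row per family) and the per-family
    holdout predictions.
    """
    fm = encode_features(cohort)
    split = holdout_split(cohort, fraction=fraction, seed=derived_seed(seed, 10))
    fm_train = fm.subset(split.train_ids)
    fm_test = fm.subset(split.test_ids)
    rows = []
    results: dict[str, PredictionResult] = {}
    for family in families:
        model = train_predictor(
            fm_train.X, fm_train.y, family, seed=derived_seed(seed, 11)
        )
        result = predict_mds(model, fm_test)
        report = evaluate_agreement(
            result.gmfm_true, result.mds,
            reps=bootstrap_reps, seed=derived_seed(seed, 12),
        )
        rows.append(
            {
                "family": family,
                "ccc": report.ccc,
                "ccc_lo": report.ccc_ci[0],
                "ccc_hi": report.ccc_ci[1],
                "mae": report.mae,
                "mae_lo": report.mae_ci[0],
                "mae_hi": report.mae_ci[1],
                "rmse": report.rmse,
                "rmse_lo": report.rmse_ci[0],
                "rmse_hi": report.rmse_ci[1],
                "n_test": report.n,
            }
        )
        results[family] = result
    return pd.DataFrame(rows), results
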