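"""Random-forest SBP/DBP regression with per-subject calibration.

The regressor is a bootstrap-aggregated forest of 100 trees with max
depth 50, ``min_samples_split=2`` and ``min_samples_leaf=1``; the
prediction is the mean over trees.  No hyperparameter search is
performed — the configuration is fixed.

Calibration ("personalization") adapts the population model with a
small labeled sample from the test subjects, conventionally a quarter
of each subject's test records.  Two strategies are provided:

* ``"augment"`` (default): the forest is refit on the original training
  data plus the calibration records, the latter upweighted (w=5) so a
  handful of personal records can bend the model;
* ``"offset"``: a per-target additive bias correction equal to the mean
  calibration residual.

:class:`BPRandomForest` is a scikit-learn estimator (``fit`` /
``predict`` / ``get_params``); the module-level ``train`` /
``calibrate`` / ``split_calibration`` functions are thin wrappers.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "ModelConfig",
    "BPRandomForest",
    "features_to_frame",
    "train",
    "calibrate",
    "split_calibration",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

MIN_TRAIN_RECORDS = 20


@dataclass(frozen=True)
class ModelConfig:
    """Forest hyperparameters (fixed defaults, no search)."""

    n_trees: int = 100
    max_depth: int = 50
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    bootstrap: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "max_depth", "min_samples_split", "min_samples_leaf"):
            if not getattr(self, name) >= 1:
                raise ValueError(f"{name} must be a positive integer")


class BPRandomForest(RegressorMixin, BaseEstimator):
    """Random-forest blood-pressure regressor with calibration support.

    Parameters mirror :class:`ModelConfig`; ``target_name`` is carried
    for reporting.  Inputs may be DataFrames (name-keyed; column order
    is irrelevant) or plain arrays in ``feature_names`` order.

    Attributes
    ----------
    model_ : fitted :class:`RandomForestRegressor`
    feature_names_ : ordered feature list the model expects
    training_summary_ : dict with n_records, seed and the calibration
        strategy applied (if any)
    offset_ : additive bias correction (0 until offset calibration)
    """

    def __init__(
        self,
        n_trees: int = 100,
        max_depth: int = 50,
        min_samples_split: int = 2,
        min_samples_leaf: int = 1,
        bootstrap: bool = True,
        max_features: float | str = 1.0,
        random_state: int | None = 0,
        target_name: str = "SBP",
        calibration_strategy: str = "augment",
        calibration_weight: float = 5.0,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.bootstrap = bootstrap
        self.max_features = max_features
        self.random_state = random_state
        self.target_name = target_name
        self.calibration_strategy = calibration_strategy
        self.calibration_weight = calibration_weight

    # -- helpers ---------------------------------------------------------
    def _coerce(self, X, fit: bool = False) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            if fit:
                self.feature_names_ = names
            else:
                missing = set(self.feature_names_) - set(names)
                extra = set(names) - set(self.feature_names_)
                if missing or extra:
                    raise ValueError(
                        f"feature-name mismatch: missing={sorted(missing)}, "
                        f"unexpected={sorted(extra)}"
                    )
                X = X[self.feature_names_]
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if fit:
            self.feature_names_ = [f"f{i}" for i in range(X.shape[1])]
        elif X.shape[1] != len(self.feature_names_):
            raise ValueError(
                f"expected {len(self.feature_names_)} features, got {X.shape[1]}"
            )
        return X

    def _new_forest(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=self.bootstrap,
            max_features=self.max_features,
            random_state=self.random_state,
            n_jobs=1,
        )

    # -- sklearn surface -------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        Xv = self._coerce(X, fit=True)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(y) != Xv.shape[0]:
            raise ValueError("X and y length mismatch")
        if Xv.shape[0] < MIN_TRAIN_RECORDS:
            raise ValueError(
                f"need at least {MIN_TRAIN_RECORDS} training records, got {Xv.shape[0]}"
            )
        if np.ptp(y) == 0:
            raise ValueError("constant target: nothing to regress")
        if not np.isfinite(Xv).all():
            raise ValueError("training features contain missing values")
        self.model_ = self._new_forest()
        self.model_.fit(Xv, y, sample_weight=sample_weight)
        self._X_train_ = Xv
        self._y_train_ = y
        self._w_train_ = sample_weight
        self.offset_ = 0.0
        self.training_summary_ = {
            "target": self.target_name,
            "n_records": int(Xv.shape[0]),
            "seed": self.random_state,
            "calibration": None,
        }
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        Xv = self._coerce(X)
        return self.model_.predict(Xv) + self.offset_

    def calibrate(self, X_cal, y_cal) -> "BPRandomForest":
        """Personalize the fitted model with a small labeled sample.

        Returns ``self``; with an empty calibration set the model is
        returned unchanged with a warning.
        """
        check_is_fitted(self, "model_")
        y_cal = np.asarray(y_cal, dtype=float).reshape(-1)
        if len(y_cal) == 0:
            logger.warning("empty calibration set: model returned unchanged")
            return self
        Xc = self._coerce(X_cal)
        if self.calibration_strategy == "offset":
            self.offset_ += float(np.mean(y_cal - self.predict(X_cal)))
        elif self.calibration_strategy == "augment":
            Xa = np.vstack([self._X_train_, Xc])
            ya = np.concatenate([self._y_train_, y_cal])
            w_base = (self._w_train_ if self._w_train_ is not None
                      else np.ones(len(self._y_train_)))
            wa = np.concatenate([w_base, np.full(len(y_cal), self.calibration_weight)])
            self.model_ = self._new_forest()
            self.model_.fit(Xa, ya, sample_weight=wa)
        else:
            raise ValueError(f"unknown calibration strategy {self.calibration_strategy!r}")
        self.training_summary_["calibration"] = {
            "strategy": self.calibration_strategy,
            "n_calibration": int(len(y_cal)),
            "weight": self.calibration_weight,
        }
        return self


# ---------------------------------------------------------------------------
# FeatureVector-level wrappers
# ---------------------------------------------------------------------------

def features_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame (one row per record)."""
    return pd.DataFrame([v.as_row() for v in vectors])


def _design(
    vectors: Sequence[FeatureVector],
    target: str,
    selected: Sequence[str],
    ppt_mean: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray, float | None]:
    """Design matrix restricted to the selected features.

    A missing PPT (a record whose beats showed no dicrotic landmark) is
    imputed with the training-set mean when PPT is selected; records
    missing any other selected feature or the label are dropped with a
    logged count.
    """
    df = features_to_frame(vectors)
    label_col = {"SBP": "sbp_ref", "DBP": "dbp_ref"}[target.upper()]
    selected = list(selected)
    unknown = set(selected) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
    X = df[selected].copy()
    y = df[label_col].to_numpy(float)
    if "PPT" in selected:
        if ppt_mean is None:
            ppt_mean = float(np.nanmean(X["PPT"])) if not X["PPT"].isna().all() else 0.0
        n_imputed = int(X["PPT"].isna().sum())
        if n_imputed:
            logger.info("imputed PPT for %d record(s) with the training mean", n_imputed)
        X["PPT"] = X["PPT"].fillna(ppt_mean)
    keep = np.isfinite(X.to_numpy(float)).all(axis=1) & np.isfinite(y)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d record(s) with missing selected features or label", dropped)
    return X.loc[keep], y[keep], ppt_mean


def train(
    vectors: Sequence[FeatureVector],
    target: str,
    selected: Sequence[str] | None = None,
    config: ModelConfig | None = None,
) -> BPRandomForest:
    """Fit a forest on the selected features of a training cohort."""
    config = config or ModelConfig()
    selected = list(selected) if selected is not None else list(FEATURE_NAMES)
    X, y, ppt_mean = _design(vectors, target, selected)
    est = BPRandomForest(
        n_trees=config.n_trees, max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        min_samples_leaf=config.min_samples_leaf,
        bootstrap=config.bootstrap, random_state=config.random_seed,
        target_name=target.upper(),
    )
    est.fit(X, y)
    est._ppt_mean_ = ppt_mean
    return est


def predict_records(model: BPRandomForest, vectors: Sequence[FeatureVector]) -> np.ndarray:
    """Predict mmHg for feature vectors, reusing training-time imputation."""
    X, _, _ = _design(vectors, model.target_name, model.feature_names_,
                      ppt_mean=getattr(model, "_ppt_mean_", None))
    return model.predict(X)


def calibrate(model: BPRandomForest, calibration: Sequence[FeatureVector]) -> BPRandomForest:
    """Personalize a trained model with calibration records."""
    if len(calibration) == 0:
        logger.warning("empty calibration set: model returned unchanged")
        return model
    X, y, _ = _design(calibration, model.target_name, model.feature_names_,
                      ppt_mean=getattr(model, "_ppt_mean_", None))
    return model.calibrate(X, y)


def split_calibration(
    test_records: Sequence[FeatureVector],
    fraction: float = 0.25,
    seed: int = 0,
) -> tuple[list[FeatureVector], list[FeatureVector]]:
    """Per-subject stratified calibration/evaluation split.

    For each subject with k test records, ``ceil(fraction * k)`` go to
    calibration (deterministic under ``seed``); a subject with a single
    record contributes it to evaluation only.  The two sets are disjoint
    and exhaustive.
    """
    if len(test_records) < 8:
        raise ValueError("need at least 8 test records to split")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_subject: dict[str, list[int]] = defaultdict(list)
    for i, v in enumerate(test_records):
        by_subject[v.subject_id].append(i)
    cal_idx: list[int] = []
    for subject in sorted(by_subject):
        idx = by_subject[subject]
        if len(idx) < 2:
            logger.warning("subject %s has a single record: kept for evaluation", subject)
            continue
        n_cal = math.ceil(fraction * len(idx)) if fraction > 0 else 0
        picked = rng.permutation(len(idx))[:n_cal]
        cal_idx.extend(idx[j] for j in picked)
    cal_set = set(cal_idx)
    calibration = [test_records[i] for i in sorted(cal_set)]
    evaluation = [test_records[i] for i in range(len(test_records)) if i not in cal_set]
    return calibration, evaluation


# ---------------------------------------------------------------------------
# Persistence: estimator + JSON-style manifest in one versioned artifact
# ---------------------------------------------------------------------------

def save_model(model: BPRandomForest, path: str | Path) -> None:
    check_is_fitted(model, "model_")
    manifest = {
        "format_version": 1,
        "target": model.target_name,
        "feature_names": model.feature_names_,
        "params": model.get_params(),
        "training_summary": model.training_summary_,
    }
    joblib.dump({"manifest": manifest, "estimator": model}, path)


def load_model(path: str | Path) -> BPRandomForest:
    payload = joblib.load(path)
    if payload.get("manifest", {}).get("format_version") != 1:
        raise ValueError("unrecognized model file version")
    return payload["estimator"]
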