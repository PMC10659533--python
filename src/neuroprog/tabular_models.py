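"""The three tabular predictor-set models.

Predictor sets:

* ``clinical`` — age, sex, education, baseline MMSE, ADAS delayed word
  recall, APOE e4 allele count (6 features);
* ``hippocampus`` — clinical plus hippocampal and intracranial volume (8);
* ``freesurfer`` — clinical plus the 68 regional gray-matter volumes and
  intracranial volume (75).

The clinical and hippocampus sets use plain (unpenalized) logistic
regression for the progression outcome and ordinary linear regression for
the MMSE-slope outcome; the freesurfer set uses a random forest with
library-default hyperparameters.  Features are z-scored with statistics
fitted on the training rows only.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression

from .errors import DataError
from .preprocessing import NormalizationStats, apply_standardizer, fit_standardizer
from .synthetic_cohort import REGION_NAMES, SubjectRecord

__all__ = [
    "PREDICTOR_SETS",
    "predictor_set_features",
    "assemble_features",
    "fit_tabular",
    "predict_tabular",
    "FittedTabularModel",
]

CLINICAL_FEATURES = (
    "age", "sex", "education", "mmse_baseline", "adas_delayed_recall", "apoe_e4",
)

PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "clinical": CLINICAL_FEATURES,
    "hippocampus": CLINICAL_FEATURES + ("hippocampal_volume", "intracranial_volume"),
    "freesurfer": CLINICAL_FEATURES + REGION_NAMES + ("intracranial_volume",),
}

#: Learner family per predictor set: generalized-linear for the two small
#: sets, random forest for the 75-feature freesurfer set.
DEFAULT_LEARNER = {
    "clinical": "generalized-linear",
    "hippocampus": "generalized-linear",
    "freesurfer": "random-forest",
}


def predictor_set_features(name: str) -> tuple[str, ...]:
    try:
        return PREDICTOR_SETS[name]
    except KeyError:
        raise DataError(f"unknown predictor set {name!r}; choose from {sorted(PREDICTOR_SETS)}")


def _feature_value(record: SubjectRecord, feature: str) -> float:
    # Sex encoded F=1 / M=0; APOE as e4 allele count 0-2.
    if feature == "sex":
        return 1.0 if record.sex == "F" else 0.0
    if feature == "apoe_e4":
        return float(record.apoe_e4_count)
    try:
        if feature in record.regional_volumes:
            return float(record.regional_volumes[feature])
        if hasattr(record, feature) and getattr(record, feature) is not None:
            return float(getattr(record, feature))
    except (TypeError, ValueError):
        pass
    raise DataError(f"subject {record.subject_id} is missing feature {feature!r}")


def assemble_features(
    cohort: Iterable[SubjectRecord], predictor_set: str
) -> pd.DataFrame:
    """One row per subject, columns in predictor-set order, indexed by id."""
    names = predictor_set_features(predictor_set)
    rows, ids = [], []
    for r in cohort:
        rows.append([_feature_value(r, f) for f in names])
        ids.append(r.subject_id)
    if not rows:
        raise DataError("empty cohort")
    return pd.DataFrame(rows, columns=list(names), index=pd.Index(ids, name="subject_id"))


@dataclass
class FittedTabularModel:
    predictor_set: str
    task: str  # "binary" | "continuous"
    learner: str  # "generalized-linear" | "random-forest"
    estimator: object
    stats: NormalizationStats
    seed: int

    def save(self, path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path) -> "FittedTabularModel":
        return pickle.loads(Path(path).read_bytes())


def fit_tabular(
    features: pd.DataFrame,
    outcome: Sequence[float],
    task: str,
    learner: str | None = None,
    seed: int = 0,
    predictor_set: str = "",
) -> FittedTabularModel:
    """Standardize on the given (training) rows and fit the learner.

    Logistic regression is fitted without penalty (plain maximum
    likelihood); the random forest uses the library defaults with only the
    seed fixed.
    """
    if learner is None:
        learner = DEFAULT_LEARNER.get(predictor_set, "generalized-linear")
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != features.shape[0]:
        raise DataError("outcome length does not match the feature matrix")
    if task == "binary" and np.unique(y).size < 2:
        raise DataError("binary task requires both outcome classes in training data")
    if task not in ("binary", "continuous"):
        raise DataError(f"task must be 'binary' or 'continuous', got {task!r}")

    stats = fit_standardizer(features.to_numpy(), features.columns, fitted_on="train")
    X = apply_standardizer(stats, features.to_numpy())

    if learner == "generalized-linear":
        if task == "binary":
            # C=inf disables the penalty: plain maximum-likelihood logistic fit
            est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000,
                                     tol=1e-10)
        else:
            est = LinearRegression()
    elif learner == "random-forest":
        if task == "binary":
            est = RandomForestClassifier(random_state=seed)
        else:
            est = RandomForestRegressor(random_state=seed)
    else:
        raise DataError(f"unknown learner {learner!r}")
    est.fit(X, y.astype(int) if task == "binary" else y)
    return FittedTabularModel(
        predictor_set=predictor_set or "custom", task=task, learner=learner,
        estimator=est, stats=stats, seed=seed,
    )


def predict_tabular(model: FittedTabularModel, features: pd.DataFrame) -> np.ndarray:
    """Risk scores in [0, 1] (binary) or real-valued predictions (continuous)."""
    if list(features.columns) != model.stats.feature_names:
        raise DataError(
            "feature columns do not match the model's predictor set "
            f"({model.predictor_set})"
        )
    X = apply_standardizer(model.stats, features.to_numpy())
    if model.task == "binary":
        return model.estimator.predict_proba(X)[:, 1]
    return model.estimator.predict(X)
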