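"""Survivorship prediction from serum N-glycome profiles.

The prognostic question is asked at ICU admission: can the day-1 serum
N-glycome predict whether a septic shock patient will survive? The model is
a random forest trained on untransformed glycan relative abundances from all
samples collected on ICU day >= 2 (each sample labelled with its patient's
outcome) and tested on the held-out day-1 sample of every patient, one
prediction per patient. Nonsurvivors are the positive class throughout.

Note the design deliberately evaluates on day-1 samples of the *same*
patients whose later samples were trained on. Because serum N-glycome
profiles are strongly patient-stable, this longitudinal split shares
patient-level information between train and test; a patient-disjoint
cross-validation mode is provided for honest generalization estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold

from .errors import SpecValidationError

__all__ = [
    "POSITIVE_CLASS",
    "NEGATIVE_CLASS",
    "ModelSpec",
    "SplitDesign",
    "ConfusionCounts",
    "PerformanceMetrics",
    "longitudinal_split",
    "train_model",
    "predict_patients",
    "confusion_counts",
    "confusion_metrics",
    "feature_importance_ranking",
    "evaluate_survivorship",
    "patient_disjoint_cv",
]

POSITIVE_CLASS = "nonsurvivor"
NEGATIVE_CLASS = "survivor"


@dataclass
class ModelSpec:
    """Random-forest hyperparameters; the seed is mandatory for reproducibility."""

    n_trees: int = 500
    max_depth: Optional[int] = None
    class_weighting: str = "none"  # "none" or "balanced"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise SpecValidationError("n_trees", "must be >= 1")
        if self.class_weighting not in ("none", "balanced"):
            raise SpecValidationError("class_weighting", "must be 'none' or 'balanced'")
        if not isinstance(self.seed, (int, np.integer)):
            raise SpecValidationError("seed", "must be an integer")


@dataclass
class SplitDesign:
    """Longitudinal train/test partition of cohort samples.

    train: all samples from ICU day >= 2; test: the single day-1 sample per
    patient. Patients lacking either side are excluded with a warning.
    """

    train: pd.DataFrame
    test: pd.DataFrame
    excluded_patients: List[str] = field(default_factory=list)


def longitudinal_split(samples: pd.DataFrame) -> SplitDesign:
    """Partition a cohort table (patient_id, outcome, icu_day, sample_id)."""
    required = {"patient_id", "outcome", "icu_day", "sample_id"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    excluded = []
    keep = []
    for pid, grp in samples.groupby("patient_id", sort=False):
        days = set(grp["icu_day"])
        if 1 not in days or not any(d >= 2 for d in days):
            excluded.append(str(pid))
        else:
            keep.append(grp)
    if excluded:
        warnings.warn(
            f"excluded patients without both a day-1 and a day>=2 sample: {excluded}"
        )
    if not keep:
        raise ValueError("no patient has both a day-1 and a day>=2 sample")
    kept = pd.concat(keep)
    train = kept[kept["icu_day"] >= 2].copy()
    test = kept[kept["icu_day"] == 1].copy()
    if train.empty or test.empty:
        raise ValueError("longitudinal split produced an empty train or test set")
    return SplitDesign(train=train, test=test, excluded_patients=excluded)


@dataclass
class FittedModel:
    """A trained forest plus the feature contract it was trained under."""

    forest: RandomForestClassifier
    feature_names: List[str]
    classes: Tuple[str, ...]


def train_model(features: pd.DataFrame, labels: Sequence[str], spec: ModelSpec) -> FittedModel:
    """Fit the survivorship forest on day >= 2 samples.

    ``features`` holds untransformed glycan relative abundances (one row per
    sample); ``labels`` is the outcome of each sample's patient. Training is
    deterministic given ``spec.seed``.
    """
    labels = np.asarray(labels, dtype=object)
    if features.shape[0] != labels.size:
        raise ValueError("features and labels disagree in length")
    if np.unique(labels).size < 2:
        raise ValueError("training labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_depth=spec.max_depth,
        max_features="sqrt",
        class_weight=None if spec.class_weighting == "none" else "balanced",
        random_state=spec.seed,
    )
    forest.fit(features.to_numpy(dtype=float), labels)
    return FittedModel(
        forest=forest,
        feature_names=list(features.columns),
        classes=tuple(forest.classes_),
    )


def predict_patients(model: FittedModel, test_features: pd.DataFrame) -> pd.DataFrame:
    """Predict one outcome per patient from day-1 features.

    The score is the fraction of trees voting for the positive
    (nonsurvivor) class; the call is the majority vote with ties broken
    toward nonsurvivor (score >= 0.5).
    """
    if list(test_features.columns) != model.feature_names:
        raise ValueError(
            "test feature columns do not match training features: "
            f"{list(test_features.columns)} vs {model.feature_names}"
        )
    X = test_features.to_numpy(dtype=float)
    # individual trees predict indices into forest.classes_, not labels
    pos_idx = list(model.forest.classes_).index(POSITIVE_CLASS)
    votes = np.stack(
        [tree.predict(X).astype(int) for tree in model.forest.estimators_]
    )
    score = (votes == pos_idx).mean(axis=0)
    predicted = np.where(score >= 0.5, POSITIVE_CLASS, NEGATIVE_CLASS)
    return pd.DataFrame(
        {"predicted": predicted, "score": score}, index=test_features.index
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with nonsurvivor as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionCounts:
    t = np.asarray(y_true, dtype=object)
    p = np.asarray(y_pred, dtype=object)
    return ConfusionCounts(
        tp=int(((t == POSITIVE_CLASS) & (p == POSITIVE_CLASS)).sum()),
        tn=int(((t == NEGATIVE_CLASS) & (p == NEGATIVE_CLASS)).sum()),
        fp=int(((t == NEGATIVE_CLASS) & (p == POSITIVE_CLASS)).sum()),
        fn=int(((t == POSITIVE_CLASS) & (p == NEGATIVE_CLASS)).sum()),
    )


@dataclass(frozen=True)
class PerformanceMetrics:
    """Accuracy / sensitivity / specificity, as fractions and percent.

    A metric whose denominator is zero is undefined: it is reported as NaN
    and listed in ``undefined`` rather than silently coerced to 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    undefined: Tuple[str, ...] = ()

    @property
    def accuracy_pct(self) -> float:
        return self.accuracy * 100.0

    @property
    def sensitivity_pct(self) -> float:
        return self.sensitivity * 100.0

    @property
    def specificity_pct(self) -> float:
        return self.specificity * 100.0

    def as_dict(self) -> Dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "undefined": list(self.undefined),
        }


def confusion_metrics(cc: ConfusionCounts) -> PerformanceMetrics:
    """Accuracy (TP+TN)/(all), sensitivity TP/(TP+FN), specificity TN/(TN+FP)."""
    if cc.total == 0:
        raise ValueError("confusion counts are all zero")
    undefined = []
    accuracy = (cc.tp + cc.tn) / cc.total
    if cc.tp + cc.fn > 0:
        sensitivity = cc.tp / (cc.tp + cc.fn)
    else:
        sensitivity = float("nan")
        undefined.append("sensitivity")
    if cc.tn + cc.fp > 0:
        specificity = cc.tn / (cc.tn + cc.fp)
    else:
        specificity = float("nan")
        undefined.append("specificity")
    return PerformanceMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        undefined=tuple(undefined),
    )


def feature_importance_ranking(model: FittedModel) -> List[Tuple[str, float]]:
    """Impurity-based importances, descending; they are >= 0 and sum to 1."""
    if not hasattr(model.forest, "feature_importances_"):
        raise ValueError("model is not fitted")
    pairs = list(zip(model.feature_names, model.forest.feature_importances_.tolist()))
    return sorted(pairs, key=lambda kv: (-kv[1], kv[0]))


def _align(profiles: pd.DataFrame, sample_ids: Sequence[str]) -> pd.DataFrame:
    missing = [s for s in sample_ids if s not in profiles.index]
    if missing:
        raise ValueError(f"profiles missing samples: {missing[:5]}...")
    return profiles.loc[list(sample_ids)]


def evaluate_survivorship(
    profiles: pd.DataFrame, cohort: pd.DataFrame, spec: ModelSpec
) -> Dict[str, object]:
    """End-to-end longitudinal evaluation on one cohort.

    Returns the fitted model, per-patient day-1 predictions, confusion
    counts, performance metrics and the importance ranking.
    """
    design = longitudinal_split(cohort)
    X_train = _align(profiles, design.train["sample_id"])
    model = train_model(X_train, design.train["outcome"].to_numpy(), spec)
    test = design.test.set_index("patient_id")
    X_test = _align(profiles, test["sample_id"])
    X_test.index = test.index
    preds = predict_patients(model, X_test)
    cc = confusion_counts(test["outcome"].to_numpy(), preds["predicted"].to_numpy())
    return {
        "model": model,
        "design": design,
        "predictions": preds.assign(outcome=test["outcome"]),
        "confusion": cc,
        "metrics": confusion_metrics(cc),
        "importances": feature_importance_ranking(model),
    }


def patient_disjoint_cv(
    profiles: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: ModelSpec,
    n_splits: int = 5,
) -> Dict[str, object]:
    """Strict patient-disjoint alternative to the longitudinal design.

    Folds are grouped by patient: the forest trains on day >= 2 samples of
    the training patients and predicts day-1 samples of held-out patients,
    so no patient contributes to both sides. Pooled confusion counts over
    folds estimate honest generalization.
    """
    design = longitudinal_split(cohort)
    patients = design.test["patient_id"].to_numpy()
    splitter = GroupKFold(n_splits=n_splits)
    y_true: List[str] = []
    y_pred: List[str] = []
    test_idx = design.test.set_index("patient_id")
    for fold, (_, held_out) in enumerate(
        splitter.split(patients, groups=patients)
    ):
        held = set(patients[held_out])
        tr = design.train[~design.train["patient_id"].isin(held)]
        if tr["outcome"].nunique() < 2:
            warnings.warn(f"fold {fold}: single-class training labels; skipped")
            continue
        model = train_model(
            _align(profiles, tr["sample_id"]), tr["outcome"].to_numpy(), spec
        )
        te = test_idx.loc[sorted(held)]
        X_te = _align(profiles, te["sample_id"])
        X_te.index = te.index
        preds = predict_patients(model, X_te)
        y_true.extend(te["outcome"].tolist())
        y_pred.extend(preds["predicted"].tolist())
    cc = confusion_counts(y_true, y_pred)
    return {"confusion": cc, "metrics": confusion_metrics(cc)}
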