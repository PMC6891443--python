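"""Classifier estimator and the staged assessment pipelines.

The live acquisition flow is two-staged: each camera-preview frame first
passes an *artifact* gate (is there a skin mole at all, or only lens dirt /
background?) and, only if it passes, a *focus* gate.  The final acquired
picture is assessed by a single focus model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .features import extract_features_image
from .image import DEFAULT_CROP_FRACTION, RawImage
from .tree import DecisionTreeModel

__all__ = [
    "Verdict",
    "AssessmentResult",
    "FocusTreeClassifier",
    "ModelTaskMismatchError",
    "assess_preview",
    "assess_photo",
    "LABEL_ARTIFACT",
    "LABEL_MOLE",
    "LABEL_FOCUSED",
    "LABEL_NON_FOCUSED",
]

LABEL_ARTIFACT = "artifact"
LABEL_MOLE = "mole"
LABEL_FOCUSED = "focused"
LABEL_NON_FOCUSED = "non_focused"


class Verdict(str, enum.Enum):
    ARTIFACT = "ARTIFACT"
    NOT_FOCUSED = "NOT_FOCUSED"
    FOCUSED = "FOCUSED"


class ModelTaskMismatchError(ValueError):
    """A model was handed to a pipeline stage it was not trained for."""


@dataclass
class AssessmentResult:
    verdict: Verdict
    stage_outputs: dict[str, dict] = field(default_factory=dict)
    features_used: dict[str, float] = field(default_factory=dict)


class FocusTreeClassifier(ClassifierMixin, BaseEstimator):
    """Decision-tree classifier over named focus features.

    Fitting is delegated to :class:`sklearn.tree.DecisionTreeClassifier`;
    the fitted structure is converted to the package's serialisable
    :class:`DecisionTreeModel`, which performs all prediction.

    Parameters mirror the hyper-parameters explored during training.

    Parameters
    ----------
    features : sequence of str or None
        Feature columns the tree may split on (None = all columns).
    max_depth : int, default 3
    criterion : {"gini", "entropy"}, default "gini"
    splitter : {"best", "random"}, default "best"
    min_samples_split : int or float, default 2
        Floats are fractions of the training-set size.
    task : str, default "unspecified"
    random_state : int or None
    """

    def __init__(
        self,
        features=None,
        max_depth: int = 3,
        criterion: str = "gini",
        splitter: str = "best",
        min_samples_split=2,
        task: str = "unspecified",
        random_state=None,
    ):
        self.features = features
        self.max_depth = max_depth
        self.criterion = criterion
        self.splitter = splitter
        self.min_samples_split = min_samples_split
        self.task = task
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        cols = list(self.features) if self.features is not None else list(X.columns)
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"feature columns absent from X: {missing}")
        Xs = X.loc[:, cols].to_numpy(dtype=float)
        if np.isnan(Xs).any():
            raise ValueError("training features contain NaN sentinels")
        est = DecisionTreeClassifier(
            max_depth=self.max_depth,
            criterion=self.criterion,
            splitter=self.splitter,
            min_samples_split=self.min_samples_split,
            random_state=self.random_state,
        )
        est.fit(Xs, np.asarray(y))
        self.sk_estimator_ = est
        self.classes_ = est.classes_
        self.n_features_in_ = len(cols)
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.model_ = DecisionTreeModel.from_sklearn(
            est,
            cols,
            task=self.task,
            metadata={"params": {k: repr(v) for k, v in self.get_params().items()}},
        )
        return self

    def _rows(self, X: pd.DataFrame):
        return (row for _, row in pd.DataFrame(X).iterrows())

    def predict(self, X):
        check_is_fitted(self, "model_")
        return np.asarray([self.model_.predict_one(row)[0] for row in self._rows(X)])

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        out = []
        for row in self._rows(X):
            _, scores = self.model_.predict_one(row)
            out.append([scores.get(str(c), 0.0) for c in self.classes_])
        return np.asarray(out)


# ------------------------------------------------------------- pipelines

def _require_task(model: DecisionTreeModel, task: str) -> None:
    if model.task != task:
        raise ModelTaskMismatchError(f"model task {model.task!r}, expected {task!r}")


def _focus_verdict(label: str) -> Verdict:
    return Verdict.FOCUSED if label == LABEL_FOCUSED else Verdict.NOT_FOCUSED


def assess_preview(
    image: RawImage,
    artifact_model: DecisionTreeModel,
    focus_model: DecisionTreeModel,
    crop_fraction: float = DEFAULT_CROP_FRACTION,
) -> AssessmentResult:
    """Two-stage preview assessment: artifact gate, then focus gate.

    Features are extracted once and shared by both stages.  If the artifact
    stage fires, the focus model is never consulted.
    """
    _require_task(artifact_model, "artifact")
    _require_task(focus_model, "preview_focus")
    feats = extract_features_image(image, crop_fraction)
    used = {n: feats[n] for n in set(artifact_model.feature_names_used())}
    label, scores = artifact_model.predict_one(feats)
    stages = {"artifact": {"label": label, "scores": scores}}
    if label == LABEL_ARTIFACT:
        return AssessmentResult(Verdict.ARTIFACT, stages, used)
    used.update({n: feats[n] for n in focus_model.feature_names_used()})
    flabel, fscores = focus_model.predict_one(feats)
    stages["focus"] = {"label": flabel, "scores": fscores}
    return AssessmentResult(_focus_verdict(flabel), stages, used)


def assess_photo(
    image: RawImage,
    acquired_model: DecisionTreeModel,
    crop_fraction: float = DEFAULT_CROP_FRACTION,
) -> AssessmentResult:
    """Single-stage focus assessment of the final acquired picture."""
    _require_task(acquired_model, "acquired_focus")
    feats = extract_features_image(image, crop_fraction)
    label, scores = acquired_model.predict_one(feats)
    used = {n: feats[n] for n in acquired_model.feature_names_used()}
    return AssessmentResult(
        _focus_verdict(label), {"focus": {"label": label, "scores": scores}}, used
    )
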