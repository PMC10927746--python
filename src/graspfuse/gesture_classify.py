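"""Window features and the two extra-trees classifiers.

From each preprocessed EMG window three time-domain features are taken
per channel -- root mean square (RMS), mean absolute value (MAV) and
variance (VAR) -- giving a 3C-length vector Z ordered
(RMS_1..RMS_C, MAV_1..MAV_C, VAR_1..VAR_C).

Windows are labeled from a trial's phase segmentation: the phase
containing the window's center sample, with gesture label l equal to the
executed grasp (1..13) during reach/grasp/return and the open-palm/rest
label l=0 during rest.  Two extremely-randomized-trees ensembles (50
trees, min_samples_split=2) are trained on these features: a 14-class
gesture classifier and a 4-class motion-phase classifier.  Return-phase
windows are excluded from gesture training by default (the hand has
already released the object there); validation always keeps all phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from .emg_preproc import EmgWindow
from .evidence_fusion import N_GRASP_CLASSES
from .ggs_segmentation import Segmentation

__all__ = [
    "REST_LABEL",
    "FeatureVector",
    "WindowLabel",
    "TrainedClassifier",
    "extract_features",
    "feature_names",
    "annotate_windows",
    "build_training_set",
    "train_classifier",
    "predict_proba",
    "restrict_to_grasp_classes",
]

REST_LABEL = 0


@dataclass
class FeatureVector:
    """3C-length feature vector for one window, with its end timestamp."""

    Z: np.ndarray
    t_end_s: float


@dataclass(frozen=True)
class WindowLabel:
    gesture: int
    phase: str

    def __post_init__(self) -> None:
        if (self.phase == "rest") != (self.gesture == REST_LABEL):
            raise ValueError("gesture is 0 if and only if the phase is rest")


def extract_features(window: EmgWindow) -> FeatureVector:
    """Per-channel RMS, MAV and VAR, concatenated in that fixed order."""
    x = np.asarray(window.X, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    rms = np.sqrt(np.mean(x**2, axis=1))
    mav = np.mean(np.abs(x), axis=1)
    var = np.mean((x - x.mean(axis=1, keepdims=True)) ** 2, axis=1)
    return FeatureVector(Z=np.concatenate([rms, mav, var]), t_end_s=window.t_end_s)


def feature_names(channel_names) -> list[str]:
    return [f"{feat}_{ch}" for feat in ("RMS", "MAV", "VAR") for ch in channel_names]


def annotate_windows(
    windows: list[EmgWindow], seg: Segmentation, gesture_id: int
) -> list[WindowLabel]:
    """Label each window by the phase containing its center sample."""
    labels = []
    for w in windows:
        phase = seg.phase_of_sample(w.center_sample())
        gesture = REST_LABEL if phase == "rest" else gesture_id
        labels.append(WindowLabel(gesture=gesture, phase=phase))
    return labels


def build_training_set(
    features: list[FeatureVector],
    labels: list[WindowLabel],
    task: str = "gesture",
    exclude_return: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (X, y) matrix for one of the two classifiers.

    For the gesture task, return-phase windows are dropped when
    ``exclude_return`` is on; the phase task always keeps all phases.
    """
    if len(features) != len(labels):
        raise ValueError("features / labels length mismatch")
    if task not in ("gesture", "phase"):
        raise ValueError("task must be 'gesture' or 'phase'")
    rows, ys = [], []
    for f, lab in zip(features, labels):
        if task == "gesture" and exclude_return and lab.phase == "return":
            continue
        rows.append(f.Z)
        ys.append(lab.gesture if task == "gesture" else lab.phase)
    if not rows:
        raise ValueError("no training rows left after filtering")
    return np.array(rows), np.array(ys)


@dataclass
class TrainedClassifier:
    """A fitted extra-trees ensemble plus its task and training config."""

    task: str
    model: ExtraTreesClassifier
    seed: int
    n_trees: int = 50
    min_samples_split: int = 2

    @property
    def classes_(self) -> np.ndarray:
        return self.model.classes_


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "gesture",
    seed: int = 0,
    n_trees: int = 50,
    min_samples_split: int = 2,
) -> TrainedClassifier:
    """Fit 50 extremely randomized trees; deterministic for a fixed seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y must have the same number of rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    model = ExtraTreesClassifier(
        n_estimators=n_trees,
        min_samples_split=min_samples_split,
        random_state=seed,
    )
    model.fit(X, y)
    return TrainedClassifier(
        task=task, model=model, seed=seed,
        n_trees=n_trees, min_samples_split=min_samples_split,
    )


def predict_proba(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Per-window class probabilities (average of per-tree leaf frequencies)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != clf.model.n_features_in_:
        raise ValueError(
            f"feature dimension {X.shape[1]} != trained {clf.model.n_features_in_}"
        )
    return clf.model.predict_proba(X)


def restrict_to_grasp_classes(
    proba: np.ndarray, classes: np.ndarray, n_classes: int = N_GRASP_CLASSES
) -> np.ndarray:
    """Renormalize a (possibly 14-class) posterior over grasp labels 1..13.

    Classes absent from training get zero mass; if the grasp classes
    carry no mass at all (e.g. the classifier is certain of rest) the
    result is uniform, which is inert under product fusion.
    """
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    out = np.zeros((proba.shape[0], n_classes))
    for j, cls in enumerate(np.asarray(classes)):
        cls = int(cls)
        if 1 <= cls <= n_classes:
            out[:, cls - 1] = proba[:, j]
    totals = out.sum(axis=1, keepdims=True)
    uniform = np.full(n_classes, 1.0 / n_classes)
    zero = (totals <= 0).ravel()
    out[~zero] = out[~zero] / totals[~zero]
    out[zero] = uniform
    return out
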