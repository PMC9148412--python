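"""Frame-level posture classification and fusion with the transition prior.

The classifier is a deterministic nearest-centroid soft classifier over
L2-normalised frame descriptors: each posture's centroid is the mean of
its training descriptors, and class probabilities are proportional to
exp(-d^2 / T) for squared Euclidean distance d^2 and temperature T.  It
stands behind a small interface so a learned model can be swapped in; the
testable contribution of the pipeline is the Bayesian fusion with the
transition prior, not the classifier's weights.

The default temperature (0.05) is chosen so that on noise-free rendered
frames the observation term is decisive against any transition prior:
with T = 1 the prior's stay/move odds (which grow with the amount of
fitting data) override a correct observation at posture-change epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import ConflictError, InvalidTrainingSetError
from .features import FeatureVector
from .predictor import CORE_POSTURES, Posture, posture_order

__all__ = [
    "DEFAULT_TEMPERATURE",
    "TemplateClassifier",
    "EvaluationResult",
    "train_classifier",
    "classify",
    "fuse_with_prior",
    "evaluate",
]

DEFAULT_TEMPERATURE = 0.05


def _descriptor(feat) -> np.ndarray:
    if isinstance(feat, FeatureVector):
        return np.concatenate([feat.hog, feat.weights])
    return np.asarray(feat, dtype=float)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


@dataclass
class TemplateClassifier:
    """Per-posture centroids in L2-normalised descriptor space."""

    labels: tuple[Posture, ...]
    centroids: np.ndarray             # (n_labels, dim)
    temperature: float = DEFAULT_TEMPERATURE


def train_classifier(
    features: list,
    labels: list[Posture],
    temperature: float = DEFAULT_TEMPERATURE,
) -> TemplateClassifier:
    """Centroid = per-label mean of L2-normalised descriptors; deterministic.

    The four core postures must all be present; OFFBED is included as an
    extra class when it appears in the training labels.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    labels = [Posture(l) for l in labels]
    present = set(labels)
    missing = [l.value for l in CORE_POSTURES if l not in present]
    if missing:
        raise InvalidTrainingSetError(f"missing labels in training set: {missing}")
    out_labels = posture_order(include_offbed=Posture.OFFBED in present)
    vecs = [_unit(_descriptor(f)) for f in features]
    dims = {v.shape[0] for v in vecs}
    if len(dims) != 1:
        raise ValueError(f"descriptor lengths differ: {sorted(dims)}")
    centroids = np.stack([
        np.mean([v for v, l in zip(vecs, labels) if l == lab], axis=0)
        for lab in out_labels
    ])
    return TemplateClassifier(labels=out_labels, centroids=centroids,
                              temperature=temperature)


def classify(clf: TemplateClassifier, feat) -> dict[Posture, float]:
    """Soft class probabilities: p(label) proportional to exp(-d^2 / T)."""
    v = _unit(_descriptor(feat))
    if v.shape[0] != clf.centroids.shape[1]:
        raise ValueError(
            f"descriptor length {v.shape[0]} does not match classifier "
            f"dimensionality {clf.centroids.shape[1]}"
        )
    d2 = np.sum((clf.centroids - v) ** 2, axis=1)
    logits = -d2 / clf.temperature
    p = np.exp(logits - logits.max())
    p /= p.sum()
    return {l: float(x) for l, x in zip(clf.labels, p)}


def fuse_with_prior(obs: dict[Posture, float], prior: dict[Posture, float]
                    ) -> dict[Posture, float]:
    """Elementwise product of observation and prior, renormalised.

    A uniform prior returns the observation unchanged; a structural zero in
    the prior forces the fused probability of that label to zero.
    """
    keys = [l for l in obs if l in prior]
    if not keys:
        raise ValueError("obs and prior share no labels")
    o = np.array([obs[l] for l in keys], dtype=float)
    p = np.array([prior[l] for l in keys], dtype=float)
    for name, vec in (("obs", o), ("prior", p)):
        if abs(vec.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} must sum to 1 (got {vec.sum():.8f})")
    fused = o * p
    total = fused.sum()
    if total <= 0:
        raise ConflictError("observation and prior have disjoint support")
    fused /= total
    return {l: float(x) for l, x in zip(keys, fused)}


@dataclass
class EvaluationResult:
    labels: tuple[Posture, ...]
    confusion: np.ndarray             # rows = truth, cols = predicted
    accuracy: float
    recall: dict[Posture, float]      # per-class recall; nan if class absent

    def to_jsonable(self) -> dict:
        return {
            "labels": [l.value for l in self.labels],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "recall": {l.value: r for l, r in self.recall.items()},
        }


def evaluate(predicted: list[Posture], truth: list[Posture]) -> EvaluationResult:
    """Confusion matrix, overall accuracy and per-class recall."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    if not truth:
        raise ValueError("cannot evaluate empty label lists")
    predicted = [Posture(l) for l in predicted]
    truth = [Posture(l) for l in truth]
    offbed = Posture.OFFBED in set(truth) | set(predicted)
    labels = posture_order(include_offbed=offbed)
    cm = _sk_confusion([t.value for t in truth], [p.value for p in predicted],
                       labels=[l.value for l in labels])
    accuracy = float(np.trace(cm) / cm.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rec = np.diag(cm) / cm.sum(axis=1)
    recall = {l: float(r) for l, r in zip(labels, rec)}
    return EvaluationResult(labels=labels, confusion=cm, accuracy=accuracy,
                            recall=recall)
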