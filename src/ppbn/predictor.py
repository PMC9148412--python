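"""Constraint-aware Bayesian posture-transition model.

Sleep is modelled as a discrete-time Markov process over four in-bed
postures — supine, prone, left lateral recumbent (LLR) and right lateral
recumbent (RLR) — with one label per fixed-length epoch (default 30 s).
Anatomy constrains which transitions are possible: the prone posture is
entered only from a lateral one, and a lateral posture only from supine.
Those constraints are *structural zeros*: their probability is exactly 0
regardless of data or smoothing.

Prediction is sequential Bayes: the transition model supplies a prior over
the next posture given the last one or two postures, which is multiplied by
an observation likelihood (from a frame classifier or a physiological
signal) and renormalised.

An optional fifth state, OFFBED, represents time out of bed; it is used by
the synthetic generator to carry the residual occupancy mass and is only
ever reachable to and from supine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ConflictError

logger = logging.getLogger(__name__)

__all__ = [
    "Posture",
    "CORE_POSTURES",
    "PostureSequence",
    "TransitionModel",
    "PredictionResult",
    "posture_order",
    "default_allowed_mask",
    "fit_transition_model",
    "predict_next",
    "estimate_occupancy",
    "shifts_per_hour",
]


class Posture(str, Enum):
    """The four in-bed posture classes, plus the off-bed calibration state."""

    SUPINE = "SUPINE"
    PRONE = "PRONE"
    LLR = "LLR"
    RLR = "RLR"
    OFFBED = "OFFBED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical label order used for every table, matrix and tie-break.
CORE_POSTURES: tuple[Posture, ...] = (
    Posture.SUPINE,
    Posture.PRONE,
    Posture.LLR,
    Posture.RLR,
)

DEFAULT_EPOCH_SECONDS = 30.0


def posture_order(include_offbed: bool = False) -> tuple[Posture, ...]:
    """Canonical label ordering, optionally extended with OFFBED."""
    return CORE_POSTURES + ((Posture.OFFBED,) if include_offbed else ())


@dataclass
class PostureSequence:
    """Ordered posture labels at a fixed epoch duration."""

    labels: list[Posture]
    epoch_seconds: float = DEFAULT_EPOCH_SECONDS

    def __post_init__(self) -> None:
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        self.labels = [Posture(l) for l in self.labels]

    def __len__(self) -> int:
        return len(self.labels)


def default_allowed_mask(include_offbed: bool = False) -> np.ndarray:
    """Boolean table of anatomically permitted transitions.

    Rows index the current posture, columns the next, in canonical order.
    Self-transitions are always allowed.  Prone is entered only from a
    lateral posture; a lateral posture is entered only from supine; prone
    exits only to supine (keeping the graph strongly connected).  OFFBED,
    when included, connects to and from supine only.
    """
    labels = posture_order(include_offbed)
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    mask = np.zeros((n, n), dtype=bool)
    for l in labels:
        mask[idx[l], idx[l]] = True
    S, P, L, R = (idx[p] for p in CORE_POSTURES)
    mask[S, L] = mask[S, R] = True          # lateral entered only from supine
    mask[L, S] = mask[R, S] = True
    mask[L, P] = mask[R, P] = True          # prone entered only from lateral
    mask[P, S] = True                       # prone exits to supine
    if include_offbed:
        O = idx[Posture.OFFBED]
        mask[S, O] = mask[O, S] = True
    return mask


@dataclass
class TransitionModel:
    """Conditional distributions P(next | history) with structural zeros.

    ``probs`` has shape ``(n,) * order + (n,)``: the leading axes index the
    history (oldest first), the trailing axis the next posture.  Forbidden
    targets (per ``mask`` applied to the most recent history element) are
    exactly zero in every row.
    """

    order: int
    labels: tuple[Posture, ...]
    probs: np.ndarray
    mask: np.ndarray
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        self.probs = np.asarray(self.probs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def index(self) -> dict[Posture, int]:
        return {l: i for i, l in enumerate(self.labels)}

    def row(self, history: list[Posture]) -> np.ndarray:
        """Conditional distribution over the next posture for a history."""
        if len(history) < self.order:
            raise ValueError(
                f"history of length {len(history)} is shorter than model order {self.order}"
            )
        idx = self.index
        key = tuple(idx[Posture(h)] for h in history[-self.order:])
        return self.probs[key]


@dataclass
class PredictionResult:
    posterior: dict[Posture, float]
    predicted: Posture
    history_used: list[Posture] = field(default_factory=list)


def _infer_labels(sequences: list[PostureSequence]) -> tuple[Posture, ...]:
    seen = {l for seq in sequences for l in seq.labels}
    return posture_order(Posture.OFFBED in seen)


def fit_transition_model(
    sequences: list[PostureSequence],
    order: int = 2,
    alpha: float = 1.0,
    mask: np.ndarray | None = None,
    labels: tuple[Posture, ...] | None = None,
) -> TransitionModel:
    """Fit conditional transition probabilities by smoothed counting.

    ``alpha`` pseudo-counts are added to *allowed* targets only, so
    structural zeros survive any amount of smoothing.  Observed transitions
    that violate the mask are skipped with a warning (real data may violate
    the idealised model).  Histories never observed fall back to a uniform
    distribution over allowed targets so prediction is always defined.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if not sequences and alpha == 0:
        raise ValueError("need data or a positive alpha to define the model")
    if labels is None:
        labels = _infer_labels(sequences)
    if mask is None:
        mask = default_allowed_mask(include_offbed=Posture.OFFBED in labels)
    mask = np.asarray(mask, dtype=bool)
    n = len(labels)
    if mask.shape != (n, n):
        raise ValueError(f"mask shape {mask.shape} does not match {n} labels")
    idx = {l: i for i, l in enumerate(labels)}

    counts = np.zeros((n,) * order + (n,), dtype=float)
    n_skipped = 0
    for seq in sequences:
        codes = [idx[l] for l in seq.labels]
        for t in range(order, len(codes)):
            hist = tuple(codes[t - order:t])
            nxt = codes[t]
            if not mask[hist[-1], nxt]:
                n_skipped += 1
                continue
            counts[hist + (nxt,)] += 1.0
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} observed transitions forbidden by the mask",
            stacklevel=2,
        )

    probs = np.zeros_like(counts)
    it = np.ndindex(*counts.shape[:-1])
    for hist in it:
        allowed = mask[hist[-1]]
        row = counts[hist] + alpha * allowed
        total = row.sum()
        if total == 0:
            row = allowed.astype(float)
            total = row.sum()
        probs[hist] = row / total
    return TransitionModel(order=order, labels=tuple(labels), probs=probs,
                           mask=mask, alpha=alpha)


def predict_next(
    model: TransitionModel,
    history: list[Posture],
    obs_likelihood: dict[Posture, float] | None = None,
) -> PredictionResult:
    """Posterior over the next posture: transition prior x observation likelihood.

    With no likelihood the posterior is the transition row itself.  Ties in
    the argmax are broken by the canonical label order.
    """
    history = [Posture(h) for h in history]
    prior = model.row(history)
    if obs_likelihood is None:
        lik = np.ones(len(model.labels))
    else:
        lik = np.array([float(obs_likelihood.get(l, 0.0)) for l in model.labels])
        if np.any(lik < 0):
            raise ValueError("likelihood values must be non-negative")
    post = prior * lik
    total = post.sum()
    if total <= 0.0:
        raise ConflictError(
            f"prior {dict(zip([l.value for l in model.labels], prior.round(6)))} and "
            f"likelihood {dict(zip([l.value for l in model.labels], lik.round(6)))} "
            "have disjoint support"
        )
    post = post / total
    predicted = model.labels[int(np.argmax(post))]
    return PredictionResult(
        posterior={l: float(p) for l, p in zip(model.labels, post)},
        predicted=predicted,
        history_used=history[-model.order:],
    )


def estimate_occupancy(seq: PostureSequence) -> dict[Posture, float]:
    """Fraction of epochs spent in each posture; fractions sum to 1."""
    if len(seq) == 0:
        raise ValueError("cannot estimate occupancy of an empty sequence")
    labels = posture_order(Posture.OFFBED in seq.labels)
    n = len(seq)
    return {l: sum(1 for x in seq.labels if x == l) / n for l in labels}


def shifts_per_hour(seq: PostureSequence) -> float:
    """Posture changes per hour of observation.

    The denominator is the full recording duration (n_epochs x epoch length),
    so doubling the epoch duration halves the rate for the same labels.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 epochs to count shifts")
    changes = sum(1 for a, b in zip(seq.labels, seq.labels[1:]) if a != b)
    hours = len(seq) * seq.epoch_seconds / 3600.0
    return changes / hours
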