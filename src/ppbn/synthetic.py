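"""Synthetic sleep-night generator calibrated to cohort posture statistics.

Accelerometer cohort studies of sleeping adults report, on average, 54.1%
of the night in a lateral recumbent posture (left or right), 37.5% prone,
7.3% supine, and about 1.6 posture shifts per hour.  Those figures sum to
98.9%; the 1.1% remainder is modelled here as an explicit OFFBED state
(reachable to and from supine only) rather than renormalised away, so the
printed percentages are recovered exactly in expectation.  The lateral
total is split equally between LLR and RLR.

The calibrated transition matrix is built from a jump chain plus holding
rates.  The anatomical constraint mask is irreversible (prone is entered
from a lateral posture but exits to supine), so no detailed-balance
construction can reach every state; instead the generator picks a uniform
jump proposal over allowed neighbours, computes its stationary jump
distribution nu, and sets each state's per-epoch exit rate to
r_i = q * nu_i / pi_i, where q is the per-epoch shift probability implied
by the target shift rate and pi the target occupancy.  The resulting chain
has stationary distribution exactly pi and expected shift rate exactly the
target (verified internally by power iteration).

Posture-conditioned images and heartbeat traces use invented geometric
templates and per-posture bpm means; they are generator parameters, not
cohort values, and are recorded as such in every dataset manifest.

All randomness flows from a single seed through numpy SeedSequence
spawn keys, so each module's stream is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

from .errors import InfeasibleCalibrationError
from .predictor import (
    Posture,
    PostureSequence,
    default_allowed_mask,
    posture_order,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "build_calibrated_matrix",
    "simulate_sequence",
    "render_posture_image",
    "simulate_heartbeat",
    "heartbeat_likelihood",
    "make_dataset",
]

# stream ids for counter-based seed splitting
_STREAM_SEQUENCE = 0
_STREAM_IMAGE = 1
_STREAM_HEARTBEAT = 2


def _default_occupancy() -> dict[Posture, float]:
    return {
        Posture.SUPINE: 0.073,
        Posture.PRONE: 0.375,
        Posture.LLR: 0.2705,      # 54.1% lateral total, split equally
        Posture.RLR: 0.2705,
        Posture.OFFBED: 0.011,    # residual of the 98.9% on-bed total
    }


def _default_hbr_means() -> dict[Posture, float]:
    # invented generator parameters (bpm), not cohort values
    return {
        Posture.SUPINE: 60.0,
        Posture.PRONE: 63.0,
        Posture.LLR: 66.0,
        Posture.RLR: 69.0,
        Posture.OFFBED: 75.0,
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Occupancy targets and the shift rate default to the cohort figures;
    image templates and heartbeat means are invented generator parameters.
    """

    occupancy_targets: dict[Posture, float] = field(default_factory=_default_occupancy)
    shift_rate_per_hour: float = 1.6
    epoch_seconds: float = 30.0
    image_size: int = 64
    image_noise_sd: float = 0.05
    hbr_means: dict[Posture, float] = field(default_factory=_default_hbr_means)
    hbr_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.occupancy_targets = {Posture(k): float(v)
                                  for k, v in self.occupancy_targets.items()}
        total = sum(self.occupancy_targets.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy targets sum to {total}, expected 1")
        if self.shift_rate_per_hour <= 0:
            raise ValueError("shift_rate_per_hour must be positive")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if self.image_noise_sd < 0:
            raise ValueError("image_noise_sd must be non-negative")

    @property
    def labels(self) -> tuple[Posture, ...]:
        return posture_order(include_offbed=Posture.OFFBED in self.occupancy_targets)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["occupancy_targets"] = {k.value: v for k, v in self.occupancy_targets.items()}
        d["hbr_means"] = {k.value: v for k, v in self.hbr_means.items()}
        d["note"] = ("image templates and hbr_means are invented generator "
                     "parameters, not cohort values")
        return d


def _rng(seed: int, stream: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(stream, *map(int, key)))
    )


def build_calibrated_matrix(cfg: GeneratorConfig, mask: np.ndarray | None = None) -> np.ndarray:
    """Constrained transition matrix with the target stationary distribution.

    Rows/columns follow ``cfg.labels`` (canonical posture order).  Forbidden
    entries are exactly 0, rows sum to 1, the stationary distribution equals
    the occupancy targets, and the expected shift rate equals
    ``cfg.shift_rate_per_hour``.
    """
    labels = cfg.labels
    n = len(labels)
    pi = np.array([cfg.occupancy_targets[l] for l in labels])
    if mask is None:
        mask = default_allowed_mask(include_offbed=Posture.OFFBED in labels)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n, n):
        raise ValueError(f"mask shape {mask.shape} does not match {n} states")
    if np.any(pi <= 0):
        raise InfeasibleCalibrationError("all target occupancies must be positive")

    adj = mask.copy()
    np.fill_diagonal(adj, False)
    n_comp, _ = connected_components(adj.astype(int), directed=True, connection="strong")
    if n_comp != 1:
        raise InfeasibleCalibrationError(
            "the allowed-transition graph is not strongly connected; some "
            "positive-mass state is unreachable"
        )

    # uniform jump proposal over allowed neighbours
    J = adj.astype(float)
    J /= J.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(J.T)
    nu = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    nu = np.abs(nu) / np.abs(nu).sum()

    epochs_per_hour = 3600.0 / cfg.epoch_seconds
    q = cfg.shift_rate_per_hour / epochs_per_hour     # per-epoch shift probability
    r = q * nu / pi                                   # per-state exit rates
    if np.any(r > 1.0):
        raise InfeasibleCalibrationError(
            f"shift rate {cfg.shift_rate_per_hour}/h is too high for the "
            f"occupancy targets (max exit rate {r.max():.3f} > 1)"
        )
    P = J * r[:, None]
    np.fill_diagonal(P, 1.0 - r)

    residual = np.abs(pi @ P - pi).max()
    if residual > 1e-9:
        raise RuntimeError("internal calibration check failed: stationarity "
                           f"residual {residual:.2e}")
    return P


def simulate_sequence(
    matrix: np.ndarray,
    n_epochs: int,
    seed: int,
    initial: Posture = Posture.SUPINE,
    labels: tuple[Posture, ...] | None = None,
    epoch_seconds: float = 30.0,
) -> PostureSequence:
    """Sample a posture sequence from a transition matrix (Markov order 1).

    The initial state defaults to supine ("the initial position is on the
    bed").  Identical seeds give identical sequences.
    """
    P = np.asarray(matrix, dtype=float)
    if n_epochs < 1:
        raise ValueError("n_epochs must be at least 1")
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("transition matrix rows must be distributions")
    if labels is None:
        labels = posture_order(include_offbed=P.shape[0] == 5)
    if len(labels) != P.shape[0]:
        raise ValueError("labels do not match matrix size")

    idx = {l: i for i, l in enumerate(labels)}
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    rng = _rng(seed, _STREAM_SEQUENCE)
    u = rng.random(n_epochs - 1)
    states = np.empty(n_epochs, dtype=np.int64)
    s = idx[Posture(initial)]
    states[0] = s
    rows = [cum[i] for i in range(len(labels))]
    for t in range(1, n_epochs):
        s = int(np.searchsorted(rows[s], u[t - 1], side="right"))
        states[t] = s
    return PostureSequence(labels=[labels[i] for i in states],
                           epoch_seconds=epoch_seconds)


def _lobe(size: int, cy: float, cx: float, sy: float, sx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    return np.exp(-(((yy - cy) ** 2) / (2 * sy**2) + ((xx - cx) ** 2) / (2 * sx**2)))


def posture_template(label: Posture, size: int = 64) -> np.ndarray:
    """Noise-free geometric intensity template for one posture.

    Supine: two symmetric vertically elongated lobes (bright cores).
    Prone: the same two lobe footprints with a radially inverted intensity
    profile (bright rims, dark cores).  LLR: a single off-centre lobe left
    of the image midline; RLR is its exact horizontal mirror.  OFFBED is an
    empty bed (all zeros).  Templates are invented generator parameters.
    """
    label = Posture(label)
    c = (size - 1) / 2.0
    if label == Posture.OFFBED:
        return np.zeros((size, size))
    if label == Posture.RLR:
        return posture_template(Posture.LLR, size)[:, ::-1].copy()
    if label == Posture.LLR:
        img = 0.9 * _lobe(size, c, 0.32 * size, 0.26 * size, 0.11 * size)
    elif label == Posture.SUPINE:
        img = 0.9 * (_lobe(size, c, 0.34 * size, 0.22 * size, 0.08 * size)
                     + _lobe(size, c, 0.66 * size, 0.22 * size, 0.08 * size))
    else:  # PRONE: inverted radial profile on the supine footprint
        g = (_lobe(size, c, 0.34 * size, 0.22 * size, 0.08 * size)
             + _lobe(size, c, 0.66 * size, 0.22 * size, 0.08 * size))
        img = np.where(g > 0.05, 0.9 * (1.0 - g), 0.0)
    return np.clip(img, 0.0, 1.0)


def render_posture_image(label: Posture, cfg: GeneratorConfig | None = None,
                         seed: int = 0) -> np.ndarray:
    """Posture template plus additive Gaussian noise, clipped to [0, 1].

    Deterministic for a fixed (config seed, label, seed) triple.
    """
    cfg = cfg or GeneratorConfig()
    label = Posture(label)
    img = posture_template(label, cfg.image_size)
    if cfg.image_noise_sd > 0:
        lab_idx = list(Posture).index(label)
        rng = _rng(cfg.seed, _STREAM_IMAGE, lab_idx, seed)
        img = img + rng.normal(0.0, cfg.image_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def simulate_heartbeat(label: Posture, n_samples: int,
                       cfg: GeneratorConfig | None = None, seed: int = 0) -> np.ndarray:
    """Per-epoch bpm samples ~ Normal(mean[label], sd^2), truncated to [30, 200]."""
    cfg = cfg or GeneratorConfig()
    label = Posture(label)
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    lab_idx = list(Posture).index(label)
    rng = _rng(cfg.seed, _STREAM_HEARTBEAT, lab_idx, seed)
    bpm = rng.normal(cfg.hbr_means[label], cfg.hbr_sd, size=n_samples)
    return np.clip(bpm, 30.0, 200.0)


def heartbeat_likelihood(observed_bpm: float, cfg: GeneratorConfig | None = None
                         ) -> dict[Posture, float]:
    """Gaussian observation likelihood of a bpm reading under each posture."""
    cfg = cfg or GeneratorConfig()
    sd = cfg.hbr_sd if cfg.hbr_sd > 0 else 1e-6
    return {
        l: float(np.exp(-0.5 * ((observed_bpm - m) / sd) ** 2) / (sd * np.sqrt(2 * np.pi)))
        for l, m in cfg.hbr_means.items()
    }


@dataclass
class SyntheticDataset:
    """One simulated night: sequence, per-epoch images and heartbeat windows."""

    sequence: PostureSequence
    images: list[np.ndarray]
    heartbeats: np.ndarray            # (n_epochs, samples_per_epoch) bpm
    config: GeneratorConfig
    seed: int

    @property
    def truth(self) -> list[Posture]:
        return list(self.sequence.labels)


def make_dataset(cfg: GeneratorConfig, n_epochs: int, seed: int,
                 out_dir: str | Path | None = None,
                 samples_per_epoch: int = 30) -> SyntheticDataset:
    """Generate an end-to-end dataset; optionally write it to disk.

    When ``out_dir`` is given, writes ``sequence.csv``,
    ``images/epoch_%06d.png`` (16-bit grayscale), ``heartbeat.csv`` and a
    ``manifest.json`` recording the resolved config and seed.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be at least 1")
    matrix = build_calibrated_matrix(cfg)
    seq = simulate_sequence(matrix, n_epochs, seed=seed,
                            epoch_seconds=cfg.epoch_seconds)
    images = [render_posture_image(l, cfg, seed=t)
              for t, l in enumerate(seq.labels)]
    heartbeats = np.stack([
        simulate_heartbeat(l, samples_per_epoch, cfg, seed=t)
        for t, l in enumerate(seq.labels)
    ])
    ds = SyntheticDataset(sequence=seq, images=images, heartbeats=heartbeats,
                          config=cfg, seed=int(seed))
    if out_dir is not None:
        from . import io as ppbn_io
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        ppbn_io.write_sequence_csv(out / "sequence.csv", seq)
        for t, img in enumerate(images):
            ppbn_io.write_image(out / "images" / f"epoch_{t:06d}.png", img)
        # one continuous single-site trace spanning the whole night
        ppbn_io.write_heartbeat_csv(out / "heartbeat.csv",
                                    heartbeats.reshape(1, -1),
                                    epoch_seconds=cfg.epoch_seconds * n_epochs,
                                    sites=["pulse"])
        manifest = {"config": cfg.to_jsonable(), "seed": int(seed),
                    "n_epochs": int(n_epochs),
                    "samples_per_epoch": int(samples_per_epoch)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ds
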