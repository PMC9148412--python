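"""HOG descriptors and pressure-weight normalisation.

The frame-level descriptor of a preprocessed pulse image combines a
histogram-of-oriented-gradients (HOG) vector with per-cell pressure
weights.  Gradients are taken by central differences; unsigned orientation
is binned over [0, 180) degrees; blocks of cells slide with stride one
cell and are L2-normalised with a small epsilon guard, so a constant image
yields an all-zero descriptor.

Pressure weights divide each cell's total intensity by the grand total;
the scale factor Sf = sqrt(w_n / w_1) relates the last and first weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ScaleUndefinedError
from .imaging import as_pulse_image

__all__ = [
    "HogConfig",
    "FeatureVector",
    "compute_hog",
    "pressure_weight_normalize",
    "extract_features",
]


@dataclass(frozen=True)
class HogConfig:
    """HOG geometry: 8x8-pixel cells, 2x2-cell blocks, 9 unsigned bins."""

    cell_size: int = 8
    block_cells: int = 2
    n_bins: int = 9


def _cell_histograms(img: np.ndarray, cell_size: int, n_bins: int) -> np.ndarray:
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    bins = np.minimum((ang / (180.0 / n_bins)).astype(int), n_bins - 1)
    n_cy, n_cx = img.shape[0] // cell_size, img.shape[1] // cell_size
    hist = np.zeros((n_cy, n_cx, n_bins))
    rows, cols = np.indices(img.shape)
    cy, cx = rows // cell_size, cols // cell_size
    inside = (cy < n_cy) & (cx < n_cx)
    np.add.at(hist, (cy[inside], cx[inside], bins[inside]), mag[inside])
    return hist


def compute_hog(
    img,
    cell_size: int = 8,
    block_cells: int = 2,
    n_bins: int = 9,
) -> np.ndarray:
    """Flat HOG descriptor with stride-1 block L2 normalisation.

    Output length is n_blocks_y * n_blocks_x * block_cells^2 * n_bins, e.g.
    7 * 7 * 4 * 9 = 1764 for a 64x64 image with the default geometry.
    """
    img = as_pulse_image(img)
    if cell_size < 1 or block_cells < 1 or n_bins < 1:
        raise ValueError("cell_size, block_cells and n_bins must be positive")
    n_cy, n_cx = img.shape[0] // cell_size, img.shape[1] // cell_size
    if n_cy < block_cells or n_cx < block_cells:
        raise ValueError(
            f"image {img.shape} smaller than one {block_cells}x{block_cells}-cell "
            f"block of {cell_size}x{cell_size}-pixel cells"
        )
    hist = _cell_histograms(img, cell_size, n_bins)
    eps = 1e-6
    blocks = []
    for by in range(n_cy - block_cells + 1):
        for bx in range(n_cx - block_cells + 1):
            v = hist[by:by + block_cells, bx:bx + block_cells].ravel()
            blocks.append(v / np.sqrt(v @ v + eps**2))
    return np.concatenate(blocks)


def pressure_weight_normalize(pressure_points) -> tuple[np.ndarray, float]:
    """Normalise pressure points to weights summing to 1, with scale factor.

    weight_i = p_i / sum(p); Sf = sqrt(w_n / w_1) for the first and last
    weights.  All-zero input is degenerate; a zero *first* weight leaves
    the scale factor undefined.
    """
    p = np.asarray(pressure_points, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pressure points must be a non-empty 1-D list")
    if np.any(p < 0):
        raise ValueError("pressure points must be non-negative")
    total = p.sum()
    if total == 0:
        raise DegenerateInputError("all pressure points are zero")
    weights = p / total
    if weights[0] == 0:
        raise ScaleUndefinedError("first weight is zero; scale factor undefined")
    return weights, float(np.sqrt(weights[-1] / weights[0]))


@dataclass
class FeatureVector:
    """HOG descriptor plus pressure-weight terms for one frame."""

    hog: np.ndarray
    weights: np.ndarray
    scale_factor: float = 1.0
    config: HogConfig = field(default_factory=HogConfig)


def extract_features(img, config: HogConfig | None = None) -> FeatureVector:
    """Full frame descriptor: HOG plus per-cell pressure weights.

    Pressure points are the per-cell intensity sums, flattened row-major.
    A blank image falls back to uniform weights with a warning (so batch
    pipelines survive empty frames); a zero first cell merely leaves the
    scale factor at 0, since background-zero corners are common.
    """
    img = as_pulse_image(img)
    cfg = config or HogConfig()
    hog = compute_hog(img, cfg.cell_size, cfg.block_cells, cfg.n_bins)
    n_cy, n_cx = img.shape[0] // cfg.cell_size, img.shape[1] // cfg.cell_size
    cells = img[: n_cy * cfg.cell_size, : n_cx * cfg.cell_size]
    cells = cells.reshape(n_cy, cfg.cell_size, n_cx, cfg.cell_size)
    pressure = cells.sum(axis=(1, 3)).ravel()
    try:
        weights, scale = pressure_weight_normalize(pressure)
    except DegenerateInputError:
        warnings.warn("blank image: falling back to uniform pressure weights",
                      stacklevel=2)
        weights = np.full(pressure.size, 1.0 / pressure.size)
        scale = 1.0
    except ScaleUndefinedError:
        weights = pressure / pressure.sum()
        scale = 0.0
    return FeatureVector(hog=hog, weights=weights, scale_factor=scale, config=cfg)
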