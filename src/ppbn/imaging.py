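"""Pulse-point image preprocessing.

Operators act on 2-D non-negative intensity maps ("pulse images", default
64 x 64) coming from a pressure/pulse sensor array.  The preprocessing
chain is: min-max standardisation with area-average resampling, threshold
filtering against the mean intensity of occupied points, 5 x 5 Gaussian
smoothing, and an optional rotation-PCA alignment that makes the principal
axis of the body's pressure footprint vertical.

Conventions: images are row-major float arrays with 0-based indices;
rotation angles are counter-clockwise positive (with the y axis pointing
up) and reported in (-90, 90].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateImageError

__all__ = [
    "DEFAULT_INTENSITY_THRESHOLD",
    "GaussianKernel",
    "AlignmentResult",
    "as_pulse_image",
    "standardize_image",
    "compute_pulse_threshold",
    "apply_threshold_filter",
    "make_gaussian_kernel",
    "apply_gaussian_filter",
    "rotation_pca_align",
]

#: Default foreground threshold for alignment, on [0, 1]-standardised images.
DEFAULT_INTENSITY_THRESHOLD = 0.5725


def as_pulse_image(raw) -> np.ndarray:
    """Validate and coerce an array-like into a pulse image (float64 copy)."""
    img = np.array(raw, dtype=float)
    if img.size == 0:
        raise ValueError("pulse image must be non-empty")
    if img.ndim != 2:
        raise ValueError(f"pulse image must be 2-D, got {img.ndim}-D")
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"pulse image must be at least 2x2, got {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("pulse image contains non-finite values")
    if np.any(img < 0):
        raise ValueError("pulse image intensities must be non-negative")
    return img


def _resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Exact area-overlap weights mapping n_in samples onto n_out samples."""
    W = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for o in range(n_out):
        lo, hi = o * scale, (o + 1) * scale
        for i in range(int(np.floor(lo)), min(int(np.ceil(hi)), n_in)):
            W[o, i] = min(hi, i + 1) - max(lo, i)
    return W / scale


def standardize_image(raw, target_height: int = 32, target_width: int = 32) -> np.ndarray:
    """Min-max scale to [0, 1], then resample by exact area averaging.

    A constant input maps to an all-zero output (max = min convention).
    Area averaging is exact for any integer or fractional resize ratio, so
    down-sampling a 4x4 checkerboard to 2x2 gives a uniform 0.5 image.
    """
    img = as_pulse_image(raw)
    if target_height < 2 or target_width < 2:
        raise ValueError("target dimensions must be at least 2")
    lo, hi = img.min(), img.max()
    img = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    if img.shape != (target_height, target_width):
        Wr = _resample_matrix(img.shape[0], target_height)
        Wc = _resample_matrix(img.shape[1], target_width)
        img = Wr @ img @ Wc.T
        img = np.clip(img, 0.0, 1.0)
    return img


def compute_pulse_threshold(img) -> float:
    """Mean intensity of occupied (nonzero) pulse points.

    threshold = (sum of all intensities) / (number of nonzero pixels).
    Void (zero-valued) points contribute nothing to either term, so this is
    the average strength of the occupied part of the map.
    """
    img = as_pulse_image(img)
    n_occupied = int(np.count_nonzero(img))
    if n_occupied == 0:
        raise DegenerateImageError("threshold undefined for an all-void image")
    return float(img.sum() / n_occupied)


def apply_threshold_filter(img, threshold: float, mode: str = "keep_low") -> np.ndarray:
    """Zero out pixels on one side of a threshold.

    ``keep_low`` keeps values <= threshold (the literal filtering rule);
    ``keep_high`` reverses the inequality, keeping values > threshold, which
    is the usual denoising direction.  Both modes are idempotent.
    """
    img = as_pulse_image(img)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if mode == "keep_low":
        keep = img <= threshold
    elif mode == "keep_high":
        keep = img > threshold
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'keep_low' or 'keep_high'")
    return np.where(keep, img, 0.0)


@dataclass(frozen=True)
class GaussianKernel:
    """Discrete 2-D Gaussian weights, renormalised to sum to 1."""

    weights: np.ndarray
    size: int
    sigma: float


def make_gaussian_kernel(size: int = 5, sigma: float = 1.0) -> GaussianKernel:
    """Sampled isotropic Gaussian on the integer grid centred at 0.

    The continuous normaliser 1/(2*pi*sigma^2) does not sum to 1 on a
    truncated grid, so the sampled weights are renormalised discretely.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError("kernel size must be odd and >= 3")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(x, x)
    w = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return GaussianKernel(weights=w / w.sum(), size=size, sigma=float(sigma))


def apply_gaussian_filter(img, kernel: GaussianKernel | None = None) -> np.ndarray:
    """2-D convolution with reflect border handling; constants are fixed points."""
    img = as_pulse_image(img)
    if kernel is None:
        kernel = make_gaussian_kernel()
    if kernel.size > img.shape[0] or kernel.size > img.shape[1]:
        raise ValueError(
            f"kernel of size {kernel.size} larger than image {img.shape}"
        )
    return ndimage.convolve(img, kernel.weights, mode="reflect")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of rotation-PCA alignment."""

    rotated: np.ndarray
    angle: float                       # degrees CCW in (-90, 90]
    principal_axis: np.ndarray = field(default=None)  # unit (x, y), y >= 0
    degenerate: bool = False


def rotation_pca_align(img, intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD) -> AlignmentResult:
    """Align the principal axis of the bright pixel cloud to vertical.

    Pixels above ``intensity_threshold`` form an intensity-weighted point
    cloud; the leading eigenvector of its coordinate covariance gives the
    body axis.  The image is rotated (bilinear, zeros outside support) so
    that axis becomes vertical.  The eigenvector's sign ambiguity is fixed
    by forcing a non-negative vertical component.  An isotropic cloud
    (relative eigenvalue gap < 1e-9) returns angle 0 with ``degenerate``
    set — there is no preferred axis to align.
    """
    img = as_pulse_image(img)
    rows, cols = np.nonzero(img > intensity_threshold)
    if rows.size < 3:
        raise DegenerateImageError(
            f"need at least 3 pixels above {intensity_threshold}, found {rows.size}"
        )
    w = img[rows, cols]
    # math coordinates: x = column, y = -row (y axis pointing up)
    x = cols.astype(float)
    y = -rows.astype(float)
    wsum = w.sum()
    mx, my = (w * x).sum() / wsum, (w * y).sum() / wsum
    X = np.stack([x - mx, y - my])
    cov = (X * w) @ X.T / wsum
    evals, evecs = np.linalg.eigh(cov)       # ascending
    gap = evals[1] - evals[0]
    if gap < 1e-9 * max(evals[1], 1e-300):
        return AlignmentResult(rotated=img.copy(), angle=0.0,
                               principal_axis=np.array([0.0, 1.0]),
                               degenerate=True)
    v = evecs[:, 1]
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    angle = -float(np.degrees(np.arctan2(v[0], v[1])))
    if angle <= -90.0:
        angle += 180.0
    rotated = ndimage.rotate(img, -angle, reshape=False, order=1,
                             mode="constant", cval=0.0)
    rotated = np.clip(rotated, 0.0, None)
    return AlignmentResult(rotated=rotated, angle=angle, principal_axis=v)
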