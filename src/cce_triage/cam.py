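"""Class activation mapping (CAM) heatmaps.

CAM localizes the image evidence behind a classification score as the
channel-weighted sum of the final convolutional feature maps:

    raw(x, y) = sum_c  w[c] * F[c](x, y)

where F is the C x H x W feature stack and w the classifier weights for
the target class. The raw map is min-max normalized per frame to [0, 1],
bilinearly upsampled to image resolution (corner-aligned: output corner
pixels coincide with input corner pixels), and alpha-blended over the RGB
frame with a pseudocolor colormap.

The network that produces the features is out of scope; the module takes
feature stacks and weights as plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .models import ValidationError


@dataclass(frozen=True)
class Heatmap:
    """A CAM heatmap: the raw weighted sum and its [0, 1] normalization."""

    raw: np.ndarray
    grid: Optional[np.ndarray] = None  # normalized; None until normalize()


def compute_cam(features: np.ndarray, weights: np.ndarray) -> Heatmap:
    """Weighted sum of feature channels: the standard CAM map, unnormalized.

    ``features`` is C x H x W; ``weights`` has length C.
    """
    features = np.asarray(features, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if features.ndim != 3:
        raise ValidationError(f"features must be C x H x W, got shape {features.shape}")
    if weights.shape != (features.shape[0],):
        raise ValidationError(
            f"weights length {weights.shape} does not match "
            f"channel count {features.shape[0]}"
        )
    raw = np.tensordot(weights, features, axes=(0, 0))
    return Heatmap(raw=raw)


def normalize_heatmap(heatmap: Heatmap | np.ndarray) -> Heatmap:
    """Shift-scale the raw map to [0, 1] via (raw - min) / (max - min).

    A constant raw map (including all-zero, as produced when no unit is
    activated) normalizes to all zeros rather than dividing by zero, so
    "no activation" renders as no overlay.
    """
    raw = heatmap.raw if isinstance(heatmap, Heatmap) else np.asarray(heatmap, float)
    if not np.all(np.isfinite(raw)):
        raise ValidationError("raw heatmap contains non-finite values")
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo == 0.0:
        grid = np.zeros_like(raw)
    else:
        grid = (raw - lo) / (hi - lo)
    return Heatmap(raw=raw, grid=grid)


def upsample_heatmap(values: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling with corner alignment.

    The output grid is ``linspace(0, H-1, H')`` x ``linspace(0, W-1, W')``
    in source pixel coordinates, so the four corner values are preserved
    exactly and all outputs stay within [source min, source max]. The
    target must be at least as large as the source in both dimensions.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("heatmap to upsample must be 2-D")
    h, w = values.shape
    th, tw = shape
    if th < h or tw < w:
        raise ValidationError(
            f"target {shape} smaller than source {(h, w)}; refusing to downsample"
        )
    if (th, tw) == (h, w):
        return values.copy()
    # degenerate 1-pixel axes broadcast as constants
    ys = np.linspace(0, h - 1, th) if h > 1 else np.zeros(th)
    xs = np.linspace(0, w - 1, tw) if w > 1 else np.zeros(tw)
    interp = RegularGridInterpolator(
        (np.arange(h), np.arange(w)), values, method="linear"
    )
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(th, tw)


def apply_colormap(grid: np.ndarray, colormap: str = "viridis") -> np.ndarray:
    """Map a [0, 1] heatmap to uint8 RGB via a matplotlib colormap."""
    import matplotlib

    cmap = matplotlib.colormaps[colormap]
    rgba = cmap(np.clip(grid, 0.0, 1.0))
    return (rgba[..., :3] * 255).round().astype(np.uint8)


def overlay(
    image: np.ndarray,
    grid: np.ndarray,
    alpha: float = 0.4,
    colormap: str = "viridis",
) -> np.ndarray:
    """Alpha-blend a pseudocolored heatmap over an RGB frame.

    ``alpha = 0`` returns the original image bit-exactly; ``alpha = 1``
    returns the pure colormapped heatmap.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("image must be H x W x 3 (RGB)")
    if grid.shape != image.shape[:2]:
        raise ValidationError(
            f"heatmap shape {grid.shape} does not match image {image.shape[:2]}; "
            "upsample first"
        )
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        return image.copy()
    colored = apply_colormap(grid, colormap)
    blended = (1.0 - alpha) * image.astype(float) + alpha * colored.astype(float)
    return np.rint(blended).astype(np.uint8)


def save_overlay(path: str | Path, image: np.ndarray) -> None:
    """Write an RGB uint8 array as PNG/JPEG (by file extension)."""
    from PIL import Image

    Image.fromarray(image).save(path)
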