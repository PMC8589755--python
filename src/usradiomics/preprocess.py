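"""Grayscale conversion, intensity normalization and gray-level discretization.

B-mode ultrasound captures are usually stored as RGB even though the content
is monochrome; the first step collapses them with the ITU-R 601-2 luma
weights.  Whole-image z-normalization then makes images from different
scanners comparable (scale 100, shift 300, so the +/-3 sigma band spans
0-600 gray units), and ROI gray levels are discretized with a fixed bin
width (3 gray units by default) anchored at the ROI minimum.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DiscretizedROI, GrayImage

#: ITU-R 601-2 luma weights for R, G, B.
LUMA_WEIGHTS = (299 / 1000, 587 / 1000, 114 / 1000)

DEFAULT_BIN_WIDTH = 3.0
NORMALIZE_SCALE = 100.0
NORMALIZE_SHIFT = 300.0


def rgb_to_gray(image: np.ndarray) -> GrayImage:
    """Collapse an RGB image to luminance; grayscale input passes through.

    L = R*299/1000 + G*587/1000 + B*114/1000 per pixel.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return GrayImage(arr, provenance="original")
    if arr.ndim == 3 and arr.shape[2] == 1:
        return GrayImage(arr[:, :, 0], provenance="original")
    if arr.ndim == 3 and arr.shape[2] == 3:
        r, g, b = arr[:, :, 0], arr[:, :, 1], arr[:, :, 2]
        lum = r * LUMA_WEIGHTS[0] + g * LUMA_WEIGHTS[1] + b * LUMA_WEIGHTS[2]
        return GrayImage(lum, provenance="original")
    raise ValueError(
        f"expected a 2D grayscale or 3-channel image, got shape {arr.shape}"
    )


def normalize_intensities(
    image: GrayImage | np.ndarray,
    scale: float = NORMALIZE_SCALE,
    shift: float = NORMALIZE_SHIFT,
    lesion_id: str = "<unknown>",
) -> GrayImage:
    """Whole-image z-score normalization mapped onto a nominal 0-600 range.

    x -> ((x - mu) / sigma) * scale + shift, with mu and sigma computed over
    every pixel of the image.  With the defaults, pixels at mu +/- 3 sigma
    land at 600 and 0; values further out are kept as-is (the range is
    nominal, not clamped).
    """
    gray = image if isinstance(image, GrayImage) else GrayImage(np.asarray(image))
    mu = float(gray.pixels.mean())
    sigma = float(gray.pixels.std())
    if sigma == 0.0:
        raise ValueError(
            f"lesion {lesion_id}: constant image (sigma = 0) cannot be normalized"
        )
    out = (gray.pixels - mu) / sigma * scale + shift
    return GrayImage(out, provenance=gray.provenance)


def discretize_roi(
    image: GrayImage | np.ndarray,
    mask: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DiscretizedROI:
    """Discretize ROI intensities into fixed-width bins anchored at the minimum.

    level(x) = floor((x - min_ROI) / bin_width) + 1, so level 1 is always
    occupied and ``n_levels`` adapts to the ROI dynamic range.  Bins are
    half-open [min + (k-1)w, min + kw); the ROI maximum falls in the last bin.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    mask = np.asarray(mask, dtype=bool)
    if pixels.shape != mask.shape:
        raise ValueError("image and mask dimensions disagree")
    if not mask.any():
        raise ValueError("cannot discretize an empty mask")
    roi = pixels[mask]
    levels = np.zeros(pixels.shape, dtype=np.int64)
    levels[mask] = np.floor((roi - roi.min()) / bin_width).astype(np.int64) + 1
    n_levels = int(levels.max())
    return DiscretizedROI(levels=levels, mask=mask, n_levels=n_levels, bin_width=bin_width)
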