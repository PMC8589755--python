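"""The filtered-image bank: Laplacian-of-Gaussian scales and wavelet subbands.

Texture features are extracted not only from the original (normalized) image
but also from band-pass versions of it: LoG responses at sigma = 1..5 pixels
(finer to coarser structure) and the four subbands of a one-level separable
2D wavelet transform.  The wavelet transform is stationary (undecimated) so
every subband keeps the original resolution and the untouched lesion mask
applies directly.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .datatypes import GrayImage

DEFAULT_LOG_SIGMAS = (1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_WAVELET = "coif1"

#: Subband tags: first letter = filter along axis 0 (rows), second = axis 1.
WAVELET_SUBBANDS = ("LL", "LH", "HL", "HH")

#: Single-letter subband names seen in some feature exports, mapped onto the
#: canonical two-letter tags used here.
WAVELET_ALIASES = {"H": "HH", "L": "LL"}


def _log_kernels(sigma: float, truncate: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """1D Gaussian smoothing and second-derivative kernels for a separable LoG.

    The truncated kernels are corrected so that the smoothing kernel sums to
    exactly 1 and the derivative kernel to exactly 0; the LoG response to
    constant and linear images is then zero to machine precision, as the
    continuous operator demands.
    """
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=float)
    gauss = np.exp(-(x**2) / (2 * sigma**2))
    norm = gauss.sum()
    smooth = gauss / norm
    second = (x**2 / sigma**4 - 1.0 / sigma**2) * gauss / norm
    second -= second.mean()  # exact zero-sum despite truncation
    return smooth, second


def log_filter(image: GrayImage | np.ndarray, sigma: float) -> GrayImage:
    """Laplacian-of-Gaussian response at scale ``sigma`` (reflect boundary).

    Separable implementation (Gxx*G + G*Gyy) with sum-corrected kernels;
    a bright blob of matching scale gives a negative response at its center.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    smooth, second = _log_kernels(sigma)
    d_rows = ndimage.correlate1d(
        ndimage.correlate1d(pixels, second, axis=0, mode="reflect"),
        smooth, axis=1, mode="reflect",
    )
    d_cols = ndimage.correlate1d(
        ndimage.correlate1d(pixels, smooth, axis=0, mode="reflect"),
        second, axis=1, mode="reflect",
    )
    return GrayImage(d_rows + d_cols, provenance=f"log-sigma-{sigma:g}")


def wavelet_decompose(
    image: GrayImage | np.ndarray, wavelet: str = DEFAULT_WAVELET
) -> dict[str, GrayImage]:
    """One-level stationary 2D wavelet transform -> {LL, LH, HL, HH}.

    The transform is normalized (energy-preserving for an orthogonal basis)
    and undecimated, so all four subbands have the input's shape.  Odd image
    dimensions are handled by reflective padding to even size, then cropping.
    """
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    w = pywt.Wavelet(wavelet)
    if min(pixels.shape) < w.dec_len:
        raise ValueError(
            f"image {pixels.shape} smaller than the {wavelet} filter support "
            f"({w.dec_len})"
        )
    pad_r = pixels.shape[0] % 2
    pad_c = pixels.shape[1] % 2
    padded = np.pad(pixels, ((0, pad_r), (0, pad_c)), mode="reflect")
    c_a, (c_h, c_v, c_d) = pywt.swt2(padded, wavelet, level=1, trim_approx=True, norm=True)
    rows, cols = pixels.shape
    # cH varies along axis 0 (high-pass on rows), cV along axis 1.
    subbands = {"LL": c_a, "HL": c_h, "LH": c_v, "HH": c_d}
    return {
        tag: GrayImage(sub[:rows, :cols], provenance=f"wavelet-{tag}")
        for tag, sub in subbands.items()
    }


def wavelet_reconstruct(
    subbands: dict[str, GrayImage | np.ndarray], wavelet: str = DEFAULT_WAVELET
) -> np.ndarray:
    """Inverse of :func:`wavelet_decompose` (even-sized inputs round-trip exactly)."""

    def _arr(tag: str) -> np.ndarray:
        sub = subbands[tag]
        return sub.pixels if isinstance(sub, GrayImage) else np.asarray(sub, float)

    coeffs = [(_arr("LL"), (_arr("HL"), _arr("LH"), _arr("HH")))]
    return pywt.iswt2(coeffs, wavelet, norm=True)


def filter_bank(
    image: GrayImage | np.ndarray,
    log_sigmas: tuple[float, ...] = DEFAULT_LOG_SIGMAS,
    wavelet: str | None = DEFAULT_WAVELET,
) -> list[GrayImage]:
    """Original image plus every configured filtered version, in manifest order."""
    gray = image if isinstance(image, GrayImage) else GrayImage(np.asarray(image))
    bank = [GrayImage(gray.pixels, provenance="original")]
    for sigma in log_sigmas:
        bank.append(log_filter(gray, sigma))
    if wavelet is not None:
        decomposed = wavelet_decompose(gray, wavelet)
        bank.extend(decomposed[tag] for tag in WAVELET_SUBBANDS)
    return bank
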