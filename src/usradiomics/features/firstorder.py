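"""First-order (histogram) statistics of the ROI intensities.

Eighteen statistics of the raw intensities inside the mask; Entropy and
Uniformity are computed on the fixed-bin-width discretized levels so that
they share the binning of the texture families.  Moments use the population
(n-denominator) convention and Kurtosis is not excess-corrected; for a
zero-variance ROI, Skewness and Kurtosis are defined as 0.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import DiscretizedROI

FIRSTORDER_FEATURES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)


def firstorder_features(
    image: np.ndarray, roi: DiscretizedROI, pixel_area: float = 1.0
) -> dict[str, float]:
    """18 first-order statistics of ``image`` values inside ``roi.mask``."""
    pixels = np.asarray(image, dtype=float)
    x = pixels[roi.mask]
    if x.size == 0:
        raise ValueError("empty mask")
    mean = float(x.mean())
    var = float(x.var())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        centered = x - mean
        skew = float((centered**3).mean() / var**1.5)
        kurt = float((centered**4).mean() / var**2)
    else:
        skew = 0.0
        kurt = 0.0
    levels = roi.roi_levels
    hist = np.bincount(levels, minlength=roi.n_levels + 1)[1:]
    p = hist / hist.sum()
    pos = p[p > 0]
    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * pixel_area,
        "Entropy": float(-(pos * np.log2(pos)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
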