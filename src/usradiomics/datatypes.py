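"""Core data containers shared across the pipeline.

The package passes images around as plain numpy arrays wrapped in small
dataclasses that carry provenance: which lesion, which annotator, and which
stage of the filter bank produced the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BENIGN = "benign"
MALIGNANT = "malignant"
CLASS_LABELS = (BENIGN, MALIGNANT)

#: Positive class for every metric in the package (sensitivity, PPV, AUC ...).
POSITIVE_CLASS = MALIGNANT


@dataclass
class GrayImage:
    """A 2D real-valued image plus a tag saying which filter produced it.

    ``provenance`` is ``"original"``, ``"log-sigma-<s>"`` or
    ``"wavelet-<XX>"`` with ``XX`` one of LL/LH/HL/HH.
    """

    pixels: np.ndarray
    provenance: str = "original"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"GrayImage expects a 2D array, got {self.pixels.ndim}D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GrayImage contains non-finite values")


@dataclass
class DiscretizedROI:
    """Integer gray levels over the ROI; background pixels are level 0.

    Levels are 1-based (level 1 is always occupied because bins are anchored
    at the ROI minimum); ``n_levels`` is the largest level present.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float

    @property
    def roi_levels(self) -> np.ndarray:
        """Flat array of levels inside the mask."""
        return self.levels[self.mask]


@dataclass
class AnnotatedImage:
    """A lesion image, its binary segmentation and its identifiers."""

    pixels: np.ndarray
    mask: np.ndarray
    lesion_id: str
    class_label: str
    reader_id: str = "R1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2D grayscale or HxWx3 RGB")
        if self.pixels.shape[:2] != self.mask.shape:
            raise ValueError(
                f"lesion {self.lesion_id}: pixel grid {self.pixels.shape[:2]} "
                f"does not match mask grid {self.mask.shape}"
            )
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if not self.mask.any():
            raise ValueError(f"lesion {self.lesion_id}: mask is empty")
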