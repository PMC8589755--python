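"""Whole-lesion feature extraction across the original + filtered image bank.

For each lesion: the four shape features are computed once from the mask,
then the 18 first-order and 69 texture features (23 GLCM + 16 GLRLM +
16 GLSZM + 14 GLDM) are computed on the original normalized image and on
each filtered version (five LoG scales, four wavelet subbands).  With all
defaults that is 4 + 10 x 87 = 874 features per lesion.

Feature keys are ``<provenance>_<family>_<name>``, e.g.
``original_glcm_Autocorrelation`` or ``wavelet-HH_firstorder_Mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..datatypes import AnnotatedImage
from ..filters import DEFAULT_LOG_SIGMAS, DEFAULT_WAVELET, filter_bank
from ..preprocess import (
    DEFAULT_BIN_WIDTH,
    NORMALIZE_SCALE,
    NORMALIZE_SHIFT,
    discretize_roi,
    normalize_intensities,
    rgb_to_gray,
)
from .firstorder import FIRSTORDER_FEATURES, firstorder_features
from .shape import SHAPE_FEATURES, shape2d_features
from .texture import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
)

#: Metadata columns of a feature table; everything else is a feature key.
ID_COLUMNS = ("lesion_id", "reader_id", "class_label")

_FAMILIES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
}


@dataclass(frozen=True)
class ExtractionConfig:
    """Everything that determines the feature manifest and the values."""

    bin_width: float = DEFAULT_BIN_WIDTH
    normalize: bool = True
    normalize_scale: float = NORMALIZE_SCALE
    normalize_shift: float = NORMALIZE_SHIFT
    log_sigmas: tuple[float, ...] = DEFAULT_LOG_SIGMAS
    wavelet: str | None = DEFAULT_WAVELET
    gldm_alpha: int = 0
    families: tuple[str, ...] = ("firstorder", "glcm", "glrlm", "glszm", "gldm")
    include_shape: bool = True

    def provenances(self) -> list[str]:
        out = ["original"]
        out += [f"log-sigma-{s:g}" for s in self.log_sigmas]
        if self.wavelet is not None:
            out += [f"wavelet-{tag}" for tag in ("LL", "LH", "HL", "HH")]
        return out

    def manifest(self) -> list[str]:
        """Ordered feature keys implied by this configuration."""
        keys: list[str] = []
        if self.include_shape:
            keys += [f"original_shape2D_{name}" for name in SHAPE_FEATURES]
        for prov in self.provenances():
            for family in self.families:
                keys += [f"{prov}_{family}_{name}" for name in _FAMILIES[family]]
        return keys


class RadiomicsExtractor:
    """Transform-shaped extractor: ``AnnotatedImage`` -> feature rows.

    The extractor is stateless apart from its configuration; ``transform``
    on a list of lesions returns a :class:`pandas.DataFrame` whose columns
    are the metadata ids followed by the manifest keys.
    """

    def __init__(self, config: ExtractionConfig | None = None):
        self.config = config or ExtractionConfig()
        self.manifest_ = self.config.manifest()

    def extract(self, lesion: AnnotatedImage) -> dict[str, float]:
        """Feature vector (keyed per the manifest) for one annotated lesion."""
        cfg = self.config
        try:
            gray = rgb_to_gray(lesion.pixels)
            if cfg.normalize:
                gray = normalize_intensities(
                    gray,
                    scale=cfg.normalize_scale,
                    shift=cfg.normalize_shift,
                    lesion_id=lesion.lesion_id,
                )
            values: dict[str, float] = {}
            if cfg.include_shape:
                for name, val in shape2d_features(lesion.mask).items():
                    values[f"original_shape2D_{name}"] = val
            bank = filter_bank(gray, log_sigmas=cfg.log_sigmas, wavelet=cfg.wavelet)
            for img in bank:
                roi = discretize_roi(img.pixels, lesion.mask, cfg.bin_width)
                for family in cfg.families:
                    if family == "firstorder":
                        feats = firstorder_features(img.pixels, roi)
                    elif family == "glcm":
                        feats = glcm_features(roi)
                    elif family == "glrlm":
                        feats = glrlm_features(roi)
                    elif family == "glszm":
                        feats = glszm_features(roi)
                    elif family == "gldm":
                        feats = gldm_features(roi, alpha=cfg.gldm_alpha)
                    else:  # pragma: no cover - config is validated by _FAMILIES
                        raise ValueError(f"unknown feature family {family!r}")
                    for name, val in feats.items():
                        values[f"{img.provenance}_{family}_{name}"] = val
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for lesion {lesion.lesion_id} "
                f"(reader {lesion.reader_id}): {exc}"
            ) from exc
        return {key: values[key] for key in self.manifest_}

    def transform(self, lesions: list[AnnotatedImage]) -> pd.DataFrame:
        """Feature table with one row per (lesion, reader)."""
        rows = []
        for lesion in lesions:
            row: dict[str, object] = {
                "lesion_id": lesion.lesion_id,
                "reader_id": lesion.reader_id,
                "class_label": lesion.class_label,
            }
            row.update(self.extract(lesion))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(ID_COLUMNS) + self.manifest_)


def extract_all(lesion: AnnotatedImage, config: ExtractionConfig | None = None) -> dict[str, float]:
    """Convenience wrapper: one lesion -> feature dict."""
    return RadiomicsExtractor(config).extract(lesion)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature keys of a feature table (everything but the id columns)."""
    return [c for c in table.columns if c not in ID_COLUMNS and c != "split"]


def write_manifest(path, manifest: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(manifest) + "\n")
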