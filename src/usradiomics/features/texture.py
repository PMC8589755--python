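"""Texture feature formulas computed from the gray-level count matrices.

Feature names follow the naming used throughout the radiomics literature
(Autocorrelation, ClusterShade, RunLengthNonUniformity, ...).  GLCM and GLRLM
features are computed per angle on the angle's own (normalized) matrix and
then averaged over the four angles; GLSZM and GLDM are orientation-free.

Degenerate conventions (single-level ROI): correlation-type GLCM features
(Correlation, MCC) are defined as 1 — a one-level texture is perfectly
autocorrelated — and the information-measure features Imc1/Imc2 as 0; these
choices keep downstream selection free of NaNs.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import DiscretizedROI
from . import _matrices

_EPS = np.finfo(float).tiny  # guards log(0); 0*log(0) terms must vanish


def _xlog2x(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, p * np.log2(np.maximum(p, _EPS)), 0.0)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "Mcc",
    "SumEntropy",
    "SumSquares",
)


def _glcm_features_one_angle(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((p * ii).sum())
    sigma2 = float((p * (ii - mu) ** 2).sum())

    # difference distribution p_{x-y}(k), k = 0..Ng-1
    k_diff = np.abs(ii - jj)
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=ng)
    kd = np.arange(ng)
    diff_avg = float((p_diff * kd).sum())

    # sum distribution p_{x+y}(k), k = 2..2Ng
    k_sum = ii + jj
    p_sum = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]

    hxy = float(-_xlog2x(p).sum())
    px_py = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pxpy = np.where(px_py > 0, np.log2(np.maximum(px_py, _EPS)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-_xlog2x(px_py).sum())
    hx = float(-_xlog2x(px).sum())

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sigma2 > 0:
        correlation = float(((p * ii * jj).sum() - mu * mu) / sigma2)
    else:
        correlation = 1.0

    present = px > 0
    if present.sum() > 1:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)) over present levels
        ps = p[np.ix_(present, present)]
        pxs = px[present]
        q = (ps / pxs[:, None]) @ (ps / pxs[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    off = ii != jj
    inv_variance = float((p[off] / (ii - jj)[off].astype(float) ** 2).sum())

    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-_xlog2x(p_diff).sum()),
        "DifferenceVariance": float((p_diff * (kd - diff_avg) ** 2).sum()),
        "Id": float((p / (1.0 + k_diff)).sum()),
        "Idm": float((p / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + k_diff / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_variance,
        "JointAverage": mu,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "Mcc": mcc,
        "SumEntropy": float(-_xlog2x(p_sum).sum()),
        "SumSquares": sigma2,
    }


def glcm_features(roi: DiscretizedROI) -> dict[str, float]:
    """23 co-occurrence features (the standard 24-set minus SumAverage),
    averaged over the four angles."""
    mats = _matrices.glcm(roi)
    acc: dict[str, float] = {name: 0.0 for name in GLCM_FEATURES}
    for a in range(mats.shape[0]):
        p = mats[a] / mats[a].sum()
        for name, val in _glcm_features_one_angle(p).items():
            acc[name] += val
    return {name: val / mats.shape[0] for name, val in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM / GLSZM shared formulas
# ---------------------------------------------------------------------------

def _rl_style_features(mat: np.ndarray, n_pixels: int, names: dict[str, str]) -> dict[str, float]:
    """The 16 formulas shared by run-length and size-zone matrices.

    ``mat`` has rows = gray level (1-based), columns = run length / zone
    size (1-based); ``names`` maps the generic formula key to the family's
    feature name.
    """
    nr = float(mat.sum())
    i = np.arange(1, mat.shape[0] + 1, dtype=float)
    j = np.arange(1, mat.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = mat / nr
    row = mat.sum(axis=1).astype(float)
    col = mat.sum(axis=0).astype(float)
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    generic = {
        "short": float((mat / jj**2).sum() / nr),
        "long": float((mat * jj**2).sum() / nr),
        "gln": float((row**2).sum() / nr),
        "glnn": float((row**2).sum() / nr**2),
        "rln": float((col**2).sum() / nr),
        "rlnn": float((col**2).sum() / nr**2),
        "pct": float(nr / n_pixels),
        "glv": float((p * (ii - mu_i) ** 2).sum()),
        "rv": float((p * (jj - mu_j) ** 2).sum()),
        "entropy": float(-_xlog2x(p).sum()),
        "lgl": float((mat / ii**2).sum() / nr),
        "hgl": float((mat * ii**2).sum() / nr),
        "srlgl": float((mat / (ii**2 * jj**2)).sum() / nr),
        "srhgl": float((mat * ii**2 / jj**2).sum() / nr),
        "lrlgl": float((mat * jj**2 / ii**2).sum() / nr),
        "lrhgl": float((mat * ii**2 * jj**2).sum() / nr),
    }
    return {feature_name: generic[key] for key, feature_name in names.items()}


_GLRLM_NAMES = {
    "short": "ShortRunEmphasis",
    "long": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "rln": "RunLengthNonUniformity",
    "rlnn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage",
    "glv": "GrayLevelVariance",
    "rv": "RunVariance",
    "entropy": "RunEntropy",
    "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis",
    "srlgl": "ShortRunLowGrayLevelEmphasis",
    "srhgl": "ShortRunHighGrayLevelEmphasis",
    "lrlgl": "LongRunLowGrayLevelEmphasis",
    "lrhgl": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "short": "SmallAreaEmphasis",
    "long": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "rln": "SizeZoneNonUniformity",
    "rlnn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage",
    "glv": "GrayLevelVariance",
    "rv": "ZoneVariance",
    "entropy": "ZoneEntropy",
    "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis",
    "srlgl": "SmallAreaLowGrayLevelEmphasis",
    "srhgl": "SmallAreaHighGrayLevelEmphasis",
    "lrlgl": "LargeAreaLowGrayLevelEmphasis",
    "lrhgl": "LargeAreaHighGrayLevelEmphasis",
}

GLRLM_FEATURES = tuple(sorted(_GLRLM_NAMES.values()))
GLSZM_FEATURES = tuple(sorted(_GLSZM_NAMES.values()))


def glrlm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 run-length features, averaged over the four angles."""
    mats = _matrices.glrlm(roi)
    n_pixels = int(roi.mask.sum())
    acc = {name: 0.0 for name in _GLRLM_NAMES.values()}
    for a in range(mats.shape[0]):
        for name, val in _rl_style_features(mats[a], n_pixels, _GLRLM_NAMES).items():
            acc[name] += val
    return {name: val / mats.shape[0] for name, val in acc.items()}


def glszm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features (orientation-free)."""
    mat = _matrices.glszm(roi)
    return _rl_style_features(mat, int(roi.mask.sum()), _GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

GLDM_FEATURES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)


def gldm_features(roi: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    """14 dependence features.  The matrix row is the gray level; the column
    index d (0..8) counts qualifying neighbors, and formulas use the
    dependence size j = d + 1 (center pixel included), so every pixel
    contributes exactly once and j is never zero."""
    mat = _matrices.gldm(roi, alpha=alpha)
    nz = float(mat.sum())  # == number of ROI pixels
    i = np.arange(1, mat.shape[0] + 1, dtype=float)
    j = np.arange(1, mat.shape[1] + 1, dtype=float)  # dependence size d+1
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = mat / nz
    row = mat.sum(axis=1).astype(float)
    col = mat.sum(axis=0).astype(float)
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    return {
        "SmallDependenceEmphasis": float((mat / jj**2).sum() / nz),
        "LargeDependenceEmphasis": float((mat * jj**2).sum() / nz),
        "GrayLevelNonUniformity": float((row**2).sum() / nz),
        "DependenceNonUniformity": float((col**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((col**2).sum() / nz**2),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (jj - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-_xlog2x(p).sum()),
        "LowGrayLevelEmphasis": float((mat / ii**2).sum() / nz),
        "HighGrayLevelEmphasis": float((mat * ii**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (ii**2 * jj**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * ii**2 / jj**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * jj**2 / ii**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * ii**2 * jj**2).sum() / nz),
    }
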