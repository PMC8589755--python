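"""Construction of the four gray-level texture count matrices.

All matrices are built from a :class:`~usradiomics.datatypes.DiscretizedROI`
(levels 1..Ng inside the mask, 0 outside).  Pixels outside the mask never
contribute: co-occurrence pairs, runs and dependence neighborhoods that
straddle the ROI boundary are dropped, and runs are broken by background.

Conventions (fixed across the package):
  * 2D angles 0, 45, 90, 135 degrees at pixel distance 1; the GLCM is
    symmetric (both directions counted).
  * GLSZM zones are 8-connected and orientation-free.
  * GLDM dependence of a pixel = number of its 8-neighbors inside the mask
    whose level differs by at most ``alpha`` (default 0).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..datatypes import DiscretizedROI

#: (row offset, col offset) for the four standard 2D angles.
ANGLE_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def _crop(roi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Crop levels and mask to the mask bounding box (counts are unchanged)."""
    rows = np.flatnonzero(roi.mask.any(axis=1))
    cols = np.flatnonzero(roi.mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return roi.levels[sl], roi.mask[sl]


def glcm(roi: DiscretizedROI) -> np.ndarray:
    """Symmetric co-occurrence counts, shape (4, Ng, Ng), one slice per angle."""
    levels, mask = _crop(roi)
    ng = roi.n_levels
    out = np.zeros((len(ANGLE_OFFSETS), ng, ng), dtype=np.int64)
    for a, (dr, dc) in enumerate(ANGLE_OFFSETS):
        r0, r1 = max(0, -dr), levels.shape[0] - max(0, dr)
        c0, c1 = max(0, -dc), levels.shape[1] - max(0, dc)
        src = levels[r0:r1, c0:c1]
        dst = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        i = src[valid] - 1
        j = dst[valid] - 1
        counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
        out[a] = counts + counts.T  # symmetric: count both directions
    return out


def _run_lengths_of_rows(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode each row of ``arr``; returns (level, length) of runs
    with level > 0.  A zero column is appended so runs never cross rows."""
    padded = np.hstack([arr, np.zeros((arr.shape[0], 1), dtype=arr.dtype)])
    flat = padded.ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [flat.size]))
    values = flat[starts]
    keep = values > 0
    return values[keep], (ends - starts)[keep]


def _skew_diagonals(levels: np.ndarray, anti: bool) -> np.ndarray:
    """Rearrange so that (anti)diagonals of ``levels`` become rows."""
    rows, cols = levels.shape
    out = np.zeros((rows + cols - 1, rows), dtype=levels.dtype)
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    diag = (r + c) if anti else (c - r + rows - 1)
    out[diag.ravel(), np.broadcast_to(r, (rows, cols)).ravel()] = levels.ravel()
    return out


def glrlm(roi: DiscretizedROI) -> np.ndarray:
    """Run-length counts, shape (4, Ng, max_run), one slice per angle.

    Runs are maximal same-level segments along the angle direction, broken
    by the mask boundary.
    """
    levels, mask = _crop(roi)
    masked = np.where(mask, levels, 0)
    per_angle: list[tuple[np.ndarray, np.ndarray]] = [
        _run_lengths_of_rows(masked),  # 0 degrees
        _run_lengths_of_rows(_skew_diagonals(masked, anti=True)),  # 45
        _run_lengths_of_rows(masked.T),  # 90
        _run_lengths_of_rows(_skew_diagonals(masked, anti=False)),  # 135
    ]
    ng = roi.n_levels
    max_run = max(int(lengths.max()) for _, lengths in per_angle)
    out = np.zeros((4, ng, max_run), dtype=np.int64)
    for a, (values, lengths) in enumerate(per_angle):
        np.add.at(out[a], (values - 1, lengths - 1), 1)
    return out


def glszm(roi: DiscretizedROI) -> np.ndarray:
    """Size-zone counts, shape (Ng, max_zone); zones are 8-connected."""
    levels, mask = _crop(roi)
    ng = roi.n_levels
    entries: list[tuple[int, np.ndarray]] = []
    max_zone = 1
    for lv in np.unique(levels[mask]):
        labeled, n_zones = ndimage.label(levels == lv, structure=_EIGHT_CONN)
        sizes = np.bincount(labeled.ravel())[1:]
        entries.append((int(lv), sizes))
        max_zone = max(max_zone, int(sizes.max()))
    out = np.zeros((ng, max_zone), dtype=np.int64)
    for lv, sizes in entries:
        np.add.at(out, (lv - 1, sizes - 1), 1)
    return out


def gldm(roi: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence counts, shape (Ng, 9): column d = pixels with d qualifying
    8-neighbors (level difference <= alpha, neighbor inside the mask)."""
    levels, mask = _crop(roi)
    padded_lv = np.pad(levels, 1)
    padded_mk = np.pad(mask, 1)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb_lv = padded_lv[1 + dr : 1 + dr + levels.shape[0], 1 + dc : 1 + dc + levels.shape[1]]
            nb_mk = padded_mk[1 + dr : 1 + dr + levels.shape[0], 1 + dc : 1 + dc + levels.shape[1]]
            dep += (np.abs(nb_lv - levels) <= alpha) & nb_mk & mask
    ng = roi.n_levels
    out = np.zeros((ng, 9), dtype=np.int64)
    np.add.at(out, (levels[mask] - 1, dep[mask]), 1)
    return out
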