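"""Reading and writing images, masks and tables.

Images: 8-bit PNG (written for synthetic data) and single-frame DICOM
(read-only, pixel data only).  Masks: PNG with nonzero = foreground, or a
plain-text run-length format.  Coordinate convention everywhere: row-major,
origin top-left, 0-based, mask pixel (i, j) annotates image pixel (i, j).

Run-length mask format (text, one mask per file)::

    <rows> <cols>
    <len0> <len1> <len2> ...

where the lengths alternate background/foreground runs of the flattened
row-major mask, starting with background (a leading foreground pixel is
encoded by a first length of 0).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image


def _atomic_write(path: Path, write_fn) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    write_fn(tmp)
    os.replace(tmp, path)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPG (grayscale or RGB) or a single-frame DICOM image."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim == 3 and arr.shape[0] == 1:
            arr = arr[0]
        if arr.ndim not in (2, 3):
            raise ValueError(f"{path}: expected a single 2D frame, got shape {arr.shape}")
        return np.asarray(arr, dtype=float)
    img = Image.open(path)
    if img.mode not in ("L", "RGB"):
        img = img.convert("RGB")
    return np.asarray(img, dtype=float)


def write_image_png(path: str | Path, pixels: np.ndarray) -> None:
    """Write a 2D array as 8-bit grayscale PNG (values clipped to 0-255)."""
    arr = np.clip(np.asarray(pixels, float), 0, 255).astype(np.uint8)
    _atomic_write(Path(path), lambda p: Image.fromarray(arr, mode="L").save(p, format="PNG"))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask from PNG (nonzero = foreground) or run-length text."""
    path = Path(path)
    if path.suffix.lower() == ".txt":
        return read_mask_rle(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    write_image_png(path, np.asarray(mask, bool).astype(np.uint8) * 255)


def read_mask_rle(path: str | Path) -> np.ndarray:
    lines = Path(path).read_text().split("\n")
    rows, cols = (int(v) for v in lines[0].split())
    lengths = np.array([int(v) for v in lines[1].split()], dtype=np.int64)
    if lengths.sum() != rows * cols:
        raise ValueError(f"{path}: run lengths sum to {lengths.sum()}, expected {rows * cols}")
    values = np.arange(len(lengths)) % 2  # starts with background
    flat = np.repeat(values, lengths).astype(bool)
    return flat.reshape(rows, cols)


def write_mask_rle(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask, bool)
    flat = mask.ravel().astype(np.int8)
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    lengths = np.diff(bounds)
    if flat[0] == 1:  # must start with a background run
        lengths = np.concatenate(([0], lengths))
    text = f"{mask.shape[0]} {mask.shape[1]}\n" + " ".join(str(v) for v in lengths) + "\n"
    _atomic_write(Path(path), lambda p: p.write_text(text, encoding="utf-8"))


def write_csv(path: str | Path, table) -> None:
    """CSV with header, UTF-8, '.' decimal separator, atomically replaced."""
    _atomic_write(Path(path), lambda p: table.to_csv(p, index=False, encoding="utf-8"))


def write_json(path: str | Path, payload: dict) -> None:
    import json

    _atomic_write(
        Path(path),
        lambda p: p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                               encoding="utf-8"),
    )
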