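"""Synthetic B-mode-like lesion images with masks and multi-reader annotations.

No patient data ships with the package; this module fabricates two lesion
phenotypes so that every downstream stage can be exercised and validated:

* a "benign-like" class — oval (low minor/major axis ratio), smooth
  circumscribed margin, homogeneous interior;
* a "malignant-like" class — rounder but with an irregular margin and a
  markedly heterogeneous echotexture, with an optional posterior acoustic
  shadow.

The lesion boundary is a star-convex radial curve: an ellipse modulated by a
truncated random Fourier series (orders 2-8) whose RMS amplitude, as a
fraction of the mean radius, is the ``boundary_irregularity`` knob.  The
interior echotexture is a spatially correlated Gaussian field around the
lesion mean, and the whole image is multiplied by unit-mean gamma speckle
(shape parameter ``speckle_shape``; larger = less noisy).  Simulated
annotators are produced by re-thresholding the mask's signed distance
against a smooth noise surface (boundary-normal displacement) plus an
occasional one-pixel morphological step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import BENIGN, MALIGNANT, AnnotatedImage

_FOURIER_ORDERS = np.arange(2, 9)  # orders 2..8 of the boundary perturbation


@dataclass(frozen=True)
class SyntheticLesionSpec:
    """All knobs of one lesion phenotype (units in the field docstrings)."""

    class_label: str = BENIGN
    #: Equivalent radius of the unperturbed lesion, pixels.
    mean_radius: float = 16.0
    #: Minor/major axis ratio of the base ellipse, in (0, 1].
    elongation_ratio: float = 0.55
    #: RMS radial boundary perturbation as a fraction of mean_radius (>= 0).
    boundary_irregularity: float = 0.04
    #: Mean interior echo intensity, gray units (0-255 scale).
    lesion_mean_intensity: float = 70.0
    #: SD of the correlated interior Gaussian field, gray units.
    heterogeneity_sd: float = 5.0
    #: Correlation length of the interior field, pixels.
    correlation_length: float = 2.5
    #: Gamma shape of the unit-mean multiplicative speckle; 0 disables it.
    speckle_shape: float = 60.0
    #: Darken the column below the lesion (posterior acoustic shadowing).
    posterior_shadow: bool = False
    #: Square image side, pixels.
    image_size: int = 128
    #: Mean background echo intensity, gray units.
    background_intensity: float = 110.0

    def validate(self) -> None:
        if self.mean_radius < 3:
            raise ValueError("mean_radius must be >= 3 pixels")
        if not (0 < self.elongation_ratio <= 1):
            raise ValueError("elongation_ratio must be in (0, 1]")
        if self.boundary_irregularity < 0 or self.heterogeneity_sd < 0:
            raise ValueError("amplitudes and SDs must be >= 0")
        if self.speckle_shape < 0 or self.correlation_length <= 0:
            raise ValueError("speckle_shape >= 0 and correlation_length > 0 required")
        # worst-case extent: semi-major axis times the largest plausible
        # boundary excursion (4 RMS amplitudes)
        reach = self.mean_radius / np.sqrt(self.elongation_ratio)
        reach *= 1.0 + 4.0 * self.boundary_irregularity
        if reach >= self.image_size / 2 - 1:
            raise ValueError(
                f"lesion (reach {reach:.1f} px) does not fit in a "
                f"{self.image_size}x{self.image_size} image"
            )


#: Default study conditions: strong-effect class pair.
DEFAULT_BENIGN_SPEC = SyntheticLesionSpec(
    class_label=BENIGN,
    mean_radius=16.0,
    elongation_ratio=0.55,
    boundary_irregularity=0.04,
    lesion_mean_intensity=70.0,
    heterogeneity_sd=5.0,
    correlation_length=2.5,
    speckle_shape=60.0,
    posterior_shadow=False,
)

DEFAULT_MALIGNANT_SPEC = SyntheticLesionSpec(
    class_label=MALIGNANT,
    mean_radius=15.0,
    elongation_ratio=0.80,
    boundary_irregularity=0.22,
    lesion_mean_intensity=55.0,
    heterogeneity_sd=16.0,
    correlation_length=2.0,
    speckle_shape=60.0,
    posterior_shadow=True,
)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _correlated_field(shape, sd: float, length: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random field with SD ``sd`` and correlation length
    ``length`` (Gaussian kernel smoothing of white noise, re-scaled)."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=length, mode="reflect")
    return smooth * (sd / smooth.std())


def generate_lesion_mask(spec: SyntheticLesionSpec, rng_seed) -> np.ndarray:
    """Star-convex lesion mask from the radial boundary model (deterministic
    per seed).  Raises if the lesion would leave the image."""
    spec.validate()
    rng = _rng(rng_seed)
    size = spec.image_size
    center = (size - 1) / 2.0
    # base ellipse with area pi * mean_radius^2 and axis ratio elongation_ratio
    semi_major = spec.mean_radius / np.sqrt(spec.elongation_ratio)
    semi_minor = spec.mean_radius * np.sqrt(spec.elongation_ratio)
    orientation = rng.uniform(0, np.pi)
    cos_c = rng.standard_normal(len(_FOURIER_ORDERS))
    sin_c = rng.standard_normal(len(_FOURIER_ORDERS))

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - center, xx - center
    # rotate into the ellipse frame
    u = dx * np.cos(orientation) + dy * np.sin(orientation)
    v = -dx * np.sin(orientation) + dy * np.cos(orientation)
    rho = np.sqrt((u / semi_major) ** 2 + (v / semi_minor) ** 2)
    phi = np.arctan2(v, u)

    if spec.boundary_irregularity > 0:
        basis = cos_c @ np.cos(np.outer(_FOURIER_ORDERS, phi.ravel())) + sin_c @ np.sin(
            np.outer(_FOURIER_ORDERS, phi.ravel())
        )
        rms = np.sqrt((cos_c**2).sum() / 2 + (sin_c**2).sum() / 2)
        pert = spec.boundary_irregularity * basis.reshape(phi.shape) / rms
        pert = np.clip(pert, -0.9, None)
    else:
        pert = 0.0

    mask = rho <= 1.0 + pert
    border = np.zeros((size, size), bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (mask & border).any():
        raise ValueError("lesion exceeds image bounds; enlarge image_size")
    # irregular boundaries can pinch off slivers: keep the main component
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if n > 1:
        sizes = np.bincount(labeled.ravel())[1:]
        mask = labeled == (int(np.argmax(sizes)) + 1)
    return mask


def render_ultrasound_image(
    mask: np.ndarray, spec: SyntheticLesionSpec, rng_seed
) -> AnnotatedImage:
    """Draw the echotexture for a lesion mask (see module docstring)."""
    rng = _rng(rng_seed)
    shape = mask.shape
    background = spec.background_intensity + _correlated_field(shape, 8.0, 3.0, rng)
    interior = spec.lesion_mean_intensity + _correlated_field(
        shape, spec.heterogeneity_sd, spec.correlation_length, rng
    )
    img = np.where(mask, interior, background)
    if spec.posterior_shadow:
        cols = np.flatnonzero(mask.any(axis=0))
        bottom = np.max(np.flatnonzero(mask.any(axis=1)))
        depth = np.clip(
            (np.arange(shape[0]) - bottom) / 6.0, 0.0, 1.0
        )  # smooth onset over ~6 px
        shadow = 1.0 - 0.45 * depth[:, None]
        col_sel = np.zeros(shape[1])
        col_sel[cols] = 1.0
        img = img * (1.0 - col_sel[None, :] * (1.0 - shadow))
    if spec.speckle_shape > 0:
        speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=shape)
        img = img * speckle
    img = np.clip(img, 0.0, 255.0)
    return AnnotatedImage(
        pixels=img, mask=mask, lesion_id="synthetic", class_label=spec.class_label
    )


def perturb_mask(
    mask: np.ndarray, magnitude: float, rng_seed, max_attempts: int = 5
) -> np.ndarray:
    """Simulate an independent annotator's segmentation of the same lesion.

    The mask's signed distance (positive inside) is re-thresholded against a
    smooth unit-SD noise surface scaled by ``magnitude`` times the
    equivalent radius — a boundary-normal Gaussian displacement — and, with
    probability ~2*magnitude, a one-pixel erosion or dilation is applied.
    ``magnitude = 0`` returns the input unchanged.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if magnitude == 0:
        return mask.copy()
    rng = _rng(rng_seed)
    r_eq = np.sqrt(mask.sum() / np.pi)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = inside - outside
    for _ in range(max_attempts):
        surface = _correlated_field(mask.shape, 1.0, 4.0, rng)
        new = signed > surface * (magnitude * r_eq)
        if rng.uniform() < min(1.0, 2.0 * magnitude):
            op = ndimage.binary_erosion if rng.uniform() < 0.5 else ndimage.binary_dilation
            new = op(new, structure=np.ones((3, 3), bool))
        if new.any():
            labeled, n = ndimage.label(new, structure=np.ones((3, 3), bool))
            if n > 1:
                sizes = np.bincount(labeled.ravel())[1:]
                new = labeled == (int(np.argmax(sizes)) + 1)
            return new
    raise RuntimeError(
        f"mask perturbation at magnitude {magnitude} emptied the mask "
        f"{max_attempts} times"
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * float((a & b).sum()) / float(a.sum() + b.sum())


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    seed,
    benign_spec: SyntheticLesionSpec = DEFAULT_BENIGN_SPEC,
    malignant_spec: SyntheticLesionSpec = DEFAULT_MALIGNANT_SPEC,
    n_readers: int = 1,
    reproducibility_subset: int = 0,
    reader_magnitude: float = 0.05,
    id_prefix: str = "L",
) -> tuple[list[AnnotatedImage], pd.DataFrame]:
    """Generate a labeled cohort of lesions with (optionally) multi-reader masks.

    Every lesion is annotated by reader R1; the first ``reproducibility_subset``
    lesions (interleaved over classes, so both are represented) additionally
    get perturbed masks from readers R2..R<n_readers>.  Per-lesion phenotype
    diversity comes from jittering the class spec (radius, intensity) around
    its defaults.  Fully reproducible from ``seed``.

    Returns the list of :class:`AnnotatedImage` records (one per lesion and
    reader) and a truth table with columns lesion_id, class_label.
    """
    rng = _rng(seed)
    specs: list[SyntheticLesionSpec] = []
    labels = [BENIGN] * n_benign + [MALIGNANT] * n_malignant
    # interleave classes so any prefix subset contains both
    order = np.argsort(rng.random(len(labels)), kind="stable")
    labels = [labels[i] for i in order]
    for label in labels:
        base = benign_spec if label == BENIGN else malignant_spec
        jitter = replace(
            base,
            mean_radius=base.mean_radius * rng.uniform(0.75, 1.3),
            lesion_mean_intensity=base.lesion_mean_intensity + rng.normal(0, 5),
            elongation_ratio=float(
                np.clip(base.elongation_ratio + rng.normal(0, 0.06), 0.2, 1.0)
            ),
        )
        specs.append(jitter)

    records: list[AnnotatedImage] = []
    truth_rows = []
    for idx, spec in enumerate(specs):
        lesion_id = f"{id_prefix}{idx:04d}"
        mask = generate_lesion_mask(spec, rng)
        img = render_ultrasound_image(mask, spec, rng)
        records.append(
            AnnotatedImage(
                pixels=img.pixels,
                mask=mask,
                lesion_id=lesion_id,
                class_label=spec.class_label,
                reader_id="R1",
            )
        )
        if idx < reproducibility_subset:
            for reader in range(2, n_readers + 1):
                records.append(
                    AnnotatedImage(
                        pixels=img.pixels,
                        mask=perturb_mask(mask, reader_magnitude, rng),
                        lesion_id=lesion_id,
                        class_label=spec.class_label,
                        reader_id=f"R{reader}",
                    )
                )
        truth_rows.append({"lesion_id": lesion_id, "class_label": spec.class_label})
    return records, pd.DataFrame(truth_rows)
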