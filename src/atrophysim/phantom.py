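"""Synthetic brain-like phantoms for end-to-end testing without real MRI.

The phantom is a set of concentric spheres emulating the tissue layout the
deformation model cares about: background and a skull shell (Label 0,
rigid), a CSF shell plus a central ventricle (Label 1, freely compensating),
and a parenchyma shell with optional embedded ROI blobs (Label 2, prescribed
divergence).  Intensities are per-tissue means plus Gaussian noise; repeat
scans re-draw the noise and can multiply in a smooth low-order polynomial
bias field, emulating the intensity/inhomogeneity differences between two
real acquisitions of the same subject.  Follow-up scans warp the noiseless
anatomy by a known field and return the exact registration ground truth, so
registration-dependent pipeline stages can be exercised with a controlled,
perturbable Φ_reg.

All randomness flows from explicit integer seeds; the same spec yields
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import invert_field
from .images import (
    DisplacementField,
    ImageGrid,
    LabelImage,
    RoiSegmentation,
    ScalarImage,
)
from .warp import warp_image

__all__ = ["PhantomSpec", "make_phantom", "make_repeat_scan", "make_followup_scan",
           "noiseless_anatomy", "tissue_mask"]

DEFAULT_INTENSITIES = {
    "background": 0.0,
    "skull": 40.0,
    "csf": 30.0,
    "ventricle": 30.0,
    "parenchyma": 110.0,
}

ROI_PARENCHYMA = 1  # ROI label of the parenchyma remainder; blobs start at 17


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of a concentric phantom.

    Radii are in mm and must nest strictly:
    ``r_skull > r_csf > r_parenchyma > r_ventricle``.  ``roi_blobs`` is a
    list of ``(center_offset_mm, radius_mm)`` spheres carved out of the
    parenchyma as separate ROIs (e.g. a hippocampus stand-in).
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    r_skull: float = 14.1
    r_csf: float = 13.4
    r_parenchyma: float = 9.6
    r_ventricle: float = 3.8
    roi_blobs: tuple[tuple[tuple[float, float, float], float], ...] = (
        ((6.7, 0.0, 0.0), 2.2),
    )
    intensities: tuple[tuple[str, float], ...] = tuple(DEFAULT_INTENSITIES.items())
    noise_sd: float = 5.0
    noise_model: str = "gaussian"
    bias_amplitude: float = 0.2
    bias_order: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        radii = (self.r_skull, self.r_csf, self.r_parenchyma, self.r_ventricle)
        if not all(a > b for a, b in zip(radii, radii[1:])) or radii[-1] <= 0:
            raise ValueError(
                "radii must nest strictly: r_skull > r_csf > r_parenchyma > "
                f"r_ventricle > 0, got {radii}"
            )
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    @classmethod
    def for_shape(cls, shape, spacing=(1.0, 1.0, 1.0), **kwargs) -> "PhantomSpec":
        """Proportionally scaled geometry for a given grid size."""
        extent = min(n * s for n, s in zip(shape, spacing))
        return cls(
            shape=tuple(shape),
            spacing=tuple(spacing),
            r_skull=0.44 * extent,
            r_csf=0.42 * extent,
            r_parenchyma=0.30 * extent,
            r_ventricle=0.12 * extent,
            roi_blobs=(((0.21 * extent, 0.0, 0.0), 0.07 * extent),),
            **kwargs,
        )

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(shape=self.shape, spacing=self.spacing)

    @property
    def intensity_map(self) -> dict[str, float]:
        return dict(self.intensities)


def _radius_map(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    grid = spec.grid
    centers = grid.voxel_centers()
    mid = np.asarray(grid.origin) + np.asarray(grid.spacing) * (
        np.asarray(grid.shape, dtype=float) - 1.0
    ) / 2.0 @ grid.direction_matrix.T
    r = np.sqrt(((centers - mid) ** 2).sum(axis=-1))
    return r, centers - mid


def _tissues(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel tissue name index and ROI segmentation array."""
    r, offsets = _radius_map(spec)
    tissue = np.full(spec.shape, "background", dtype=object)
    tissue[r <= spec.r_skull] = "skull"
    tissue[r <= spec.r_csf] = "csf"
    tissue[r <= spec.r_parenchyma] = "parenchyma"
    tissue[r <= spec.r_ventricle] = "ventricle"

    rois = np.zeros(spec.shape, dtype=np.int32)
    rois[tissue == "parenchyma"] = ROI_PARENCHYMA
    for n, (center, radius) in enumerate(spec.roi_blobs):
        blob = ((offsets - np.asarray(center)) ** 2).sum(axis=-1) <= radius**2
        inside = blob & (tissue == "parenchyma")
        rois[inside] = 17 + n
    return tissue, rois


_TISSUE_TO_LABEL = {
    "background": 0,
    "skull": 0,
    "csf": 1,
    "ventricle": 1,
    "parenchyma": 2,
}


def noiseless_anatomy(spec: PhantomSpec) -> ScalarImage:
    """Piecewise-constant image of the per-tissue mean intensities."""
    tissue, _ = _tissues(spec)
    means = spec.intensity_map
    values = np.zeros(spec.shape)
    for name, mean in means.items():
        values[tissue == name] = mean
    return ScalarImage(spec.grid, values)


def tissue_mask(spec: PhantomSpec, image: ScalarImage) -> np.ndarray:
    """Threshold mask of the brightest tissue (parenchyma) for Dice checks."""
    means = sorted(spec.intensity_map.values())
    threshold = 0.5 * (means[-1] + means[-2])
    return image.values > threshold


def _bias_field(spec: PhantomSpec, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * P(x,y,z), max |P| = 1."""
    if amplitude == 0:
        return np.ones(spec.shape)
    coords = [np.linspace(-1.0, 1.0, n) for n in spec.shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    poly = np.zeros(spec.shape)
    for px in range(spec.bias_order + 1):
        for py in range(spec.bias_order + 1 - px):
            for pz in range(spec.bias_order + 1 - px - py):
                poly += rng.normal() * xx**px * yy**py * zz**pz
    poly /= max(np.abs(poly).max(), 1e-12)
    return 1.0 + amplitude * poly


def _noisy(anatomy: np.ndarray, spec: PhantomSpec, seed: int, amplitude: float) -> np.ndarray:
    rng = np.random.default_rng(seed)
    biased = anatomy * _bias_field(spec, rng, amplitude)
    if spec.noise_model == "rician":
        # magnitude of the complex signal with Gaussian perturbations on the
        # real and imaginary channels
        real = biased + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        imag = rng.normal(0.0, spec.noise_sd, size=spec.shape)
        return np.sqrt(real**2 + imag**2)
    return biased + rng.normal(0.0, spec.noise_sd, size=spec.shape)


def make_phantom(
    spec: PhantomSpec,
) -> tuple[ScalarImage, LabelImage, RoiSegmentation]:
    """Baseline scan, model segmentation and ROI parcellation.

    The baseline carries noise but no bias field; bias differences are a
    property of *other* scans relative to the baseline.
    """
    tissue, rois = _tissues(spec)
    labels = np.zeros(spec.shape, dtype=np.int32)
    for name, lab in _TISSUE_TO_LABEL.items():
        labels[tissue == name] = lab
    anatomy = noiseless_anatomy(spec).values
    values = _noisy(anatomy, spec, spec.seed, amplitude=0.0)
    grid = spec.grid
    return (
        ScalarImage(grid, values),
        LabelImage(grid, labels),
        RoiSegmentation(grid, rois),
    )


def make_repeat_scan(
    spec: PhantomSpec, seed: int, bias_amplitude: float | None = None
) -> ScalarImage:
    """Same-session scan: identical anatomy, fresh noise, optional bias field.

    With ``bias_amplitude=0`` and ``seed == spec.seed`` this reproduces the
    baseline exactly.
    """
    if bias_amplitude is None:
        bias_amplitude = spec.bias_amplitude
    anatomy = noiseless_anatomy(spec).values
    return ScalarImage(spec.grid, _noisy(anatomy, spec, seed, bias_amplitude))


def make_followup_scan(
    spec: PhantomSpec,
    true_field: DisplacementField,
    seed: int,
    bias_amplitude: float | None = None,
) -> tuple[ScalarImage, DisplacementField]:
    """Later-time scan with known morphological change.

    The noiseless anatomy is warped by ``true_field`` (the forward map from
    baseline anatomy to follow-up anatomy), then noise and bias are added.
    Returns the scan together with the ground-truth registration field
    mapping the follow-up back onto the baseline (the inverse of
    ``true_field``), so downstream stages can use a perfect Φ_reg or perturb
    it deliberately.
    """
    if bias_amplitude is None:
        bias_amplitude = spec.bias_amplitude
    anatomy = noiseless_anatomy(spec)
    if np.any(true_field.values):
        inv = invert_field(true_field)
        warped = warp_image(anatomy, inv, field_is_inverse=True, interpolation_order=1)
        reg_field = inv
    else:
        warped = anatomy
        reg_field = DisplacementField.zeros(spec.grid)
    values = _noisy(warped.values, spec, seed, bias_amplitude)
    return ScalarImage(spec.grid, values), reg_field
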