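"""Computer-generated holograms for SLM projection.

The projection system displays a phase-only mask on a spatial light
modulator; the far field (a single optical Fourier transform away) carries
the intensity pattern that deforms the substrate.  The phase mask for a
target intensity is computed with the Gerchberg-Saxton iterative Fourier
transform algorithm: alternate between the SLM plane (unit amplitude, free
phase) and the image plane (amplitude = sqrt(target), free phase).

The forward model here is a single unitary FFT with the image-plane origin
at the raster center; bench optics (zeroth-order block, relay lenses,
aberrations) are not simulated.

Also included: construction of cell-complementary binary illumination masks
from bright-field images, magnification scaling, the tunable synthetic-lens
quadratic phase, and the polarization-sequencing plan that pairs each mask
with a linear polarization state and an exposure time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, binary_dilation
from skimage.transform import rescale

from .angles import reduce_axial

__all__ = [
    "IntensityPattern",
    "PhaseMask",
    "BinaryMask",
    "PolarizationStep",
    "compute_phase_mask",
    "reconstruct",
    "pattern_correlation",
    "mask_from_brightfield",
    "complement_mask",
    "scale_mask",
    "lens_phase",
    "save_plan_json",
    "load_plan_json",
]

TWO_PI = 2.0 * np.pi


@dataclass
class IntensityPattern:
    """Nonnegative intensity raster with projection metadata.

    values are relative; the physical scale comes from ``power_mw`` (total
    laser power reaching the sample, paper setup up to 20 mW) spread over
    the nonzero pixels, and ``pixel_size`` in µm/px.
    """

    values: np.ndarray
    pixel_size: float = 1.0
    power_mw: float = 20.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("intensity values must be nonnegative")

    @property
    def total(self):
        return float(self.values.sum())

    def local_intensity(self, x, y):
        """Physical intensity (mW/µm²) at points, bilinear interpolation.

        Normalized so the raster integrates to ``power_mw``.
        """
        if self.total == 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        scale = self.power_mw / (self.total * self.pixel_size ** 2)
        coords = np.array([np.asarray(y, float) / self.pixel_size - 0.5,
                           np.asarray(x, float) / self.pixel_size - 0.5])
        return scale * ndimage.map_coordinates(self.values, coords, order=1,
                                               mode="nearest")


@dataclass
class PhaseMask:
    """Phase raster in radians, wrapped to [0, 2*pi)."""

    values: np.ndarray
    image_errors: np.ndarray = dc_field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.mod(np.asarray(self.values, dtype=float), TWO_PI)

    def to_tiff(self, path):
        """8-bit grayscale export, 0..255 mapped onto 0..2*pi (SLM dialect)."""
        q = np.round(self.values / TWO_PI * 256.0) % 256
        tifffile.imwrite(path, q.astype(np.uint8))

    @classmethod
    def from_tiff(cls, path):
        q = tifffile.imread(path).astype(float)
        return cls(q / 256.0 * TWO_PI)


@dataclass
class BinaryMask:
    """Boolean raster with provenance and capture scale."""

    values: np.ndarray
    pixel_size: float = 1.0
    provenance: str = "auto-segmented"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def n_true(self):
        return int(self.values.sum())


@dataclass
class PolarizationStep:
    """One entry of a sequencing plan: mask, half-wave-plate angle, exposure."""

    mask: BinaryMask
    angle_deg: float
    exposure_s: float


# -- phase retrieval ------------------------------------------------------

def _forward(field):
    """SLM plane -> image plane (unitary FFT, image origin at raster center)."""
    return np.fft.fftshift(np.fft.fft2(field, norm="ortho"))


def _backward(img):
    return np.fft.ifft2(np.fft.ifftshift(img), norm="ortho")


def reconstruct(mask):
    """Image-plane intensity produced by a phase mask, normalized to unit power.

    |FFT of the unit-amplitude field exp(i*phi)|^2; energy conservation of
    the unitary transform means the raw intensity already sums to the pupil
    power, so the output always sums to exactly 1.
    """
    values = mask.values if isinstance(mask, PhaseMask) else np.asarray(mask, float)
    img = np.abs(_forward(np.exp(1j * values))) ** 2
    return IntensityPattern(img / img.sum())


def compute_phase_mask(target, n_iter=50, seed=0):
    """Gerchberg-Saxton phase retrieval for a target intensity pattern.

    Parameters
    ----------
    target : IntensityPattern or array
        Desired image-plane intensity; must not be identically zero.
    n_iter : int
        Number of full SLM<->image iterations (>= 1).  The image-plane
        amplitude error is non-increasing across iterations.
    seed : int
        Seed for the uniform-random initial SLM phase.

    Returns
    -------
    PhaseMask with ``image_errors`` holding the per-iteration RMS amplitude
    error in the image plane.
    """
    tv = target.values if isinstance(target, IntensityPattern) else np.asarray(target, float)
    if np.any(tv < 0):
        raise ValueError("target intensity must be nonnegative")
    if tv.sum() == 0:
        raise ValueError("target intensity is identically zero")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    amp_t = np.sqrt(tv / tv.sum())
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, TWO_PI, size=tv.shape)
    errors = np.empty(n_iter)
    for k in range(n_iter):
        img = _forward(np.exp(1j * phase))
        errors[k] = float(np.sqrt(np.mean((np.abs(img) - amp_t) ** 2)))
        img = amp_t * np.exp(1j * np.angle(img))
        slm = _backward(img)
        phase = np.angle(slm)
    return PhaseMask(phase, image_errors=errors)


def pattern_correlation(a, b):
    """Zero-mean normalized cross-correlation of two intensity patterns."""
    av = (a.values if isinstance(a, IntensityPattern) else np.asarray(a, float)).ravel()
    bv = (b.values if isinstance(b, IntensityPattern) else np.asarray(b, float)).ravel()
    if av.shape != bv.shape:
        raise ValueError("patterns must have the same shape")
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.linalg.norm(av) * np.linalg.norm(bv)
    if denom == 0:
        raise ValueError("correlation undefined for constant pattern")
    return float(np.dot(av, bv) / denom)


# -- illumination masks ---------------------------------------------------

def mask_from_brightfield(image, method="auto", margin_um=0.0, pixel_size=1.0):
    """Binary cell-footprint mask from a single-channel bright-field image.

    Auto mode: Otsu threshold (cells appear dark on a bright background),
    largest connected component, hole fill, dilation by ``margin_um``.  In
    ``user`` mode the image is taken as an already-drawn mask (nonzero =
    cell).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("bright-field image must be single-channel (2D)")
    if method == "user":
        fg = img > 0
        provenance = "user-drawn"
    elif method == "auto":
        if np.ptp(img) == 0:
            raise ValueError("blank image: no object to segment")
        thr = threshold_otsu(img)
        fg = img < thr  # cells are dark on bright background
        provenance = "auto-segmented"
    else:
        raise ValueError(f"unknown method {method!r}")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("segmentation found no object (check contrast/polarity)")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    if margin_um > 0:
        r = max(1, int(round(margin_um / pixel_size)))
        fg = binary_dilation(fg, disk(r))
    return BinaryMask(fg, pixel_size=pixel_size, provenance=provenance)


def complement_mask(cell_mask, roi):
    """Illumination mask complementary to the cell footprint within a ROI.

    The projected pattern covers the ROI minus the cell, minimizing the
    direct irradiation of the cell itself.
    """
    cm = cell_mask.values if isinstance(cell_mask, BinaryMask) else np.asarray(cell_mask, bool)
    rv = roi.values if isinstance(roi, BinaryMask) else np.asarray(roi, bool)
    if cm.shape != rv.shape:
        raise ValueError("cell mask and ROI must share a grid")
    out = rv & ~cm
    if not out.any():
        raise ValueError("complement is empty: nothing left to illuminate")
    ps = cell_mask.pixel_size if isinstance(cell_mask, BinaryMask) else 1.0
    return BinaryMask(out, pixel_size=ps, provenance="complement")


def scale_mask(mask, magnification):
    """Nearest-neighbor rescale between capture and projection optics."""
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    if magnification == 1.0:
        return BinaryMask(mask.values.copy(), pixel_size=mask.pixel_size,
                          provenance=mask.provenance)
    out = rescale(mask.values.astype(float), magnification, order=0,
                  anti_aliasing=False, preserve_range=True) > 0.5
    return BinaryMask(out, pixel_size=mask.pixel_size / magnification,
                      provenance=mask.provenance)


def lens_phase(focal_length_um, wavelength_um, shape, pixel_size=1.0):
    """Quadratic synthetic-lens phase: phi(r) = -pi r^2 / (lambda f), wrapped.

    ``focal_length_um`` may be +/- inf for a flat (no-lens) phase; its sign
    sets the sign of the curvature.  r is measured from the raster center.
    """
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    if focal_length_um == 0:
        raise ValueError("focal length must be nonzero")
    ny, nx = shape
    y = (np.arange(ny) - ny // 2) * pixel_size
    x = (np.arange(nx) - nx // 2) * pixel_size
    X, Y = np.meshgrid(x, y)
    if np.isinf(focal_length_um):
        return PhaseMask(np.zeros(shape))
    phi = -np.pi * (X ** 2 + Y ** 2) / (wavelength_um * focal_length_um)
    return PhaseMask(phi)


# -- sequencing plans -----------------------------------------------------

def save_plan_json(steps, path):
    """Serialize an ordered polarization-sequencing plan to JSON."""
    from .fields import _rle_encode

    doc = [{"mask_shape": list(s.mask.values.shape),
            "mask_rle": _rle_encode(s.mask.values),
            "pixel_size_um": s.mask.pixel_size,
            "angle_deg": reduce_axial(s.angle_deg),
            "exposure_s": s.exposure_s} for s in steps]
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_plan_json(path):
    from .fields import _rle_decode

    with open(path) as fh:
        doc = json.load(fh)
    return [PolarizationStep(
        BinaryMask(_rle_decode(d["mask_rle"], tuple(d["mask_shape"])),
                   pixel_size=d["pixel_size_um"]),
        d["angle_deg"], d["exposure_s"]) for d in doc]
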