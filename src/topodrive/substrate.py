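"""Azopolymer micropillar arrays and their light-induced deformation.

The substrate is a square lattice of azopolymer micropillars (default
fabrication geometry: 4 µm x 4 µm square cross-section, 1.3 µm tall, pitches
of 5, 7, 9 or 11 µm over a 2.5 mm x 2.5 mm array).  Under linearly polarized
laser light the pillar cross-section elongates along the local polarization
direction (directional photofluidization).  No constitutive law is published
for this process; the model here is a saturating-exponential dose response
with a volume-conserving uniaxial stretch at constant height:

    e(D) = e_max * (1 - exp(-D / D0)),     e_max = pitch/side - 1

where D is the accumulated optical dose (local intensity x exposure time,
mW*s/µm²) and D0 a material constant.  e_max caps the long axis at the
lattice pitch — the documented near-merge regime.  The cross-section is a
rectangle with sides side*(1+e) (along the polarization axis) and
side/(1+e), so its area is conserved exactly.

Rendering (AFM-like height maps, bright-field-like images) is vectorized
over pixels via the lattice structure: every pillar lies inside its own
lattice cell because the long half-axis never exceeds pitch/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.signal import find_peaks
from scipy import ndimage

__all__ = [
    "PillarArray",
    "DEFAULT_D0",
    "make_array",
    "deform",
    "height_map",
    "render_brightfield",
    "measure_height",
    "measure_pitch",
    "measure_side",
    "measure_extent",
    "save_array_json",
    "load_array_json",
]

# Dose constant (mW*s/µm²) such that 20 mW spread over a 100 µm x 100 µm
# projection region for 50 s drives e to 0.8*e_max: D0 = 0.1 / ln(5).
DEFAULT_D0 = 0.1 / np.log(5.0)


@dataclass
class PillarArray:
    """Square-lattice pillar array with per-pillar deformation state.

    Per-pillar arrays are stored on the lattice grid, shape (n_rows, n_cols);
    pillar (j, i) sits at ((i + 0.5) * pitch, (j + 0.5) * pitch).
    ``axis_deg`` is NaN for undeformed pillars.
    """

    pitch: float
    side: float
    height: float
    extent: tuple
    dose: np.ndarray
    elongation: np.ndarray
    axis_deg: np.ndarray

    @property
    def shape(self):
        return self.dose.shape

    @property
    def n_pillars(self):
        return int(np.prod(self.dose.shape))

    @property
    def e_max(self):
        return self.pitch / self.side - 1.0

    def centers(self):
        """(n, 2) array of pillar centers in µm (x, y)."""
        ny, nx = self.shape
        x = (np.arange(nx) + 0.5) * self.pitch
        y = (np.arange(ny) + 0.5) * self.pitch
        X, Y = np.meshgrid(x, y)
        return np.column_stack([X.ravel(), Y.ravel()])

    def copy(self):
        return PillarArray(self.pitch, self.side, self.height, tuple(self.extent),
                           self.dose.copy(), self.elongation.copy(), self.axis_deg.copy())

    def footprint_bounds(self):
        """Bounding box (width, height) of all pillar footprints, µm."""
        ny, nx = self.shape
        return (nx * self.pitch - (self.pitch - self.side),
                ny * self.pitch - (self.pitch - self.side))


def make_array(pitch, side=4.0, height=1.3, extent=(2500.0, 2500.0)):
    """Build an undeformed square-lattice array filling ``extent``.

    The number of pillars per dimension is floor(extent / pitch); pillars
    must not overlap at fabrication (side < pitch).
    """
    if not 0 < side < pitch:
        raise ValueError("need 0 < side < pitch (pillars must not overlap)")
    if height <= 0:
        raise ValueError("height must be positive")
    nx = int(np.floor(extent[0] / pitch))
    ny = int(np.floor(extent[1] / pitch))
    if nx < 1 or ny < 1:
        raise ValueError("extent too small for one pillar")
    shape = (ny, nx)
    return PillarArray(float(pitch), float(side), float(height), tuple(extent),
                       np.zeros(shape), np.zeros(shape), np.full(shape, np.nan))


def deform(array, intensity, field, exposure_s, D0=DEFAULT_D0):
    """Apply one laser exposure; returns a new array with accumulated dose.

    Each pillar inside the field's illuminated mask receives dose
    I(center) * exposure_s and elongates along the local polarization
    direction sampled from ``field``.  Pillars outside the mask or at zero
    intensity are untouched (bit-identical state).  Dose accumulates over
    repeated exposures.
    """
    if exposure_s < 0:
        raise ValueError("exposure time must be nonnegative")
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    fw, fh = field.extent
    aw, ah = array.extent
    if fw < aw - array.pitch or fh < ah - array.pitch:
        raise ValueError("orientation field does not cover the array extent")

    out = array.copy()
    c = array.centers()
    # clip sampling to the field grid (outer pillars of a larger array)
    inside = (c[:, 0] <= fw) & (c[:, 1] <= fh)
    I = np.zeros(len(c))
    I[inside] = intensity.local_intensity(c[inside, 0], c[inside, 1])
    theta = np.full(len(c), np.nan)
    mask = np.zeros(len(c), dtype=bool)
    if inside.any():
        th, mk = field.sample_many(c[inside, 0], c[inside, 1])
        theta[inside] = th
        mask[inside] = mk

    hit = mask & (I > 0) & (exposure_s > 0)
    dose = out.dose.ravel()
    elong = out.elongation.ravel()
    axis = out.axis_deg.ravel()
    dose[hit] += I[hit] * exposure_s
    elong[hit] = array.e_max * (1.0 - np.exp(-dose[hit] / D0))
    axis[hit] = theta[hit]
    return out


# -- rendering ------------------------------------------------------------

def _coverage(array, pixel_size, region, oversample=4, expand_um=0.0,
              _row_block=512):
    """Per-pixel pillar footprint coverage in [0, 1] over a µm region.

    region = (x0, y0, width, height); anti-aliasing by ``oversample`` x
    ``oversample`` subsampling.  ``expand_um`` grows each rectangle
    isotropically (used for bright-field rims).
    """
    x0, y0, w, h = region
    npx = max(1, int(round(w / pixel_size)))
    npy = max(1, int(round(h / pixel_size)))
    ny_p, nx_p = array.shape
    sub = pixel_size / oversample
    xs = (x0 + (np.arange(npx * oversample) + 0.5) * sub).astype(np.float32)
    elong = array.elongation
    axis = np.nan_to_num(array.axis_deg)
    out = np.empty((npy, npx), dtype=np.float32)

    for r0 in range(0, npy, _row_block):
        r1 = min(npy, r0 + _row_block)
        ys = (y0 + (np.arange(r0 * oversample, r1 * oversample) + 0.5) * sub
              ).astype(np.float32)
        X, Y = np.meshgrid(xs, ys)
        i = np.floor(X / array.pitch).astype(np.int32)
        j = np.floor(Y / array.pitch).astype(np.int32)
        valid = (i >= 0) & (i < nx_p) & (j >= 0) & (j < ny_p)
        i = np.clip(i, 0, nx_p - 1)
        j = np.clip(j, 0, ny_p - 1)
        e = elong[j, i]
        t = np.deg2rad(axis[j, i])
        dx = X - (i + 0.5) * array.pitch
        dy = Y - (j + 0.5) * array.pitch
        ct, st = np.cos(t), np.sin(t)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        L1 = 0.5 * array.side * (1.0 + e) + expand_um
        L2 = 0.5 * array.side / (1.0 + e) + expand_um
        inside = valid & (np.abs(u) <= L1) & (np.abs(v) <= L2)
        out[r0:r1] = inside.reshape(r1 - r0, oversample, npx, oversample
                                    ).mean(axis=(1, 3), dtype=np.float32)
    return out


def height_map(array, pixel_size=0.5, region=None, oversample=4):
    """AFM-like height raster (µm) of the (possibly deformed) array.

    Pillars are rendered as rotated rectangles of value ``height`` on a zero
    background with area-coverage anti-aliasing.  ``region`` crops to a
    (x0, y0, w, h) µm window; default is the full array extent.
    """
    if region is None:
        region = (0.0, 0.0, array.extent[0], array.extent[1])
    cov = _coverage(array, pixel_size, region, oversample=oversample)
    return (array.height * cov).astype(np.float64)


def render_brightfield(array, pixel_size=0.5, noise_sigma=0.02, seed=0,
                       region=None, oversample=4):
    """Bright-field-like image: dark rimmed pillars on a bright background.

    Deterministic for a given seed; ``noise_sigma`` = 0 gives a noiseless
    frame.
    """
    if region is None:
        region = (0.0, 0.0, array.extent[0], array.extent[1])
    body = _coverage(array, pixel_size, region, oversample=oversample)
    outer = _coverage(array, pixel_size, region, oversample=oversample,
                      expand_um=0.4)
    rim = np.clip(outer - body, 0.0, 1.0)
    img = 1.0 - 0.45 * body - 0.75 * rim
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return img.astype(np.float64)


def save_height_tiff(hmap, path, pixel_size):
    """32-bit TIFF with µm/px resolution metadata."""
    tifffile.imwrite(path, hmap.astype(np.float32),
                     resolution=(1.0 / pixel_size, 1.0 / pixel_size),
                     metadata={"unit": "um", "pixel_size_um": pixel_size})


# -- profilometry emulation ----------------------------------------------

def measure_height(hmap, bin_width=0.01):
    """Modal plateau value (µm) of the nonzero pixels of a height map."""
    vals = np.asarray(hmap, float)
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("height map has no nonzero pixels")
    lo, hi = vals.min(), vals.max()
    nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(vals, bins=nbins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def _profile_period(profile, pixel_size):
    p = profile - profile.mean()
    ac = np.correlate(p, p, mode="full")[p.size - 1:]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    # lags beyond half the profile have too few overlapping samples
    peaks, _ = find_peaks(ac[: p.size // 2 + 1], height=0.1)
    if len(peaks) == 0:
        return None
    return float(peaks[0] * pixel_size)


def measure_pitch(hmap, pixel_size):
    """Lattice period (µm) from the first off-center autocorrelation peak.

    The 2D autocorrelation of a periodic lattice has its first off-origin
    maxima one period away along each lattice axis; here the x and y
    marginal profiles are autocorrelated and their first peaks averaged.
    """
    h = np.asarray(hmap, float)
    periods = [q for q in (_profile_period(h.mean(axis=0), pixel_size),
                           _profile_period(h.mean(axis=1), pixel_size))
               if q is not None]
    if not periods:
        raise ValueError("no lattice period detectable (single pillar?)")
    return float(np.mean(periods))


def _fwhm_lines(bw, period_px):
    """Mean per-period above-half width (px) over scan lines of ``bw``.

    Each scan line crossing at least one pillar is cropped to an integer
    number of lattice periods starting at its first above-half pixel, so the
    fraction-above-half times the period is the pillar FWHM even in the
    near-merge regime where footprints abut.
    """
    widths = []
    for line in bw:
        idx = np.flatnonzero(line)
        if idx.size == 0:
            continue
        first = idx[0]
        n_per = int((line.size - first) // period_px)
        if n_per < 1:
            continue
        stop = first + int(round(n_per * period_px))
        count = int(line[first:stop].sum())
        widths.append(count / n_per)
    return widths


def measure_side(hmap, pixel_size, direction="both"):
    """Mean pillar full width at half maximum (µm) along a lattice axis.

    direction: 'x', 'y' or 'both' (mean of both).  The map is binarized at
    half the plateau height and widths are measured per scan line over an
    integer number of lattice periods (robust up to the saturation regime
    where contiguous pillars touch).
    """
    h = np.asarray(hmap, float)
    half = 0.5 * measure_height(h)
    bw = h >= half
    if not bw.any():
        raise ValueError("no pillars above half maximum")
    pitch = measure_pitch(h, pixel_size)
    period_px = pitch / pixel_size
    widths_x = _fwhm_lines(bw, period_px)
    widths_y = _fwhm_lines(bw.T, period_px)
    if not widths_x and not widths_y:
        raise ValueError("no full lattice period inside the map")
    if direction == "x":
        return float(np.mean(widths_x) * pixel_size)
    if direction == "y":
        return float(np.mean(widths_y) * pixel_size)
    if direction == "both":
        return float(np.mean(widths_x + widths_y) * pixel_size)
    raise ValueError(f"unknown direction {direction!r}")


def measure_extent(hmap, pixel_size):
    """(width, height) µm of the bounding box of nonzero pixels."""
    h = np.asarray(hmap, float)
    rows = np.flatnonzero(h.max(axis=1) > 0)
    cols = np.flatnonzero(h.max(axis=0) > 0)
    if rows.size == 0:
        raise ValueError("height map is empty")
    return ((cols[-1] - cols[0] + 1) * pixel_size,
            (rows[-1] - rows[0] + 1) * pixel_size)


# -- serialization --------------------------------------------------------

def save_array_json(array, path):
    doc = {"pitch_um": array.pitch, "side_um": array.side,
           "height_um": array.height, "extent_um": list(array.extent),
           "shape": list(array.shape),
           "dose": array.dose.ravel().tolist(),
           "elongation": array.elongation.ravel().tolist(),
           "axis_deg": [None if np.isnan(a) else a
                        for a in array.axis_deg.ravel()]}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_array_json(path):
    with open(path) as fh:
        doc = json.load(fh)
    shape = tuple(doc["shape"])
    axis = np.array([np.nan if a is None else a for a in doc["axis_deg"]])
    return PillarArray(doc["pitch_um"], doc["side_um"], doc["height_um"],
                       tuple(doc["extent_um"]),
                       np.array(doc["dose"]).reshape(shape),
                       np.array(doc["elongation"]).reshape(shape),
                       axis.reshape(shape))
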