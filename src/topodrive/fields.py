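"""Spatially varying axial orientation fields (polarization patterns).

An :class:`OrientationField` is the 2D function giving, at every point of the
substrate, the axial direction along which light will elongate the local
micropillar — the direction of the projected laser polarization.  Supported
analytic patterns are uniform linear polarization, azimuthal and radial
vortex-like patterns (topological charge +1), a hyperbolic pattern (charge
-1), and piecewise-constant compositions built from a time-sequence of
complementary masks each carrying one linear polarization state.

Coordinates: origin at the image top-left corner, x rightward, y downward,
micrometre units; angles in degrees from the +x axis, axial (mod 180).
Points outside the illuminated mask are "undeformed": sampling there returns
the sentinel ``UNDEFORMED`` (None).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import tifffile

from .angles import reduce_axial

__all__ = [
    "UNDEFORMED",
    "OrientationField",
    "make_uniform",
    "make_azimuthal",
    "make_radial",
    "make_hyperbolic",
    "compose_piecewise",
    "sample_theta",
    "save_field_json",
    "load_field_json",
]

#: Sentinel returned when a point lies outside the illuminated region.
UNDEFORMED = None


def _grid_shape(extent, pixel_size):
    w, h = float(extent[0]), float(extent[1])
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    nx = max(1, int(round(w / pixel_size)))
    ny = max(1, int(round(h / pixel_size)))
    return ny, nx


def _node_coords(extent, pixel_size):
    """Grid-node coordinates (pixel centers) in micrometres."""
    ny, nx = _grid_shape(extent, pixel_size)
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    return np.meshgrid(x, y)


@dataclass
class OrientationField:
    """Axial direction theta(x, y) on a calibrated raster grid.

    Attributes
    ----------
    theta : (ny, nx) float array, degrees in [0, 180)
    illum_mask : (ny, nx) bool array
        True where the substrate is illuminated (hence deformed).
    pixel_size : float, µm per grid node
    extent : (width_um, height_um)
    pattern_kind : one of {uniform, azimuthal, radial, hyperbolic, piecewise}
    params : constructor parameters, kept for serialization
    """

    theta: np.ndarray
    illum_mask: np.ndarray
    pixel_size: float
    extent: tuple
    pattern_kind: str
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.theta = reduce_axial(np.asarray(self.theta, dtype=float))
        self.illum_mask = np.asarray(self.illum_mask, dtype=bool)
        if self.theta.shape != self.illum_mask.shape:
            raise ValueError("theta and illum_mask shapes differ")

    # -- sampling ---------------------------------------------------------

    def _to_index(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        w, h = self.extent
        if np.any(x < 0) or np.any(x > w) or np.any(y < 0) or np.any(y > h):
            raise ValueError("point outside field extent")
        # continuous index of the surrounding node cell
        fx = x / self.pixel_size - 0.5
        fy = y / self.pixel_size - 0.5
        return fx, fy

    def sample_raw(self, x, y):
        """Interpolated theta (degrees) ignoring the illumination mask.

        Bilinear interpolation on the doubled angle (cos 2t, sin 2t): the
        axial topology means naive averaging of 179 and 1 degrees must give
        0, not 90.
        """
        fx, fy = self._to_index(x, y)
        ny, nx = self.theta.shape
        i0 = np.clip(np.floor(fy).astype(int), 0, ny - 1)
        j0 = np.clip(np.floor(fx).astype(int), 0, nx - 1)
        i1 = np.clip(i0 + 1, 0, ny - 1)
        j1 = np.clip(j0 + 1, 0, nx - 1)
        ty = np.clip(np.asarray(fy) - i0, 0.0, 1.0)
        tx = np.clip(np.asarray(fx) - j0, 0.0, 1.0)

        t2 = np.deg2rad(2.0 * self.theta)
        c, s = np.cos(t2), np.sin(t2)

        def bilin(a):
            return ((1 - ty) * (1 - tx) * a[i0, j0] + (1 - ty) * tx * a[i0, j1]
                    + ty * (1 - tx) * a[i1, j0] + ty * tx * a[i1, j1])

        ang = 0.5 * np.rad2deg(np.arctan2(bilin(s), bilin(c)))
        out = reduce_axial(ang)
        return out

    def in_mask(self, x, y):
        """Nearest-node illumination-mask lookup."""
        fx, fy = self._to_index(x, y)
        ny, nx = self.illum_mask.shape
        i = np.clip(np.rint(fy).astype(int), 0, ny - 1)
        j = np.clip(np.rint(fx).astype(int), 0, nx - 1)
        return self.illum_mask[i, j]

    def sample(self, x, y):
        """Sample the local deformation direction at a single point.

        Returns the axial angle in degrees, or :data:`UNDEFORMED` if the
        point lies outside the illuminated region.
        """
        if not self.in_mask(x, y):
            return UNDEFORMED
        return float(self.sample_raw(x, y))

    def sample_many(self, xs, ys):
        """Vectorized sampling: (theta_deg array, deformed bool array).

        theta is interpolated everywhere (the pattern direction is defined on
        the whole grid); the boolean array marks points inside the
        illuminated (deformed) region.
        """
        theta = np.atleast_1d(self.sample_raw(xs, ys))
        mask = np.atleast_1d(self.in_mask(xs, ys))
        return theta, mask

    # -- I/O --------------------------------------------------------------

    def to_tiff(self, path):
        """Export theta as a 32-bit single-channel TIFF (degrees)."""
        tifffile.imwrite(path, self.theta.astype(np.float32))


def _base_grid(extent, pixel_size):
    X, Y = _node_coords(extent, pixel_size)
    return X, Y


def make_uniform(angle_deg, extent, pixel_size, region_mask=None):
    """Uniform linear polarization: theta == angle on the illuminated region.

    ``region_mask`` restricts the illuminated area (boolean raster matching
    the grid); by default the whole extent is illuminated.
    """
    ang = reduce_axial(float(angle_deg))
    ny, nx = _grid_shape(extent, pixel_size)
    if region_mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    else:
        mask = np.asarray(region_mask, dtype=bool)
        if mask.shape != (ny, nx):
            raise ValueError("region_mask shape does not match extent/pixel_size grid")
    theta = np.full((ny, nx), ang)
    params = {"angle_deg": ang}
    if region_mask is not None:
        params["mask_rle"] = _rle_encode(mask)
    return OrientationField(theta, mask, pixel_size, tuple(extent), "uniform", params)


def _polar_angle(X, Y, center):
    return np.rad2deg(np.arctan2(Y - center[1], X - center[0]))


def make_azimuthal(center, extent, pixel_size, annulus):
    """Doughnut-shaped azimuthal pattern: theta tangent to circles about center.

    Only the annulus (r_inner, r_outer) is illuminated; pillars in the dark
    central region stay undeformed.
    """
    r_in, r_out = float(annulus[0]), float(annulus[1])
    if not r_in < r_out:
        raise ValueError("annulus inner radius must be smaller than outer radius")
    w, h = extent
    if not (0 <= center[0] <= w and 0 <= center[1] <= h):
        warnings.warn("azimuthal pattern center lies outside the field extent")
    X, Y = _base_grid(extent, pixel_size)
    alpha = _polar_angle(X, Y, center)
    theta = reduce_axial(alpha + 90.0)
    r = np.hypot(X - center[0], Y - center[1])
    mask = (r >= r_in) & (r <= r_out)
    return OrientationField(theta, mask, pixel_size, tuple(extent), "azimuthal",
                            {"center": list(center), "annulus": [r_in, r_out]})


def make_radial(center, extent, pixel_size):
    """Radial pattern: theta points away from (equivalently toward) center."""
    X, Y = _base_grid(extent, pixel_size)
    theta = reduce_axial(_polar_angle(X, Y, center))
    mask = np.ones_like(theta, dtype=bool)
    return OrientationField(theta, mask, pixel_size, tuple(extent), "radial",
                            {"center": list(center)})


def make_hyperbolic(center, axis_angle_deg, extent, pixel_size):
    """Hyperbolic (charge -1) pattern: theta = axis_angle - polar angle.

    Integral curves are hyperbola-like with a saddle at the center, matching
    the cross-shaped deformation produced by a theta-cell polarization
    converter.
    """
    X, Y = _base_grid(extent, pixel_size)
    alpha = _polar_angle(X, Y, center)
    theta = reduce_axial(float(axis_angle_deg) - alpha)
    mask = np.ones_like(theta, dtype=bool)
    return OrientationField(theta, mask, pixel_size, tuple(extent), "hyperbolic",
                            {"center": list(center), "axis_angle_deg": float(axis_angle_deg)})


def compose_piecewise(masks, angles_deg, extent, pixel_size):
    """Piecewise-constant field from disjoint region masks.

    Emulates the sequential projection of complementary patterns, each with
    one linear polarization state.  Masks must be pairwise disjoint (a point
    cannot receive two different deformation directions); their union is the
    illuminated region.
    """
    if len(masks) != len(angles_deg):
        raise ValueError("need one angle per mask")
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    ny, nx = _grid_shape(extent, pixel_size)
    total = np.zeros((ny, nx), dtype=int)
    theta = np.zeros((ny, nx), dtype=float)
    for m, a in zip(masks, angles_deg):
        m = np.asarray(m, dtype=bool)
        if m.shape != (ny, nx):
            raise ValueError("mask shape does not match extent/pixel_size grid")
        total += m
        theta[m] = reduce_axial(float(a))
    if np.any(total > 1):
        raise ValueError("masks overlap: deformation direction would be ambiguous")
    mask = total > 0
    return OrientationField(theta, mask, pixel_size, tuple(extent), "piecewise",
                            {"angles_deg": [reduce_axial(float(a)) for a in angles_deg],
                             "masks_rle": [_rle_encode(np.asarray(m, bool)) for m in masks]})


def sample_theta(field, point):
    """Module-level convenience: local deformation direction at ``point``.

    Returns degrees in [0, 180) or :data:`UNDEFORMED` outside the
    illuminated region; raises if the point is outside the grid extent.
    """
    return field.sample(point[0], point[1])


# -- serialization --------------------------------------------------------

def _rle_encode(mask):
    """Run-length encode a boolean raster (flattened, starts with False-run)."""
    flat = mask.ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    runs = np.diff(np.concatenate(([0], change, [flat.size])))
    lead = [] if not flat[0] else [0]
    return lead + runs.tolist()


def _rle_decode(runs, shape):
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            flat[pos:pos + r] = True
        pos += r
        val = not val
    return flat.reshape(shape)


def save_field_json(field, path):
    """Serialize a field as JSON: pattern kind + parameters, not rasters."""
    doc = {
        "pattern_kind": field.pattern_kind,
        "extent_um": list(field.extent),
        "pixel_size_um": field.pixel_size,
        "params": field.params,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_field_json(path):
    with open(path) as fh:
        doc = json.load(fh)
    kind = doc["pattern_kind"]
    extent = tuple(doc["extent_um"])
    ps = doc["pixel_size_um"]
    p = doc["params"]
    if kind == "uniform":
        mask = None
        if "mask_rle" in p:
            mask = _rle_decode(p["mask_rle"], _grid_shape(extent, ps))
        return make_uniform(p["angle_deg"], extent, ps, region_mask=mask)
    if kind == "azimuthal":
        return make_azimuthal(p["center"], extent, ps, p["annulus"])
    if kind == "radial":
        return make_radial(p["center"], extent, ps)
    if kind == "hyperbolic":
        return make_hyperbolic(p["center"], p["axis_angle_deg"], extent, ps)
    if kind == "piecewise":
        shape = _grid_shape(extent, ps)
        masks = [_rle_decode(r, shape) for r in p["masks_rle"]]
        return compose_piecewise(masks, p["angles_deg"], extent, ps)
    raise ValueError(f"unknown pattern kind {kind!r}")
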