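"""Quantification pipeline: segmentation, orientation, tracking, statistics.

Mirrors the measurement chain used on the live-cell experiments: segment
cytoplasmic and nuclear signals, measure each cell's centroid and major-axis
orientation psi from second image moments, compare psi (or a displacement
direction, or a division axis) with the local substrate deformation
direction theta to obtain the deviation angle phi in [0, 90] degrees and
|cos phi|, link detections across frames by minimum distance, measure
colony outlines, and compare angle distributions with two-sample
Kolmogorov-Smirnov tests.

Conventions: image coordinates (x right, y down, µm); all orientations
axial in degrees.  phi is invariant under flipping either direction by
180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu, gaussian
from skimage.measure import regionprops, find_contours
from skimage.segmentation import watershed

from .angles import axial_deviation, direction_of, reduce_axial

__all__ = [
    "CellRecord",
    "AlignmentRecord",
    "TrackedObject",
    "segment_objects",
    "detect_nuclei",
    "measure_cell",
    "measure_cells",
    "alignment",
    "link_tracks",
    "detect_divisions",
    "division_interval_table",
    "mean_division_interval",
    "displacement_alignment",
    "division_orientation",
    "colony_metrics",
    "ks_two_sample",
    "summarize_angles",
    "alignment_table",
    "violin_plot",
]

#: aspect ratio below which the principal axis is numerically degenerate
MIN_ASPECT = 1.05


@dataclass
class CellRecord:
    """Per-cell shape measurement (µm units, axial degrees)."""

    label: int
    x_um: float
    y_um: float
    psi_deg: float  # NaN when aspect <= MIN_ASPECT
    major_um: float
    minor_um: float
    aspect: float


@dataclass
class AlignmentRecord:
    """Deviation of one measured direction from the local pattern direction."""

    subject: int
    kind: str  # body | displacement | division
    phi_deg: float  # in [0, 90]
    cos_phi: float  # in [0, 1]
    region: str  # deformed | undeformed


@dataclass
class TrackedObject:
    """A linked trajectory: frame indices and centroids (µm)."""

    track: int
    frames: np.ndarray
    xy_um: np.ndarray

    @property
    def n(self):
        return len(self.frames)


# -- segmentation ---------------------------------------------------------

def segment_objects(image, min_area_px=30, nuclei_seeds=None, pixel_size=1.0,
                    smooth_sigma=1.0):
    """Label foreground objects in a single-channel image.

    Global Otsu threshold then connected components; when nucleus seed
    points are given (µm coordinates), touching cells are split by seeded
    watershed on the inverted smoothed intensity.  A blank image yields an
    empty labeling, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel (2D) image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    sm = gaussian(img, smooth_sigma) if smooth_sigma else img
    thr = threshold_otsu(sm)
    fg = sm > thr
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)
    fg = ndimage.binary_fill_holes(fg)
    if nuclei_seeds is not None and len(nuclei_seeds) > 0:
        markers = np.zeros(img.shape, dtype=np.int32)
        for k, (x, y) in enumerate(np.asarray(nuclei_seeds, float), start=1):
            i = int(round(y / pixel_size))
            j = int(round(x / pixel_size))
            if 0 <= i < img.shape[0] and 0 <= j < img.shape[1]:
                markers[i, j] = k
        labels = watershed(-sm, markers=markers, mask=fg)
    else:
        labels, _ = ndimage.label(fg)
    if min_area_px > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area_px)
        labels[np.isin(labels, small[small > 0])] = 0
    return labels.astype(np.int32)


def detect_nuclei(image, pixel_size=1.0, min_distance_um=8.0,
                  smooth_sigma_um=1.5, rel_threshold=0.3):
    """Detect nucleus centers as local maxima of the smoothed nuclear signal.

    Returns an (n, 2) array of (x, y) µm coordinates with sub-pixel
    refinement by intensity-weighted centroid in a small window.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return np.zeros((0, 2))
    sm = gaussian(img, smooth_sigma_um / pixel_size)
    md = max(1, int(round(min_distance_um / pixel_size)))
    peaks = peak_local_max(sm, min_distance=md,
                           threshold_abs=rel_threshold * sm.max(),
                           exclude_border=False)
    out = []
    r = md // 2 + 1
    for i, j in peaks:
        # two-pass windowed center of mass (second pass re-centers the
        # window, removing the half-pixel bias of the integer peak)
        ci, cj = float(i), float(j)
        for _ in range(2):
            y0, y1 = max(0, int(round(ci)) - r), min(img.shape[0],
                                                     int(round(ci)) + r + 1)
            x0, x1 = max(0, int(round(cj)) - r), min(img.shape[1],
                                                     int(round(cj)) + r + 1)
            win = sm[y0:y1, x0:x1]
            wsum = win.sum()
            if wsum <= 0:
                break
            yy, xx = np.mgrid[y0:y1, x0:x1]
            ci = (yy * win).sum() / wsum
            cj = (xx * win).sum() / wsum
        out.append((cj, ci))
    return np.asarray(out, float) * pixel_size


# -- per-cell shape -------------------------------------------------------

def _orientation_from_moments(mu):
    """Axial principal-axis angle (deg) from central moments.

    mu is the skimage central-moment matrix mu[p, q] with p the row (y)
    order and q the column (x) order; the angle is measured from +x toward
    +y (image convention), matching the field convention.
    """
    mxx, myy, mxy = mu[0, 2], mu[2, 0], mu[1, 1]
    return reduce_axial(np.rad2deg(0.5 * np.arctan2(2.0 * mxy, mxx - myy)))


def measure_cell(labels, label, pixel_size=1.0):
    """Centroid, axis lengths and orientation of one labeled object.

    Orientation and the axis-length ratio come from second central moments
    of the binary footprint (the standard ellipse-of-inertia measures).
    psi is NaN (undefined) when the aspect ratio is below ``MIN_ASPECT``.
    """
    mask = labels == label
    if not mask.any():
        raise ValueError(f"label {label} absent from labeling")
    props = regionprops(mask.astype(np.uint8))[0]
    cy, cx = props.centroid
    major = props.axis_major_length * pixel_size
    minor = props.axis_minor_length * pixel_size
    aspect = major / minor if minor > 0 else np.inf
    psi = (_orientation_from_moments(props.moments_central)
           if aspect > MIN_ASPECT else np.nan)
    # renderer/measurement convention: pixel (i, j) is centered at
    # (j * pixel_size, i * pixel_size)
    return CellRecord(int(label), cx * pixel_size, cy * pixel_size,
                      psi, major, minor, aspect)


def measure_cells(labels, pixel_size=1.0, origin=(0.0, 0.0)):
    """Measure every labeled object; returns a DataFrame in µm coordinates.

    ``origin`` offsets centroids when the labeling is a sub-window of a
    larger scene.
    """
    rows = []
    for props in regionprops(np.asarray(labels)):
        cy, cx = props.centroid
        major = props.axis_major_length * pixel_size
        minor = props.axis_minor_length * pixel_size
        aspect = major / minor if minor > 0 else np.inf
        psi = (_orientation_from_moments(props.moments_central)
               if aspect > MIN_ASPECT else np.nan)
        rows.append((props.label, origin[0] + cx * pixel_size,
                     origin[1] + cy * pixel_size, psi, major, minor,
                     aspect, props.area * pixel_size ** 2))
    return pd.DataFrame(rows, columns=["label", "x_um", "y_um", "psi_deg",
                                       "major_um", "minor_um", "aspect",
                                       "area_um2"])


# -- alignment ------------------------------------------------------------

def alignment(direction_deg, field, point, kind="body", subject=0):
    """Deviation record of a measured axial direction vs the local pattern.

    theta is the pattern direction interpolated at ``point`` (defined on the
    whole grid); the record's region label says whether the point lies in
    the illuminated (deformed) area.  Returns None when the direction is
    undefined (NaN, round cell).
    """
    if direction_deg is None or not np.isfinite(direction_deg):
        return None
    theta, deformed = field.sample_many(point[0], point[1])
    phi = float(axial_deviation(direction_deg, theta[0]))
    return AlignmentRecord(int(subject), kind, phi,
                           float(np.cos(np.deg2rad(phi))),
                           "deformed" if deformed[0] else "undeformed")


def alignment_table(records):
    """AlignmentRecord list -> DataFrame (skips None entries)."""
    recs = [r for r in records if r is not None]
    return pd.DataFrame({
        "subject": [r.subject for r in recs],
        "kind": [r.kind for r in recs],
        "phi_deg": [r.phi_deg for r in recs],
        "cos_phi": [r.cos_phi for r in recs],
        "region": [r.region for r in recs],
    })


# -- tracking -------------------------------------------------------------

def link_tracks(detections, max_disp_um):
    """Greedy minimum-distance frame-to-frame linking.

    ``detections`` is a sequence of (n_i, 2) centroid arrays (µm), one per
    frame, in frame order.  Candidate links between consecutive frames are
    sorted by distance and accepted while both endpoints are free and the
    distance is within ``max_disp_um``.  Unmatched detections start new
    tracks; unmatched track ends terminate.
    """
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be positive")
    tracks = []  # list of [frames], [points]
    active = {}  # track index -> last point
    for f, pts in enumerate(detections):
        pts = np.asarray(pts, float).reshape(-1, 2)
        if f == 0 or not active:
            new_active = {}
            for p in pts:
                tracks.append(([f], [p]))
                new_active[len(tracks) - 1] = p
            active = new_active
            continue
        tids = list(active.keys())
        prev = np.array([active[t] for t in tids])
        if len(pts) and len(prev):
            d = np.hypot(prev[:, None, 0] - pts[None, :, 0],
                         prev[:, None, 1] - pts[None, :, 1])
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None),
                                               d.shape))[0]
        else:
            order = []
        used_t, used_d = set(), set()
        new_active = {}
        for a, b in order:
            if d[a, b] > max_disp_um:
                break
            if a in used_t or b in used_d:
                continue
            used_t.add(a)
            used_d.add(b)
            t = tids[a]
            tracks[t][0].append(f)
            tracks[t][1].append(pts[b])
            new_active[t] = pts[b]
        for b, p in enumerate(pts):
            if b not in used_d:
                tracks.append(([f], [p]))
                new_active[len(tracks) - 1] = p
        active = new_active
    return [TrackedObject(i, np.asarray(fr), np.asarray(xy))
            for i, (fr, xy) in enumerate(tracks)]


def detect_divisions(tracks, max_parent_dist_um, min_track_len=2):
    """Infer mitoses from track topology.

    A division is scored when a new track is born next to an existing track
    that was present in the previous frame: the nearby track is the parent
    continuing as one daughter, the new track is the other daughter.  A
    parent's "birth" is either its own track start or its previous division,
    so parent-birth-to-division intervals can be chained down a lineage.

    Returns a DataFrame with columns t_frame, parent_track, daughter_track,
    parent_birth_frame, interval_frames, x1..y2 (daughter positions).
    """
    by_birth = {}
    for t in tracks:
        if t.n >= min_track_len:
            by_birth.setdefault(int(t.frames[0]), []).append(t)
    pos_at = {}
    for t in tracks:
        for f, p in zip(t.frames, t.xy_um):
            pos_at[(t.track, int(f))] = p
    last_division = {}  # track id -> frame of its last division
    rows = []
    for f in sorted(by_birth):
        if f == 0:
            continue
        for new in by_birth[f]:
            best, best_d = None, np.inf
            for cand in tracks:
                if cand.track == new.track or cand.n < min_track_len:
                    continue
                if (cand.track, f - 1) not in pos_at or (cand.track, f) not in pos_at:
                    continue
                # compare to the parent's pre-division position: at frame f
                # the candidate has already moved to the other daughter
                dd = np.linalg.norm(pos_at[(cand.track, f - 1)] - new.xy_um[0])
                if dd < best_d:
                    best, best_d = cand, dd
            if best is None or best_d > max_parent_dist_um:
                continue
            birth_f = last_division.get(best.track, int(best.frames[0]))
            rows.append((f, best.track, new.track, birth_f, f - birth_f,
                         pos_at[(best.track, f)][0], pos_at[(best.track, f)][1],
                         new.xy_um[0][0], new.xy_um[0][1]))
            last_division[best.track] = f
    return pd.DataFrame(rows, columns=["t_frame", "parent_track",
                                       "daughter_track", "parent_birth_frame",
                                       "interval_frames",
                                       "x1_um", "y1_um", "x2_um", "y2_um"])


def division_interval_table(tracks, divisions, n_frames):
    """Birth-to-division durations with right-censoring flags.

    Observed rows come from detected mitoses (``interval_frames``); every
    track segment still alive at the movie end — or lost before dividing —
    contributes a censored duration from its last birth (track start or last
    division) to its final frame.  Columns: duration_frames, observed.
    """
    rows = [(int(r.interval_frames), True) for r in divisions.itertuples()]
    last_birth = {t.track: int(t.frames[0]) for t in tracks}
    for r in divisions.itertuples():
        last_birth[int(r.parent_track)] = int(r.t_frame)
        last_birth[int(r.daughter_track)] = int(r.t_frame)
    for t in tracks:
        end = int(t.frames[-1])
        dur = end - last_birth[t.track]
        if dur > 0:
            rows.append((dur, False))
    return pd.DataFrame(rows, columns=["duration_frames", "observed"])


def mean_division_interval(intervals, dt_h):
    """Mean division interval (hours) by Kaplan-Meier restricted mean.

    A movie of finite length observes preferentially the short cycles; the
    naive mean of completed intervals is biased low.  The product-limit
    estimator with censored entries (cells that had not divided again by
    their last frame) removes that bias up to tail truncation at the
    largest observed duration.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    if not intervals["observed"].any():
        raise ValueError("no completed division intervals")
    T = intervals["duration_frames"].to_numpy(float) * dt_h
    E = intervals["observed"].to_numpy(bool)
    km = KaplanMeierFitter().fit(T, E)
    return float(restricted_mean_survival_time(km, t=float(T.max())))


# -- track / division alignment ------------------------------------------

def displacement_alignment(track, field, dt_s, window_h=1.0, min_step_um=2.0):
    """Alignment of non-overlapping 1-h displacement segments with the field.

    The displacement vector of each window is compared (as an axial
    direction) with the field sampled at the window-start centroid; windows
    with net displacement below ``min_step_um`` are skipped.
    """
    steps = max(1, int(round(window_h * 3600.0 / dt_s)))
    recs = []
    xy = track.xy_um
    tid = getattr(track, "track", None)
    if tid is None:
        tid = getattr(track, "cell", 0)
    for s in range(0, len(xy) - steps, steps):
        d = xy[s + steps] - xy[s]
        if np.hypot(*d) < min_step_um:
            continue
        rec = alignment(direction_of(d[0], d[1]), field, xy[s],
                        kind="displacement", subject=tid)
        if rec is not None:
            recs.append(rec)
    return recs


def division_orientation(divisions, field):
    """Alignment of daughter-joining axes with the local pattern direction.

    ``divisions`` is a DataFrame with daughter positions x1..y2 and, when
    available, the parent's last centroid (parent_x_um / parent_y_um) used
    as the field sampling point; otherwise the daughter midpoint is used.
    """
    recs = []
    for k, row in enumerate(divisions.itertuples()):
        dx = row.x2_um - row.x1_um
        dy = row.y2_um - row.y1_um
        if dx == 0 and dy == 0:
            continue
        px = getattr(row, "parent_x_um", None)
        if px is None or not np.isfinite(px):
            p = (0.5 * (row.x1_um + row.x2_um), 0.5 * (row.y1_um + row.y2_um))
        else:
            p = (row.parent_x_um, row.parent_y_um)
        w, h = field.extent
        p = (min(max(p[0], 0.0), w), min(max(p[1], 0.0), h))
        rec = alignment(direction_of(dx, dy), field, p, kind="division",
                        subject=k)
        if rec is not None:
            recs.append(rec)
    return recs


# -- colony morphometrics -------------------------------------------------

def colony_metrics(frames, pixel_size=1.0, min_area_px=50):
    """Per-frame area, elongation and orientation of the largest colony.

    Each frame is segmented (Otsu), the largest connected component kept,
    and its outline, area and ellipse-of-inertia orientation/elongation
    computed.  Returns (metrics DataFrame, list of outline polygons in µm).
    """
    rows, outlines = [], []
    for f, img in enumerate(frames):
        labels = segment_objects(img, min_area_px=min_area_px)
        if labels.max() == 0:
            rows.append((f, np.nan, np.nan, np.nan))
            outlines.append(None)
            continue
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        big = int(np.argmax(counts))
        mask = labels == big
        props = regionprops(mask.astype(np.uint8))[0]
        area = props.area * pixel_size ** 2
        major, minor = props.axis_major_length, props.axis_minor_length
        elong = major / minor if minor > 0 else np.inf
        orient = _orientation_from_moments(props.moments_central)
        cont = find_contours(mask.astype(float), 0.5)
        poly = (max(cont, key=len)[:, ::-1] * pixel_size) if cont else None
        rows.append((f, area, elong, orient))
        outlines.append(poly)
    return (pd.DataFrame(rows, columns=["frame", "area_um2", "elongation",
                                        "orientation_deg"]), outlines)


# -- statistics -----------------------------------------------------------

def ks_two_sample(sample_a, sample_b):
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum ECDF distance evaluated over the pooled sample; the
    p-value uses the asymptotic Kolmogorov distribution at the effective
    sample size n_eff = n_a * n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(sample_a, float))
    b = np.sort(np.asarray(sample_b, float))
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs nonempty samples")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    D = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(np.clip(special.kolmogorov(np.sqrt(n_eff) * D), 0.0, 1.0))
    return D, p


def summarize_angles(records):
    """Summary of deviation angles: median phi overall and per region.

    ``records`` is a list of AlignmentRecord or an alignment DataFrame.
    Returns a dict with medians (degrees), counts, and the long-form table
    ready for violin plotting.
    """
    df = records if isinstance(records, pd.DataFrame) else alignment_table(records)
    if len(df) == 0:
        raise ValueError("no alignment records to summarize")
    out = {"n": int(len(df)), "median_phi_deg": float(df["phi_deg"].median()),
           "median_cos_phi": float(df["cos_phi"].median()), "per_region": {}}
    for region, grp in df.groupby("region"):
        out["per_region"][region] = {"n": int(len(grp)),
                                     "median_phi_deg": float(grp["phi_deg"].median()),
                                     "median_cos_phi": float(grp["cos_phi"].median())}
    out["table"] = df
    return out


def violin_plot(df, path=None, value="phi_deg", by="region", ax=None):
    """Violin plot of a deviation-angle distribution split by region."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [(k, g[value].to_numpy()) for k, g in df.groupby(by)]
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    else:
        fig = ax.figure
    ax.violinplot([g for _, g in groups], showmedians=True)
    ax.set_xticks(np.arange(1, len(groups) + 1),
                  labels=[k for k, _ in groups])
    ax.set_ylabel("deviation angle phi (deg)" if value == "phi_deg" else value)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return ax
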