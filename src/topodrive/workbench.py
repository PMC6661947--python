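"""Reproducible experiment runner: design -> deformation -> cells -> numbers.

Ties the package together the way the platform is used at the bench: build
an orientation field, (optionally) compute the hologram, deform the pillar
array, seed synthetic cells or a colony, render frames, and run the full
quantification, writing CSV tables, a JSON summary and a manifest with
seeds and checksums.  Two bundled experiment kinds mirror the two
biological case studies:

* ``orientation`` — single mesenchymal-like cells on a linearly deformed
  region vs the surrounding undeformed lattice; output: per-cell deviation
  angles, medians per region, deformed-vs-undeformed KS test.
* ``colony`` — an epithelial colony growing on a deformed region; output:
  colony area/elongation/orientation time series, tracked mitoses,
  division-axis alignment and the mean division interval.

A run is reproducible from its config alone; every random stage takes its
seed from the config.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import fields, quantify, substrate, synthetic_cells
from .hologram import IntensityPattern

__all__ = [
    "default_config",
    "run_orientation_experiment",
    "run_colony_experiment",
    "run_experiment",
    "save_stack",
    "load_stack",
]


# -- configs --------------------------------------------------------------

def default_config(kind="orientation"):
    """Bundled run configurations for the two case-study experiments."""
    if kind == "orientation":
        return {
            "kind": "orientation",
            "seed": 7,
            "field": {"pattern": "uniform", "angle_deg": 30.0,
                      "extent_um": [1200.0, 1200.0], "pixel_size_um": 5.0},
            "substrate": {"pitch_um": 5.0, "side_um": 4.0, "height_um": 1.3,
                          "exposure_s": 90.0, "power_mw": 20.0},
            "cells": {"n": 220, "target_median_deg": 22.4,
                      "min_separation_um": 60.0},
            "render": {"pixel_size_um": 0.65, "tile_um": 600.0},
            "quantify": {"min_aspect": 1.05},
        }
    if kind == "colony":
        return {
            "kind": "colony",
            "seed": 11,
            "field": {"pattern": "uniform", "angle_deg": 0.0,
                      "extent_um": [420.0, 420.0], "pixel_size_um": 5.0},
            "colony": {"seed_cells": 5, "duration_h": 72.0,
                       "mean_div_h": 26.0, "div_shape": 8, "div_bias": 4.0,
                       "dt_min": 15.0},
            "render": {"pixel_size_um": 0.65},
            "quantify": {"max_disp_um": 12.0},
        }
    raise ValueError(f"unknown experiment kind {kind!r}")


def _build_field(fc):
    kind = fc.get("pattern", "uniform")
    extent = tuple(fc.get("extent_um", (1000.0, 1000.0)))
    ps = fc.get("pixel_size_um", 5.0)
    if kind == "uniform":
        return fields.make_uniform(fc.get("angle_deg", 0.0), extent, ps)
    if kind == "azimuthal":
        return fields.make_azimuthal(fc["center"], extent, ps, fc["annulus"])
    if kind == "radial":
        return fields.make_radial(fc["center"], extent, ps)
    if kind == "hyperbolic":
        return fields.make_hyperbolic(fc["center"], fc.get("axis_angle_deg", 0.0),
                                      extent, ps)
    raise ValueError(f"unknown field pattern {kind!r}")


# -- orientation experiment ----------------------------------------------

def run_orientation_experiment(field, n_cells, kappa, seed,
                               pixel_size=0.65, tile_um=600.0,
                               min_separation_um=60.0, array=None,
                               photons=200.0, gauss_sigma=0.01):
    """End-to-end single-cell orientation pipeline on synthetic data.

    Samples ``n_cells`` on the field, renders nuclei + cytoplasm tiles at
    ``pixel_size``, segments with nucleus-seeded watershed, measures each
    cell's orientation, and scores the deviation phi against the field.

    Returns (alignment DataFrame, measured cells DataFrame, truth DataFrame).
    """
    rng = np.random.default_rng(seed)
    truth = synthetic_cells.sample_cells(
        n_cells, field, kappa, seed=int(rng.integers(2 ** 31 - 1)),
        min_separation=min_separation_um)

    w, h = field.extent
    nx = max(1, int(np.ceil(w / tile_um)))
    ny = max(1, int(np.ceil(h / tile_um)))
    measured = []
    for ty in range(ny):
        for tx in range(nx):
            ox, oy = tx * tile_um, ty * tile_um
            tw = min(tile_um, w - ox)
            th = min(tile_um, h - oy)
            stack, _ = synthetic_cells.render_cells(
                truth, (tw, th), pixel_size=pixel_size,
                channels=("nuclei", "cytoplasm"), origin=(ox, oy),
                photons=photons, gauss_sigma=gauss_sigma,
                seed=int(rng.integers(2 ** 31 - 1)), array=array)
            nuc, cyto = stack[0], stack[1]
            seeds = quantify.detect_nuclei(nuc, pixel_size=pixel_size,
                                           min_distance_um=10.0)
            labels = quantify.segment_objects(cyto, nuclei_seeds=seeds,
                                              pixel_size=pixel_size,
                                              min_area_px=80)
            cells = quantify.measure_cells(labels, pixel_size=pixel_size,
                                           origin=(ox, oy))
            # drop objects clipped by the tile border (remeasured elsewhere
            # or discarded; a border cell's moments are unreliable)
            margin = 25.0
            keep = ((cells.x_um > ox + margin) & (cells.x_um < ox + tw - margin)
                    & (cells.y_um > oy + margin) & (cells.y_um < oy + th - margin))
            measured.append(cells[keep])
    cells = pd.concat(measured, ignore_index=True) if measured else pd.DataFrame()

    records = []
    for k, row in enumerate(cells.itertuples()):
        rec = quantify.alignment(row.psi_deg, field, (row.x_um, row.y_um),
                                 kind="body", subject=k)
        if rec is not None:
            records.append(rec)
    return quantify.alignment_table(records), cells, truth


# -- colony experiment ----------------------------------------------------

def run_colony_experiment(field, seed, seed_cells=5, duration_h=72.0,
                          mean_div_h=26.0, div_shape=8, div_bias=0.0,
                          dt_min=15.0, pixel_size=0.65, max_disp_um=12.0,
                          photons=200.0, gauss_sigma=0.01):
    """End-to-end colony pipeline: simulate, render, track, score divisions.

    Returns a dict with the colony ground truth, the per-frame colony
    metrics, the detected divisions (with the mean parent-birth-to-division
    interval in hours), and the division-axis alignment table.
    """
    rng = np.random.default_rng(seed)
    colony = synthetic_cells.simulate_colony(
        seed_cells, duration_h=duration_h, mean_div_h=mean_div_h,
        div_shape=div_shape, field=field, div_bias=div_bias,
        seed=int(rng.integers(2 ** 31 - 1)), dt_min=dt_min)

    movie, _ = synthetic_cells.render_colony_frames(
        colony, field.extent, pixel_size=pixel_size,
        channels=("nuclei", "cytoplasm"), photons=photons,
        gauss_sigma=gauss_sigma, seed=int(rng.integers(2 ** 31 - 1)))

    detections = [quantify.detect_nuclei(movie[f, 0], pixel_size=pixel_size,
                                         min_distance_um=10.0)
                  for f in range(movie.shape[0])]
    tracks = quantify.link_tracks(detections, max_disp_um=max_disp_um)
    divisions = quantify.detect_divisions(tracks,
                                          max_parent_dist_um=max_disp_um)
    dt_h = dt_min / 60.0
    intervals = quantify.division_interval_table(tracks, divisions,
                                                 n_frames=movie.shape[0])
    mean_interval_h = (quantify.mean_division_interval(intervals, dt_h)
                       if len(divisions) else np.nan)

    metrics, outlines = quantify.colony_metrics(
        [movie[f, 1] for f in range(movie.shape[0])], pixel_size=pixel_size)
    div_align = quantify.alignment_table(
        quantify.division_orientation(divisions, field))
    return {"colony": colony, "movie": movie, "tracks": tracks,
            "divisions": divisions, "intervals": intervals,
            "mean_interval_h": mean_interval_h,
            "metrics": metrics, "outlines": outlines,
            "division_alignment": div_align}


# -- runner ---------------------------------------------------------------

def _checksum(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(config, outdir):
    """Execute a configured experiment end-to-end into ``outdir``.

    Writes CSV tables, a summary.json, a violin plot and a manifest.json
    with the config, per-stage timing and output checksums.  Reruns with the
    same config produce identical CSV checksums.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages = {}
    kind = config.get("kind", "orientation")
    seed = int(config.get("seed", 0))
    field = _build_field(config.get("field", {}))
    fields.save_field_json(field, out / "field.json")
    stages["field"] = time.time() - t0

    summary = {"kind": kind, "seed": seed}
    if kind == "orientation":
        cc = config.get("cells", {})
        kappa = synthetic_cells.calibrate_kappa(
            cc.get("target_median_deg", 22.4))
        rc = config.get("render", {})
        align, cells, truth = run_orientation_experiment(
            field, cc.get("n", 200), kappa, seed,
            pixel_size=rc.get("pixel_size_um", 0.65),
            tile_um=rc.get("tile_um", 600.0),
            min_separation_um=cc.get("min_separation_um", 60.0))
        align.to_csv(out / "alignment.csv", index=False)
        cells.to_csv(out / "cells.csv", index=False)
        truth.to_csv(out / "truth_cells.csv", index=False)
        s = quantify.summarize_angles(align)
        table = s.pop("table")
        summary.update(s)
        summary["kappa"] = kappa
        dd = table[table.region == "deformed"]["phi_deg"]
        uu = table[table.region == "undeformed"]["phi_deg"]
        if len(dd) and len(uu):
            D, p = quantify.ks_two_sample(dd, uu)
            summary["ks"] = {"D": D, "p": p}
        quantify.violin_plot(table, out / "violin.png")
    elif kind == "colony":
        cc = config.get("colony", {})
        rc = config.get("render", {})
        res = run_colony_experiment(
            field, seed, seed_cells=cc.get("seed_cells", 5),
            duration_h=cc.get("duration_h", 72.0),
            mean_div_h=cc.get("mean_div_h", 26.0),
            div_shape=cc.get("div_shape", 8),
            div_bias=cc.get("div_bias", 0.0),
            dt_min=cc.get("dt_min", 15.0),
            pixel_size=rc.get("pixel_size_um", 0.65),
            max_disp_um=config.get("quantify", {}).get("max_disp_um", 12.0))
        res["divisions"].to_csv(out / "divisions.csv", index=False)
        res["metrics"].to_csv(out / "colony_metrics.csv", index=False)
        res["colony"].divisions.to_csv(out / "truth_divisions.csv", index=False)
        res["division_alignment"].to_csv(out / "division_alignment.csv",
                                         index=False)
        summary["mean_interval_h"] = res["mean_interval_h"]
        summary["n_divisions"] = int(len(res["divisions"]))
        if len(res["division_alignment"]):
            summary["median_division_phi_deg"] = float(
                res["division_alignment"]["phi_deg"].median())
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")
    stages["pipeline"] = time.time() - t0 - stages["field"]

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    manifest = {
        "config": config,
        "stages_s": stages,
        "outputs": {p.name: _checksum(p) for p in sorted(out.iterdir())
                    if p.suffix in {".csv", ".json"} and p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return summary


# -- image stack I/O ------------------------------------------------------

def save_stack(stack, path, pixel_size_um, dt_min=None):
    """Write a (T, C, H, W) or (C, H, W) float32 stack as an OME-style TIFF
    with µm/px (and frame-interval) metadata."""
    stack = np.asarray(stack, dtype=np.float32)
    meta = {"axes": "TCYX" if stack.ndim == 4 else "CYX",
            "PhysicalSizeX": pixel_size_um, "PhysicalSizeY": pixel_size_um,
            "PhysicalSizeXUnit": "um", "PhysicalSizeYUnit": "um"}
    if dt_min is not None:
        meta["TimeIncrement"] = dt_min
        meta["TimeIncrementUnit"] = "min"
    tifffile.imwrite(path, stack, metadata=meta)


def load_stack(path):
    return tifffile.imread(path)
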