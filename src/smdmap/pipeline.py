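"""End-to-end orchestration: timing validation, configuration, stage runs.

Wires the stages together: (simulate or load) -> optional drift correction
-> Voronoi cell segmentation -> per-cell alignment and region assignment ->
displacement extraction -> whole-cell and per-region maximum-likelihood
fits -> diffusivity maps -> machine-readable report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellseg, simkit, smdm, spt
from .io import read_localizations, write_localizations, write_map_tiff
from .locfit import estimate_and_apply_drift

__all__ = [
    "FrameTiming",
    "RunConfig",
    "validate_timing",
    "run_smdm_pipeline",
    "run_spt_pipeline",
    "read_localizations",
    "write_localizations",
]

log = logging.getLogger("smdmap")

REPORT_SCHEMA_VERSION = 1


@dataclass
class FrameTiming:
    """Camera/illumination timing of one acquisition mode.

    The total frame time is exposure plus camera dead time; the excitation
    peak-to-peak interval dt must fit inside one frame time for the
    end-of-odd-frame / start-of-even-frame pulse placement to pair frames.
    """

    exposure_ms: float
    dead_time_ms: float
    total_frame_ms: float
    frame_rate_hz: float
    pulse_405_ms: float
    pulse_561_ms: float
    dt_peak_to_peak_ms: float


def validate_timing(
    exposure_ms: float,
    dead_time_ms: float,
    pulse_405_ms: float = 1.0,
    pulse_561_ms: float = 0.5,
    dt_peak_to_peak_ms: float = 1.5,
) -> FrameTiming:
    """Check acquisition timing and derive the frame rate.

    Example: the 250x250-pixel readout mode has a 17.08 ms exposure and
    0.78 ms dead time, hence a 17.86 ms total frame time (~56 Hz).
    Rejects a peak-to-peak interval that cannot straddle the frame boundary
    (dt >= frame time, or shorter than dead time plus pulse width).
    """
    if min(exposure_ms, dead_time_ms, pulse_405_ms, pulse_561_ms,
           dt_peak_to_peak_ms) < 0 or exposure_ms == 0:
        raise ValueError("timing inputs must be positive")
    total = exposure_ms + dead_time_ms
    if dt_peak_to_peak_ms >= total:
        raise ValueError(
            f"dt = {dt_peak_to_peak_ms} ms >= frame time {total:.2f} ms: "
            "the two pulses of a pair cannot land in consecutive frames")
    if dt_peak_to_peak_ms < dead_time_ms + pulse_561_ms:
        raise ValueError(
            "dt too short: pulses would overlap the camera dead time")
    return FrameTiming(
        exposure_ms=exposure_ms,
        dead_time_ms=dead_time_ms,
        total_frame_ms=total,
        frame_rate_hz=1000.0 / total,
        pulse_405_ms=pulse_405_ms,
        pulse_561_ms=pulse_561_ms,
        dt_peak_to_peak_ms=dt_peak_to_peak_ms,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SegmentationConfig:
    alpha_density: float = 2.0
    min_points: int = 300
    max_length_nm: float = 4000.0
    max_width_nm: float = 1500.0
    pole_fraction: float = 0.2


@dataclass
class FittingConfig:
    dt_ms: float = 1.5
    r_max_nm: float = 600.0
    n_components: int = 1
    fix_b: float | None = None
    nearest_only: bool = False


@dataclass
class MapConfig:
    pixel_nm: float = 50.0
    min_count: int = 20


@dataclass
class SptConfig:
    link_radius_nm: float = 800.0
    min_len: int = 5
    max_len: int = 30
    dt_ms: float = 30.0
    n_components: int = 2


@dataclass
class DriftConfig:
    enabled: bool = False
    segment_len_frames: int = 2000
    bin_nm: float = 20.0


@dataclass
class RunConfig:
    """Declarative run configuration; validated before any stage runs."""

    mode: str = "smdm"                       # smdm | spt | simulate
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    map: MapConfig = field(default_factory=MapConfig)
    spt: SptConfig = field(default_factory=SptConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.mode not in ("smdm", "spt", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fitting.n_components not in (1, 2, 3):
            raise ValueError("n_components must be 1, 2 or 3")
        if not 0 < self.segmentation.pole_fraction < 0.5:
            raise ValueError("pole_fraction must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sub = {
            "segmentation": SegmentationConfig,
            "fitting": FittingConfig,
            "map": MapConfig,
            "spt": SptConfig,
            "drift": DriftConfig,
        }
        kwargs = {}
        for k, v in raw.items():
            if k in sub:
                kwargs[k] = sub[k](**(v or {}))
            else:
                kwargs[k] = v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# SMdM pipeline
# ---------------------------------------------------------------------------

def _fit_or_none(ds: smdm.DisplacementSet, n_components: int,
                 fix_b: float | None):
    try:
        return smdm.fit_displacement_mle(ds, n_components, fix_b=fix_b)
    except ValueError as e:
        log.debug("fit skipped: %s", e)
        return None


def run_smdm_pipeline(table: pd.DataFrame, config: RunConfig,
                      out_dir: str | None = None) -> dict:
    """Run segmentation, region fits and diffusivity maps over one table.

    Returns a versioned, JSON-serializable report: per accepted cell the
    whole-cell, middle and pole fit results and map summary, plus the list
    of rejected clusters with reasons and a row-accounting block (every
    input row is a cell member, background, or member of a rejected
    cluster). If ``out_dir`` is given, the report, a per-cell summary table
    and the per-cell D/count maps (float TIFF) are written there.
    """
    cfg = config
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "mode": "smdm", "cells": [], "rejected_clusters": [],
                    "n_localizations": int(len(table))}
    if len(table) == 0:
        report["accounting"] = {"cell": 0, "rejected": 0, "background": 0}
        _write_report(report, out_dir)
        return report

    if cfg.drift.enabled:
        table, _ = estimate_and_apply_drift(
            table, cfg.drift.segment_len_frames, cfg.drift.bin_nm)

    pts = table[["x_nm", "y_nm"]].to_numpy(float)
    clusters = cellseg.segment_cells(
        pts, cfg.segmentation.alpha_density, cfg.segmentation.min_points,
        (cfg.segmentation.max_length_nm, cfg.segmentation.max_width_nm))
    log.info("segmentation: %d cluster(s), %d accepted", len(clusters),
             sum(c.accepted for c in clusters))

    n_cell_rows = n_rej_rows = 0
    maps = {}
    cell_tables = {}
    for cid, cl in enumerate(c for c in clusters if not c.accepted):
        report["rejected_clusters"].append(
            {"n_points": cl.n_points, "reason": cl.reason})
        n_rej_rows += cl.n_points

    for cid, cl in enumerate(c for c in clusters if c.accepted):
        n_cell_rows += cl.n_points
        sub = table.iloc[cl.member_idx]
        ds_world = smdm.extract_displacements(
            sub, cfg.fitting.dt_ms, cfg.fitting.r_max_nm,
            nearest_only=cfg.fitting.nearest_only)
        ds = ds_world.transformed(cl.transform)
        regions = cellseg.assign_regions(cl, cfg.segmentation.pole_fraction)
        left_end, right_start = regions.bounds_nm

        entry = {
            "cell_id": cid,
            "n_points": cl.n_points,
            "rotation_angle_deg": cl.rotation_angle_deg,
            "centroid_nm": [float(v) for v in cl.centroid_nm],
            "n_displacements": len(ds),
            "fits": {},
        }
        whole = _fit_or_none(ds, cfg.fitting.n_components, cfg.fitting.fix_b)
        entry["fits"]["whole"] = whole.to_dict() if whole else None

        x0 = ds.x0
        masks = {
            "middle": (x0 >= left_end) & (x0 <= right_start),
            "pole_left": x0 < left_end,
            "pole_right": x0 > right_start,
            "poles": (x0 < left_end) | (x0 > right_start),
        }
        for name, m in masks.items():
            fit = _fit_or_none(ds.subset(m, region=name),
                               cfg.fitting.n_components, cfg.fitting.fix_b)
            entry["fits"][name] = fit.to_dict() if fit else None

        b_shared = whole.b if whole else 0.0
        dmap = smdm.build_diffusion_map(ds, cfg.map.pixel_nm,
                                        cfg.map.min_count, b=b_shared)
        valid = dmap.valid_mask & np.isfinite(dmap.D)
        entry["map"] = {
            "pixel_nm": dmap.pixel_nm,
            "n_valid_pixels": int(valid.sum()),
            "median_D": float(np.nanmedian(dmap.D[valid])) if valid.any() else None,
        }
        maps[cid] = dmap
        aligned_tab = sub.copy()
        ax, ay = cl.transform(sub["x_nm"].to_numpy(float),
                              sub["y_nm"].to_numpy(float))
        aligned_tab["x_nm"], aligned_tab["y_nm"] = ax, ay
        cell_tables[cid] = aligned_tab
        report["cells"].append(entry)
        log.info("cell %d: %d points, %d displacements", cid, cl.n_points,
                 len(ds))

    report["accounting"] = {
        "cell": n_cell_rows,
        "rejected": n_rej_rows,
        "background": int(len(table)) - n_cell_rows - n_rej_rows,
    }
    _write_report(report, out_dir, maps, cell_tables)
    return report


def run_spt_pipeline(table: pd.DataFrame, config: RunConfig,
                     out_dir: str | None = None) -> dict:
    """Link trajectories and fit the pooled step-size distribution."""
    cfg = config.spt
    trajs = spt.link_trajectories(table, cfg.link_radius_nm,
                                  cfg.min_len, cfg.max_len)
    n_steps = int(sum(len(t) - 1 for t in trajs))
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "mode": "spt",
        "n_localizations": int(len(table)),
        "n_trajectories": len(trajs),
        "n_steps": n_steps,
        "fit": None,
    }
    try:
        fit = spt.fit_trajectory_displacements(trajs, cfg.dt_ms,
                                               cfg.n_components)
        report["fit"] = fit.to_dict()
    except ValueError as e:
        report["note"] = str(e)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [(i, f, x, y) for i, t in enumerate(trajs)
                for f, x, y in zip(t.frames, t.x_nm, t.y_nm)]
        pd.DataFrame(rows, columns=["traj_id", "frame", "x_nm", "y_nm"]) \
            .to_csv(out / "trajectories.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _write_report(report: dict, out_dir, maps: dict | None = None,
                  cell_tables: dict | None = None) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    rows = []
    for c in report.get("cells", []):
        whole = c["fits"]["whole"] or {}
        rows.append({
            "cell_id": c["cell_id"], "n_points": c["n_points"],
            "rotation_angle_deg": c["rotation_angle_deg"],
            "n_displacements": c["n_displacements"],
            "D_whole": (whole.get("D") or [None])[0],
        })
    pd.DataFrame(rows).to_csv(out / "cells.csv", index=False)
    for cid, dmap in (maps or {}).items():
        write_map_tiff(dmap.D, out / f"cell{cid:03d}_D.tif")
        write_map_tiff(dmap.counts.astype(float), out / f"cell{cid:03d}_counts.tif")
    for cid, tab in (cell_tables or {}).items():
        write_localizations(tab, out / f"cell{cid:03d}_locs_aligned.csv")
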