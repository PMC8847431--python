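"""File formats: list-mode CSV/HDF5, YAML configuration, raw volumes.

List-mode CSV uses the header ``time_ns,camera_id,plane,ix,iy,energy_kev``
(plane in {front, rear}; pixel indices 0-based, (22, 22) on the optical
axis) with an optional trailing ``angle_id`` column for multi-angle
tables.  The HDF5 container stores one table per acquisition angle
under ``angle_<id>`` plus the configuration as a JSON attribute.
Volumes are written as float32 raw with a JSON sidecar carrying the
grid (dims, pitch, origin).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import geometry as geo
from .events import HIT_COLUMNS
from .image import Image3D
from .nuclides import EmissionLine
from .simulator import PhantomSlab, SourceSpec

_PLANES = ["front", "rear"]


def _normalize(hits: pd.DataFrame) -> pd.DataFrame:
    cols = list(HIT_COLUMNS) + (["angle_id"] if "angle_id" in hits.columns else [])
    out = hits[cols].copy()
    out["plane"] = out["plane"].astype(str)
    return out


def write_listmode_csv(hits: pd.DataFrame, path):
    _normalize(hits).to_csv(path, index=False)


def read_listmode_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"list-mode file missing columns: {sorted(missing)}")
    return df


def write_listmode_h5(hits: pd.DataFrame, path, config: dict | None = None):
    hits = _normalize(hits)
    if "angle_id" not in hits.columns:
        hits = hits.assign(angle_id=0)
    with h5py.File(path, "w") as f:
        if config is not None:
            f.attrs["config_json"] = json.dumps(config)
        for aid, sub in hits.groupby("angle_id"):
            g = f.create_group(f"angle_{int(aid):02d}")
            g.attrs["angle_id"] = int(aid)
            g.create_dataset("time_ns", data=sub["time_ns"].to_numpy(float))
            g.create_dataset("camera_id", data=sub["camera_id"].to_numpy(np.int16))
            g.create_dataset(
                "plane",
                data=np.array([_PLANES.index(p) for p in sub["plane"]], dtype=np.int8),
            )
            g.create_dataset("ix", data=sub["ix"].to_numpy(np.int16))
            g.create_dataset("iy", data=sub["iy"].to_numpy(np.int16))
            g.create_dataset("energy_kev", data=sub["energy_kev"].to_numpy(float))


def read_listmode_h5(path):
    """Returns (hits DataFrame with angle_id, config dict or None)."""
    frames = []
    with h5py.File(path, "r") as f:
        config = json.loads(f.attrs["config_json"]) if "config_json" in f.attrs else None
        for name in sorted(f):
            g = f[name]
            frames.append(
                pd.DataFrame(
                    {
                        "time_ns": g["time_ns"][:],
                        "camera_id": g["camera_id"][:],
                        "plane": pd.Categorical.from_codes(g["plane"][:], categories=_PLANES),
                        "ix": g["ix"][:],
                        "iy": g["iy"][:],
                        "energy_kev": g["energy_kev"][:],
                        "angle_id": np.int16(g.attrs["angle_id"]),
                    }
                )
            )
    hits = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=HIT_COLUMNS + ["angle_id"]
    )
    return hits, config


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def setup_from_config(cfg: dict) -> geo.AcquisitionSetup:
    g = cfg.get("setup", {})
    front = geo.DetectorPlane(
        "front",
        n_x=g.get("n_pixels", 45), n_y=g.get("n_pixels", 45),
        pixel_pitch=g.get("pixel_pitch_mm", 1.0),
        thickness=g.get("front_thickness_mm", 3.0),
        hole_half_width=g.get("hole_mm", 3.0) / 2.0,
    )
    rear = geo.DetectorPlane(
        "rear",
        n_x=g.get("n_pixels", 45), n_y=g.get("n_pixels", 45),
        pixel_pitch=g.get("pixel_pitch_mm", 1.0),
        thickness=g.get("rear_thickness_mm", 5.0),
    )
    ring_d = g.get("ring_diameter_mm", 300.0)
    n_cams = g.get("n_cameras", 4)
    base = geo.CameraGeometry(
        front=front, rear=rear,
        plane_separation=g.get("plane_separation_mm", 40.0),
        position=np.array([0.0, 0.0, ring_d / 2.0]),
    )
    cams = [base.rotated(2.0 * np.pi * c / n_cams) for c in range(n_cams)]
    return geo.AcquisitionSetup(
        cameras=cams,
        angles_deg=tuple(g.get("angles_deg", (0.0, 30.0, 60.0))),
        ring_diameter=ring_d,
    )


def sources_from_config(cfg: dict) -> list[SourceSpec]:
    out = []
    for s in cfg.get("sources", []):
        extent = None
        ext = s.get("extent")
        if ext:
            if "sphere_mm" in ext:
                extent = ("sphere", float(ext["sphere_mm"]))
            elif "box_mm" in ext:
                extent = ("box", tuple(float(v) for v in ext["box_mm"]))
            else:
                raise ValueError(f"unknown extent spec {ext!r}")
        lines = None
        if "lines" in s:
            lines = tuple(
                EmissionLine(float(l["energy_kev"]), float(l["intensity"]),
                             l.get("kind", "gamma"))
                for l in s["lines"]
            )
        out.append(
            SourceSpec(
                nuclide=s["nuclide"],
                activity_bq=float(s["activity_bq"]),
                position=tuple(float(v) for v in s.get("position_mm", (0, 0, 0))),
                extent=extent,
                lines=lines,
            )
        )
    return out


def phantoms_from_config(cfg: dict) -> list[PhantomSlab]:
    return [
        PhantomSlab(
            camera_index=int(p.get("camera_index", 0)),
            thickness_cm=float(p["thickness_cm"]),
            gap_mm=float(p.get("gap_mm", 30.0)),
            material=p.get("material", "water"),
        )
        for p in cfg.get("phantoms", [])
    ]


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def grid_from_config(cfg: dict) -> geo.VoxelGrid:
    g = cfg.get("grid", {})
    n = g.get("n_voxels", 31)
    pitch = g.get("voxel_pitch_mm", 2.3)
    if "origin_mm" in g:
        return geo.VoxelGrid(origin=np.asarray(g["origin_mm"], float),
                             voxel_pitch=pitch,
                             shape=tuple(g.get("shape", (n, n, n))))
    return geo.VoxelGrid.centered(n, pitch)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def write_volume(img: Image3D, path):
    """float32 raw volume (C order) + JSON sidecar with the grid."""
    path = Path(path)
    img.values.astype(np.float32).tofile(path)
    sidecar = {
        "dims": list(img.grid.shape),
        "voxel_pitch_mm": img.grid.voxel_pitch,
        "origin_mm": img.grid.origin.tolist(),
        "dtype": "float32",
        "order": "C",
        "n_iter": img.n_iter,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_volume(path) -> Image3D:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.fromfile(path, dtype=np.float32).reshape(meta["dims"]).astype(float)
    grid = geo.VoxelGrid(
        origin=np.asarray(meta["origin_mm"], float),
        voxel_pitch=meta["voxel_pitch_mm"],
        shape=tuple(meta["dims"]),
    )
    return Image3D(values=values, grid=grid, n_iter=meta.get("n_iter", 0))
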