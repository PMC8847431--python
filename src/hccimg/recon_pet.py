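"""PET coincidence pairing and line-of-response back projection.

Each PET event defines a line of response (LOR) joining the two
detection positions; the image is the superposition of all LORs, each
voxel receiving the exact intersection length of the line with that
voxel (Siddon-style parametric traversal, half-open voxel boundaries:
grazing rays assign length to the lower-index voxel).  Simple back
projection only — no filtering, normalisation or iterative update.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geometry as geo
from .events import select_pet as pair_pet_events  # noqa: F401  (re-export)
from .image import Image3D


def lor_endpoints(pet_events: pd.DataFrame) -> np.ndarray:
    """(N, 2, 3) LOR endpoints from a paired PET event table."""
    a = pet_events[["ax", "ay", "az"]].to_numpy(dtype=float)
    b = pet_events[["bx", "by", "bz"]].to_numpy(dtype=float)
    if np.any(np.linalg.norm(a - b, axis=1) == 0):
        raise ValueError("degenerate LOR with coincident endpoints")
    return np.stack([a, b], axis=1)


def backproject_lors(lors: np.ndarray, grid: geo.VoxelGrid) -> Image3D:
    """Back-project LORs onto ``grid``.

    ``lors`` is (N, 2, 3) world endpoints (mm).  Every traversed voxel
    is incremented by the chord length of the line inside it; LORs
    entirely outside the grid contribute nothing.
    """
    if grid.n_voxels == 0:
        raise ValueError("grid has no voxels")
    lors = np.asarray(lors, dtype=float).reshape(-1, 2, 3)
    img = np.zeros(grid.shape)
    lo = grid.origin
    hi = grid.origin + np.asarray(grid.shape) * grid.voxel_pitch
    for p0, p1 in lors:
        d = p1 - p0
        length = np.linalg.norm(d)
        if length == 0:
            continue
        # clip the segment to the grid box (slab method)
        t0, t1 = 0.0, 1.0
        ok = True
        for ax in range(3):
            if d[ax] == 0.0:
                if not (lo[ax] <= p0[ax] < hi[ax]):
                    ok = False
                    break
                continue
            ta = (lo[ax] - p0[ax]) / d[ax]
            tb = (hi[ax] - p0[ax]) / d[ax]
            ta, tb = min(ta, tb), max(ta, tb)
            t0, t1 = max(t0, ta), min(t1, tb)
        if not ok or t1 <= t0:
            continue
        # voxel-boundary crossings per axis
        ts = [np.array([t0, t1])]
        for ax in range(3):
            if d[ax] == 0.0:
                continue
            i0 = (lo[ax] + np.ceil((p0[ax] + t0 * d[ax] - lo[ax]) / grid.voxel_pitch)
                  * grid.voxel_pitch)
            planes = np.arange(i0, p0[ax] + t1 * d[ax], grid.voxel_pitch) if d[ax] > 0 \
                else np.arange(i0 - grid.voxel_pitch, p0[ax] + t1 * d[ax], -grid.voxel_pitch)
            ts.append((planes - p0[ax]) / d[ax])
        t = np.unique(np.concatenate(ts))
        t = t[(t >= t0) & (t <= t1)]
        if len(t) < 2:
            continue
        mid = p0[None, :] + 0.5 * (t[:-1] + t[1:])[:, None] * d[None, :]
        idx = grid.world_to_index(mid)
        inside = grid.contains_index(idx)
        seg = np.diff(t) * length
        idx = idx[inside]
        np.add.at(img, (idx[:, 0], idx[:, 1], idx[:, 2]), seg[inside])
    return Image3D(values=img, grid=grid)
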