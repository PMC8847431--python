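"""List-mode MLEM Compton reconstruction.

The update is

    lambda_j^n = lambda_j^{n-1} * sum_k (1/s_j^{l_k}) t_kj v_k / (sum_j' t_kj' lambda_j'^{n-1})

where ``t_kj`` is the simplified cone system matrix

    t_kj = 2 pi (1 - d / sqrt(d^2 + a^2))
           * exp(-((|Theta_j| - |theta_k|) / sigma)^2 / 2) / sin(theta_k)

with ``a`` the voxel half size, ``d`` the distance from the scatter
pixel to voxel ``j``, ``Theta_j`` the angle between the scatter axis
(absorption -> scatter direction) and the voxel direction, ``theta_k``
the kinematic scattering angle, and ``sigma`` the angular uncertainty
(2.5 deg by default).  ``v_k``, the probability that event ``k``
originates in the image space, is 1 for every event (kept as a hook for
future weighting).  The per-angle sensitivity ``s_j^l`` is estimated by
Monte Carlo irradiation from a uniform source over the field of view.

The matrix is sparsified at the 3-sigma cone shell: entries beyond it
are below exp(-4.5) of the ridge and numerically negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import map_coordinates, uniform_filter

from . import events as ev
from . import geometry as geo
from . import simulator as sim
from .image import Image3D
from .nuclides import EmissionLine

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_RAD = np.deg2rad(2.5)
_SHELL_SIGMAS = 3.0
_SENS_FLOOR_FRACTION = 0.01


def system_matrix_element(scatter_pos, absorb_pos, theta_k, voxel_center,
                          a: float, sigma: float = DEFAULT_SIGMA_RAD) -> float:
    """Single cone system-matrix element t_kj (no shell truncation)."""
    if a <= 0 or sigma <= 0:
        raise ValueError("a and sigma must be positive")
    if not 0.0 < theta_k < np.pi:
        raise ValueError("theta_k must lie in (0, pi)")
    scatter_pos = np.asarray(scatter_pos, dtype=float)
    axis = scatter_pos - np.asarray(absorb_pos, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rel = np.asarray(voxel_center, dtype=float) - scatter_pos
    d = np.linalg.norm(rel)
    solid = 2.0 * np.pi * (1.0 - d / np.hypot(d, a))
    if d == 0:
        big_theta = 0.0
    else:
        big_theta = np.arccos(np.clip(rel @ axis / d, -1.0, 1.0))
    gauss = np.exp(-0.5 * ((abs(big_theta) - abs(theta_k)) / sigma) ** 2)
    return float(solid * gauss / np.sin(theta_k))


def build_compton_system(events: pd.DataFrame, grid: geo.VoxelGrid,
                         sigma: float = DEFAULT_SIGMA_RAD,
                         batch: int = 64):
    """Sparse t_kj (events x voxels), truncated at the 3-sigma shell.

    Returns ``(T_csr, kept)`` where ``kept`` flags events with at least
    one nonzero element; empty-row events are dropped with a warning.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = grid.half_voxel
    centers = grid.centers()  # (J, 3)
    j_norm2 = np.einsum("ij,ij->i", centers, centers)
    scat = events[["scatter_x", "scatter_y", "scatter_z"]].to_numpy(dtype=float)
    absb = events[["absorb_x", "absorb_y", "absorb_z"]].to_numpy(dtype=float)
    theta = events["theta"].to_numpy(dtype=float)
    axis = scat - absb
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    K = len(events)
    rows, cols, vals = [], [], []
    for s in range(0, K, batch):
        e = min(s + batch, K)
        sc = scat[s:e]
        ax = axis[s:e]
        th = theta[s:e]
        # d^2 and voxel-direction dot products without (B, J, 3) arrays
        cross = centers @ sc.T  # (J, B)
        d2 = j_norm2[:, None] - 2.0 * cross + np.einsum("ij,ij->i", sc, sc)[None, :]
        d = np.sqrt(np.maximum(d2, 0.0))
        dot = centers @ ax.T - np.einsum("ij,ij->i", sc, ax)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_big = np.where(d > 0, dot / np.where(d > 0, d, 1.0), 1.0)
        big = np.arccos(np.clip(cos_big, -1.0, 1.0))
        del cos_big, dot
        dev = np.abs(big - th[None, :])
        del big
        # event-major nonzeros: entries arrive row-sorted with ascending
        # columns, so the CSR can be assembled without a COO pass
        kk, jj = np.nonzero(dev.T <= _SHELL_SIGMAS * sigma)
        if len(jj) == 0:
            continue
        dd = d[jj, kk]
        solid = 2.0 * np.pi * (1.0 - dd / np.hypot(dd, a))
        t = solid * np.exp(-0.5 * (dev[jj, kk] / sigma) ** 2) / np.sin(th[kk])
        rows.append((kk + s).astype(np.int32))
        cols.append(jj.astype(np.int32))
        vals.append(t.astype(np.float32))
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:
        rows = np.array([], dtype=np.int32)
        cols = np.array([], dtype=np.int32)
        vals = np.array([], dtype=np.float32)
    indptr = np.zeros(K + 1, dtype=np.int64)
    np.cumsum(np.bincount(rows, minlength=K), out=indptr[1:])
    T = sp.csr_matrix((vals, cols, indptr), shape=(K, grid.n_voxels))
    row_sums = np.asarray(T.sum(axis=1)).ravel()
    kept = row_sums > 0
    if not kept.all():
        logger.warning("dropping %d events with empty system-matrix rows",
                       int((~kept).sum()))
        T = T[kept]
    return T, kept


@dataclass
class SensitivityMap:
    """Per-voxel, per-angle Compton detection probability s_j^l."""

    values: np.ndarray  # (n_angles, nx, ny, nz)
    grid: geo.VoxelGrid
    n_photons: int
    seed: object = None

    def layer(self, angle_id: int) -> np.ndarray:
        return self.values[angle_id].ravel()


def uniform_sensitivity(grid: geo.VoxelGrid, n_angles: int) -> SensitivityMap:
    """Flat unit sensitivity (useful for oracle-scale tests)."""
    return SensitivityMap(
        values=np.ones((n_angles,) + grid.shape), grid=grid, n_photons=0
    )


def sensitivity_mc(
    setup: geo.AcquisitionSetup,
    grid: geo.VoxelGrid,
    target: str,
    n_photons: int,
    seed=None,
    cell_shape=(5, 5, 5),
    reuse_rotation: bool = True,
) -> SensitivityMap:
    """Monte Carlo sensitivity: irradiate the cameras from a uniform
    source over the field of view and record the fraction of emissions
    accepted as Compton events of ``target``, per coarse cell.

    The raw per-cell map is smoothed by one 3^3 box pass and floored at
    1 % of its median to keep the MLEM denominator finite at the FOV
    edge.  For a phantom-free rotation acquisition the per-angle maps
    are the angle-0 map evaluated at rotated voxel positions
    (``reuse_rotation``), which is exact for rigid rotations about the
    vertical axis.
    """
    if grid.n_voxels == 0:
        raise ValueError("grid has no voxels")
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    cut = ev.ENERGY_CUTS[str(target).lower()]
    energy = cut["energy_kev"]
    rng = np.random.default_rng(seed)
    half = 0.5 * np.asarray(grid.shape) * grid.voxel_pitch
    center = grid.origin + half
    spec = sim.SourceSpec(
        nuclide="mono",
        activity_bq=1.0,
        position=tuple(center),
        extent=("box", tuple(half)),
        lines=(EmissionLine(energy, 1.0),),
    )
    poses = dict(geo.build_multi_angle(setup))
    angle_ids = sorted(poses)
    cell_shape = tuple(int(c) for c in cell_shape)
    cell_pitch = 2.0 * half / np.asarray(cell_shape)

    def cell_map(angle_id):
        # one-angle acquisition holding the cameras in this angle's pose
        single = geo.AcquisitionSetup(
            cameras=poses[angle_id],
            angles_deg=(0.0,),
            ring_diameter=setup.ring_diameter,
        )
        res = sim.simulate_acquisition(
            spec, single, duration_s=float(n_photons), rng=rng, blur=True,
            track_origins=True,
        )
        hits = ev.group_coincidences(res.hits)
        selected = ev.select_compton(hits, {0: poses[angle_id]}, target)
        if len(selected) == 0:
            counts = np.zeros(cell_shape)
        else:
            origins = _event_origins(hits, selected)
            idx = np.floor((origins - (center - half)) / cell_pitch).astype(int)
            idx = np.clip(idx, 0, np.asarray(cell_shape) - 1)
            counts = np.zeros(cell_shape)
            np.add.at(counts, tuple(idx.T), 1.0)
        per_cell_emitted = res.emitted["n_photons"].sum() / np.prod(cell_shape)
        return counts / max(per_cell_emitted, 1.0)

    def interpolate(cells, pts):
        # trilinear interpolation at cell centers (avoids 1/s steps at
        # cell boundaries propagating into the image)
        coords = ((pts - (center - half)) / cell_pitch - 0.5).T
        return map_coordinates(cells, coords, order=1, mode="nearest")

    values = np.empty((len(angle_ids),) + grid.shape)
    centers = grid.centers()
    if reuse_rotation:
        base = _postprocess_cells(cell_map(0))
        for l in angle_ids:
            rot = geo.rot_y(np.deg2rad(setup.angles_deg[l]))
            values[l] = interpolate(base, centers @ rot.T).reshape(grid.shape)
    else:
        for l in angle_ids:
            cells = _postprocess_cells(cell_map(l))
            values[l] = interpolate(cells, centers).reshape(grid.shape)
    return SensitivityMap(values=values, grid=grid, n_photons=n_photons, seed=seed)


def _postprocess_cells(cells: np.ndarray) -> np.ndarray:
    smoothed = uniform_filter(cells, size=3, mode="nearest")
    positive = smoothed[smoothed > 0]
    if positive.size == 0:
        return np.full_like(smoothed, 1e-12)
    floor = _SENS_FLOOR_FRACTION * float(np.median(positive))
    return np.maximum(smoothed, floor)


def _event_origins(hits: pd.DataFrame, selected: pd.DataFrame) -> np.ndarray:
    """Emission origins of selected events (requires track_origins)."""
    per_event = hits.drop_duplicates(subset=["event_id"]).set_index("event_id")
    ori = per_event.loc[selected["event_id"], ["src_x", "src_y", "src_z"]]
    return ori.to_numpy(dtype=float)


def mlem_listmode(
    events: pd.DataFrame,
    grid: geo.VoxelGrid,
    sens: SensitivityMap,
    sigma: float = DEFAULT_SIGMA_RAD,
    n_iter: int = 20,
    v_k=None,
) -> Image3D:
    """List-mode MLEM over Compton cone events.

    ``events`` is the output of :func:`hccimg.events.select_compton`;
    every event's ``angle_id`` must have a sensitivity layer.  The
    image is initialized uniformly at 1 and stays non-negative.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if v_k is None:
        v_k = np.ones(len(events))
    else:
        v_k = np.asarray(v_k, dtype=float)
    angle_ids = events["angle_id"].to_numpy()
    # per-angle system matrices keep peak memory at one angle's worth of
    # intermediates; Tl.T is used as a CSC view (no transpose copy)
    groups = []
    for l in np.unique(angle_ids):
        rows = np.flatnonzero(angle_ids == l)
        Tl, kept_l = build_compton_system(events.iloc[rows], grid, sigma=sigma)
        inv_s = 1.0 / sens.layer(int(l))
        groups.append((Tl, v_k[rows][kept_l], inv_s))
    lam = np.ones(grid.n_voxels)
    for _ in range(n_iter):
        corr = np.zeros(grid.n_voxels)
        for Tl, vl, inv_s in groups:
            y = Tl @ lam
            ratio = np.where(y > 0, vl / np.where(y > 0, y, 1.0), 0.0)
            corr += (Tl.T @ ratio) * inv_s
        lam = lam * corr
    return Image3D(values=lam.reshape(grid.shape), grid=grid, n_iter=n_iter)
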