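"""List-mode data model and event selection.

A *hit* is one pixel firing: ``(time_ns, camera_id, plane, ix, iy,
energy_kev)``.  Hits are grouped into coincidence *events*; each event
is then classified per reconstruction mode from its detector hit
pattern:

* Compton candidate — the same camera has front and rear hits;
* pinhole candidate — a camera has rear hit(s) and no front hit;
* PET candidate — two distinct cameras each carry deposits.

After classification, a per-nuclide energy cut restricts each mode to
its target line.  The Compton front-energy window eliminates
back-scattering events (front deposit too large for a forward scatter).

Bulk selection functions operate on pandas DataFrames and are the fast
path used by the simulator/reconstruction pipeline; the ``Event`` class
and ``classify_event`` provide the single-event view of the same rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attenuation import ELECTRON_REST_KEV

HIT_COLUMNS = ["time_ns", "camera_id", "plane", "ix", "iy", "energy_kev"]

DEFAULT_COINCIDENCE_WINDOW_NS = 100.0


@dataclass(frozen=True)
class EnergyWindow:
    lo: float
    hi: float
    applies_to: str  # "E_f" | "E_r" | "E_f+E_r"

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("window requires lo < hi")

    def contains(self, values):
        v = np.asarray(values)
        return (v > self.lo) & (v < self.hi)


#: Per-nuclide selection: reconstruction mode, target line (keV) and
#: energy windows.  Compton rows carry both the front window (rejects
#: back-scatter) and the total window; the PET window is applied to each
#: camera's total deposit separately.
ENERGY_CUTS: dict[str, dict] = {
    "cs137": {
        "mode": "compton",
        "energy_kev": 662.0,
        "windows": (EnergyWindow(20, 80, "E_f"), EnergyWindow(607, 717, "E_f+E_r")),
    },
    "am241": {
        "mode": "pinhole",
        "energy_kev": 60.0,
        "windows": (EnergyWindow(47, 73, "E_r"),),
    },
    "na22": {
        "mode": "pet",
        "energy_kev": 511.0,
        "windows": (EnergyWindow(471, 551, "E_f+E_r"),),
    },
    "ga67_93": {
        "mode": "pinhole",
        "energy_kev": 93.0,
        "windows": (EnergyWindow(75, 111, "E_r"),),
    },
    "ga67_300": {
        "mode": "compton",
        "energy_kev": 300.0,
        "windows": (EnergyWindow(20, 80, "E_f"), EnergyWindow(273, 327, "E_f+E_r")),
    },
    "in111": {
        "mode": "compton",
        "energy_kev": 245.0,
        "windows": (EnergyWindow(20, 80, "E_f"), EnergyWindow(220, 270, "E_f+E_r")),
    },
    "at211": {
        "mode": "pinhole",
        "energy_kev": 79.0,
        "windows": (EnergyWindow(69, 89, "E_r"),),
    },
}


def target_windows(nuclide_target) -> tuple[EnergyWindow, ...]:
    """Resolve an energy-cut target name (or explicit windows)."""
    if isinstance(nuclide_target, (tuple, list)):
        return tuple(nuclide_target)
    try:
        return ENERGY_CUTS[str(nuclide_target).lower()]["windows"]
    except KeyError:
        raise ValueError(
            f"unknown energy-cut target {nuclide_target!r}; pass explicit windows"
        ) from None


# ---------------------------------------------------------------------------
# Coincidence grouping
# ---------------------------------------------------------------------------

def group_coincidences(hits: pd.DataFrame, window_ns: float = DEFAULT_COINCIDENCE_WINDOW_NS) -> pd.DataFrame:
    """Greedy coincidence grouping of time-sorted hits.

    An event opens at the first unassigned hit and absorbs every hit
    within ``window_ns`` of that opener (window anchored at the opener,
    not the last hit).  Returns a copy with an ``event_id`` column;
    every hit belongs to exactly one event.
    """
    if window_ns <= 0:
        raise ValueError("window must be positive")
    out = hits.copy()
    n = len(out)
    if n == 0:
        out["event_id"] = np.array([], dtype=np.int64)
        return out
    t = out["time_ns"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt < 0):
        raise ValueError("hits must be sorted by time")
    # Chains of hits linked by gaps <= window are supersets of events;
    # only chains longer than one window need the explicit greedy walk.
    opener = np.empty(n, dtype=bool)
    opener[0] = True
    opener[1:] = dt > window_ns
    starts = np.flatnonzero(opener)
    ends = np.append(starts[1:], n)
    # only chains longer than one window need the explicit greedy walk
    long_chain = t[ends - 1] - t[starts] > window_ns
    for s, e in zip(starts[long_chain], ends[long_chain]):
        i = s
        while i < e:
            j = i + np.searchsorted(t[i:e], t[i] + window_ns, side="right")
            opener[i] = True
            i = j
    out["event_id"] = np.cumsum(opener) - 1
    return out


def group_by_angle(hits: pd.DataFrame, window_ns: float = DEFAULT_COINCIDENCE_WINDOW_NS) -> pd.DataFrame:
    """Coincidence-group a multi-angle hit table.

    Angles are separate measurements, so events never span angles;
    event ids are made unique across the whole table.
    """
    if len(hits) == 0 or "angle_id" not in hits.columns:
        return group_coincidences(hits, window_ns)
    frames = []
    offset = 0
    for _, sub in hits.groupby("angle_id", sort=True):
        g = group_coincidences(
            sub.sort_values("time_ns", kind="stable").reset_index(drop=True), window_ns
        )
        g["event_id"] += offset
        offset = int(g["event_id"].max()) + 1
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


class Event:
    """One coincidence event: a view over its hits with per-camera sums."""

    def __init__(self, hits: pd.DataFrame):
        if len(hits) == 0:
            raise ValueError("an event must contain at least one hit")
        self.hits = hits

    def cameras(self):
        return sorted(self.hits["camera_id"].unique())

    def plane_energy(self, camera_id: int, plane: str) -> float:
        m = (self.hits["camera_id"] == camera_id) & (self.hits["plane"] == plane)
        return float(self.hits.loc[m, "energy_kev"].sum())

    def E_f(self, camera_id: int) -> float:
        return self.plane_energy(camera_id, "front")

    def E_r(self, camera_id: int) -> float:
        return self.plane_energy(camera_id, "rear")


def classify_event(event: Event, mode: str):
    """Candidate cameras (or camera pairs) of ``event`` for ``mode``.

    Returns a possibly empty list; an event may be a candidate for
    several modes at once (selection is per reconstruction run).
    """
    cams = event.cameras()
    if mode == "compton":
        return [c for c in cams if event.E_f(c) > 0 and event.E_r(c) > 0]
    if mode == "pinhole":
        return [c for c in cams if event.E_f(c) == 0 and event.E_r(c) > 0]
    if mode == "pet":
        with_dep = [c for c in cams if event.E_f(c) + event.E_r(c) > 0]
        return [
            (a, b) for i, a in enumerate(with_dep) for b in with_dep[i + 1:]
        ]
    raise ValueError(f"unknown mode {mode!r}")


def apply_energy_cut(candidates: pd.DataFrame, nuclide_target) -> pd.DataFrame:
    """Keep candidate rows passing every window of the target's cut.

    ``candidates`` must carry ``E_f``/``E_r`` columns as produced by the
    bulk selectors below (for pinhole candidates ``E_f`` is 0).
    """
    windows = target_windows(nuclide_target)
    keep = np.ones(len(candidates), dtype=bool)
    quantities = {
        "E_f": lambda d: d["E_f"].to_numpy(),
        "E_r": lambda d: d["E_r"].to_numpy(),
        "E_f+E_r": lambda d: d["E_f"].to_numpy() + d["E_r"].to_numpy(),
    }
    for w in windows:
        keep &= w.contains(quantities[w.applies_to](candidates))
    return candidates.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Compton kinematics
# ---------------------------------------------------------------------------

def compute_scatter_angle(E_f, E_r):
    """Scattering angle (rad) from the energy pair of a Compton event.

    cos(theta) = 1 - m_e c^2 (1/E_r - 1/(E_f + E_r)), assuming full
    absorption of the scattered photon in the rear plane.  Returns NaN
    where the pair is kinematically invalid (|cos| >= 1); such events
    must be discarded upstream.
    """
    E_f = np.asarray(E_f, dtype=float)
    E_r = np.asarray(E_r, dtype=float)
    if np.any(E_f <= 0) or np.any(E_r <= 0):
        raise ValueError("deposited energies must be positive")
    cos_t = 1.0 - ELECTRON_REST_KEV * (1.0 / E_r - 1.0 / (E_f + E_r))
    with np.errstate(invalid="ignore"):
        theta = np.where(np.abs(cos_t) < 1.0, np.arccos(np.clip(cos_t, -1, 1)), np.nan)
    if theta.ndim == 0:
        return float(theta)
    return theta


# ---------------------------------------------------------------------------
# Bulk selection (DataFrame pipeline)
# ---------------------------------------------------------------------------

_SUMMARY_COLS = ["angle_id", "event_id", "camera_id", "E_f", "E_r",
                 "ix_f", "iy_f", "ix_r", "iy_r"]


def _plane_is_rear(df: pd.DataFrame) -> np.ndarray:
    pl = df["plane"]
    if isinstance(pl.dtype, pd.CategoricalDtype):
        rear_code = list(pl.cat.categories).index("rear")
        return pl.cat.codes.to_numpy() == rear_code
    return pl.to_numpy() == "rear"


def _camera_summary(hits: pd.DataFrame, keep=None) -> pd.DataFrame:
    """One row per (angle, event, camera) with per-plane sums/positions.

    Multi-hit planes are summed in energy; the interaction position is
    the highest-energy pixel of the plane.  Cameras without a deposit
    in a plane carry 0 energy and pixel index -1 for that plane.
    ``keep`` is an optional ``f(E_f, E_r) -> bool mask`` applied before
    the table is materialised (selection fast path).
    """
    df = hits
    if "angle_id" not in df.columns:
        df = df.assign(angle_id=0)
    n = len(df)
    if n == 0:
        return pd.DataFrame(columns=_SUMMARY_COLS)
    angle = df["angle_id"].to_numpy(np.int64)
    eid = df["event_id"].to_numpy(np.int64)
    cam = df["camera_id"].to_numpy(np.int64)
    is_rear = _plane_is_rear(df).astype(np.int64)
    e = df["energy_kev"].to_numpy(dtype=float)
    n_cam = int(cam.max()) + 1
    eid_span = int(eid.max()) + 1
    group_key = (angle * eid_span + eid) * n_cam + cam
    uk, inv = np.unique(group_key, return_inverse=True)
    m = len(uk)
    plane_inv = inv * 2 + is_rear
    esum = np.bincount(plane_inv, weights=e, minlength=2 * m)
    e_f, e_r = esum[0::2], esum[1::2]
    sel = keep(e_f, e_r) if keep is not None else np.ones(m, dtype=bool)
    # highest-energy pixel per (group, plane)
    order = np.lexsort((e, plane_inv))
    counts = np.bincount(plane_inv, minlength=2 * m)
    ends = np.cumsum(counts) - 1  # last (max-energy) row of each slot
    has = counts > 0
    ix = np.full(2 * m, -1, dtype=np.int64)
    iy = np.full(2 * m, -1, dtype=np.int64)
    ix_all = df["ix"].to_numpy(np.int64)
    iy_all = df["iy"].to_numpy(np.int64)
    ix[has] = ix_all[order[ends[has]]]
    iy[has] = iy_all[order[ends[has]]]
    uk = uk[sel]
    out_cam = uk % n_cam
    rest = uk // n_cam
    return pd.DataFrame({
        "angle_id": rest // eid_span,
        "event_id": rest % eid_span,
        "camera_id": out_cam,
        "E_f": e_f[sel],
        "E_r": e_r[sel],
        "ix_f": ix[0::2][sel],
        "iy_f": iy[0::2][sel],
        "ix_r": ix[1::2][sel],
        "iy_r": iy[1::2][sel],
    })


def _positions(poses, angle_id, camera_id, plane, ix, iy):
    """World positions of pixel centers for arrays of indices."""
    pos = np.empty((len(angle_id), 3))
    angle_id = np.asarray(angle_id)
    camera_id = np.asarray(camera_id)
    for aid in np.unique(angle_id):
        cams = poses[int(aid)]
        for cid in np.unique(camera_id[angle_id == aid]):
            m = (angle_id == aid) & (camera_id == cid)
            pos[m] = cams[int(cid)].pixel_center_world(plane, ix[m], iy[m])
    return pos


def select_compton(hits: pd.DataFrame, poses, nuclide_target) -> pd.DataFrame:
    """Select Compton events and compute their cone parameters.

    ``poses`` maps angle_id -> list of CameraGeometry (the output of
    :func:`hccimg.geometry.build_multi_angle` as a dict).  Returns one
    row per accepted event with scatter/absorb world positions, the
    energy pair and the kinematic scattering angle ``theta``.
    """
    both = _camera_summary(hits, keep=lambda f, r: (f > 0) & (r > 0))
    cand = apply_energy_cut(both, nuclide_target)
    if len(cand) == 0:
        return pd.DataFrame(
            columns=["angle_id", "event_id", "camera_id", "E_f", "E_r", "theta",
                     "scatter_x", "scatter_y", "scatter_z",
                     "absorb_x", "absorb_y", "absorb_z"]
        )
    theta = compute_scatter_angle(cand["E_f"].to_numpy(), cand["E_r"].to_numpy())
    cand = cand.assign(theta=theta)
    cand = cand[np.isfinite(cand["theta"])].reset_index(drop=True)
    aid = cand["angle_id"].to_numpy()
    cid = cand["camera_id"].to_numpy()
    sc = _positions(poses, aid, cid, "front",
                    cand["ix_f"].to_numpy(int), cand["iy_f"].to_numpy(int))
    ab = _positions(poses, aid, cid, "rear",
                    cand["ix_r"].to_numpy(int), cand["iy_r"].to_numpy(int))
    out = cand[["angle_id", "event_id", "camera_id", "E_f", "E_r", "theta"]].copy()
    out[["scatter_x", "scatter_y", "scatter_z"]] = sc
    out[["absorb_x", "absorb_y", "absorb_z"]] = ab
    return out


def select_pinhole(hits: pd.DataFrame, nuclide_target) -> pd.DataFrame:
    """Select pinhole events: rear-only cameras passing the rear window.

    Returns one row per accepted event with the rear pixel indices (the
    detector bin of the hist-mode reconstruction).
    """
    both = _camera_summary(hits, keep=lambda f, r: (f == 0) & (r > 0))
    cand = apply_energy_cut(both, nuclide_target)
    out = cand[["angle_id", "event_id", "camera_id", "E_r"]].copy()
    out["ix"] = cand["ix_r"].to_numpy(int) if len(cand) else np.array([], dtype=int)
    out["iy"] = cand["iy_r"].to_numpy(int) if len(cand) else np.array([], dtype=int)
    return out


def select_pet(hits: pd.DataFrame, poses, nuclide_target="na22") -> pd.DataFrame:
    """Pair PET events: exactly two cameras inside the energy window.

    The window is applied to each camera's total deposit separately
    (each annihilation photon).  Events with three or more qualifying
    cameras are ambiguous and discarded.  The LOR endpoint of a camera
    is the front pixel center when the camera saw a front deposit,
    otherwise the rear pixel center.
    """
    windows = target_windows(nuclide_target)
    for w in windows:
        if w.applies_to != "E_f+E_r":
            raise ValueError("PET cut must be a total-energy window")

    def in_window(f, r):
        ok = np.ones(len(f), dtype=bool)
        for w in windows:
            ok &= w.contains(f + r)
        return ok

    qual = _camera_summary(hits, keep=in_window)
    counts = qual.groupby(["angle_id", "event_id"], sort=False)["camera_id"].transform("size")
    pairs = qual[counts == 2].sort_values(["angle_id", "event_id", "camera_id"], kind="stable")
    if len(pairs) == 0:
        return pd.DataFrame(columns=["angle_id", "event_id", "E_a", "E_b",
                                     "ax", "ay", "az", "bx", "by", "bz"])
    # endpoint: front pixel if present, else rear pixel
    has_front = pairs["E_f"].to_numpy() > 0
    plane = np.where(has_front, "front", "rear")
    ix = np.where(has_front, pairs["ix_f"].to_numpy(), pairs["ix_r"].to_numpy()).astype(int)
    iy = np.where(has_front, pairs["iy_f"].to_numpy(), pairs["iy_r"].to_numpy()).astype(int)
    aid = pairs["angle_id"].to_numpy()
    cid = pairs["camera_id"].to_numpy()
    pos = np.empty((len(pairs), 3))
    for pl in ("front", "rear"):
        m = plane == pl
        if m.any():
            pos[m] = _positions(poses, aid[m], cid[m], pl, ix[m], iy[m])
    e_tot = pairs["E_f"].to_numpy() + pairs["E_r"].to_numpy()
    pa, pb = pos[0::2], pos[1::2]
    out = pd.DataFrame({
        "angle_id": aid[0::2],
        "event_id": pairs["event_id"].to_numpy()[0::2],
        "E_a": e_tot[0::2], "E_b": e_tot[1::2],
        "ax": pa[:, 0], "ay": pa[:, 1], "az": pa[:, 2],
        "bx": pb[:, 0], "by": pb[:, 1], "bz": pb[:, 2],
    })
    return out.reset_index(drop=True)
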