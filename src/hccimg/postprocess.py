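"""Image analysis: peak reports, ROI ratios, fusion, slicing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Image3D


@dataclass
class PeakReport:
    index: tuple[int, int, int]
    position_mm: np.ndarray
    value: float
    fwhm_mm: tuple[float, float, float]  # per axis, NaN if unresolved


@dataclass
class ROIStat:
    center_mm: np.ndarray
    radius_mm: float
    integral: float


def _axis_fwhm(profile: np.ndarray, peak_i: int, pitch: float) -> float:
    """Linear-interpolated FWHM of a 1-D profile around ``peak_i``."""
    half = profile[peak_i] / 2.0
    left = right = np.nan
    for i in range(peak_i, 0, -1):
        if profile[i - 1] < half <= profile[i]:
            frac = (profile[i] - half) / (profile[i] - profile[i - 1])
            left = i - frac
            break
    for i in range(peak_i, len(profile) - 1):
        if profile[i + 1] < half <= profile[i]:
            frac = (profile[i] - half) / (profile[i] - profile[i + 1])
            right = i + frac
            break
    return float((right - left) * pitch)


def find_peak(img: Image3D) -> PeakReport:
    """Argmax voxel report; ties broken by the lowest flattened index."""
    v = img.values
    if not np.any(v > 0):
        raise ValueError("cannot locate a peak in an all-zero image")
    flat = int(np.argmax(v))
    idx = np.unravel_index(flat, v.shape)
    fwhm = []
    for ax in range(3):
        sl = [idx[0], idx[1], idx[2]]
        sl[ax] = slice(None)
        fwhm.append(_axis_fwhm(v[tuple(sl)], idx[ax], img.grid.voxel_pitch))
    return PeakReport(
        index=tuple(int(i) for i in idx),
        position_mm=img.grid.index_to_world(idx),
        value=float(v[idx]),
        fwhm_mm=tuple(fwhm),
    )


def _sphere_mask(img: Image3D, center_mm, radius_mm: float) -> np.ndarray:
    centers = img.grid.centers().reshape(img.grid.shape + (3,))
    d = np.linalg.norm(centers - np.asarray(center_mm, dtype=float), axis=-1)
    return d <= radius_mm


def roi_integral(img: Image3D, center_mm, radius_mm: float) -> ROIStat:
    mask = _sphere_mask(img, center_mm, radius_mm)
    if not mask.any():
        raise ValueError("ROI contains no voxels")
    return ROIStat(
        center_mm=np.asarray(center_mm, dtype=float),
        radius_mm=radius_mm,
        integral=float(img.values[mask].sum()),
    )


def roi_ratio(img: Image3D, center_a, center_b, radius_mm: float = 6.9) -> float:
    """Ratio of integrated values in two non-overlapping spherical ROIs.

    The default radius is 3 voxels (~7 mm), matching point-like sources
    of diameter < 1 cm.
    """
    if np.linalg.norm(np.asarray(center_a, float) - np.asarray(center_b, float)) <= 2 * radius_mm:
        raise ValueError("ROIs overlap")
    denom = roi_integral(img, center_b, radius_mm).integral
    if denom == 0:
        raise ValueError("zero denominator ROI")
    return roi_integral(img, center_a, radius_mm).integral / denom


def roi_ratio_bootstrap(events, reconstruct, center_a, center_b,
                        radius_mm: float = 6.9, n_boot: int = 20, seed=None):
    """Event-level bootstrap error of the ROI ratio.

    ``reconstruct`` maps a resampled event table to an :class:`Image3D`.
    Returns (ratio, bootstrap standard deviation); the point estimate
    uses the full event set.
    """
    rng = np.random.default_rng(seed)
    ratio = roi_ratio(reconstruct(events), center_a, center_b, radius_mm)
    reps = []
    n = len(events)
    for _ in range(n_boot):
        sample = events.sample(n=n, replace=True, random_state=rng.integers(2**31))
        reps.append(roi_ratio(reconstruct(sample.reset_index(drop=True)),
                              center_a, center_b, radius_mm))
    return ratio, float(np.std(reps, ddof=1)) if n_boot > 1 else np.nan


def fuse_multimodal(images) -> tuple[np.ndarray, list[str]]:
    """Stack per-channel max-normalized images on a common grid.

    ``images`` is a list of (Image3D, channel_tag); returns the
    (n_channels, nx, ny, nz) stack and the tag order.
    """
    images = list(images)
    if not images:
        raise ValueError("no images to fuse")
    grid = images[0][0].grid
    out = []
    tags = []
    for img, tag in images:
        if img.grid != grid:
            raise ValueError("all images must share the same grid")
        peak = img.values.max()
        out.append(img.values / peak if peak > 0 else img.values)
        tags.append(tag)
    return np.stack(out), tags


def extract_slices(img: Image3D, axis: int, pitch_mm: float | None = None):
    """Ordered 2-D slices along ``axis`` at the requested pitch.

    ``pitch_mm`` must be a multiple of the voxel pitch (default: every
    voxel slice), e.g. 2.3 mm slices from one side to the other.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    vp = img.grid.voxel_pitch
    pitch_mm = vp if pitch_mm is None else float(pitch_mm)
    step = pitch_mm / vp
    if abs(step - round(step)) > 1e-9:
        raise ValueError("pitch must be a multiple of the voxel pitch")
    step = int(round(step))
    coords = img.grid.axis_centers(axis)[::step]
    slicer = [slice(None)] * 3
    slices = []
    for i in range(0, img.grid.shape[axis], step):
        slicer[axis] = i
        slices.append(img.values[tuple(slicer)].copy())
    return list(zip(coords.tolist(), slices))
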