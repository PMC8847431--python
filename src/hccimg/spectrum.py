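"""Spectral analysis and absorber-thickness estimation.

A body placed between a source and the camera attenuates low-energy
photons more strongly than high-energy ones, so the ratio of net
photopeak areas at two emission energies encodes the absorber
thickness.  For a Ba-133 source behind water the 81 keV / 356 keV
ratio follows Beer--Lambert:

    R(d) = R0 * exp(-(mu_w(81) - mu_w(356)) * d) = R0 * exp(-dmu * d)

so ``ln R`` is linear in thickness ``d``.  The calibration fits
``(ln R0, dmu)`` by weighted least squares over measured nodes and the
inversion is ``d = ln(R0 / R) / dmu`` with propagated uncertainty.

Photopeak areas are net areas from a Gaussian + local linear background
fit, which is robust against the Compton continuum that grows with
absorber thickness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import events as ev


@dataclass
class Spectrum:
    """Energy histogram of per-event deposited energy."""

    edges: np.ndarray  # keV, len = n_bins + 1
    counts: np.ndarray
    live_time: float = 1.0  # s

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("counts/edges length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if not np.array_equal(self.edges, other.edges):
            raise ValueError("cannot add spectra with different binning")
        return Spectrum(self.edges, self.counts + other.counts,
                        self.live_time + other.live_time)


def histogram_spectrum(hits: pd.DataFrame, edges=None, live_time: float = 1.0,
                       camera_id=None, window_ns: float = ev.DEFAULT_COINCIDENCE_WINDOW_NS) -> Spectrum:
    """Histogram of per-event total deposited energy (per camera).

    Hits are coincidence-grouped if no ``event_id`` column is present;
    the summed front+rear deposit of each (event, camera) is one
    spectrum entry.  ``edges`` defaults to 1 keV bins over 0-800 keV.
    """
    if edges is None:
        edges = np.arange(0.0, 801.0, 1.0)
    edges = np.asarray(edges, dtype=float)
    if len(hits) == 0:
        return Spectrum(edges, np.zeros(len(edges) - 1), live_time)
    df = hits
    if "event_id" not in df.columns:
        df = ev.group_coincidences(df.sort_values("time_ns", kind="stable").reset_index(drop=True),
                                   window_ns)
    if camera_id is not None:
        df = df[df["camera_id"] == camera_id]
    eid = df["event_id"].to_numpy(np.int64)
    cid = df["camera_id"].to_numpy(np.int64)
    n_cam = int(cid.max()) + 1 if len(cid) else 1
    key = eid * n_cam + cid
    key = np.unique(key, return_inverse=True)[1]
    totals = np.bincount(key, weights=df["energy_kev"].to_numpy())
    counts, _ = np.histogram(totals, bins=edges)
    return Spectrum(edges, counts.astype(float), live_time)


def write_spectrum_csv(spec: Spectrum, path):
    """Two-column CSV export (keV bin center, counts)."""
    with open(path, "w") as f:
        f.write("energy_kev,counts\n")
        for c, n in zip(spec.centers, spec.counts):
            f.write(f"{c},{n}\n")


def read_spectrum_csv(path) -> Spectrum:
    df = pd.read_csv(path)
    centers = df["energy_kev"].to_numpy(dtype=float)
    width = centers[1] - centers[0]
    edges = np.append(centers - width / 2.0, centers[-1] + width / 2.0)
    return Spectrum(edges, df["counts"].to_numpy(dtype=float))


@dataclass
class PhotopeakFit:
    centroid: float  # keV
    sigma: float  # keV
    area: float  # net counts
    area_err: float
    background: tuple[float, float]  # linear background (intercept, slope)
    window: tuple[float, float]


def fit_photopeak(spec: Spectrum, e0: float, window,
                  expected_sigma: float | None = None) -> PhotopeakFit:
    """Gaussian + linear-background least squares around ``e0``.

    ``window`` is the half-width in keV, or a ``(below, above)`` pair
    for an asymmetric window (useful to exclude a neighbouring line on
    one side).  The net area is the integral of the Gaussian component
    in counts.  When ``expected_sigma`` (keV) is given — e.g. from the
    detector resolution model — the fitted width is constrained to
    within 25 % of it, which stabilises the area estimate without
    biasing area *ratios* (the peak shape is thickness-independent).
    """
    try:
        w_lo, w_hi = window
    except TypeError:
        w_lo = w_hi = float(window)
    lo, hi = e0 - w_lo, e0 + w_hi
    m = (spec.centers >= lo) & (spec.centers <= hi)
    if m.sum() < 5:
        raise ValueError("window must cover at least 5 bins")
    x = spec.centers[m]
    y = spec.counts[m]
    if y.sum() == 0:
        raise ValueError(f"no counts in the fit window around {e0} keV")

    def model(x, amp, mu, sig, b0, b1):
        return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2) + b0 + b1 * (x - e0)

    base = 0.5 * (y[0] + y[-1])
    if expected_sigma is not None:
        sig_lo, sig_hi = 0.75 * expected_sigma, 1.25 * expected_sigma
        sig0 = expected_sigma
    else:
        sig_lo, sig_hi = spec.bin_width / 2.0, max(w_lo, w_hi)
        sig0 = max(0.03 * e0, spec.bin_width)
    p0 = [max(y.max() - base, 1.0), e0, sig0, base, 0.0]
    bounds = ([0.0, lo, sig_lo, -np.inf, -np.inf],
              [np.inf, hi, sig_hi, np.inf, np.inf])
    # two-pass weighting: first with raw-count weights, then with
    # model-predicted weights (avoids the low-count bias of weighting
    # by the observed bins themselves)
    sigma_y = np.sqrt(np.maximum(y, 1.0))
    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, sigma=sigma_y,
                               absolute_sigma=True, bounds=bounds, maxfev=20000)
        sigma_y = np.sqrt(np.maximum(model(x, *popt), 1.0))
        popt, pcov = curve_fit(model, x, y, p0=popt, sigma=sigma_y,
                               absolute_sigma=True, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"photopeak fit at {e0} keV did not converge: {exc}"
        ) from exc
    amp, mu, sig, b0, b1 = popt
    scale = np.sqrt(2.0 * np.pi) / spec.bin_width
    area = amp * sig * scale
    var = (
        (sig * scale) ** 2 * pcov[0, 0]
        + (amp * scale) ** 2 * pcov[2, 2]
        + 2.0 * (sig * scale) * (amp * scale) * pcov[0, 2]
    )
    return PhotopeakFit(
        centroid=float(mu), sigma=float(sig), area=float(area),
        area_err=float(np.sqrt(max(var, 0.0))),
        background=(float(b0), float(b1)), window=(lo, hi),
    )


@dataclass
class CalibrationCurve:
    """Log-linear photopeak-ratio vs thickness calibration."""

    thickness_cm: np.ndarray
    ratios: np.ndarray
    ratio_errs: np.ndarray
    ln_r0: float
    delta_mu: float  # cm^-1, > 0 for a decreasing ratio
    cov: np.ndarray  # 2x2 covariance of (ln_r0, delta_mu)

    @property
    def r0(self) -> float:
        return float(np.exp(self.ln_r0))

    def ratio_at(self, thickness_cm):
        return np.exp(self.ln_r0 - self.delta_mu * np.asarray(thickness_cm))


DEFAULT_PEAKS = (81.0, 356.0)
#: fit windows (keV below, keV above) chosen to exclude the 53 keV and
#: 303 keV satellite lines while keeping background leverage
DEFAULT_WINDOWS = ((15.0, 24.0), (26.0, 48.0))


def peak_ratio(spec: Spectrum, peaks=DEFAULT_PEAKS, windows=DEFAULT_WINDOWS,
               expected_sigmas=None):
    """Net-area photopeak ratio area(peaks[0]) / area(peaks[1]).

    Returns ``(ratio, error)`` with the error propagated from both fits.
    """
    sig = expected_sigmas or (None, None)
    f_lo = fit_photopeak(spec, peaks[0], windows[0], expected_sigma=sig[0])
    f_hi = fit_photopeak(spec, peaks[1], windows[1], expected_sigma=sig[1])
    r = f_lo.area / f_hi.area
    return r, r * np.hypot(f_lo.area_err / f_lo.area, f_hi.area_err / f_hi.area)


def build_calibration(thicknesses_cm, spectra, peaks=DEFAULT_PEAKS,
                      windows=DEFAULT_WINDOWS, expected_sigmas=None) -> CalibrationCurve:
    """Fit the ratio-vs-thickness calibration from node spectra.

    ``spectra[i]`` was measured behind ``thicknesses_cm[i]`` of water.
    The ratio area(peaks[0]) / area(peaks[1]) is computed per node and
    ln R is fitted against thickness by weighted least squares.
    """
    d = np.asarray(thicknesses_cm, dtype=float)
    if len(set(d.tolist())) < 3:
        raise ValueError("need at least 3 distinct thickness nodes")
    if len(d) != len(spectra):
        raise ValueError("one spectrum per thickness required")
    ratios, errs = [], []
    for spec in spectra:
        r, e = peak_ratio(spec, peaks, windows, expected_sigmas)
        ratios.append(r)
        errs.append(e)
    ratios = np.array(ratios)
    errs = np.array(errs)
    order = np.argsort(d)
    viol = np.diff(ratios[order]) - 3.0 * np.hypot(errs[order][:-1], errs[order][1:])
    if np.any(viol > 0):
        warnings.warn("photopeak ratio is not monotonically decreasing "
                      "beyond noise tolerance", stacklevel=2)
    ln_r = np.log(ratios)
    w = (ratios / errs) ** 2  # var(ln R) = (err/R)^2
    design = np.stack([np.ones_like(d), -d], axis=1)
    wd = design * w[:, None]
    ata = design.T @ wd
    atb = wd.T @ ln_r
    coef = np.linalg.solve(ata, atb)
    cov = np.linalg.inv(ata)
    return CalibrationCurve(
        thickness_cm=d, ratios=ratios, ratio_errs=errs,
        ln_r0=float(coef[0]), delta_mu=float(coef[1]), cov=cov,
    )


def estimate_thickness(ratio: float, curve: CalibrationCurve,
                       ratio_err: float = 0.0, tol_sigma: float = 3.0):
    """Invert the calibration: d = ln(R0 / ratio) / dmu, with error.

    Raises if the measured ratio exceeds R0 beyond ``tol_sigma`` times
    its uncertainty (negative thickness).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    d = (curve.ln_r0 - np.log(ratio)) / curve.delta_mu
    if d < 0 and (curve.r0 - ratio) < -tol_sigma * max(ratio_err, 1e-300):
        raise ValueError("measured ratio above R0: negative thickness")
    jac = np.array([1.0 / curve.delta_mu, -d / curve.delta_mu])
    var = jac @ curve.cov @ jac
    var += (ratio_err / (ratio * curve.delta_mu)) ** 2
    return float(d), float(np.sqrt(max(var, 0.0)))
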