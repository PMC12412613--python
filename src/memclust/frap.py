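"""FRAP analysis: trace normalization, effective bleach radius,
recovery half-time and diffusion coefficient.

The diffusion coefficient follows the standard confocal-FRAP protocol
D = (re^2 + rn^2) / (8 * tau_half), where rn is the nominal bleach ROI
radius, re the effective radius fitted from the first post-bleach
radial profile f(x) = 1 - K exp(-2 x^2 / re^2), and tau_half the
half-time of the recovery. The formula is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import interpolate, optimize

__all__ = [
    "FrapSeries",
    "roi_trace",
    "normalize_trace",
    "effective_radius",
    "half_time",
    "diffusion_coefficient",
    "analyze_frap",
]


@dataclass
class FrapSeries:
    """Fitted FRAP result for one position."""

    times: np.ndarray  # s, post-bleach times (first frame at 0)
    trace: np.ndarray  # normalized ROI intensities (incl. pre-bleach)
    rn: float  # nominal bleach ROI radius, um
    re: float  # effective radius, um
    tau_half: float  # s
    tau_half_ci: tuple[float, float]  # 95% CI
    diffusion: float  # um^2/s
    plateau: float
    bleach_floor: float


def roi_trace(
    frames: np.ndarray,
    center: tuple[float, float],
    radius_px: float,
    mode: str = "disk",
) -> np.ndarray:
    """Mean intensity inside the bleach ROI per frame.

    ``mode='disk'`` averages a hard disk of ``radius_px``;
    ``mode='gaussian'`` uses a Gaussian aperture exp(-2 r^2 / radius^2).
    """
    frames = np.asarray(frames, dtype=float)
    yy, xx = np.indices(frames.shape[1:])
    rr = np.hypot(yy - center[0], xx - center[1])
    if mode == "disk":
        sel = rr <= radius_px
        if not sel.any():
            raise ValueError("ROI contains no pixels")
        return frames[:, sel].mean(axis=1)
    if mode == "gaussian":
        w = np.exp(-2.0 * rr**2 / radius_px**2)
        return (frames * w).sum(axis=(1, 2)) / w.sum()
    raise ValueError("mode must be 'disk' or 'gaussian'")


def normalize_trace(
    raw: np.ndarray,
    n_prebleach: int,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Divide the trace by its mean pre-bleach intensity.

    With ``reference`` (a reference-ROI trace) given, the trace is first
    divided by the reference's relative intensity to correct global
    observational photobleaching (off by default in the pipeline).
    """
    raw = np.asarray(raw, dtype=float)
    if n_prebleach < 3:
        raise ValueError("need at least 3 pre-bleach frames")
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        ref_pre = reference[:n_prebleach].mean()
        if ref_pre == 0:
            raise ValueError("zero reference pre-bleach mean")
        raw = raw / (reference / ref_pre)
    pre = raw[:n_prebleach].mean()
    if pre == 0:
        raise ValueError("zero pre-bleach mean intensity")
    return raw / pre


def effective_radius(
    postbleach_frame: np.ndarray,
    roi_center: tuple[float, float],
    pixel_size: float,
) -> float:
    """Effective bleach radius re (um) from the first post-bleach frame.

    The radial average f(x) about the ROI center is fitted with
    f(x) = 1 - K exp(-2 x^2 / re^2).
    """
    frame = np.asarray(postbleach_frame, dtype=float)
    yy, xx = np.indices(frame.shape)
    rr = np.hypot(yy - roi_center[0], xx - roi_center[1]) * pixel_size
    r_edges = np.arange(0.0, rr.max(), pixel_size)
    idx = np.digitize(rr.ravel(), r_edges)
    prof, rads = [], []
    flat = frame.ravel()
    for i in range(1, r_edges.size):
        sel = idx == i
        if sel.any():
            prof.append(flat[sel].mean())
            rads.append(0.5 * (r_edges[i - 1] + r_edges[i]))
    rads, prof = np.asarray(rads), np.asarray(prof)

    def model(x, k, re):
        return 1.0 - k * np.exp(-2.0 * x**2 / re**2)

    depth0 = 1.0 - prof.min()
    if depth0 < 0.02:
        raise RuntimeError("no discernible bleach; effective-radius fit degenerate")
    try:
        popt, _ = optimize.curve_fit(
            model, rads, prof, p0=(depth0, rads[np.argmin(np.abs(prof - (1 - depth0 / 2)))]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"effective-radius fit diverged; profile head: {prof[:10]!r}"
        ) from exc
    return abs(float(popt[1]))


def _exp_model(t, f_inf, f0, tau):
    return f_inf - (f_inf - f0) * np.exp(-t * math.log(2.0) / tau)


def half_time(
    trace: np.ndarray,
    times: np.ndarray,
    method: str = "exp",
) -> tuple[float, tuple[float, float], float, float]:
    """Half-time of post-bleach recovery.

    ``method='exp'`` (default) fits F(t) = Finf - (Finf - F0) *
    exp(-t ln2 / tau_half); ``method='interp'`` locates the half-recovery
    crossing on a monotone interpolant. Returns
    ``(tau_half, (ci_lo, ci_hi), plateau, floor)``.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.shape != times.shape:
        raise ValueError("trace and times must align")
    f0 = trace[0]
    plateau_est = trace[-3:].mean()
    if plateau_est - f0 < 0.02:
        if np.ptp(trace) < 0.05 and f0 > 0.8:
            # already at the pre-bleach level: recovery faster than sampling
            warnings.warn("recovery complete within first frame; tau bounded by dt")
            dt = times[1] - times[0] if times.size > 1 else 0.0
            return dt, (0.0, dt), float(plateau_est), float(f0)
        raise RuntimeError("trace never recovers; cannot determine half-time")
    half_level = 0.5 * (f0 + plateau_est)
    if trace.max() < half_level:
        raise RuntimeError("trace does not reach half recovery")

    if method == "exp":
        popt, pcov = optimize.curve_fit(
            _exp_model, times, trace, p0=(plateau_est, f0, max(times[1], 1.0)),
            maxfev=20000,
        )
        tau = abs(float(popt[2]))
        err = float(np.sqrt(np.abs(pcov[2, 2])))
        return tau, (tau - 1.96 * err, tau + 1.96 * err), float(popt[0]), float(popt[1])
    if method == "interp":
        interpolant = interpolate.PchipInterpolator(times, trace)
        grid = np.linspace(times[0], times[-1], 20001)
        vals = interpolant(grid)
        above = np.flatnonzero(vals >= half_level)
        tau = float(grid[above[0]])
        dt = float(np.max(np.diff(times)))
        return tau, (max(tau - dt, 0.0), tau + dt), float(plateau_est), float(f0)
    raise ValueError("method must be 'exp' or 'interp'")


def diffusion_coefficient(
    re: float,
    rn: float,
    tau_half: float,
    formula: Callable[[float, float, float], float] | None = None,
) -> float:
    """D in um^2/s from the adopted protocol: D = (re^2 + rn^2)/(8 tau)."""
    if re <= 0 or rn <= 0:
        raise ValueError("radii must be positive")
    if tau_half <= 0:
        raise ValueError("tau_half must be positive")
    if formula is not None:
        return float(formula(re, rn, tau_half))
    return (re**2 + rn**2) / (8.0 * tau_half)


def analyze_frap(
    frames: np.ndarray,
    times: np.ndarray,
    roi_center: tuple[float, float],
    rn: float,
    pixel_size: float,
    method: str = "exp",
) -> FrapSeries:
    """Full single-position FRAP pipeline.

    ``times`` span the whole series with the bleach at t = 0 (negative
    times are pre-bleach frames); lengths in um.
    """
    times = np.asarray(times, dtype=float)
    pre = times < 0
    if pre.sum() < 3:
        raise ValueError("need at least 3 pre-bleach frames")
    raw = roi_trace(frames, roi_center, rn / pixel_size, mode="disk")
    norm = normalize_trace(raw, int(pre.sum()))
    post = ~pre
    re = effective_radius(frames[post][0], roi_center, pixel_size)
    tau, ci, plateau, floor = half_time(norm[post], times[post], method=method)
    d = diffusion_coefficient(re, rn, tau)
    return FrapSeries(
        times=times[post], trace=norm, rn=rn, re=re, tau_half=tau,
        tau_half_ci=ci, diffusion=d, plateau=plateau, bleach_floor=floor,
    )
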