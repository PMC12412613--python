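"""Cluster boundary dynamics in polar coordinates.

Radial profiles R(theta, t) of a tracked cluster mask, radius-change
maps, the mean leading-edge velocity, and line-tension estimation from
the capillary-wave Fourier spectrum of the boundary fluctuations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ClusterTrace",
    "TensionFit",
    "radial_profile",
    "radius_change",
    "mean_leading_edge_velocity",
    "fit_line_tension",
]

DEFAULT_DTHETA = 2.0 * math.pi / 180.0  # 2 degree bins


@dataclass
class ClusterTrace:
    """Time-resolved polar radial profile R(theta, t) of one cluster.

    ``radii`` has shape (n_frames, n_theta) in nm; ``theta`` covers
    [0, 2*pi) uniformly; ``frame_interval`` is the frame spacing in s.
    """

    theta: np.ndarray
    radii: np.ndarray
    frame_interval: float
    centers: np.ndarray | None = None  # (n_frames, 2) nm, optional
    masks: np.ndarray | None = None  # (T, H, W) bool, optional

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.radii = np.atleast_2d(np.asarray(self.radii, dtype=float))
        if self.radii.shape[1] != self.theta.size:
            raise ValueError("radii and theta grids disagree")
        if np.any(self.radii <= 0):
            raise ValueError("radial profile must be strictly positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        dth = np.diff(self.theta)
        if self.theta.size > 1 and not np.allclose(dth, dth[0]):
            raise ValueError("theta grid must be uniform")

    @property
    def n_frames(self) -> int:
        return self.radii.shape[0]

    @property
    def dtheta(self) -> float:
        return 2.0 * math.pi / self.theta.size

    @classmethod
    def from_masks(
        cls,
        masks: np.ndarray,
        pixel_size: float,
        frame_interval: float,
        dtheta: float = DEFAULT_DTHETA,
    ) -> "ClusterTrace":
        """Build a trace from a (T, H, W) boolean mask stack.

        Each frame is referenced to its own center of mass, which makes
        the downstream statistics invariant to rigid translations.
        """
        masks = np.asarray(masks, dtype=bool)
        n_theta = int(round(2.0 * math.pi / dtheta))
        theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
        radii = np.empty((masks.shape[0], n_theta))
        centers = np.empty((masks.shape[0], 2))
        for t, m in enumerate(masks):
            cy, cx = ndimage.center_of_mass(m)
            centers[t] = (cx * pixel_size, cy * pixel_size)
            radii[t] = radial_profile(m, (cx, cy), dtheta) * pixel_size
        return cls(
            theta=theta, radii=radii, frame_interval=frame_interval,
            centers=centers, masks=masks,
        )


@dataclass
class TensionFit:
    """Result of the boundary-fluctuation line-tension fit."""

    modes: np.ndarray  # k values (>= 2)
    mean_sq_amplitude: np.ndarray  # <a_k^2 + b_k^2> per mode
    r0: float  # mean radius, nm
    line_tension: float  # kB*T / nm (inf if no fluctuation)
    slope: float  # fitted 1/lambda
    slope_ols: float  # unweighted through-origin slope
    r_squared: float
    residuals: np.ndarray
    loglog_slope: float  # slope of log<a^2+b^2> vs log(k^2-1); -1 expected
    n_frames: int
    infinite_tension: bool = False


def radial_profile(
    mask: np.ndarray,
    center: tuple[float, float],
    dtheta: float = DEFAULT_DTHETA,
    radial_step: float = 0.25,
    max_empty_fraction: float = 0.25,
) -> np.ndarray:
    """Radius of the mask boundary along each angular bin, in pixels.

    Along each ray the mask is sampled at sub-pixel steps; the radius is
    the outer end of the inside-run containing the center when the shape
    is star-convex in that bin, otherwise the outer end of the longest
    (most probable) inside-run. Empty bins are interpolated from their
    neighbors; traces with more than ``max_empty_fraction`` empty bins
    are rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    cx, cy = center
    iy, ix = int(round(cy)), int(round(cx))
    if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]) or not mask[iy, ix]:
        raise ValueError("center must lie inside the mask")
    n_theta = int(round(2.0 * math.pi / dtheta))
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    r_max = math.hypot(*mask.shape) + 1.0
    rs = np.arange(0.0, r_max, radial_step)

    xs = cx + np.outer(np.cos(theta), rs)  # (n_theta, n_r)
    ys = cy + np.outer(np.sin(theta), rs)
    inside = ndimage.map_coordinates(
        mask.astype(np.uint8), [ys.ravel(), xs.ravel()], order=0, mode="constant", cval=0
    ).reshape(n_theta, rs.size).astype(bool)

    radii = np.full(n_theta, np.nan)
    for i in range(n_theta):
        v = inside[i]
        if not v[0]:
            continue  # empty bin (center sample off-mask after rounding)
        # run-length encode
        change = np.flatnonzero(np.diff(v.astype(np.int8)))
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change, [v.size - 1]))
        run_inside = v[starts]
        ins_starts, ins_ends = starts[run_inside], ends[run_inside]
        if ins_starts.size == 1:
            j = 0  # star-convex in this bin: outermost crossing
        else:
            j = int(np.argmax(ins_ends - ins_starts))  # modal (dominant) run
        radii[i] = rs[ins_ends[j]] + 0.5 * radial_step

    empty = np.isnan(radii)
    if empty.mean() > max_empty_fraction:
        raise ValueError(
            f"{empty.mean():.0%} of angular bins empty; trace rejected"
        )
    if empty.any():
        good = ~empty
        radii[empty] = np.interp(
            theta[empty], theta[good], radii[good], period=2.0 * math.pi
        )
    return radii


def radius_change(trace: ClusterTrace) -> np.ndarray:
    """Delta R(theta, t) = R(theta, t + dt) - R(theta, t), shape (T-1, n_theta)."""
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames")
    return np.diff(trace.radii, axis=0)


def mean_leading_edge_velocity(trace: ClusterTrace) -> float:
    """Time- and angle-averaged absolute boundary displacement rate, nm/s.

    mu_v = mean over frame pairs and angular bins of |Delta R| / dt,
    i.e. the (dtheta / 2 pi) angular sum of |Delta R| averaged over all
    consecutive frame pairs, per frame interval.
    """
    dr = radius_change(trace)
    return float(np.mean(np.abs(dr)) / trace.frame_interval)


def fourier_coefficients(u: np.ndarray, theta: np.ndarray, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Fourier cosine/sine coefficients of u(theta) for modes k = 2..kmax.

    a_k = (2/N) sum u cos(k theta), b_k likewise; returns arrays of shape
    (n_frames, kmax-1).
    """
    u = np.atleast_2d(u)
    n = theta.size
    ks = np.arange(2, kmax + 1)
    cos = np.cos(np.outer(ks, theta))
    sin = np.sin(np.outer(ks, theta))
    a = (2.0 / n) * u @ cos.T
    b = (2.0 / n) * u @ sin.T
    return a, b


def fit_line_tension(
    trace: ClusterTrace,
    temperature: float = 298.0,
    kmax: int = 12,
    normalization: str = "profile",
) -> TensionFit:
    """Line tension from the capillary-wave spectrum of boundary modes.

    Per frame, the normalized radial profile R(theta, t) / r0 is expanded
    in a Fourier series; the per-mode mean squared amplitude
    <a_k^2 + b_k^2> over frames is regressed through the origin against
    2 / (pi * r0 * (k^2 - 1)); the inverse slope is the line tension in
    kB*T / nm at the given temperature (temperature cancels because the
    tension is reported in thermal units).

    ``normalization='difference'`` instead expands the frame-difference
    ratio (R(t+dt) - R(t)) / R(t), offered for comparison only — the
    equipartition relation applies to instantaneous shape deviations.
    """
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if trace.n_frames < 50:
        warnings.warn("fewer than 50 frames; line-tension estimate will be noisy")
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if 2 * kmax >= trace.theta.size:
        raise ValueError("kmax too large for the angular grid")

    r0 = float(trace.radii.mean())
    if normalization == "profile":
        u = trace.radii / r0
    elif normalization == "difference":
        u = np.diff(trace.radii, axis=0) / trace.radii[:-1]
    else:
        raise ValueError("normalization must be 'profile' or 'difference'")

    a, b = fourier_coefficients(u, trace.theta, kmax)
    msq = np.mean(a**2 + b**2, axis=0)  # <a_k^2 + b_k^2>
    ks = np.arange(2, kmax + 1)
    x = 2.0 / (math.pi * r0 * (ks.astype(float) ** 2 - 1.0))

    if np.all(msq < 1e-20):  # numerically zero fluctuation
        return TensionFit(
            modes=ks, mean_sq_amplitude=msq, r0=r0, line_tension=math.inf,
            slope=0.0, slope_ols=0.0, r_squared=1.0, residuals=np.zeros_like(msq),
            loglog_slope=math.nan, n_frames=trace.n_frames, infinite_tension=True,
        )

    # weighted through-origin regression: each mode's msq has relative
    # error ~ 1/sqrt(n_frames), so weights 1/x^2 equalize them -> the
    # slope is the mean per-mode ratio
    slope = float(np.mean(msq / x))
    slope_ols = float(np.sum(x * msq) / np.sum(x * x))
    if slope <= 0:
        raise RuntimeError("non-positive fitted slope; fluctuation fit failed")
    residuals = msq - slope * x
    ss_tot = float(np.sum((msq - msq.mean()) ** 2))
    r_sq = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else 1.0
    with np.errstate(divide="ignore"):
        valid = msq > 0
        loglog = (
            float(np.polyfit(np.log(ks[valid] ** 2 - 1.0), np.log(msq[valid]), 1)[0])
            if valid.sum() >= 2 else math.nan
        )
    return TensionFit(
        modes=ks, mean_sq_amplitude=msq, r0=r0, line_tension=1.0 / slope,
        slope=slope, slope_ols=slope_ols, r_squared=r_sq, residuals=residuals,
        loglog_slope=loglog, n_frames=trace.n_frames,
    )
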