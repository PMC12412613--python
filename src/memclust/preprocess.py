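"""Frame conditioning and segmentation for topography movies.

Flattening, drift alignment, isodata (intermeans) thresholding, the
three-frame walking average used to denoise mask stacks, three-class
surface-coverage fractions, and selection of isolated cluster traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label
from skimage.registration import phase_cross_correlation

__all__ = [
    "TopographyMovie",
    "MaskStack",
    "flatten_frame",
    "align_frames",
    "isodata_threshold",
    "walking_average",
    "surface_coverage",
    "select_isolated_clusters",
]


@dataclass
class TopographyMovie:
    """Calibrated height-map stack.

    frames are in nm, ``pixel_size`` in nm/px, ``frame_interval`` in s.
    ``timestamps`` default to ``frame_interval * arange(n_frames)``.
    """

    frames: np.ndarray  # (T, H, W) float, nm
    pixel_size: float  # nm / px
    frame_interval: float  # s
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.timestamps is None:
            self.timestamps = self.frame_interval * np.arange(self.n_frames)
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.n_frames,):
                raise ValueError("timestamps length must match frame count")
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class MaskStack:
    """Binary cluster masks per frame plus the thresholds that produced them."""

    masks: np.ndarray  # (T, H, W) bool
    thresholds: np.ndarray | None = None  # nm, per frame

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (T, H, W) stack")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


def isodata_threshold(frame: np.ndarray, tol: float = 1e-6, max_iter: int = 100) -> float:
    """Iterative intermeans ('isodata') threshold.

    t_{i+1} = (mean(px <= t_i) + mean(px > t_i)) / 2, iterated to a fixed
    point. Raises on (near-)constant input where no split exists.
    """
    values = np.asarray(frame, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    if not np.isfinite(vmin) or not np.isfinite(vmax):
        raise ValueError("frame contains non-finite values")
    if vmax - vmin <= tol:
        raise ValueError("degenerate input: frame has no intensity contrast")
    t = 0.5 * (vmin + vmax)
    for _ in range(max_iter):
        lo = values[values <= t]
        hi = values[values > t]
        if hi.size == 0:  # threshold drifted above all data
            t = vmax - tol
            continue
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) <= tol:
            return float(t_new)
        t = t_new
    return float(t)


def flatten_frame(frame: np.ndarray, degree: int = 1) -> np.ndarray:
    """Remove per-scan-line polynomial background, referencing the membrane.

    The background model (degree <= 1 polynomial per scan line) is fitted
    only to pixels below the frame's isodata threshold so that protein
    does not bias the fit; afterwards the median background level is set
    to zero. Scan lines without enough background pixels fall back to a
    whole-line fit.
    """
    if degree not in (0, 1):
        raise ValueError("degree must be 0 or 1")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2D array")
    try:
        thresh = isodata_threshold(frame)
        background = frame <= thresh
    except ValueError:
        # constant frame: offset removal only
        return frame - np.median(frame)

    out = np.empty_like(frame)
    x = np.arange(frame.shape[1], dtype=float)
    n_fallback = 0
    for i, row in enumerate(frame):
        sel = background[i]
        if sel.sum() < degree + 2:
            sel = np.ones_like(sel)
            n_fallback += 1
        coeffs = np.polyfit(x[sel], row[sel], degree)
        out[i] = row - np.polyval(coeffs, x)
    if n_fallback == frame.shape[0]:
        warnings.warn("frame entirely foreground; fell back to whole-line fits")
    bg_after = out[background] if background.any() else out
    return out - np.median(bg_after)


def align_frames(
    movie: TopographyMovie, upsample_factor: int = 20
) -> tuple[TopographyMovie, np.ndarray]:
    """Translate frames onto a running reference by cross-correlation.

    Each frame is registered against the previously aligned frame
    (robust to slow shape change). Returns the aligned movie and the
    per-frame cumulative drift in pixels, shape (T, 2) as (dy, dx).
    """
    frames = movie.frames
    if frames.shape[0] < 1:
        raise ValueError("empty movie")
    aligned = np.empty_like(frames)
    aligned[0] = frames[0]
    drift = np.zeros((frames.shape[0], 2))
    for t in range(1, frames.shape[0]):
        ref = aligned[t - 1]
        if np.ptp(ref) == 0 or np.ptp(frames[t]) == 0:
            warnings.warn(f"frame {t}: no contrast, assuming zero shift")
            shift = np.zeros(2)
        else:
            shift, _, _ = phase_cross_correlation(
                ref, frames[t], upsample_factor=upsample_factor, normalization=None
            )
        drift[t] = -shift  # drift of the sample; correction is +shift
        aligned[t] = ndimage.shift(frames[t], shift, order=1, mode="nearest")
    out = TopographyMovie(
        frames=aligned,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        timestamps=movie.timestamps.copy(),
    )
    return out, drift


def walking_average(masks: MaskStack, window: int = 3) -> MaskStack:
    """Temporal majority vote over a sliding window, then hole filling.

    A pixel is kept when present in the majority of the ``window``
    consecutive frames centered on t (>= 2 of 3 for the default).
    Window shrinks at the stack ends. Enclosed background is filled so
    masks contain no gap pixels.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    stack = masks.masks
    n = stack.shape[0]
    if n < window:
        raise ValueError(f"need at least {window} frames")
    half = window // 2
    out = np.empty_like(stack)
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        counts = stack[lo:hi].sum(axis=0)
        need = (hi - lo) // 2 + 1
        out[t] = counts >= need
    for t in range(n):
        out[t] = ndimage.binary_fill_holes(out[t])
    return MaskStack(masks=out, thresholds=None if masks.thresholds is None else masks.thresholds.copy())


def surface_coverage(
    frame: np.ndarray, levels: dict[str, float] | None = None
) -> dict[str, float]:
    """Fractions of pixels classified as protein / lipid / mica.

    With ``levels`` given (nominal heights per class), pixels are assigned
    to the nearest level. Otherwise two stacked isodata splits are used:
    first mica | rest, then lipid | protein within the upper class. The
    three fractions always sum to 1.
    """
    frame = np.asarray(frame, dtype=float)
    n = frame.size
    if levels is not None:
        names = ("mica", "lipid", "protein")
        centers = np.array([levels[k] for k in names])
        idx = np.argmin(np.abs(frame.ravel()[:, None] - centers[None, :]), axis=1)
        return {k: float(np.sum(idx == i)) / n for i, k in enumerate(names)}

    try:
        t1 = isodata_threshold(frame)
    except ValueError:
        warnings.warn("frame has <2 distinguishable levels; classifying all as lipid")
        return {"mica": 0.0, "lipid": 1.0, "protein": 0.0}
    upper = frame > t1
    try:
        t2 = isodata_threshold(frame[upper])
    except ValueError:
        warnings.warn("upper class not separable; merging lipid and protein")
        return {
            "mica": float(np.sum(~upper)) / n,
            "lipid": float(np.sum(upper)) / n,
            "protein": 0.0,
        }
    mica = ~upper
    protein = upper & (frame > t2)
    lipid = upper & ~protein
    return {
        "mica": float(mica.sum()) / n,
        "lipid": float(lipid.sum()) / n,
        "protein": float(protein.sum()) / n,
    }


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def select_isolated_clusters(masks: MaskStack) -> list[np.ndarray]:
    """Track connected components and keep only clean, full-span traces.

    A trace is rejected when its component merges with another trace,
    splits into several components, disappears, or touches the image
    border in any frame. Each accepted trace is returned as a boolean
    (T, H, W) stack containing only that cluster.
    """
    stack = masks.masks
    n = stack.shape[0]
    labels0, n0 = label(stack[0], return_num=True, connectivity=2)
    traces: dict[int, list[np.ndarray]] = {}
    alive: dict[int, np.ndarray] = {}
    for i in range(1, n0 + 1):
        m = labels0 == i
        traces[i] = [m]
        alive[i] = m

    rejected: set[int] = set()
    for t in range(1, n):
        lab, ncomp = label(stack[t], return_num=True, connectivity=2)
        # which components does each live trace overlap?
        claims: dict[int, list[int]] = {}
        for tid, prev in alive.items():
            comps = np.unique(lab[prev])
            comps = comps[comps > 0]
            claims[tid] = list(comps)
        # merge: one component claimed by several traces
        owners: dict[int, list[int]] = {}
        for tid, comps in claims.items():
            for c in comps:
                owners.setdefault(c, []).append(tid)
        for tid, comps in claims.items():
            if len(comps) != 1:  # vanished or split
                rejected.add(tid)
            elif len(owners[comps[0]]) > 1:  # merged
                rejected.add(tid)
        for tid in rejected:
            alive.pop(tid, None)
        for tid in list(alive):
            m = lab == claims[tid][0]
            traces[tid].append(m)
            alive[tid] = m

    accepted = []
    for tid, frames_list in traces.items():
        if tid in rejected or len(frames_list) != n:
            continue
        trace = np.stack(frames_list)
        if any(_touches_border(m) for m in trace):
            continue
        accepted.append(trace)
    if not accepted:
        warnings.warn("no isolated cluster trace survived selection")
    return accepted
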