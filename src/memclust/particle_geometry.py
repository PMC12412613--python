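"""Protomer-resolved single-particle geometry.

Rotational symmetrization with internal-symmetry-value (isv) centering,
angular-harmonic symmetry classification, tilt-plane analysis, Delaunay
neighbor pairs, signed interaction angles, angle density maps and
center-to-center distance statistics.

Angle convention: signed interaction angles are measured from the
center-to-center connection line to the closest protomer, positive when
the protomer lies clockwise of the line (with the y-axis pointing up),
bounded by +-180/nf degrees. Ties at the boundary resolve to +.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal, spatial, stats

__all__ = [
    "Particle",
    "NeighborPair",
    "refine_particle",
    "classify_symmetry",
    "tilt_angle",
    "delaunay_pairs",
    "interaction_angles",
    "signed_protomer_angle",
    "angle_density_map",
    "distance_stats",
    "compare_distance_populations",
    "classify_edge_center",
    "DistanceStats",
]

ISV_FLOOR = 0.5


@dataclass
class Particle:
    """A refined oligomeric particle."""

    center: np.ndarray  # (x, y), same units as input coordinates
    nf: int
    protomers: np.ndarray  # (nf, 2) positions
    protomer_heights: np.ndarray  # (nf,)
    isv: float  # internal symmetry value in [-1, 1]
    tilt: float | None = None  # degrees, in [0, 90]
    location_class: str | None = None  # "edge" | "center"
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.protomers = np.asarray(self.protomers, dtype=float)
        self.protomer_heights = np.asarray(self.protomer_heights, dtype=float)
        if self.protomers.shape != (self.nf, 2):
            raise ValueError("need exactly nf protomer positions")
        if not -1.0 - 1e-9 <= self.isv <= 1.0 + 1e-9:
            raise ValueError("isv must lie in [-1, 1]")


@dataclass
class NeighborPair:
    """Two interacting particles with distance and signed interaction angles."""

    particle_a: Particle
    particle_b: Particle
    distance: float
    alpha: float  # deg, signed angle at particle_a
    beta: float  # deg, signed angle at particle_b


def _rotate_patch(patch: np.ndarray, center: tuple[float, float], angle_deg: float) -> np.ndarray:
    """Rotate a patch about an arbitrary (x, y) center by bilinear resampling."""
    cy, cx = center[1], center[0]
    yy, xx = np.indices(patch.shape, dtype=float)
    a = math.radians(angle_deg)
    cos_a, sin_a = math.cos(a), math.sin(a)
    dx, dy = xx - cx, yy - cy
    src_x = cx + cos_a * dx + sin_a * dy
    src_y = cy - sin_a * dx + cos_a * dy
    return ndimage.map_coordinates(patch, [src_y, src_x], order=1, mode="nearest")


def symmetrize(patch: np.ndarray, center: tuple[float, float], nf: int) -> np.ndarray:
    """Average of the patch over its nf rotations about ``center``."""
    out = np.zeros_like(patch, dtype=float)
    for j in range(nf):
        out += _rotate_patch(patch, center, 360.0 * j / nf)
    return out / nf


def _isv(patch: np.ndarray, symmetrized: np.ndarray, center: tuple[float, float]) -> float:
    """Normalized cross-correlation between patch and its symmetrized image.

    Evaluated inside the largest circle around ``center`` that fits the
    patch, to exclude rotation edge artifacts.
    """
    yy, xx = np.indices(patch.shape, dtype=float)
    cx, cy = center
    rad = min(cx, cy, patch.shape[1] - 1 - cx, patch.shape[0] - 1 - cy)
    sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
    a = patch[sel] - patch[sel].mean()
    b = symmetrized[sel] - symmetrized[sel].mean()
    denom = math.sqrt(float(np.sum(a * a)) * float(np.sum(b * b)))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def _angular_profile(
    patch: np.ndarray, center: tuple[float, float], radius: float, n_samples: int = 360
) -> np.ndarray:
    """Intensity sampled on a circle of ``radius`` px around ``center``."""
    th = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    xs = center[0] + radius * np.cos(th)
    ys = center[1] + radius * np.sin(th)
    return ndimage.map_coordinates(patch, [ys, xs], order=1, mode="nearest")


def _ring_radius(patch: np.ndarray, center: tuple[float, float]) -> float:
    """Radius of maximal angular-mean intensity (the protomer ring)."""
    cx, cy = center
    r_max = min(cx, cy, patch.shape[1] - 1 - cx, patch.shape[0] - 1 - cy)
    rs = np.arange(1.0, max(r_max, 2.0), 0.5)
    means = [np.mean(_angular_profile(patch, center, r, 180)) for r in rs]
    # weight by r: ring signal at larger radius beats the central plateau
    score = np.asarray(means) * rs
    return float(rs[int(np.argmax(score))])


def _snap_to_peak(
    patch: np.ndarray, x: float, y: float, window: float = 2.5, step: float = 0.1
) -> tuple[float, float, float]:
    """Move a predicted protomer position to the nearby local maximum."""
    offs = np.arange(-window, window + 1e-9, step)
    xs = x + offs[None, :] + 0 * offs[:, None]
    ys = y + offs[:, None] + 0 * offs[None, :]
    vals = ndimage.map_coordinates(patch, [ys.ravel(), xs.ravel()], order=3, mode="nearest")
    i = int(np.argmax(vals))
    return float(xs.ravel()[i]), float(ys.ravel()[i]), float(vals[i])


def refine_particle(
    frame: np.ndarray,
    rough_center: tuple[float, float],
    nf: int,
    search_radius: float = 3.0,
    patch_radius: int = 10,
    search_step: float = 0.5,
    isv_floor: float = ISV_FLOOR,
    pixel_size: float = 1.0,
    ring_radius_px: float | None = None,
    strict: bool = True,
) -> Particle:
    """Refine a particle center by maximizing the internal symmetry value.

    A patch around ``rough_center`` is rotationally averaged (nf-fold)
    about each candidate origin on a sub-pixel grid; the isv is the
    normalized cross-correlation between the patch and its symmetrized
    version; the center with the highest isv wins. Protomer positions
    come from the dominant nf-fold angular harmonic of the original
    (unsymmetrized) patch at the protomer ring radius.

    Coordinates in and out are (x, y) pixels of ``frame``; setting
    ``pixel_size`` scales the returned center/protomer positions to nm.
    """
    frame = np.asarray(frame, dtype=float)
    x0, y0 = rough_center
    lo_x, hi_x = int(round(x0)) - patch_radius, int(round(x0)) + patch_radius + 1
    lo_y, hi_y = int(round(y0)) - patch_radius, int(round(y0)) + patch_radius + 1
    if lo_x < 0 or lo_y < 0 or hi_x > frame.shape[1] or hi_y > frame.shape[0]:
        raise ValueError("rough_center too close to the frame margin")
    patch = frame[lo_y:hi_y, lo_x:hi_x]
    pc = (x0 - lo_x, y0 - lo_y)

    yy, xx = np.indices(patch.shape, dtype=float)
    design = np.column_stack([xx.ravel(), yy.ravel(), np.ones(patch.size)])

    def _detrended(cand: tuple[float, float]) -> np.ndarray:
        # remove the best-fit plane inside the circular isv window about
        # the candidate center, so a tilted particle's height gradient
        # does not bias the symmetry center (a window-local fit keeps a
        # centered symmetric particle exactly symmetric)
        cx, cy = cand
        rad = min(cx, cy, patch.shape[1] - 1 - cx, patch.shape[0] - 1 - cy)
        sel = ((xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2).ravel()
        coef, *_ = np.linalg.lstsq(design[sel], patch.ravel()[sel], rcond=None)
        return patch - (design @ coef).reshape(patch.shape)

    offsets = np.arange(-search_radius, search_radius + 1e-9, search_step)
    best = (-2.0, pc, None)
    for dy in offsets:
        for dx in offsets:
            cand = (pc[0] + dx, pc[1] + dy)
            flat_c = _detrended(cand)
            sym = symmetrize(flat_c, cand, nf)
            # correlate against the non-identity rotations only, so that an
            # asymmetric (noise) patch scores ~0 rather than ~1/sqrt(nf)
            sym_rot = (nf * sym - flat_c) / (nf - 1)
            val = _isv(flat_c, sym_rot, cand)
            if val > best[0]:
                best = (val, cand, sym)
    isv, center_p, sym = best
    isv = min(max(isv, -1.0), 1.0)

    flatp = _detrended(center_p)
    # ring_radius_px pins the protomer ring when neighbors crowd the patch
    ring = ring_radius_px if ring_radius_px is not None else _ring_radius(sym, center_p)
    prof = _angular_profile(flatp, center_p, ring)
    th = np.linspace(0.0, 2.0 * math.pi, prof.size, endpoint=False)
    c = np.sum(prof * np.exp(-1j * nf * th))
    phase = -math.degrees(np.angle(c)) / nf  # peaks at phase + j*360/nf
    angles = np.deg2rad(phase + 360.0 / nf * np.arange(nf))

    # sanity: the angular profile should actually carry nf peaks; drop the
    # k <= 1 harmonics first (tilt adds a large 1-fold modulation) and
    # smooth at a fraction of the expected peak spacing
    spec_f = np.fft.rfft(prof)
    spec_f[:2] = 0.0
    detrended = np.fft.irfft(spec_f, n=prof.size)
    smooth = ndimage.gaussian_filter1d(detrended, prof.size / (6.0 * nf), mode="wrap")
    rolled = np.roll(smooth, -int(np.argmin(smooth)))  # cut at the minimum
    peaks, _ = signal.find_peaks(rolled, prominence=0.1 * max(np.ptp(smooth), 1e-12))
    n_peaks = peaks.size
    low_conf = isv < isv_floor
    if n_peaks != nf and not low_conf:
        if strict:
            raise ValueError(f"found {n_peaks} angular peaks, expected {nf}")
        low_conf = True

    # snap each predicted protomer to the actual local peak of the raw
    # patch (robust height/position readout when tilt makes the bumps
    # unequal), then recenter on the protomer centroid
    px = np.array([center_p[0] + ring * np.cos(angles), center_p[1] + ring * np.sin(angles)]).T
    heights = np.empty(nf)
    for j in range(nf):
        px[j, 0], px[j, 1], heights[j] = _snap_to_peak(patch, px[j, 0], px[j, 1])
    center_p = (float(px[:, 0].mean()), float(px[:, 1].mean()))
    center_frame = np.array([center_p[0] + lo_x, center_p[1] + lo_y])
    protomers_frame = px + np.array([lo_x, lo_y])
    return Particle(
        center=center_frame * pixel_size,
        nf=nf,
        protomers=protomers_frame * pixel_size,
        protomer_heights=np.asarray(heights, dtype=float),
        isv=isv,
        low_confidence=low_conf,
    )


def classify_symmetry(
    patch: np.ndarray,
    candidates: tuple[int, ...] = (4, 5, 6),
    center: tuple[float, float] | None = None,
    power_ratio: float = 1.5,
) -> tuple[int | None, float | None]:
    """Classify the rotational symmetry order of a centered particle patch.

    The angular intensity profile at the protomer ring radius is Fourier
    analyzed; the candidate harmonic with dominant power wins and the
    peak spacing 360/nf is returned. Returns ``(None, None)`` when no
    harmonic dominates by at least ``power_ratio``.
    """
    patch = np.asarray(patch, dtype=float)
    if center is None:
        center = ((patch.shape[1] - 1) / 2.0, (patch.shape[0] - 1) / 2.0)
    ring = _ring_radius(patch, center)
    prof = _angular_profile(patch, center, ring)
    spec = np.abs(np.fft.rfft(prof - prof.mean())) ** 2
    powers = {nf: spec[nf] for nf in candidates if nf < spec.size}
    if not powers:
        return None, None
    order = sorted(powers, key=powers.get, reverse=True)
    if len(order) > 1 and powers[order[1]] > 0 and powers[order[0]] / powers[order[1]] < power_ratio:
        return None, None
    nf = order[0]
    return nf, 360.0 / nf


def tilt_angle(protomers: np.ndarray, heights: np.ndarray) -> float:
    """Tilt of the least-squares plane through protomer (x, y, h), degrees.

    The tilt is the acute angle between the plane normal and the z-axis,
    in [0, 90]; invariant under uniform height offsets and in-plane
    rotations.
    """
    xy = np.asarray(protomers, dtype=float)
    h = np.asarray(heights, dtype=float)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 protomers")
    a = np.column_stack([xy, np.ones(xy.shape[0])])
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(xy).max())) < 3:
        raise ValueError("degenerate geometry: protomer positions are collinear")
    coef, *_ = np.linalg.lstsq(a, h, rcond=None)
    slope = math.hypot(coef[0], coef[1])
    return math.degrees(math.atan(slope))


def _wrap_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap to (-180, 180]."""
    return -(-(np.asarray(angle) - 180.0) % 360.0 - 180.0)


def signed_protomer_angle(
    center: np.ndarray, protomers: np.ndarray, other_center: np.ndarray, nf: int
) -> float:
    """Signed angle from the connection line to the closest protomer.

    Positive = clockwise (y-up convention); bounded by +-180/nf with the
    boundary tie resolved toward +.
    """
    center = np.asarray(center, dtype=float)
    other = np.asarray(other_center, dtype=float)
    pts = np.asarray(protomers, dtype=float)
    psi = math.degrees(math.atan2(other[1] - center[1], other[0] - center[0]))
    phis = np.degrees(np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0]))
    deltas = _wrap_deg(psi - phis)
    i = int(np.argmin(np.abs(deltas)))
    angle = float(deltas[i])
    half = 180.0 / nf
    if math.isclose(angle, -half, abs_tol=1e-9):
        angle = half
    return angle


def interaction_angles(
    particle_a: Particle, particle_b: Particle
) -> tuple[float, float]:
    """Signed interaction angles (alpha, beta) of a neighbor pair, degrees."""
    alpha = signed_protomer_angle(
        particle_a.center, particle_a.protomers, particle_b.center, particle_a.nf
    )
    beta = signed_protomer_angle(
        particle_b.center, particle_b.protomers, particle_a.center, particle_b.nf
    )
    return alpha, beta


def delaunay_pairs(particles: list[Particle], d_max: float) -> list[NeighborPair]:
    """Neighbor pairs: Delaunay edges no longer than ``d_max``.

    The distance cutoff stands in for the manual confirmation of
    physical contacts. Degenerate (collinear) configurations are
    handled by joggling the triangulation input.
    """
    if len(particles) < 2:
        return []
    pos = np.array([p.center for p in particles])
    if len(particles) == 2:
        edges = {(0, 1)}
    else:
        try:
            tri = spatial.Delaunay(pos)
        except spatial.QhullError:
            tri = spatial.Delaunay(pos, qhull_options="QJ")
        edges = set()
        for simplex in tri.simplices:
            for i in range(len(simplex)):
                for j in range(i + 1, len(simplex)):
                    edges.add(tuple(sorted((int(simplex[i]), int(simplex[j])))))
    pairs = []
    for i, j in sorted(edges):
        d = float(np.hypot(*(pos[i] - pos[j])))
        if d > d_max or d <= 0:
            continue
        alpha, beta = interaction_angles(particles[i], particles[j])
        pairs.append(NeighborPair(particles[i], particles[j], d, alpha, beta))
    return pairs


def angle_density_map(
    pairs: list[NeighborPair],
    bandwidth: float = 3.0,
    bin_width: float = 2.0,
    nf: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of (alpha, beta) on [-180/nf, 180/nf]^2.

    Binned with periodic wrap, smoothed with a Gaussian kernel of
    ``bandwidth`` degrees, symmetrized over (alpha, beta) <-> (beta,
    alpha) (pair order is arbitrary) and normalized to max = 1.
    Returns ``(edges_centers, density)``.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    if nf is None:
        nf = pairs[0].particle_a.nf
    half = 180.0 / nf
    alphas = np.array([p.alpha for p in pairs])
    betas = np.array([p.beta for p in pairs])
    # symmetrize: each pair contributes both orderings
    xs = np.concatenate([alphas, betas])
    ys = np.concatenate([betas, alphas])
    n_bins = int(round(2 * half / bin_width))
    edges = np.linspace(-half, half, n_bins + 1)
    hist, _, _ = np.histogram2d(xs, ys, bins=[edges, edges])
    dens = ndimage.gaussian_filter(hist, sigma=bandwidth / bin_width, mode="wrap")
    m = dens.max()
    if m > 0:
        dens = dens / m
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


@dataclass
class DistanceStats:
    peak: float
    sd: float
    n: int
    fit_converged: bool
    poor_fit: bool


def distance_stats(distances: np.ndarray, n_bins: int | None = None) -> DistanceStats:
    """Gaussian fit to the center-to-center distance histogram.

    Reports the Gaussian peak position and sd (the convention used for
    distance tables). Falls back to sample mean/sd when the fit does not
    converge; raises a poor-fit flag when residuals indicate a
    non-Gaussian (e.g. bimodal) distribution.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 10:
        raise ValueError("need at least 10 distances for a fit")
    if np.ptp(d) == 0:
        return DistanceStats(float(d[0]), 0.0, d.size, True, False)
    if n_bins is None:
        n_bins = max(10, int(math.sqrt(d.size) * 2))
    hist, edges = np.histogram(d, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sd):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))

    p0 = (hist.max(), float(d.mean()), float(d.std()))
    try:
        popt, _ = optimize.curve_fit(gauss, centers, hist, p0=p0, maxfev=10000)
        amp, mu, sd = popt
        sd = abs(float(sd))
        converged = True
    except RuntimeError:
        warnings.warn("Gaussian fit did not converge; reporting sample statistics")
        return DistanceStats(float(d.mean()), float(d.std(ddof=1)), d.size, False, True)
    resid = hist - gauss(centers, *popt)
    # poor fit: residual power comparable to histogram power
    poor = float(np.sum(resid**2)) > 0.2 * float(np.sum((hist - hist.mean()) ** 2))
    return DistanceStats(float(mu), sd, d.size, converged, poor)


def compare_distance_populations(d1: np.ndarray, d2: np.ndarray) -> float:
    """Two-sample t-test p-value between two distance populations."""
    return float(stats.ttest_ind(np.asarray(d1), np.asarray(d2), equal_var=False).pvalue)


def classify_edge_center(
    particles: list[Particle],
    contour_xy: np.ndarray,
    particle_diameter: float,
) -> list[Particle]:
    """Label each particle 'edge' or 'center' by distance to the contour.

    A particle is at the edge when its center lies within one particle
    diameter of the cluster contour polyline. Mutates and returns the
    particle list.
    """
    contour = np.asarray(contour_xy, dtype=float)
    for p in particles:
        dmin = float(np.min(np.hypot(*(contour - p.center).T)))
        p.location_class = "edge" if dmin <= particle_diameter else "center"
    return particles
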