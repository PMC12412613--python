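"""Ground-truth-annotated synthetic HS-AFM movies and FRAP series.

Clusters of nf-fold symmetric particles in a flat membrane, with the
cluster boundary fluctuating as an equilibrium capillary-wave ensemble
of known line tension, edge-localized particle tilt, pixel noise, and
FRAP recovery image series with known diffusion coefficient. Every
downstream estimator in this package can be validated closed-loop
against these generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import TopographyMovie

__all__ = [
    "SyntheticMovieSpec",
    "GroundTruth",
    "capillary_mode_variance",
    "sample_boundary_coeffs",
    "sample_boundary",
    "render_particle_patch",
    "render_movie",
    "simulate_frap",
    "SyntheticFrapSeries",
]

#: protomer Gaussian sigma as a fraction of the protomer ring radius
PROTOMER_SIGMA_FRACTION = 0.45

# cross-section areas (nm^2) used for ground-truth packing bookkeeping
CROSS_SECTION_AREA = {4: 38.0, 5: 43.0}


@dataclass
class SyntheticMovieSpec:
    """Parameters of a synthetic cluster movie.

    Line tension is expressed in thermal units (kB*T per nm) at the
    spec's temperature, so the capillary mode variance is dimensionless:
    ``var(a_k) = var(b_k) = 1 / (pi * line_tension * cluster_r0 * (k^2 - 1))``.
    """

    nf: int = 5  # oligomer symmetry (4 = tetramer, 5 = pentamer)
    n_particles: int = 12
    particle_radius: float = 2.2  # protomer ring radius, nm
    protomer_height: float = 1.2  # bump amplitude above cluster base, nm
    membrane_height: float = 0.0  # background level, nm
    cluster_r0: float = 15.0  # mean cluster radius, nm
    line_tension: float = 100.0  # lambda, kB*T / nm
    temperature: float = 298.0  # K
    n_modes: int = 12  # max Fourier mode K
    edge_tilt_deg: float = 0.0  # max tilt applied to edge particles
    pixel_size: float = 0.5  # nm / px
    frame_interval: float = 0.5  # s
    n_frames: int = 100
    noise_sd: float = 0.05  # nm
    seed: int = 0
    cluster_base_height: float | None = None  # plateau above membrane, nm

    def __post_init__(self) -> None:
        if self.nf < 3:
            raise ValueError("nf must be >= 3")
        if self.line_tension <= 0:
            raise ValueError("line_tension must be positive")
        if self.cluster_r0 <= 0:
            raise ValueError("cluster_r0 must be positive")
        if self.n_modes < 2:
            raise ValueError("n_modes must be >= 2")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.cluster_base_height is None:
            # plateau level chosen so the membrane | cluster split dominates
            # the isodata threshold (a lower plateau drops below the
            # intermeans fixed point and fragments the mask)
            self.cluster_base_height = self.protomer_height


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_line_tension: float  # kB*T / nm
    true_centers: np.ndarray  # (n_particles, 2) nm, static across frames
    true_protomer_angles: np.ndarray  # (n_particles,) deg, phase of protomer 0
    true_tilts: np.ndarray  # (n_particles,) deg
    true_tilt_axes: np.ndarray  # (n_particles,) deg, in-plane tilt axis
    true_packing_fraction: float
    edge_flags: np.ndarray  # (n_particles,) bool
    contours: np.ndarray  # (n_frames, n_theta) radii R(theta), nm
    theta: np.ndarray  # (n_theta,) rad
    cluster_center: np.ndarray  # (2,) nm, frame coords
    cluster_area: float  # mean-contour enclosed area, nm^2
    true_D: float | None = None  # um^2/s, FRAP only


def capillary_mode_variance(line_tension: float, r0: float, k: np.ndarray | int) -> np.ndarray | float:
    """Equipartition variance of each Fourier amplitude a_k (= b_k), k >= 2."""
    k = np.asarray(k)
    if np.any(k < 2):
        raise ValueError("capillary modes start at k = 2")
    return 1.0 / (math.pi * line_tension * r0 * (k.astype(float) ** 2 - 1.0))


def sample_boundary_coeffs(
    spec: SyntheticMovieSpec, frame_count: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-frame Fourier amplitudes (a, b), each (frame_count, K-1).

    Columns correspond to modes k = 2 .. n_modes; k = 1 (pure translation)
    is never generated and k = 0 is absorbed into r0.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ks = np.arange(2, spec.n_modes + 1)
    sd = np.sqrt(capillary_mode_variance(spec.line_tension, spec.cluster_r0, ks))
    a = rng.normal(0.0, sd, size=(frame_count, ks.size))
    b = rng.normal(0.0, sd, size=(frame_count, ks.size))
    return a, b


def synthesize_boundary(
    r0: float, a: np.ndarray, b: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """R(theta) = r0 * (1 + sum_k [a_k cos k theta + b_k sin k theta]), k from 2."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    ks = np.arange(2, a.shape[1] + 2)
    cos = np.cos(np.outer(ks, theta))  # (K-1, n_theta)
    sin = np.sin(np.outer(ks, theta))
    return r0 * (1.0 + a @ cos + b @ sin)


def sample_boundary(
    spec: SyntheticMovieSpec,
    frame_count: int,
    n_theta: int = 360,
    rng: np.random.Generator | None = None,
    max_attempts: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample closed polar contours R(theta) for ``frame_count`` frames.

    Returns ``(theta, R)`` with ``R`` of shape (frame_count, n_theta).
    Frames are independent draws from the equilibrium capillary-wave
    ensemble. Non-positive contours (possible only at very low tension)
    are redrawn, with a bounded number of attempts.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    out = np.empty((frame_count, n_theta))
    remaining = np.arange(frame_count)
    for _ in range(max_attempts):
        a, b = sample_boundary_coeffs(spec, remaining.size, rng)
        r = synthesize_boundary(spec.cluster_r0, a, b, theta)
        ok = (r > 0).all(axis=1)
        out[remaining[ok]] = r[ok]
        remaining = remaining[~ok]
        if remaining.size == 0:
            return theta, out
    raise RuntimeError("could not draw strictly positive contours; tension too low?")


def _protomer_layout(
    center: np.ndarray,
    nf: int,
    ring_radius: float,
    phase_deg: float,
    tilt_deg: float,
    tilt_axis_deg: float,
    base_height: float,
    bump_height: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Protomer (x, y) positions and peak heights for one particle.

    Tilt raises/lowers protomer peaks along the direction perpendicular
    to the tilt axis: the peaks lie on a plane with slope tan(tilt).
    """
    phis = np.deg2rad(phase_deg + 360.0 / nf * np.arange(nf))
    xy = center[None, :] + ring_radius * np.stack([np.cos(phis), np.sin(phis)], axis=1)
    slope = math.tan(math.radians(tilt_deg))
    axis = math.radians(tilt_axis_deg)
    # signed distance from the tilt axis line through the center
    d = -(xy[:, 0] - center[0]) * math.sin(axis) + (xy[:, 1] - center[1]) * math.cos(axis)
    h = base_height + bump_height + slope * d
    return xy, h


def _render_bumps(
    xx: np.ndarray, yy: np.ndarray, xy: np.ndarray, peak_heights: np.ndarray,
    base: np.ndarray | float, sigma: float,
) -> np.ndarray:
    """Sum of Gaussian bumps whose peaks reach ``peak_heights`` above zero."""
    out = np.zeros_like(xx)
    for (px, py), h in zip(xy, peak_heights):
        amp = h - (base if np.isscalar(base) else 0.0)
        out += float(amp) * np.exp(-(((xx - px) ** 2 + (yy - py) ** 2) / (2 * sigma**2)))
    return out


def render_particle_patch(
    nf: int = 5,
    ring_radius: float = 2.2,
    protomer_height: float = 1.2,
    phase_deg: float = 0.0,
    tilt_deg: float = 0.0,
    tilt_axis_deg: float = 0.0,
    pixel_size: float = 0.25,
    size_px: int = 41,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a single nf-fold particle centered in a square patch (nm heights)."""
    if rng is None:
        rng = np.random.default_rng(0)
    half = (size_px - 1) / 2.0
    coords = (np.arange(size_px) - half) * pixel_size
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    center = np.zeros(2)
    xy, h = _protomer_layout(
        center, nf, ring_radius, phase_deg, tilt_deg, tilt_axis_deg, 0.0, protomer_height
    )
    sigma = PROTOMER_SIGMA_FRACTION * ring_radius
    patch = _render_bumps(xx, yy, xy, h, 0.0, sigma)
    if noise_sd > 0:
        patch = patch + rng.normal(0.0, noise_sd, size=patch.shape)
    return patch


def _place_particles(
    rng: np.random.Generator,
    n: int,
    r_mean: np.ndarray,
    theta: np.ndarray,
    margin: float,
    min_sep: float,
    max_attempts_factor: int = 500,
) -> np.ndarray:
    """Rejection-sample particle centers inside the mean contour."""
    if n == 0:
        return np.zeros((0, 2))
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = max_attempts_factor * n
    rmax = r_mean.max()
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping particles inside the cluster"
            )
        r = rmax * math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        r_bound = np.interp(th, theta, r_mean, period=2.0 * math.pi)
        if r > r_bound - margin:
            continue
        p = np.array([r * math.cos(th), r * math.sin(th)])
        if any(np.hypot(*(p - q)) < min_sep for q in centers):
            continue
        centers.append(p)
    return np.asarray(centers)


def render_movie(spec: SyntheticMovieSpec) -> tuple[TopographyMovie, GroundTruth]:
    """Render a full synthetic movie and its ground truth.

    The field of view is sized to hold the fluctuating cluster with a
    membrane margin. Particle centers are static; the cluster boundary
    fluctuates frame to frame. Edge particles (centers within one
    particle diameter of the mean contour) are tilted by up to
    ``edge_tilt_deg``.
    """
    rng = np.random.default_rng(spec.seed)
    theta, contours = sample_boundary(spec, spec.n_frames, rng=rng)
    r_mean = contours.mean(axis=0)
    sigma = PROTOMER_SIGMA_FRACTION * spec.particle_radius

    margin = spec.particle_radius + 2.0 * sigma
    min_sep = 2.0 * spec.particle_radius
    centers = _place_particles(rng, spec.n_particles, r_mean, theta, margin, min_sep)

    # edge = within one particle diameter of the (mean) contour
    if spec.n_particles:
        rr = np.hypot(centers[:, 0], centers[:, 1])
        th_c = np.mod(np.arctan2(centers[:, 1], centers[:, 0]), 2.0 * math.pi)
        r_bound = np.interp(th_c, theta, r_mean, period=2.0 * math.pi)
        edge_flags = (r_bound - rr) <= 2.0 * spec.particle_radius
    else:
        edge_flags = np.zeros(0, dtype=bool)

    phases = rng.uniform(0.0, 360.0 / spec.nf, size=spec.n_particles)
    tilts = np.where(
        edge_flags, rng.uniform(0.0, spec.edge_tilt_deg, size=spec.n_particles), 0.0
    )
    tilt_axes = rng.uniform(0.0, 360.0, size=spec.n_particles)

    # field of view: cluster max radius + membrane margin
    fov_half = contours.max() + 6.0 * spec.particle_radius
    n_px = int(math.ceil(2.0 * fov_half / spec.pixel_size))
    n_px += n_px % 2  # even
    coords = (np.arange(n_px) - (n_px - 1) / 2.0) * spec.pixel_size
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    pix_th = np.mod(np.arctan2(yy, xx), 2.0 * math.pi)
    pix_r = np.hypot(xx, yy)

    bumps = np.zeros_like(xx)
    for i in range(spec.n_particles):
        xy, h = _protomer_layout(
            centers[i], spec.nf, spec.particle_radius, phases[i],
            tilts[i], tilt_axes[i], 0.0, spec.protomer_height,
        )
        bumps += _render_bumps(xx, yy, xy, h, 0.0, sigma)

    frames = np.empty((spec.n_frames, n_px, n_px), dtype=np.float32)
    for t in range(spec.n_frames):
        r_bound = np.interp(pix_th, theta, contours[t], period=2.0 * math.pi)
        inside = pix_r <= r_bound
        frame = np.full_like(xx, spec.membrane_height)
        frame[inside] += spec.cluster_base_height
        frame += bumps
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frames[t] = frame

    # ground-truth packing fraction via the cross-section bookkeeping
    area = 0.5 * np.trapezoid(
        np.append(r_mean, r_mean[0]) ** 2, np.append(theta, 2.0 * math.pi)
    )
    a_mol = CROSS_SECTION_AREA.get(spec.nf, math.pi * spec.particle_radius**2)
    packing = spec.n_particles * a_mol / area if area > 0 else 0.0

    movie = TopographyMovie(
        frames=frames, pixel_size=spec.pixel_size, frame_interval=spec.frame_interval
    )
    center_px = np.array([(n_px - 1) / 2.0, (n_px - 1) / 2.0]) * spec.pixel_size
    truth = GroundTruth(
        true_line_tension=spec.line_tension,
        true_centers=centers,
        true_protomer_angles=phases,
        true_tilts=tilts,
        true_tilt_axes=tilt_axes,
        true_packing_fraction=packing,
        edge_flags=edge_flags,
        contours=contours,
        theta=theta,
        cluster_center=center_px,
        cluster_area=float(area),
        true_D=None,
    )
    return movie, truth


@dataclass
class SyntheticFrapSeries:
    """FRAP image series with known diffusion coefficient."""

    frames: np.ndarray  # (T, H, W) fluorescence, pre-bleach level 1
    times: np.ndarray  # s, bleach at t = 0; negative = pre-bleach
    pixel_size: float  # um / px
    roi_center: np.ndarray  # (row, col) px
    rn: float  # nominal bleach ROI radius, um
    bleach_depth: float
    blur_sigma: float  # um, instrument blur of the bleach edge
    true_D: float  # um^2 / s


def simulate_frap(
    D: float,
    rn: float,
    bleach_depth: float,
    times: np.ndarray,
    image_size: int = 128,
    field_width: float = 32.4,
    blur_sigma: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticFrapSeries:
    """Simulate a FRAP image series with known diffusion coefficient.

    The bleach profile at t = 0 is a disk of radius ``rn`` (depth
    ``bleach_depth``) convolved with a Gaussian of ``blur_sigma``
    (default 0.2 * rn). Diffusion widens the profile: the frame at
    post-bleach time t is the disk convolved with a Gaussian of
    variance ``blur_sigma^2 + 2 D t``. Negative times are pre-bleach
    frames at uniform intensity 1.

    All lengths in um; ``D`` in um^2/s.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if not (0 <= bleach_depth <= 1):
        raise ValueError("bleach_depth must be in [0, 1]")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if blur_sigma is None:
        blur_sigma = 0.2 * rn
    rng = np.random.default_rng(seed)
    px = field_width / image_size
    c = (image_size - 1) / 2.0
    coords = (np.arange(image_size) - c) * px
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    disk = (np.hypot(xx, yy) <= rn).astype(float)

    frames = np.empty((times.size, image_size, image_size))
    for i, t in enumerate(times):
        if t < 0 or bleach_depth == 0:
            frame = np.ones_like(disk)
        else:
            sig_um = math.sqrt(blur_sigma**2 + 2.0 * D * t)
            bleach = ndimage.gaussian_filter(disk, sigma=sig_um / px, mode="constant")
            frame = 1.0 - bleach_depth * bleach
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames[i] = frame

    return SyntheticFrapSeries(
        frames=frames,
        times=times,
        pixel_size=px,
        roi_center=np.array([c, c]),
        rn=rn,
        bleach_depth=bleach_depth,
        blur_sigma=blur_sigma,
        true_D=D,
    )
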