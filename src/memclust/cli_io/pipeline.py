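"""End-to-end pipeline: preprocessing -> contour dynamics -> particle
geometry -> cluster metrics, with provenance logging.
"""

from __future__ import annotations

import dataclasses
import json
import math
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from .. import __version__
from ..cluster_metrics import A_FOCA, A_GLPF, composition_ratios, packing_fraction
from ..contour_dynamics import ClusterTrace, fit_line_tension, mean_leading_edge_velocity
from ..particle_geometry import (
    classify_edge_center,
    delaunay_pairs,
    distance_stats,
    refine_particle,
    tilt_angle,
)
from ..preprocess import (
    MaskStack,
    TopographyMovie,
    align_frames,
    flatten_frame,
    isodata_threshold,
    select_isolated_clusters,
    walking_average,
)
from .io import read_movie, read_particle_seeds

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

SPECIES_NF = {"glpf": 4, "foca": 5}


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_path: str | None = None
    pixel_size: float | None = None  # nm/px; may come from sidecar
    frame_interval: float | None = None  # s
    seeds_path: str | None = None  # rough particle positions CSV
    dtheta_deg: float = 2.0
    kmax: int = 12
    d_max: float | None = None  # nm; default 1.5x modal NN distance
    temperature: float = 298.0
    chi: float | None = None  # DOPC / total lipid
    area_glpf: float = A_GLPF
    area_foca: float = A_FOCA
    particle_radius: float = 2.2  # nm, for edge classification + d_max guess
    time_average_frames: int = 5
    align: bool = True
    make_plots: bool = False
    output_dir: str = "memclust_out"
    seed: int = 0

    def validate(self) -> None:
        for name in ("pixel_size", "frame_interval"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise PipelineError("config", f"{name} must be positive")
        if self.chi is not None and not 0.0 <= self.chi <= 1.0:
            raise PipelineError("config", "chi must lie in [0, 1]")
        if self.kmax < 2:
            raise PipelineError("config", "kmax must be >= 2")


def _prepare_movie(config: PipelineConfig) -> TopographyMovie:
    if config.input_path is None:
        raise PipelineError("config", "no input_path given")
    movie, meta = read_movie(config.input_path)
    if config.pixel_size is not None:
        movie.pixel_size = config.pixel_size
    if config.frame_interval is not None:
        movie.frame_interval = config.frame_interval
    if movie.pixel_size is None or movie.pixel_size <= 0:
        raise PipelineError("config", "pixel_size missing (config or sidecar)")
    return movie


def _segment(movie: TopographyMovie) -> MaskStack:
    flat = np.stack([flatten_frame(f) for f in movie.frames])
    thresholds = np.array([isodata_threshold(f) for f in flat])
    masks = np.stack([f > t for f, t in zip(flat, thresholds)])
    stack = MaskStack(masks=masks, thresholds=thresholds)
    return walking_average(stack, window=3)


def _cluster_row(
    trace: ClusterTrace, config: PipelineConfig, cluster_id: int
) -> tuple[dict, pd.DataFrame]:
    mu_v = mean_leading_edge_velocity(trace)
    fit = fit_line_tension(trace, temperature=config.temperature, kmax=config.kmax)
    mean_mask = trace.masks.mean(axis=0) > 0.5 if trace.masks is not None else None
    if mean_mask is not None and mean_mask.any():
        props = regionprops(label(mean_mask))[0]
        eccentricity = float(props.eccentricity)
        area = float(props.area)  # px^2; converted by caller
    else:
        eccentricity, area = math.nan, math.nan
    row = {
        "cluster_id": cluster_id,
        "mu_v_nm_s": mu_v,
        "line_tension_kBT_nm": fit.line_tension,
        "r0_nm": fit.r0,
        "fit_r_squared": fit.r_squared,
        "loglog_slope": fit.loglog_slope,
        "eccentricity": eccentricity,
        "area_px": area,
        "n_frames": trace.n_frames,
    }
    spectrum = pd.DataFrame(
        {
            "cluster_id": cluster_id,
            "k": fit.modes,
            "mean_sq_amplitude": fit.mean_sq_amplitude,
            "residual": fit.residuals,
        }
    )
    return row, spectrum


def _particle_stage(
    movie: TopographyMovie,
    traces: list[ClusterTrace],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    seeds = read_particle_seeds(config.seeds_path)
    n_avg = min(config.time_average_frames, movie.n_frames)
    avg = movie.frames[:n_avg].mean(axis=0)
    particles = []
    rows = []
    for _, seed_row in seeds.iterrows():
        species = str(seed_row["species"]).lower()
        nf = SPECIES_NF.get(species)
        if nf is None:
            raise PipelineError("particles", f"unknown species {species!r}")
        try:
            p = refine_particle(
                avg,
                (seed_row["x"] / movie.pixel_size, seed_row["y"] / movie.pixel_size),
                nf=nf,
                pixel_size=movie.pixel_size,
                patch_radius=max(6, int(round(2.0 * config.particle_radius / movie.pixel_size))),
                ring_radius_px=config.particle_radius / movie.pixel_size,
                strict=False,
            )
        except ValueError as exc:
            warnings.warn(f"seed at ({seed_row['x']}, {seed_row['y']}) skipped: {exc}")
            continue
        p.tilt = tilt_angle(p.protomers, p.protomer_heights)
        particles.append(p)

    if traces and particles:
        trace = traces[0]
        th = trace.theta
        contour = np.stack(
            [
                trace.centers[0][0] + trace.radii[0] * np.cos(th),
                trace.centers[0][1] + trace.radii[0] * np.sin(th),
            ],
            axis=1,
        )
        classify_edge_center(particles, contour, 2.0 * config.particle_radius)

    for i, p in enumerate(particles):
        rows.append(
            {
                "particle_id": i,
                "x_nm": p.center[0],
                "y_nm": p.center[1],
                "nf": p.nf,
                "isv": p.isv,
                "tilt_deg": p.tilt,
                "location": p.location_class,
                "low_confidence": p.low_confidence,
            }
        )
    particle_df = pd.DataFrame(rows)

    d_max = config.d_max
    if d_max is None and len(particles) >= 2:
        pos = np.array([p.center for p in particles])
        dmat = np.hypot(*(pos[:, None, :] - pos[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(dmat, np.inf)
        d_max = 1.5 * float(np.median(dmat.min(axis=1)))
    pairs = delaunay_pairs(particles, d_max) if d_max else []
    index_of = {id(p): i for i, p in enumerate(particles)}
    pair_df = pd.DataFrame(
        [
            {
                "a": index_of[id(p.particle_a)],
                "b": index_of[id(p.particle_b)],
                "d_nm": p.distance,
                "alpha_deg": p.alpha,
                "beta_deg": p.beta,
            }
            for p in pairs
        ]
    )
    return particle_df, pair_df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis chain and write result tables.

    Returns a results bundle: per-cluster table, per-mode spectra, and
    (when seeds are configured) particle and pair tables plus packing
    and composition summaries. All outputs are also written as CSV under
    ``config.output_dir`` together with a provenance log.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    try:
        movie = _prepare_movie(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    try:
        if config.align and movie.n_frames > 1:
            movie, drift = align_frames(movie)
            bundle["drift_px"] = drift
        mask_stack = _segment(movie)
        trace_masks = select_isolated_clusters(mask_stack)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    traces = []
    cluster_rows, spectra = [], []
    dtheta = math.radians(config.dtheta_deg)
    for cid, masks in enumerate(trace_masks):
        try:
            trace = ClusterTrace.from_masks(
                masks, movie.pixel_size, movie.frame_interval, dtheta
            )
            row, spectrum = _cluster_row(trace, config, cid)
        except Exception as exc:
            warnings.warn(f"cluster {cid} skipped: {exc}")
            continue
        row["area_nm2"] = row.pop("area_px") * movie.pixel_size**2
        traces.append(trace)
        cluster_rows.append(row)
        spectra.append(spectrum)

    cluster_df = pd.DataFrame(cluster_rows)
    bundle["clusters"] = cluster_df
    cluster_df.to_csv(outdir / "clusters.csv", index=False)
    if spectra:
        spec_df = pd.concat(spectra, ignore_index=True)
        bundle["spectra"] = spec_df
        spec_df.to_csv(outdir / "mode_spectra.csv", index=False)
        if config.make_plots and not cluster_df.empty:
            from .plots import plot_mode_spectrum

            plot_mode_spectrum(spec_df, outdir / "mode_spectrum.svg")

    if config.seeds_path:
        try:
            particle_df, pair_df = _particle_stage(movie, traces, config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("particles", str(exc)) from exc
        bundle["particles"] = particle_df
        bundle["pairs"] = pair_df
        particle_df.to_csv(outdir / "particles.csv", index=False)
        pair_df.to_csv(outdir / "pairs.csv", index=False)

        if not particle_df.empty and not cluster_df.empty:
            n_foca = int((particle_df["nf"] == 5).sum())
            n_glpf = int((particle_df["nf"] == 4).sum())
            packing = packing_fraction(
                n_glpf, n_foca, float(cluster_df["area_nm2"].iloc[0]),
                a_glpf=config.area_glpf, a_foca=config.area_foca,
            )
            bundle["packing"] = packing
            if len(pair_df) >= 10:
                bundle["distance_stats"] = distance_stats(pair_df["d_nm"].to_numpy())
            summary = {
                "n_foca": n_foca,
                "n_glpf": n_glpf,
                "packing_fraction": packing.f,
                "apparent_nonplanar": packing.apparent_nonplanar,
            }
            (outdir / "summary.json").write_text(json.dumps(summary, indent=1))

    provenance = {
        "memclust_version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(config),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    bundle["provenance"] = provenance
    return bundle
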