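"""File I/O: TIFF/HDF5 height stacks with JSON sidecar metadata."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from ..preprocess import TopographyMovie
from ..synthetic_data import GroundTruth, SyntheticFrapSeries

__all__ = [
    "sidecar_path",
    "write_movie",
    "read_movie",
    "write_frap_series",
    "read_frap_series",
    "read_particle_seeds",
    "write_density_map",
]


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix(".json")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_movie(
    movie: TopographyMovie,
    path: Path | str,
    ground_truth: GroundTruth | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a 32-bit float TIFF stack (heights in nm) plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {
        "pixel_size_nm": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "timestamps_s": movie.timestamps,
    }
    if ground_truth is not None:
        meta["ground_truth"] = dataclasses.asdict(ground_truth)
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, default=_jsonify, indent=1))
    return path


def read_movie(path: Path | str) -> tuple[TopographyMovie, dict]:
    """Read a TIFF or HDF5 height stack and its sidecar metadata."""
    path = Path(path)
    meta: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            frames = fh["frames"][()]
            attrs = dict(fh["frames"].attrs)
        meta = {**attrs, **meta}
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    if "pixel_size_nm" not in meta or "frame_interval_s" not in meta:
        raise ValueError(
            f"missing pixel_size_nm / frame_interval_s metadata for {path.name}"
        )
    movie = TopographyMovie(
        frames=np.asarray(frames, dtype=float),
        pixel_size=float(meta["pixel_size_nm"]),
        frame_interval=float(meta["frame_interval_s"]),
        timestamps=np.asarray(meta["timestamps_s"], dtype=float)
        if "timestamps_s" in meta
        else None,
    )
    return movie, meta


def write_frap_series(series: SyntheticFrapSeries, path: Path | str) -> Path:
    path = Path(path)
    tifffile.imwrite(path, series.frames.astype(np.float32))
    meta = {
        "times_s": series.times,
        "pixel_size_um": series.pixel_size,
        "roi_center_px": series.roi_center,
        "rn_um": series.rn,
        "bleach_depth": series.bleach_depth,
        "true_D_um2_s": series.true_D,
    }
    sidecar_path(path).write_text(json.dumps(meta, default=_jsonify, indent=1))
    return path


def read_frap_series(path: Path | str) -> dict:
    path = Path(path)
    meta = json.loads(sidecar_path(path).read_text())
    meta["frames"] = tifffile.imread(path).astype(float)
    return meta


def read_particle_seeds(path: Path | str) -> pd.DataFrame:
    """Rough particle positions: CSV with columns frame, x, y, species."""
    df = pd.read_csv(path)
    required = {"frame", "x", "y", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"seed CSV missing columns: {sorted(missing)}")
    return df


def write_density_map(path: Path | str, centers: np.ndarray, density: np.ndarray) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("angle_deg", data=centers)
        fh.create_dataset("density", data=density)
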