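"""Per-cluster scalar metrics and cluster typing.

2D packing fraction, pentamer composition ratios, the 8-feature table,
PCA and 2-component Gaussian-mixture categorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .particle_geometry import Particle

__all__ = [
    "A_GLPF",
    "A_FOCA",
    "ClusterFeatures",
    "PackingResult",
    "packing_fraction",
    "composition_ratios",
    "pca_gmm",
]

# default molecular cross-section areas, nm^2
A_GLPF = 38.0
A_FOCA = 43.0

FEATURE_NAMES = [
    "n_total",
    "edge_ratio",
    "total_ratio",
    "chi",
    "packing_fraction",
    "eccentricity",
    "line_tension",
    "leading_velocity",
]


@dataclass
class ClusterFeatures:
    """The 8 per-cluster features entering PCA."""

    n_total: int
    edge_ratio: float  # tetramer/pentamer ratio among edge particles
    total_ratio: float  # tetramer/pentamer ratio overall
    chi: float  # DOPC / total-lipid ratio, in [0, 1]
    packing_fraction: float
    eccentricity: float  # ellipse-fit eccentricity, in [0, 1)
    line_tension: float
    leading_velocity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError("chi must lie in [0, 1]")
        if self.packing_fraction < 0:
            raise ValueError("packing_fraction must be >= 0")

    def as_row(self) -> list[float]:
        return [getattr(self, f.name) for f in fields(self)]


@dataclass
class PackingResult:
    f: float
    apparent_nonplanar: bool  # f > 1


def packing_fraction(
    n_glpf: int,
    n_foca: int,
    cluster_area: float,
    a_glpf: float = A_GLPF,
    a_foca: float = A_FOCA,
) -> PackingResult:
    """2D packing fraction f = (n_GlpF*A_GlpF + n_FocA*A_FocA) / A_cluster.

    Values above 1 are legal and flagged: they indicate apparent
    nonplanarity of the cluster (tilted or domed molecules).
    """
    if n_glpf < 0 or n_foca < 0:
        raise ValueError("molecule counts must be non-negative")
    if cluster_area <= 0:
        raise ValueError("cluster_area must be positive")
    f = (n_glpf * a_glpf + n_foca * a_foca) / cluster_area
    return PackingResult(f=float(f), apparent_nonplanar=f > 1.0)


def composition_ratios(particles: list[Particle]) -> dict[str, float]:
    """Pentamer fractions at the cluster edge and overall.

    Returns ``edge_pentamer_fraction``, ``total_pentamer_fraction`` and
    their ratio ``normalized_edge_over_total`` (NaN when there are no
    edge particles or no pentamers at all).
    """
    if not particles:
        raise ValueError("no particles")
    is_penta = np.array([p.nf == 5 for p in particles])
    is_edge = np.array([p.location_class == "edge" for p in particles])
    total_frac = float(is_penta.mean())
    if is_edge.sum() == 0:
        warnings.warn("no edge particles; normalized ratio undefined")
        edge_frac = float("nan")
    else:
        edge_frac = float(is_penta[is_edge].mean())
    norm = edge_frac / total_frac if total_frac > 0 else float("nan")
    return {
        "edge_pentamer_fraction": edge_frac,
        "total_pentamer_fraction": total_frac,
        "normalized_edge_over_total": norm,
    }


def pca_gmm(
    feature_table: pd.DataFrame | np.ndarray,
    n_groups: int = 2,
    seed: int = 0,
) -> dict:
    """Standardized PCA followed by GMM grouping in (pc1, pc2) space.

    Features are standardized to zero mean / unit variance (they carry
    incommensurable units); constant columns are dropped with a warning.
    The Gaussian mixture (full covariance, 10 restarts, fixed seed) is
    fitted on the first two PC scores.
    """
    if isinstance(feature_table, pd.DataFrame):
        names = list(feature_table.columns)
        x = feature_table.to_numpy(dtype=float)
    else:
        x = np.asarray(feature_table, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
    if x.shape[0] < 10:
        raise ValueError("need at least 10 rows")

    sd = x.std(axis=0)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}")
    x = x[:, keep]
    z = (x - x.mean(axis=0)) / x.std(axis=0)

    pca = PCA()
    scores = pca.fit_transform(z)
    explained = pca.explained_variance_ratio_ * 100.0

    gmm = GaussianMixture(
        n_components=n_groups, covariance_type="full", n_init=10, random_state=seed
    )
    labels = gmm.fit_predict(scores[:, :2])
    return {
        "pc_scores": scores,
        "explained_variance_pct": explained,
        "components": pca.components_,
        "group_labels": labels,
        "gmm_means": gmm.means_,
        "gmm_covariances": gmm.covariances_,
        "dropped_features": dropped,
        "feature_names": [n for n, k in zip(names, keep) if k],
        "seed": seed,
    }
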