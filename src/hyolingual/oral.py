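"""Oral-cavity volume from a 3D alpha shape over posed bony-landmark clouds.

The oral cavity is bounded superiorly by the hard palate mucosa, anteriorly
and laterally by the lingual tooth/mandible surfaces, posteroinferiorly by the
anterior hyoid, and inferiorly by a straight reconstructed mylohyoid-raphe
segment from the inferior hyoid pole to the mandibular symphysis.  Per frame
the posed landmark clouds are pooled, Delaunay-tetrahedralized, and tetrahedra
whose circumsphere radius exceeds alpha (default 6 mm) are discarded; the
volume is the sum of the kept tetrahedra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .io import get_logger

__all__ = [
    "OralBoundaryCloud",
    "AlphaShapeConfig",
    "assemble_boundary_cloud",
    "alpha_shape_volume",
    "tetrahedron_volumes",
    "tetrahedron_circumradii",
]

_log = get_logger(__name__)


@dataclass
class AlphaShapeConfig:
    """alpha (mm): circumradius bound; min_tet_volume: sliver exclusion (mm^3)."""

    alpha: float = 6.0
    min_tet_volume: float = 1e-12

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class OralBoundaryCloud:
    """Pooled per-frame boundary point cloud with per-component counts."""

    points: np.ndarray
    component_counts: dict

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("boundary cloud contains non-finite points")

    @property
    def n_points(self) -> int:
        return len(self.points)


def assemble_boundary_cloud(
    surfaces: dict,
    poses: dict | None = None,
    raphe_endpoints: tuple | None = None,
    raphe_samples: int = 50,
) -> OralBoundaryCloud:
    """Pool posed rigid landmark clouds plus the sampled raphe segment.

    ``surfaces`` maps component name -> (n, 3) reference cloud; ``poses`` maps
    component name -> (R, t) applying p -> R p + t (identity when absent).
    ``raphe_endpoints`` is the posed (hyoid inferior pole, mandibular
    symphysis) pair, sampled as ``raphe_samples`` points on a straight line.
    """
    parts = []
    counts = {}
    for name, cloud in surfaces.items():
        cloud = np.asarray(cloud, float).reshape(-1, 3)
        if poses and name in poses and poses[name] is not None:
            rot, t = poses[name]
            cloud = cloud @ np.asarray(rot, float).T + np.asarray(t, float)
        parts.append(cloud)
        counts[name] = len(cloud)
    if raphe_endpoints is not None:
        a, b = (np.asarray(p, float).reshape(3) for p in raphe_endpoints)
        u = np.linspace(0.0, 1.0, raphe_samples)[:, None]
        raphe = a * (1 - u) + b * u
        parts.append(raphe)
        counts["raphe"] = raphe_samples
    cloud = OralBoundaryCloud(np.vstack(parts), counts)
    _log.info("assembled oral boundary cloud: %d points (%s)", cloud.n_points, counts)
    return cloud


def tetrahedron_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    m = points[simplices[:, 1:]] - a[:, None, :]
    return np.abs(np.linalg.det(m)) / 6.0


def tetrahedron_circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radii of tetrahedra (inf for numerically singular ones)."""
    a = points[simplices[:, 0]]
    m = points[simplices[:, 1:]] - a[:, None, :]  # rows b-a, c-a, d-a
    rhs = 0.5 * np.einsum("ijk,ijk->ij", m, m)
    radii = np.full(len(simplices), np.inf)
    dets = np.abs(np.linalg.det(m))
    ok = dets > 1e-12
    if ok.any():
        centers = np.linalg.solve(m[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


def alpha_shape_volume(
    cloud, config: AlphaShapeConfig | None = None
) -> float:
    """Alpha-shape volume (mm^3): sum of Delaunay tetrahedra with circumradius
    <= alpha.  Degenerate (coplanar) clouds yield 0 with a warning; sliver
    tetrahedra below ``min_tet_volume`` are excluded before the radius test."""
    config = config or AlphaShapeConfig()
    points = cloud.points if isinstance(cloud, OralBoundaryCloud) else np.asarray(cloud, float)
    if len(points) < 4:
        warnings.warn("fewer than 4 points: alpha-shape volume is 0")
        return 0.0
    try:
        tri = Delaunay(points)
    except Exception:
        warnings.warn("degenerate point cloud: alpha-shape volume is 0")
        return 0.0
    vols = tetrahedron_volumes(points, tri.simplices)
    keep = vols >= config.min_tet_volume
    simplices = tri.simplices[keep]
    vols = vols[keep]
    if len(simplices) == 0:
        warnings.warn("all tetrahedra degenerate: alpha-shape volume is 0")
        return 0.0
    radii = tetrahedron_circumradii(points, simplices)
    return float(vols[radii <= config.alpha].sum())
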