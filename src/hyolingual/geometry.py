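"""Regional tongue volumes from sparse implanted markers.

The tongue is modelled per frame as three geometric primitives delimited by
two spline-bounded coronal surfaces:

* a closed natural-cubic-spline ring is fitted through each ordered set of
  four boundary markers by wrapping the sequence three full loops and keeping
  only the middle loop (removes end-condition artifacts);
* each ring is filled with a harmonic ("minimal") surface: the ring is
  projected onto its first two principal directions, the enclosed planar
  domain is triangulated, and three Laplace equations with cotangent weights
  and Dirichlet boundary data (the ring's x, y, z coordinates) are solved;
* the anterior oral tongue (AOT) is a cone from the middle coronal surface to
  the anterior marker, the posterior oral tongue (POT) a deformed cylinder
  between the two coronal surfaces, and the tongue base (TB) a cone from the
  posterior coronal surface to the vallecular marker;
* each closed primitive's volume is the magnitude of the sum of signed
  tetrahedron volumes of its faces against the primitive centroid.

Volumes are computed in mm^3 and reported in mL (mm^3 / 1000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import CubicSpline
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .io import DegenerateGeometryError, MarkerTrajectorySet, TriMesh, get_logger

__all__ = [
    "CoronalRing",
    "CoronalSurface",
    "RegionalVolumes",
    "GeometryError",
    "fit_coronal_ring",
    "ring_from_samples",
    "resample_ring",
    "resample_matched_rings",
    "fill_harmonic_surface",
    "build_primitives",
    "signed_mesh_volume",
    "regional_volumes",
]

_log = get_logger(__name__)

# Ring marker orders (around the coronal cross-section, starting at the
# designated start marker: middle deep for the middle ring, reconstructed
# dorsal hyoid for the posterior ring).
MIDDLE_RING_ORDER = ("middle_deep", "middle_right", "middle_surface", "middle_left")
POSTERIOR_RING_ORDER = ("dorsal_hyoid", "posterior_right", "posterior_surface", "posterior_left")


class GeometryError(RuntimeError):
    """Per-frame geometric failure (self-intersection, degenerate boundary)."""


# ---------------------------------------------------------------------------
# Coronal rings
# ---------------------------------------------------------------------------


@dataclass
class CoronalRing:
    """A closed sampled curve through an ordered 4-marker coronal ring.

    ``points`` has shape (m + 1, 3) with ``points[-1] == points[0]``;
    ``points[0]`` is the designated start marker.  ``control_points`` are the
    four markers the spline interpolates (may be empty for analytic rings).
    """

    points: np.ndarray
    control_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.control_points = np.asarray(self.control_points, float).reshape(-1, 3)
        if len(self.points) < 4:
            raise ValueError("a ring needs at least 4 samples")
        if not np.allclose(self.points[0], self.points[-1], atol=1e-9):
            raise ValueError("ring must be closed (first sample == last sample)")

    @property
    def n_samples(self) -> int:
        """Number of distinct samples (closure point not double-counted)."""
        return len(self.points) - 1

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length along the closed polyline, length m + 1."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def circumference(self) -> float:
        return float(self.arc_lengths()[-1])

    def normal(self) -> np.ndarray:
        """Area-weighted (Newell) normal of the closed ring."""
        p = self.points[:-1]
        q = self.points[1:]
        n = np.sum(np.cross(p, q), axis=0)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise DegenerateGeometryError("ring has no well-defined normal")
        return n / norm

    def reversed(self) -> "CoronalRing":
        """Reverse traversal direction, keeping the start sample at index 0."""
        pts = self.points[:-1]
        rev = np.vstack([pts[0:1], pts[:0:-1], pts[0:1]])
        return CoronalRing(rev, self.control_points)


def fit_coronal_ring(control_points: np.ndarray, samples_per_loop: int = 300) -> CoronalRing:
    """Closed natural-spline ring through four ordered control points.

    The ordered markers are wrapped three full loops (13 knots, starting and
    ending at the first marker), a natural cubic spline with chord-length
    parameterization is fitted per coordinate, each loop is sampled at
    ``samples_per_loop`` points, and only the middle loop is retained.  The
    retained ring starts and ends exactly at the first control point and
    passes through all four controls.
    """
    ctrl = np.asarray(control_points, float).reshape(-1, 3)
    if len(ctrl) != 4:
        raise ValueError("a coronal ring is defined by exactly 4 control points")
    if np.isnan(ctrl).any():
        raise GeometryError("ring control point missing (NaN)")
    for i in range(4):
        for j in range(i + 1, 4):
            if np.linalg.norm(ctrl[i] - ctrl[j]) < 1e-9:
                raise DegenerateGeometryError("duplicate ring control points")
    knots = np.vstack([np.tile(ctrl, (3, 1)), ctrl[0:1]])  # 13 points, 3 loops
    chord = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, knots, bc_type="natural", axis=0)
    # Middle loop spans knots 4..8; sample it inclusively so closure is exact.
    ts = np.linspace(t[4], t[8], samples_per_loop + 1)
    pts = spline(ts)
    pts[0] = ctrl[0]
    pts[-1] = ctrl[0]
    return CoronalRing(pts, ctrl)


def ring_from_samples(points: np.ndarray) -> CoronalRing:
    """Ring from explicit ordered samples (closed automatically if needed).

    Used for analytic boundaries (e.g. exact circles) in validation work.
    """
    pts = np.asarray(points, float)
    if not np.allclose(pts[0], pts[-1], atol=1e-12):
        pts = np.vstack([pts, pts[0:1]])
    return CoronalRing(pts)


def resample_ring(ring: CoronalRing, n: int) -> np.ndarray:
    """n points at equal arc-length spacing along the ring, index 0 = start."""
    if n < 3:
        raise ValueError("need at least 3 resampled points")
    s = ring.arc_lengths()
    total = s[-1]
    targets = np.arange(n) * total / n
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, s, ring.points[:, k])
    return out


def resample_matched_rings(
    middle: CoronalRing, posterior: CoronalRing, n: int = 300
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-arc-length resampling of two rings with matched correspondence.

    Index 0 of the middle ring is its start marker (middle deep) and index 0
    of the posterior ring its start marker (reconstructed dorsal hyoid); both
    sequences are ordered with the same handedness about the middle->posterior
    axis (the posterior ring is auto-reversed, with a log entry, when its
    orientation opposes the middle ring's).
    """
    if n < 8:
        raise ValueError("need at least 8 matched samples")
    axis = posterior.points[:-1].mean(axis=0) - middle.points[:-1].mean(axis=0)
    if np.dot(middle.normal(), axis) * np.dot(posterior.normal(), axis) < 0:
        _log.info("resample_matched_rings: reversing posterior ring to match handedness")
        posterior = posterior.reversed()
    return resample_ring(middle, n), resample_ring(posterior, n)


# ---------------------------------------------------------------------------
# Harmonic surface fill
# ---------------------------------------------------------------------------


@dataclass
class CoronalSurface:
    """Harmonic fill of a coronal ring: a triangle mesh whose boundary is the
    ring samples (vertex indices 0..n_boundary-1) and whose interior vertices
    solve the cotangent-Laplacian Dirichlet problem per coordinate."""

    mesh: TriMesh
    boundary_indices: np.ndarray

    @property
    def boundary_points(self) -> np.ndarray:
        return self.mesh.vertices[self.boundary_indices]


def _principal_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and first-two-principal-direction basis (2, 3) of a ring."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt[:2]


def _interior_lattice(poly: Polygon, spacing: float) -> np.ndarray:
    """Hexagonal lattice of points strictly inside a polygon."""
    minx, miny, maxx, maxy = poly.bounds
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = []
    y = miny + dy
    row = 0
    while y < maxy:
        offset = 0.5 * spacing if row % 2 else 0.0
        xs = np.arange(minx + offset + 0.5 * spacing, maxx, spacing)
        if xs.size:
            rows.append(np.column_stack([xs, np.full(xs.size, y)]))
        y += dy
        row += 1
    if not rows:
        return np.empty((0, 2))
    pts = np.vstack(rows)
    # Keep points clear of the boundary so boundary edges survive Delaunay.
    inner = poly.buffer(-0.7 * spacing)
    if inner.is_empty:
        return np.empty((0, 2))
    keep = shapely.contains_xy(inner, pts[:, 0], pts[:, 1])
    return pts[keep]


def _cotangent_laplacian(points2d: np.ndarray, triangles: np.ndarray, clamp: bool) -> csc_matrix:
    """Sparse cotangent-weight Laplacian L = D - W on a planar triangulation."""
    i0, i1, i2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    p0, p1, p2 = points2d[i0], points2d[i1], points2d[i2]

    def cot(a, b, c):
        # cotangent of the angle at vertex a, for edge (b, c)
        u, v = b - a, c - a
        cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        return np.einsum("ij,ij->i", u, v) / np.maximum(np.abs(cross), 1e-15)

    w = np.concatenate([cot(p2, p0, p1), cot(p0, p1, p2), cot(p1, p2, p0)]) * 0.5
    if clamp:
        w = np.maximum(w, 0.0)
    rows = np.concatenate([i0, i1, i2])
    cols = np.concatenate([i1, i2, i0])
    n = len(points2d)
    wmat = coo_matrix((w, (rows, cols)), shape=(n, n))
    wmat = wmat + wmat.T
    deg = np.asarray(wmat.sum(axis=1)).ravel()
    lap = coo_matrix((deg, (np.arange(n), np.arange(n))), shape=(n, n)) - wmat
    return lap.tocsc()


def fill_harmonic_surface(
    ring, interior_spacing_factor: float = 1.0, clamp_cotangent: bool = False
) -> CoronalSurface:
    """Fill a closed ring with a harmonic (minimal-type) surface.

    The ring samples are projected onto the plane of their first two principal
    directions; the enclosed planar polygon is triangulated (Delaunay over the
    dense boundary samples plus a hexagonal interior lattice, triangles kept by
    centroid-in-polygon); and the x, y and z world coordinates of the interior
    vertices are obtained by solving the discrete Laplace equation with
    cotangent weights and the ring coordinates as Dirichlet data.  The surface
    is flat only when the ring itself is planar.

    ``interior_spacing_factor`` scales the interior lattice spacing relative to
    the boundary sample spacing (1.0 matches the boundary density).
    """
    boundary = ring.points[:-1] if isinstance(ring, CoronalRing) else np.asarray(ring, float)
    nb = len(boundary)
    centroid, basis = _principal_plane(boundary)
    b2 = (boundary - centroid) @ basis.T
    poly = Polygon(b2)
    if (not poly.is_valid) or (not poly.is_simple):
        raise GeometryError("projected ring boundary is self-intersecting")
    perim = np.sum(np.linalg.norm(np.diff(np.vstack([b2, b2[0:1]]), axis=0), axis=1))
    spacing = interior_spacing_factor * perim / nb
    interior2 = _interior_lattice(poly, spacing)
    all2 = np.vstack([b2, interior2])
    tri = Delaunay(all2)
    cent = all2[tri.simplices].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    faces = tri.simplices[keep]
    # Drop interior vertices orphaned by the filter, keeping boundary order.
    used = np.unique(faces)
    if not np.all(np.isin(np.arange(nb), used)):
        raise GeometryError("triangulation dropped boundary vertices")
    remap = -np.ones(len(all2), dtype=np.int64)
    remap[used] = np.arange(len(used))
    faces = remap[faces]
    pts2 = all2[used]
    # Boundary-edge presence check: every consecutive boundary pair is an edge.
    edges = set()
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edges.add((min(a, b), max(a, b)))
    for i in range(nb):
        j = (i + 1) % nb
        if (min(i, j), max(i, j)) not in edges:
            raise GeometryError("boundary edge lost in triangulation; ring too irregular")
    lap = _cotangent_laplacian(pts2, faces, clamp_cotangent)
    n_all = len(pts2)
    interior_idx = np.arange(nb, n_all)
    verts = np.empty((n_all, 3))
    verts[:nb] = boundary
    if interior_idx.size:
        lii = lap[interior_idx][:, interior_idx]
        lib = lap[interior_idx][:, :nb]
        rhs = -lib @ boundary
        solver = splu(lii.tocsc())
        verts[nb:] = np.column_stack([solver.solve(rhs[:, k]) for k in range(3)])
    # Orient faces consistently (counterclockwise in the projection plane).
    v2 = pts2[faces]
    signed = (v2[:, 1, 0] - v2[:, 0, 0]) * (v2[:, 2, 1] - v2[:, 0, 1]) - (
        v2[:, 2, 0] - v2[:, 0, 0]
    ) * (v2[:, 1, 1] - v2[:, 0, 1])
    flip = signed < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return CoronalSurface(TriMesh(verts, faces), np.arange(nb))


# ---------------------------------------------------------------------------
# Primitives and volumes
# ---------------------------------------------------------------------------


def _oriented(vertices: np.ndarray, faces: np.ndarray) -> TriMesh:
    """Flip all faces if needed so outward orientation gives positive volume."""
    mesh = TriMesh(vertices, faces)
    if _signed_volume_raw(mesh) < 0:
        mesh = TriMesh(vertices, faces[:, [0, 2, 1]])
    return mesh


def _consistently_wound(faces: np.ndarray) -> bool:
    """True when every directed edge appears exactly once (closed mesh with
    globally consistent winding)."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    directed = edges[:, 0].astype(np.int64) << 32 | edges[:, 1].astype(np.int64)
    if len(np.unique(directed)) != len(directed):
        return False
    undirected = np.sort(edges, axis=1)
    _, counts = np.unique(undirected, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def _assemble_closed(vertices: np.ndarray, fixed: np.ndarray, flippable: list) -> TriMesh:
    """Combine face groups into a consistently wound closed mesh, flipping
    whole groups as needed (the fill's winding sign is arbitrary per surface
    because the principal-direction basis has an arbitrary sign)."""
    k = len(flippable)
    for mask in range(2**k):
        groups = [fixed]
        for i, grp in enumerate(flippable):
            groups.append(grp[:, [0, 2, 1]] if (mask >> i) & 1 else grp)
        faces = np.vstack(groups)
        if _consistently_wound(faces):
            return _oriented(vertices, faces)
    raise GeometryError("could not assemble a consistently wound closed primitive")


def build_primitives(
    middle_surface: CoronalSurface,
    posterior_surface: CoronalSurface,
    anterior_marker: np.ndarray,
    vallecula_marker: np.ndarray | None,
) -> tuple[TriMesh, TriMesh | None, TriMesh | None]:
    """Build the three closed primitive meshes (AOT cone, POT cylinder, TB cone).

    The two coronal surfaces must be filled on matched resampled rings with
    identical sample counts.  The AOT cone fans from the anterior marker to the
    middle ring; the POT cylinder joins matched ring samples with a split quad
    strip; the TB cone fans from the vallecular marker to the posterior ring.
    When the vallecular marker is missing the TB mesh is omitted (None) and the
    event-layer fallback applies downstream.
    """
    mid_n = len(middle_surface.boundary_indices)
    post_n = len(posterior_surface.boundary_indices)
    if mid_n != post_n:
        raise ValueError("matched rings must have equal sample counts")

    def cone(surface: CoronalSurface, apex: np.ndarray) -> TriMesh:
        apex = np.asarray(apex, float).reshape(3)
        if np.isnan(apex).any():
            raise GeometryError("cone apex missing (NaN)")
        nv = surface.mesh.n_vertices
        verts = np.vstack([surface.mesh.vertices, apex])
        nb = len(surface.boundary_indices)
        fans = np.array([[nv, (i + 1) % nb, i] for i in range(nb)])
        return _assemble_closed(verts, fans, [surface.mesh.faces])

    aot = cone(middle_surface, anterior_marker)
    # POT cylinder: both base surfaces plus the side strip.
    nv_mid = middle_surface.mesh.n_vertices
    verts = np.vstack([middle_surface.mesh.vertices, posterior_surface.mesh.vertices])
    post_faces = posterior_surface.mesh.faces + nv_mid
    side = []
    n = mid_n
    for i in range(n):
        j = (i + 1) % n
        side.append([i, j, nv_mid + j])
        side.append([i, nv_mid + j, nv_mid + i])
    pot = _assemble_closed(
        verts, np.array(side), [middle_surface.mesh.faces, post_faces]
    )
    tb = None
    if vallecula_marker is not None and not np.isnan(np.asarray(vallecula_marker, float)).any():
        tb = cone(posterior_surface, vallecula_marker)
    return aot, pot, tb


def _signed_volume_raw(mesh: TriMesh, origin: np.ndarray | None = None) -> float:
    v = mesh.vertices
    o = v.mean(axis=0) if origin is None else np.asarray(origin, float)
    a = v[mesh.faces[:, 0]] - o
    b = v[mesh.faces[:, 1]] - o
    c = v[mesh.faces[:, 2]] - o
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def signed_mesh_volume(mesh: TriMesh, origin: np.ndarray | None = None) -> float:
    """Volume (mm^3) of a closed mesh as |sum of signed tetrahedron volumes|.

    Tetrahedra are spanned by each triangular face and a reference point (the
    mesh centroid by default); for a closed, consistently wound mesh the result
    is independent of that reference.  An open mesh triggers a warning (the
    reference-dependence check fails) and the centroid-based value is returned.
    """
    val = _signed_volume_raw(mesh, origin)
    if not mesh.is_closed():
        o = mesh.vertices.mean(axis=0)
        alt = _signed_volume_raw(mesh, o + np.array([10.0, 0.0, 0.0]))
        warnings.warn(
            "mesh is not closed: volume depends on the reference point "
            f"(centroid-based {val:.6g} vs shifted {alt:.6g} mm^3)"
        )
    return abs(val)


# ---------------------------------------------------------------------------
# Per-frame pipeline
# ---------------------------------------------------------------------------


@dataclass
class RegionalVolumes:
    """Per-frame AOT / POT / TB volumes in mL, plus failure log."""

    table: pd.DataFrame
    failures: list[tuple[int, str]]


def frame_volumes(
    middle_controls: np.ndarray,
    posterior_controls: np.ndarray,
    anterior: np.ndarray,
    vallecula: np.ndarray | None,
    ring_samples: int = 300,
    interior_spacing_factor: float = 2.0,
    clamp_cotangent: bool = False,
) -> tuple[float, float, float]:
    """AOT, POT, TB volumes (mL) for one frame of boundary markers."""
    mid_ring = fit_coronal_ring(middle_controls, ring_samples)
    post_ring = fit_coronal_ring(posterior_controls, ring_samples)
    mid_pts, post_pts = resample_matched_rings(mid_ring, post_ring, ring_samples)
    mid_surf = fill_harmonic_surface(ring_from_samples(mid_pts), interior_spacing_factor, clamp_cotangent)
    post_surf = fill_harmonic_surface(ring_from_samples(post_pts), interior_spacing_factor, clamp_cotangent)
    aot, pot, tb = build_primitives(mid_surf, post_surf, anterior, vallecula)
    aot_ml = signed_mesh_volume(aot) / 1000.0
    pot_ml = signed_mesh_volume(pot) / 1000.0
    tb_ml = signed_mesh_volume(tb) / 1000.0 if tb is not None else np.nan
    return aot_ml, pot_ml, tb_ml


def regional_volumes(
    markers: MarkerTrajectorySet,
    hyoid_dorsal_point: np.ndarray,
    ring_samples: int = 300,
    interior_spacing_factor: float = 2.0,
    clamp_cotangent: bool = False,
    frames: np.ndarray | None = None,
) -> RegionalVolumes:
    """Per-frame regional tongue volumes (mL) from the 10-marker constellation.

    Requires markers named middle_surface/right/left/deep, posterior_surface/
    right/left, anterior, vallecula, plus the reconstructed dorsal hyoid point
    series.  Frames whose geometry fails yield NaN volumes and are logged; the
    pipeline continues.  ``frames`` restricts computation to a frame subset
    (other rows are NaN).
    """
    hy = np.asarray(hyoid_dorsal_point, float)
    if hy.ndim == 1:
        hy = np.broadcast_to(hy, (markers.n_frames, 3))
    n = markers.n_frames
    out = np.full((n, 3), np.nan)
    failures: list[tuple[int, str]] = []
    idx = {name: markers.index(name) for name in (
        "middle_deep", "middle_right", "middle_surface", "middle_left",
        "posterior_right", "posterior_surface", "posterior_left", "anterior",
    )}
    has_vallecula = "vallecula" in markers.marker_names
    frame_list = range(n) if frames is None else np.atleast_1d(frames)
    for f in frame_list:
        c = markers.coords[f]
        mid_ctrl = np.array([c[idx["middle_deep"]], c[idx["middle_right"]],
                             c[idx["middle_surface"]], c[idx["middle_left"]]])
        post_ctrl = np.array([hy[f], c[idx["posterior_right"]],
                              c[idx["posterior_surface"]], c[idx["posterior_left"]]])
        vall = c[markers.index("vallecula")] if has_vallecula else None
        try:
            out[f] = frame_volumes(
                mid_ctrl, post_ctrl, c[idx["anterior"]], vall,
                ring_samples, interior_spacing_factor, clamp_cotangent,
            )
        except (GeometryError, DegenerateGeometryError) as exc:
            failures.append((int(f), str(exc)))
            _log.warning("frame %d: %s", f, exc)
    table = pd.DataFrame(out, columns=["aot_ml", "pot_ml", "tb_ml"])
    return RegionalVolumes(table, failures)
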