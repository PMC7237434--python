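"""Shared data model, readers/writers, configuration and logging.

Coordinate conventions used throughout the package (cranial anatomical frame):
+X anterior, +Y superior, +Z toward the animal's right; units are mm for
coordinates, mm/s for velocities, and mL (= mm^3 / 1000) for reported volumes.
Missing marker samples are carried as NaN and propagate through every derived
per-frame quantity; interpolation is never applied silently.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MarkerTrajectorySet",
    "AnatomicalFrame",
    "TriMesh",
    "PipelineConfig",
    "FormatError",
    "DegenerateGeometryError",
    "read_marker_table",
    "write_marker_table",
    "write_obj",
    "read_obj",
    "build_anatomical_frame",
    "get_logger",
]


class FormatError(ValueError):
    """Raised when an input table or mesh file violates the expected layout."""


class DegenerateGeometryError(ValueError):
    """Raised when input geometry is degenerate (collinear / duplicated points)."""


def get_logger(name: str = "hyolingual") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


# ---------------------------------------------------------------------------
# Marker trajectories
# ---------------------------------------------------------------------------


@dataclass
class MarkerTrajectorySet:
    """Per-frame 3D coordinates for a named set of markers.

    coords has shape (n_frames, n_markers, 3) in mm; missing samples are NaN.
    """

    frame_rate: float
    marker_names: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_markers, 3)")
        if self.coords.shape[1] != len(self.marker_names):
            raise ValueError("coords second dimension must match marker_names")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_markers(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def marker(self, name: str) -> np.ndarray:
        """(n_frames, 3) trajectory of a single marker."""
        return self.coords[:, self.index(name), :]

    def missing_mask(self) -> np.ndarray:
        """(n_frames, n_markers) boolean mask; True where any coordinate is NaN."""
        return np.isnan(self.coords).any(axis=2)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MarkerTrajectorySet":
        """Apply a rigid transform p -> R p + t to every marker sample."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        coords = self.coords @ rotation.T + translation
        return MarkerTrajectorySet(self.frame_rate, list(self.marker_names), coords)


def read_marker_table(path, frame_rate: float) -> MarkerTrajectorySet:
    """Read a comma-delimited marker table into a :class:`MarkerTrajectorySet`.

    The header names markers as ``<name>_X``, ``<name>_Y``, ``<name>_Z``
    triplets; one row per frame.  Non-numeric or blank cells become NaN.
    A ``frame`` index column is tolerated and ignored.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty marker table: {path}")
    cols = [c for c in df.columns if c.lower() not in ("frame", "time", "t")]
    names: list[str] = []
    for c in cols:
        if "_" not in c:
            raise FormatError(f"column {c!r} is not a <marker>_X/_Y/_Z triplet member")
        base, axis = c.rsplit("_", 1)
        if axis.upper() not in ("X", "Y", "Z"):
            raise FormatError(f"column {c!r} has unknown axis suffix {axis!r}")
        if base not in names:
            names.append(base)
    n_frames = len(df)
    coords = np.full((n_frames, len(names), 3), np.nan)
    for j, name in enumerate(names):
        for k, axis in enumerate("XYZ"):
            col = f"{name}_{axis}"
            if col not in df.columns:
                raise FormatError(f"marker {name!r} is missing coordinate column {col!r}")
            coords[:, j, k] = pd.to_numeric(df[col], errors="coerce").to_numpy()
    return MarkerTrajectorySet(frame_rate, names, coords)


def write_marker_table(traj: MarkerTrajectorySet, path) -> None:
    """Write a trajectory set to CSV (inverse of :func:`read_marker_table`)."""
    data = {"frame": np.arange(traj.n_frames)}
    for j, name in enumerate(traj.marker_names):
        for k, axis in enumerate("XYZ"):
            data[f"{name}_{axis}"] = traj.coords[:, j, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Anatomical frame
# ---------------------------------------------------------------------------


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame.

    ``axes`` rows are the frame's X (anterior), Y (superior) and Z (right
    lateral) unit vectors expressed in world coordinates.  The palate plane is
    the X-Z plane through the origin.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.axes = np.asarray(self.axes, float).reshape(3, 3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must be right-handed")

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World coordinates -> anatomical-frame coordinates."""
        points = np.asarray(points, float)
        return (points - self.origin) @ self.axes.T

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, float)
        return points @ self.axes + self.origin


def build_anatomical_frame(
    palate_landmarks: np.ndarray,
    midline_landmarks: np.ndarray,
    superior_hint: np.ndarray | None = None,
) -> AnatomicalFrame:
    """Construct the cranial anatomical frame from static bone landmarks.

    The palate plane is the least-squares plane through ``palate_landmarks``
    (which therefore have minimal Y variance in the new frame); X is the
    in-plane projection of the midline direction (``midline_landmarks`` ordered
    posterior-to-anterior, so the direction points anterior); Y is the plane
    normal on the superior side; Z = X x Y points to the animal's right.  The
    origin is the palate-landmark centroid.

    ``superior_hint`` is a world-space point on the superior side of the palate
    used to orient the normal; without it the normal closer to world +Y is
    chosen (documented convention).
    """
    palate = np.asarray(palate_landmarks, float)
    midline = np.asarray(midline_landmarks, float)
    if palate.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 palate landmarks")
    if midline.shape[0] < 2:
        raise DegenerateGeometryError("need at least 2 midline landmarks")
    origin = palate.mean(axis=0)
    centered = palate - origin
    # Least-squares plane: normal = singular vector of smallest singular value.
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("palate landmarks are collinear")
    normal = vt[2]
    if superior_hint is not None:
        if np.dot(np.asarray(superior_hint, float) - origin, normal) < 0:
            normal = -normal
    elif normal[1] < 0:
        normal = -normal
    anterior = midline[-1] - midline[0]
    anterior = anterior - np.dot(anterior, normal) * normal
    norm = np.linalg.norm(anterior)
    if norm < 1e-12:
        raise DegenerateGeometryError("midline direction is perpendicular to the palate plane")
    x_axis = anterior / norm
    y_axis = normal
    z_axis = np.cross(x_axis, y_axis)
    return AnatomicalFrame(origin=origin, axes=np.vstack([x_axis, y_axis, z_axis]))


# ---------------------------------------------------------------------------
# Triangle meshes
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """Indexed triangle mesh: vertices (n, 3) in mm, faces (m, 3) int indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def euler_characteristic(self) -> int:
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return self.n_vertices - len(edges) + self.n_faces

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def write_obj(mesh: TriMesh, path) -> None:
    """Write a Wavefront OBJ file (v/f records, 1-based indices)."""
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise ValueError("refusing to write an empty mesh")
    buf = _io.StringIO()
    for v in mesh.vertices:
        buf.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    for f in mesh.faces:
        buf.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    Path(path).write_text(buf.getvalue())


def read_obj(path) -> TriMesh:
    """Read v/f records of a Wavefront OBJ (triangles only)."""
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            vertices.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            if len(idx) != 3:
                raise FormatError("only triangular faces are supported")
            faces.append(idx)
    if not vertices:
        raise FormatError(f"no vertices in OBJ file {path}")
    return TriMesh(np.array(vertices), np.array(faces))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Tunable parameters shared across pipeline stages.

    All tolerances must be positive; the seed is recorded in every output the
    pipeline writes.
    """

    frame_rate: float = 200.0            # Hz, videoradiography frame rate
    emg_highpass_hz: float = 30.0        # EMG high-pass cutoff
    emg_lowpass_hz: float | None = None  # optional low-pass (1000-3000 Hz typical)
    emg_rms_window_s: float = 0.005      # RMS integration window (downsamples to 200 Hz)
    runs_test_reps: int = 30             # averaged runs-test replicates per channel
    runs_test_grid: int = 200            # candidate-threshold grid resolution
    alpha_mm: float = 6.0                # alpha-shape radius bound, mm
    ring_samples: int = 300              # samples per coronal ring / loop
    interior_spacing_factor: float = 2.0 # interior mesh spacing / boundary spacing
    clamp_cotangent: bool = False        # clamp negative cotangent weights at 0
    event_smooth_frames: int = 5         # moving-median width for event extrema (0 = off)
    marker_filter_hz: float | None = None  # optional marker low-pass (default: none)
    interpolate_gaps: bool = False       # explicit, logged linear gap interpolation
    max_gap_frames: int = 5
    spline_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("emg_rms_window_s", "alpha_mm", "spline_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ring_samples < 8:
            raise ValueError("ring_samples must be at least 8")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
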