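"""Rigid-body kinematics from bone-fixed marker clusters.

Pose estimation is the closed-form least-squares (Kabsch/SVD) fit with a
reflection guard; mandibular pitch is the Z component of an intrinsic Z-X-Y
Euler decomposition, signed so jaw opening is positive; hyoid excursion is the
change in basihyoid X (protraction, positive anterior) and Y (elevation,
positive superior) relative to a reference frame.  Precision statistics follow
the frozen-specimen protocol: per-animal standard deviations pooled as the
root mean square, and zero-velocity bands of +/- 2 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AnatomicalFrame, DegenerateGeometryError, MarkerTrajectorySet

__all__ = [
    "RigidBodyPose",
    "PrecisionSummary",
    "InsufficientMarkerError",
    "estimate_pose",
    "estimate_pose_series",
    "gape_pitch_angle",
    "hyoid_excursion",
    "pooled_sd",
    "zero_velocity_band",
    "central_velocity",
]


class InsufficientMarkerError(ValueError):
    """Fewer than three usable markers in a cluster frame."""


@dataclass
class RigidBodyPose:
    """Per-frame rigid transform of a bone into the cranial anatomical frame.

    ``rotation`` is (n_frames, 3, 3), ``translation`` (n_frames, 3) mm, and
    ``residual_rms`` (n_frames,) mm; frames where the fit failed are NaN.
    """

    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.rotation.shape[0]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Pose reference-configuration points: (n_frames, n_points, 3)."""
        points = np.asarray(points, float)
        return np.einsum("fij,pj->fpi", self.rotation, points) + self.translation[:, None, :]


@dataclass
class PrecisionSummary:
    """Static-trial precision: per-animal SDs, pooled SD, +/-2 SD band."""

    per_animal_sd: np.ndarray
    s_pooled: float
    band: tuple[float, float]


def estimate_pose(
    bone_markers_ref: np.ndarray, bone_markers_frame: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping a reference cluster onto one frame.

    Returns (R, t, residual_rms) minimizing sum ||R p_ref + t - p_frame||^2,
    with det(R) = +1 enforced.  Marker rows with NaN in either configuration
    are dropped; at least three non-collinear markers must remain.
    """
    ref = np.asarray(bone_markers_ref, float)
    cur = np.asarray(bone_markers_frame, float)
    if ref.shape != cur.shape:
        raise ValueError("reference and frame clusters must have matching shapes")
    ok = ~(np.isnan(ref).any(axis=1) | np.isnan(cur).any(axis=1))
    ref, cur = ref[ok], cur[ok]
    if len(ref) < 3:
        raise InsufficientMarkerError(f"only {len(ref)} usable markers (need >= 3)")
    ref_c = ref - ref.mean(axis=0)
    cur_c = cur - cur.mean(axis=0)
    s = np.linalg.svd(ref_c, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("marker cluster is collinear")
    h = ref_c.T @ cur_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cur.mean(axis=0) - rot @ ref.mean(axis=0)
    residual = cur - (ref @ rot.T + t)
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return rot, t, rms


def estimate_pose_series(
    reference: np.ndarray, trajectory: MarkerTrajectorySet | np.ndarray
) -> RigidBodyPose:
    """Pose every frame of a marker-cluster trajectory against a reference.

    ``trajectory`` is a MarkerTrajectorySet or an (n_frames, n_markers, 3)
    array; frames with fewer than three usable markers get NaN poses.
    """
    coords = trajectory.coords if isinstance(trajectory, MarkerTrajectorySet) else np.asarray(trajectory, float)
    n = coords.shape[0]
    rot = np.full((n, 3, 3), np.nan)
    trans = np.full((n, 3), np.nan)
    rms = np.full(n, np.nan)
    for f in range(n):
        try:
            rot[f], trans[f], rms[f] = estimate_pose(reference, coords[f])
        except (InsufficientMarkerError, DegenerateGeometryError):
            continue
    return RigidBodyPose(rot, trans, rms)


def _pitch_zxy(rotation: np.ndarray) -> np.ndarray:
    """Z angle (radians) of an intrinsic Z-X-Y Euler decomposition."""
    r = np.asarray(rotation, float)
    return np.arctan2(-r[..., 0, 1], r[..., 1, 1])


def gape_pitch_angle(
    mandible_pose: RigidBodyPose,
    reference_frame: int | None = None,
) -> np.ndarray:
    """Mandibular pitch in degrees, signed so jaw opening is positive.

    Pitch is the rotation of the mandible about the cranial Z (mediolateral)
    axis, taken as the Z component of an intrinsic Z-X-Y decomposition of each
    frame's rotation.  The zero reference is ``reference_frame`` when given,
    otherwise the frame of minimum gape within the series (intercuspation
    proxy, logged by callers).
    """
    raw = np.degrees(_pitch_zxy(mandible_pose.rotation))
    # Opening rotates the anterior direction inferiorly, i.e. negatively about +Z.
    gape = -raw
    if reference_frame is None:
        if np.all(np.isnan(gape)):
            return gape
        reference_frame = int(np.nanargmin(gape))
    return gape - gape[reference_frame]


def hyoid_excursion(
    hyoid_point: np.ndarray,
    frame: AnatomicalFrame,
    reference_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hyoid protraction (delta X) and elevation (delta Y) in mm.

    ``hyoid_point`` is the (n_frames, 3) world-space basihyoid reference point
    (e.g. cluster centroid); values are changes relative to ``reference_index``.
    """
    pts = np.asarray(hyoid_point, float)
    if not 0 <= reference_index < len(pts):
        raise IndexError("reference_index outside series")
    local = frame.to_frame(pts)
    delta = local - local[reference_index]
    return delta[:, 0], delta[:, 1]


def pooled_sd(sds) -> float:
    """Pooled standard deviation across k animals: sqrt(mean of squared SDs)."""
    arr = np.asarray(sds, float)
    if arr.size == 0:
        raise ValueError("need at least one standard deviation")
    if np.any(arr < 0):
        raise ValueError("standard deviations must be non-negative")
    return float(np.sqrt(np.mean(arr**2)))


def zero_velocity_band(precision_velocity_series) -> tuple[float, float]:
    """+/- 2 SD band about zero from a static-specimen velocity series."""
    arr = np.asarray(precision_velocity_series, float)
    arr = arr[~np.isnan(arr)]
    sd = float(np.std(arr))
    if sd == 0.0:
        warnings.warn("constant precision series: zero-velocity band is (0, 0)")
    return (-2.0 * sd, 2.0 * sd)


def central_velocity(series: np.ndarray, frame_rate: float) -> np.ndarray:
    """First derivative by central differences (one-sided at the endpoints)."""
    arr = np.asarray(series, float)
    return np.gradient(arr, 1.0 / frame_rate, axis=0)
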