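"""Extrinsic muscle lengths, sagittal orientation, contraction state, and
linear tongue dimensions.

Muscle length is the Euclidean distance between the two attachment points
(implanted markers or reconstructed points).  The sagittal orientation angle
is measured on the insertion-to-origin line projected into the cranial X-Y
plane, with anterior = 0 deg, superior = 90 deg, posterior = 180 deg,
inferior = 270 deg; a muscle is predominantly posteriorly oriented when
135 deg < theta < 225 deg.  Negative length velocity is shortening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnatomicalFrame, MarkerTrajectorySet

__all__ = [
    "MuscleDefinition",
    "muscle_length",
    "sagittal_angle",
    "is_posteriorly_oriented",
    "classify_state",
    "tongue_dimensions",
]

STATE_CONCENTRIC = "concentric"
STATE_ISOMETRIC = "isometric"
STATE_ECCENTRIC = "eccentric"
STATE_INACTIVE = "inactive"


@dataclass(frozen=True)
class MuscleDefinition:
    """A muscle as a pair of attachment identifiers (origin on bone, insertion
    in the tongue); attachments resolve to marker names or supplied point series."""

    name: str
    origin: str
    insertion: str

    def __post_init__(self) -> None:
        if self.origin == self.insertion:
            raise ValueError(f"muscle {self.name!r}: attachments must be distinct")


def _resolve(att: str, markers: MarkerTrajectorySet, extra: dict | None) -> np.ndarray:
    if extra and att in extra:
        pts = np.asarray(extra[att], float)
        if pts.ndim == 1:
            pts = np.broadcast_to(pts, (markers.n_frames, 3))
        return pts
    return markers.marker(att)  # raises KeyError for unknown names


def muscle_length(
    definition: MuscleDefinition,
    markers: MarkerTrajectorySet,
    extra_points: dict | None = None,
) -> np.ndarray:
    """Per-frame Euclidean muscle length in mm; NaN where an endpoint is missing."""
    a = _resolve(definition.origin, markers, extra_points)
    b = _resolve(definition.insertion, markers, extra_points)
    return np.linalg.norm(a - b, axis=1)


def sagittal_angle(
    definition: MuscleDefinition,
    markers: MarkerTrajectorySet,
    frame: AnatomicalFrame,
    extra_points: dict | None = None,
) -> np.ndarray:
    """Orientation (degrees in [0, 360)) of the insertion->origin line in the
    cranial sagittal (X-Y) plane; NaN where the projection has zero length."""
    origin = frame.to_frame(_resolve(definition.origin, markers, extra_points))
    insertion = frame.to_frame(_resolve(definition.insertion, markers, extra_points))
    v = origin - insertion
    px, py = v[:, 0], v[:, 1]
    ang = np.degrees(np.arctan2(py, px)) % 360.0
    ang[np.hypot(px, py) < 1e-12] = np.nan
    return ang


def is_posteriorly_oriented(theta_deg: np.ndarray) -> np.ndarray:
    """Predominantly posterior orientation predicate: 135 < theta < 225 deg."""
    t = np.asarray(theta_deg, float)
    return (t > 135.0) & (t < 225.0)


def classify_state(
    velocity: np.ndarray,
    band: tuple[float, float],
    active: np.ndarray,
) -> np.ndarray:
    """Per-frame contraction state from length velocity and EMG activity.

    Active frames are concentric (velocity below the zero-velocity band,
    i.e. shortening), eccentric (above it) or isometric (within it); inactive
    frames are labelled inactive regardless of velocity.
    """
    lo, hi = band
    if lo > hi:
        raise ValueError(f"malformed zero-velocity band ({lo}, {hi})")
    v = np.asarray(velocity, float)
    act = np.asarray(active, bool)
    out = np.full(v.shape, STATE_INACTIVE, dtype=object)
    out[act & (v < lo)] = STATE_CONCENTRIC
    out[act & (v > hi)] = STATE_ECCENTRIC
    out[act & (v >= lo) & (v <= hi)] = STATE_ISOMETRIC
    out[np.isnan(v)] = None
    return out


# Marker names the dimension definitions rely on.
_REQ = {
    "posterior_width": ("posterior_right", "posterior_left"),
    "posterior_length": ("posterior_surface", "middle_surface"),
    "anterior_width": ("lateral_right", "lateral_left"),
    "anterior_length": ("anterior", "middle_surface"),
    "anterior_depth": ("middle_surface", "middle_deep"),
    "tb_width": ("posterior_right", "posterior_left"),
}


def tongue_dimensions(
    markers: MarkerTrajectorySet,
    frame: AnatomicalFrame,
    hyoid_dorsal_point: np.ndarray,
    vallecula: str = "vallecula",
) -> pd.DataFrame:
    """Axis-projected linear tongue dimensions per frame (mm).

    Posterior width = Z distance between the posterior lateral markers;
    posterior depth = Y distance between the posterior surface marker and the
    hyoid dorsum; posterior length = X distance between posterior and middle
    surface markers.  Anterior dimensions use the same axis-projection scheme
    on the anterior constellation.  Tongue-base length is the X distance
    between the posterolateral midpoint and the vallecular marker; tongue-base
    depth the Y distance between posterior surface and vallecular markers.
    Dimensions with missing markers are NaN.
    """
    hy = frame.to_frame(np.asarray(hyoid_dorsal_point, float))
    if hy.ndim == 1:
        hy = np.broadcast_to(hy, (markers.n_frames, 3))

    def local(name: str) -> np.ndarray | None:
        try:
            return frame.to_frame(markers.marker(name))
        except KeyError:
            return None

    n = markers.n_frames
    nanvec = np.full(n, np.nan)
    cols: dict[str, np.ndarray] = {}

    def axis_dist(a, b, axis: int) -> np.ndarray:
        if a is None or b is None:
            return nanvec
        return np.abs(a[:, axis] - b[:, axis])

    names = set(sum(_REQ.values(), ())) | {vallecula, "posterior_surface"}
    m = {name: local(name) for name in names}
    cols["posterior_width"] = axis_dist(m["posterior_right"], m["posterior_left"], 2)
    ps = m["posterior_surface"]
    cols["posterior_depth"] = np.abs(ps[:, 1] - hy[:, 1]) if ps is not None else nanvec
    cols["posterior_length"] = axis_dist(ps, m["middle_surface"], 0)
    cols["anterior_width"] = axis_dist(m["lateral_right"], m["lateral_left"], 2)
    cols["anterior_length"] = axis_dist(m["anterior"], m["middle_surface"], 0)
    cols["anterior_depth"] = axis_dist(m["middle_surface"], m["middle_deep"], 1)
    cols["tb_width"] = axis_dist(m["posterior_right"], m["posterior_left"], 2)
    val = m[vallecula]
    if val is not None and m["posterior_right"] is not None and m["posterior_left"] is not None:
        mid_x = 0.5 * (m["posterior_right"][:, 0] + m["posterior_left"][:, 0])
        cols["tb_length"] = np.abs(mid_x - val[:, 0])
    else:
        cols["tb_length"] = nanvec
    cols["tb_depth"] = axis_dist(m.get("posterior_surface"), val, 1)
    return pd.DataFrame(cols)
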