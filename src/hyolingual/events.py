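"""Swallow-cycle event detection and temporal alignment.

Tongue base retraction (TBR) onset is the frame at which the posterior
superficial marker reaches its most anterior X position before moving
posteriorly; TBR offset the frame at which the vallecular marker reaches its
most posterior X after onset.  When no vallecular series is available the
offset falls back to the posterior-surface minimum (flagged as such).  The
intercuspal phase (IP) comprises maximal intervals in which mandibular pitch
velocity stays within the precision-study +/- 2 SD zero-velocity band.  All
aligned quantities are delta series relative to their value at TBR onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "SwallowCycleRecord",
    "EventDetectionError",
    "detect_tbr",
    "detect_ip",
    "delta_series",
]

OFFSET_VALLECULAR = "vallecular"
OFFSET_FALLBACK = "posterior-surface fallback"


class EventDetectionError(RuntimeError):
    """No usable extremum inside the search window."""


@dataclass
class SwallowCycleRecord:
    """Per-cycle events and aligned delta series."""

    cycle_id: int
    onset: int
    offset: int
    offset_method: str
    ip_intervals: list = field(default_factory=list)
    deltas: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("TBR onset must precede offset")


def _smoothed(x: np.ndarray, width: int) -> np.ndarray:
    if width and width > 1:
        return median_filter(np.asarray(x, float), size=width, mode="nearest")
    return np.asarray(x, float)


def _refined_extremum(raw: np.ndarray, smooth: np.ndarray, i0: int, i1: int,
                      width: int, mode: str) -> int:
    """Locate an extremum on the smoothed copy, then map the index back to the
    raw series by re-running arg-extremum on raw within the smoothing window
    (exact on noise-free traces, robust at precision-scale noise)."""
    pick = np.nanargmax if mode == "max" else np.nanargmin
    i_s = i0 + int(pick(smooth[i0:i1]))
    if width and width > 1:
        w = width // 2
        a, b = max(i0, i_s - w), min(i1, i_s + w + 1)
        return a + int(pick(raw[a:b]))
    return i_s


def detect_tbr(
    posterior_surface_x: np.ndarray,
    vallecular_x: np.ndarray | None,
    window: tuple[int, int] | None = None,
    smooth_frames: int = 5,
) -> tuple[int, int, str]:
    """TBR onset and offset frames within a per-cycle search window.

    X is positive anterior.  Extrema are located on an optionally median-
    smoothed copy (indices refer to the raw series).  An extremum landing on a
    window edge indicates a monotone series with no interior extremum and
    raises :class:`EventDetectionError`.
    """
    px = np.asarray(posterior_surface_x, float)
    i0, i1 = window if window is not None else (0, len(px))
    if not (0 <= i0 < i1 <= len(px)):
        raise ValueError("search window outside series")
    sm = _smoothed(px, smooth_frames)
    onset = _refined_extremum(px, sm, i0, i1, smooth_frames, "max")
    if onset in (i0, i1 - 1):
        raise EventDetectionError("no interior anterior maximum: onset detection failed")
    if vallecular_x is not None and not np.all(np.isnan(vallecular_x)):
        raw_off = np.asarray(vallecular_x, float)
        method = OFFSET_VALLECULAR
    else:
        raw_off = px
        method = OFFSET_FALLBACK
    vx = _smoothed(raw_off, smooth_frames)
    offset = _refined_extremum(raw_off, vx, onset + 1, i1, smooth_frames, "min")
    if offset == i1 - 1:
        raise EventDetectionError("no interior posterior minimum: offset detection failed")
    return onset, offset, method


def detect_ip(
    pitch_velocity: np.ndarray,
    band: tuple[float, float],
    min_duration: int = 2,
) -> list[tuple[int, int]]:
    """Maximal intervals (half-open) where pitch velocity is inside the band."""
    lo, hi = band
    v = np.asarray(pitch_velocity, float)
    inside = (v >= lo) & (v <= hi)
    padded = np.concatenate([[False], inside, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b - a >= min_duration]


def delta_series(series: np.ndarray, onset: int) -> np.ndarray:
    """Change relative to the value at TBR onset: value(t) - value(onset)."""
    arr = np.asarray(series, float)
    if not 0 <= onset < len(arr):
        raise IndexError("onset outside series")
    ref = arr[onset]
    if np.any(np.isnan(np.atleast_1d(ref))):
        raise ValueError("value at onset is missing; delta series undefined")
    return arr - ref
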