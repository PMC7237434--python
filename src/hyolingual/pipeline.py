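"""End-to-end swallow analysis over one (synthetic or recorded) trial.

Thin orchestration over the stage modules: build the cranial frame, pose the
bone clusters, detect TBR, and measure every per-cycle delta (marker
displacements, hyoid excursion, muscle length changes, tongue dimensions,
regional volumes) between TBR onset and offset.  This is the closed loop the
generator-recovery tests and the acceptance script exercise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import events, geometry, muscles, rigid
from .io import build_anatomical_frame
from .synthetic import SyntheticDataset

__all__ = ["CycleAnalysis", "analyze_trial"]

MUSCLES = ("styloglossus", "hyoglossus", "palatoglossus", "geniohyoid")


@dataclass
class CycleAnalysis:
    """Measured per-cycle quantities for one swallow trial."""

    onset: int
    offset: int
    offset_method: str
    deltas: dict          # name -> measured change over TBR
    series: dict          # name -> per-frame series (anatomical frame)


def analyze_trial(
    ds: SyntheticDataset,
    volume_frames: str = "events",
    ring_samples: int | None = None,
    interior_spacing_factor: float | None = None,
) -> CycleAnalysis:
    """Run the full measurement pipeline on one trial.

    ``volume_frames`` selects where regional volumes are evaluated: "events"
    (onset and offset only, fast) or "all".  Ring discretization defaults to
    the scenario's own settings so generator closure is apples-to-apples.
    """
    sc = ds.scenario
    n = sc.n_frames
    frame = build_anatomical_frame(
        ds.palate_landmarks, ds.midline_landmarks, superior_hint=np.array([20.0, 50.0, 0.0])
    )
    rs = ring_samples if ring_samples is not None else sc.ring_samples
    isf = interior_spacing_factor if interior_spacing_factor is not None else sc.interior_spacing_factor

    # --- rigid bodies -----------------------------------------------------
    mandible_pose = rigid.estimate_pose_series(ds.mandible_ref, ds.mandible)
    gape = rigid.gape_pitch_angle(mandible_pose)
    hyoid_pose = rigid.estimate_pose_series(ds.hyoid_ref, ds.hyoid)
    hyoid_center = hyoid_pose.apply(ds.hyoid_ref).mean(axis=1)

    # --- events -----------------------------------------------------------
    tongue_local = {
        name: frame.to_frame(ds.tongue.marker(name)) for name in ds.tongue.marker_names
    }
    onset, offset, method = events.detect_tbr(
        tongue_local["posterior_surface"][:, 0],
        tongue_local["vallecula"][:, 0] if "vallecula" in ds.tongue.marker_names else None,
        window=(0, n),
    )

    # --- kinematic deltas -------------------------------------------------
    protraction, elevation = rigid.hyoid_excursion(hyoid_center, frame, reference_index=onset)
    deltas = {
        "hyoid_protraction": float(protraction[offset]),
        "hyoid_elevation": float(elevation[offset]),
    }
    for name in ("posterior_surface", "posterior_deep", "vallecula"):
        x = tongue_local[name][:, 0]
        deltas[f"{name}_retraction"] = float(-(x[offset] - x[onset]))

    # --- muscle lengths ---------------------------------------------------
    series = {"gape_deg": gape, "hyoid_protraction": protraction, "hyoid_elevation": elevation}
    for m in MUSCLES:
        key_o, key_i = f"{m}_origin", f"{m}_insertion"
        if key_o not in ds.extra_points:
            continue
        defn = muscles.MuscleDefinition(m, key_o, key_i)
        length = muscles.muscle_length(defn, ds.tongue, ds.extra_points)
        theta = muscles.sagittal_angle(defn, ds.tongue, frame, ds.extra_points)
        series[f"{m}_length"] = length
        series[f"{m}_theta"] = theta
        deltas[f"{m}_delta"] = float(length[offset] - length[onset])

    # --- tongue dimensions ------------------------------------------------
    dims = muscles.tongue_dimensions(ds.tongue, frame, ds.hyoid_dorsal)
    series["dimensions"] = dims
    for col in ("tb_length", "posterior_width", "posterior_depth"):
        deltas[f"{col}_delta"] = float(dims[col].iloc[offset] - dims[col].iloc[onset])

    # --- regional volumes -------------------------------------------------
    frames = np.array([onset, offset]) if volume_frames == "events" else None
    vols = geometry.regional_volumes(
        ds.tongue, ds.hyoid_dorsal, ring_samples=rs,
        interior_spacing_factor=isf, frames=frames,
    )
    series["volumes"] = vols.table
    for col, key in (("aot_ml", "delta_aot_ml"), ("pot_ml", "delta_pot_ml"), ("tb_ml", "delta_tb_ml")):
        deltas[key] = float(vols.table[col].iloc[offset] - vols.table[col].iloc[onset])

    return CycleAnalysis(onset, offset, method, deltas, series)
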