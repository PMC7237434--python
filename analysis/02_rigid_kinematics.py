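#!/usr/bin/env python
"""Rigid-body kinematics: bone poses, jaw gape pitch, hyoid excursion.

Reads the synthetic trial written by 01_simulate.py, fits per-frame rigid
transforms to the mandible and hyoid marker clusters, and writes the
per-frame kinematic table to results/kinematics.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hyolingual.io import build_anatomical_frame, read_marker_table
from hyolingual.rigid import estimate_pose_series, gape_pitch_angle, hyoid_excursion

ROOT = Path(__file__).resolve().parents[1] / "results"
SYN = ROOT / "synthetic"


def main():
    palate = np.loadtxt(SYN / "palate_landmarks.csv", delimiter=",")
    midline = np.loadtxt(SYN / "midline_landmarks.csv", delimiter=",")
    frame = build_anatomical_frame(palate, midline, superior_hint=[20.0, 50.0, 0.0])

    mandible = read_marker_table(SYN / "mandible.csv", 200.0)
    hyoid = read_marker_table(SYN / "hyoid.csv", 200.0)
    mandible_ref = np.loadtxt(SYN / "mandible_ref.csv", delimiter=",")
    hyoid_ref = np.loadtxt(SYN / "hyoid_ref.csv", delimiter=",")

    mpose = estimate_pose_series(mandible_ref, mandible)
    gape = gape_pitch_angle(mpose)
    hpose = estimate_pose_series(hyoid_ref, hyoid)
    hyoid_center = hpose.apply(hyoid_ref).mean(axis=1)
    protraction, elevation = hyoid_excursion(hyoid_center, frame, reference_index=0)

    table = pd.DataFrame(
        {
            "frame": np.arange(mandible.n_frames),
            "gape_deg": gape,
            "hyoid_protraction_mm": protraction,
            "hyoid_elevation_mm": elevation,
            "mandible_residual_rms_mm": mpose.residual_rms,
            "hyoid_residual_rms_mm": hpose.residual_rms,
        }
    )
    ROOT.mkdir(exist_ok=True)
    table.to_csv(ROOT / "kinematics.csv", index=False)
    print(f"wrote {ROOT / 'kinematics.csv'}")
    print(f"  gape range {np.nanmin(gape):.2f}..{np.nanmax(gape):.2f} deg; "
          f"hyoid excursion up to {np.nanmax(protraction):.2f} mm protraction, "
          f"{np.nanmax(elevation):.2f} mm elevation")
    print(f"  mean pose residual {np.nanmean(mpose.residual_rms):.3f} mm "
          "(consistent with the 0.07 mm marker noise)")


if __name__ == "__main__":
    main()
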