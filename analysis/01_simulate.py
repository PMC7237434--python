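#!/usr/bin/env python
"""Generate the default synthetic swallow trial and write it to disk.

Produces marker trajectories (200 Hz), bone-cluster trajectories, EMG
channels, anatomical landmarks, and the ground-truth record under
results/synthetic/.  The programmed swallow uses the default study-scale
magnitudes with 0.07 mm marker noise.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from hyolingual.io import MarkerTrajectorySet, write_marker_table
from hyolingual.synthetic import SwallowScenario, generate_scenario

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def _cluster_table(arr, frame_rate, prefix="m"):
    names = [f"{prefix}{i}" for i in range(arr.shape[1])]
    return MarkerTrajectorySet(frame_rate, names, arr)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    sc = SwallowScenario(seed=args.seed)
    ds = generate_scenario(sc)

    write_marker_table(ds.tongue, OUT / "tongue.csv")
    for name, arr in (("mandible", ds.mandible), ("cranium", ds.cranium), ("hyoid", ds.hyoid)):
        write_marker_table(_cluster_table(arr, sc.frame_rate), OUT / f"{name}.csv")
    np.savetxt(OUT / "mandible_ref.csv", ds.mandible_ref, delimiter=",")
    np.savetxt(OUT / "cranium_ref.csv", ds.cranium_ref, delimiter=",")
    np.savetxt(OUT / "hyoid_ref.csv", ds.hyoid_ref, delimiter=",")
    np.savetxt(OUT / "palate_landmarks.csv", ds.palate_landmarks, delimiter=",")
    np.savetxt(OUT / "midline_landmarks.csv", ds.midline_landmarks, delimiter=",")

    extra_names = sorted(ds.extra_points)
    extra = np.stack([ds.extra_points[k] for k in extra_names], axis=1)
    write_marker_table(MarkerTrajectorySet(sc.frame_rate, extra_names, extra), OUT / "extra_points.csv")

    for name, raw in ds.emg.items():
        pd.DataFrame({name: raw}).to_csv(OUT / f"emg_{name}.csv", index=False)

    gt = {}
    for k, v in ds.ground_truth.items():
        gt[k] = v.tolist() if isinstance(v, np.ndarray) else v
    (OUT / "ground_truth.json").write_text(json.dumps(gt, indent=2, default=float))
    (OUT / "scenario.json").write_text(json.dumps(asdict(sc), indent=2))

    print(f"wrote synthetic trial (seed {args.seed}) to {OUT}")
    print(f"  {ds.tongue.n_frames} frames at {sc.frame_rate:g} Hz, "
          f"{ds.tongue.n_markers} tongue markers, {len(ds.emg)} EMG channels")
    print(f"  programmed TBR: frames {sc.tbr_onset}-{sc.tbr_offset}, "
          f"dTB {ds.ground_truth['delta_tb_ml']:.3f} mL, "
          f"dPOT {ds.ground_truth['delta_pot_ml']:.3f} mL")


if __name__ == "__main__":
    main()
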