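#!/usr/bin/env python
"""EMG conditioning and runs-test burst detection.

Band-filters, rectifies and RMS-integrates each raw channel to a 200 Hz
envelope, derives each channel's noise threshold with the averaged runs test,
and writes envelopes, thresholds, and burst intervals under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hyolingual.emg import activity_flags, condition_signal, thexton_threshold

ROOT = Path(__file__).resolve().parents[1] / "results"
SYN = ROOT / "synthetic"
FS = 2000.0


def main():
    scenario = json.loads((SYN / "scenario.json").read_text())
    fs = scenario.get("emg_fs", FS)
    envelopes = {}
    thresholds = {}
    burst_rows = []
    for path in sorted(SYN.glob("emg_*.csv")):
        name = path.stem.removeprefix("emg_")
        raw = pd.read_csv(path)[name].to_numpy()
        env = condition_signal(raw, fs=fs)
        thr = thexton_threshold(env, seed=scenario["seed"]).threshold
        flags, bursts = activity_flags(env, thr)
        envelopes[name] = env
        thresholds[name] = thr
        for onset, offset in bursts:
            if offset - onset > 5:  # ignore isolated supra-threshold blips
                burst_rows.append({"channel": name, "onset_frame": onset,
                                   "offset_frame": offset,
                                   "duration_s": (offset - onset) / 200.0})
    pd.DataFrame(envelopes).to_csv(ROOT / "emg_envelopes.csv", index=False)
    (ROOT / "emg_thresholds.json").write_text(json.dumps(thresholds, indent=2))
    pd.DataFrame(burst_rows).to_csv(ROOT / "emg_bursts.csv", index=False)
    print(f"wrote envelopes, thresholds and bursts for {len(envelopes)} channels")
    for row in burst_rows:
        print(f"  {row['channel']}: burst frames {row['onset_frame']}-{row['offset_frame']}"
              f" ({row['duration_s']:.2f} s)")


if __name__ == "__main__":
    main()
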