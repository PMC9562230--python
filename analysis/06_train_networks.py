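#!/usr/bin/env python
"""Validate the proxy with the three feed-forward network presets.

For each preset, generates a model-consistent study whose quality spread is
calibrated to panel-like statistics, augments it to 1000 synthetic rows,
trains on those rows only, and evaluates MAE on the 18 original wines (and
separately on the 6 never used in augmentation).  Three seeds per preset.
Output: results/network_validation.csv.
"""

from pathlib import Path

import pandas as pd

from winepi.experiments import end_to_end_network
from winepi.synthetic import calibrated_truth

OUT = Path("results/network_validation.csv")
SEEDS = (1, 2, 3)


def main() -> None:
    truth = calibrated_truth()
    print(f"calibrated truth: alpha={truth.alpha} n={truth.n:.4f} k={truth.k:.3f} "
          "(quality spread matched to panel ratings)")
    rows = []
    for preset in ("data1", "data2", "data3"):
        for seed in SEEDS:
            o = end_to_end_network(truth, preset=preset, data_seed=seed, train_seed=seed)
            rows.append(o.__dict__)
            print(f"  {preset} seed {seed}: stopped at epoch {o.stopping_epoch:4d}, "
                  f"MAE {o.test_mae_all:.3f} on all 18 wines, "
                  f"{o.test_mae_holdout:.3f} on the 6 held out")
    frame = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(OUT, index=False)
    summary = frame.groupby("preset")["test_mae_all"].agg(["median", "max"])
    print("per-preset test MAE (all 18 wines):")
    print(summary.round(3).to_string())
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
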