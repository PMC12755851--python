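"""Simulate the synthetic two-class population and write the recording container.

Generates a reduced-scale population (default profile ``test_scale``: 20
neurons, 10 s of frozen noise at 5 kHz plus the 10-step SH sweep set), saves
the recordings to ``results/recordings.h5`` and the ground-truth table to
``results/ground_truth.csv``, and prints per-class firing-rate summaries.

Usage: python analysis/01_simulate_population.py [--profile test_scale]
       [--n-neurons N] [--seed S]
"""

import argparse
import logging
from pathlib import Path

import numpy as np

from neuroclass.features import detect_spikes
from neuroclass.io import save_dataset
from neuroclass.population import generate_dataset, load_profile, sample_population

logging.disable(logging.WARNING)

ap = argparse.ArgumentParser()
ap.add_argument("--profile", default="test_scale")
ap.add_argument("--n-neurons", type=int, default=None)
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

cfg = load_profile(args.profile)
cfg.master_seed = args.seed
if args.n_neurons:
    cfg.n_neurons = args.n_neurons

truth = sample_population(cfg)
dataset = generate_dataset(truth)

args.out.mkdir(parents=True, exist_ok=True)
save_dataset(args.out / "recordings.h5", dataset)
truth.table.to_csv(args.out / "ground_truth.csv", index=False)

print(f"simulated {len(dataset)} neurons "
      f"({truth.table.class_label.value_counts().to_dict()})")
for label in sorted(truth.table.class_label.unique()):
    cells = truth.table.loc[truth.table.class_label == label, "cell_id"]
    rates = [
        len(detect_spikes(dataset[c]["FN"].V, dataset[c]["FN"].dt))
        / (dataset[c]["FN"].duration / 1000.0)
        for c in cells
    ]
    print(f"  class {label}: FN rate median {np.median(rates):.1f} Hz "
          f"(range {min(rates):.1f}-{max(rates):.1f})")
print(f"wrote {args.out / 'recordings.h5'} and ground_truth.csv")
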