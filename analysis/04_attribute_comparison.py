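"""Four-attribute-set comparison and MCFA variance decomposition under FN.

Reads the recording container, performs the putative E/I split from waveform
clusters (high rate + narrow spike -> inhibitory), builds the AP, passive
(R^2-filtered), adaptation-current and STA attribute sets, clusters each per
class, and writes cross-attribute agreements plus the MCFA shared/private/
residual percentages.

Usage: python analysis/04_attribute_comparison.py [--results results] [--seed S]
"""

import argparse
import json
import logging
from pathlib import Path

from neuroclass.io import load_dataset
from neuroclass.pipeline import PipelineConfig, run_attribute_comparison

logging.disable(logging.WARNING)

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
ap.add_argument("--seed", type=int, default=0)
args = ap.parse_args()

dataset = load_dataset(args.results / "recordings.h5")
config = PipelineConfig(n_neighbors=min(20, len(dataset) // 2), mcfa_d=3)
report = run_attribute_comparison(dataset, config, seed=args.seed)

report["ei_labels"].rename("ei_label").to_csv(args.results / "ei_labels.csv")
summary = {
    "seed": args.seed,
    "n_cells": int(len(report["ei_labels"])),
    "ei_counts": report["ei_labels"].value_counts().to_dict(),
    "r2_median": float(report["r2"].median()),
    "per_class": {},
}
for label, block in report["per_class"].items():
    if "error" in block:
        summary["per_class"][label] = block
        continue
    summary["per_class"][label] = {
        "n_cells": block["n_cells"],
        "agreements": block["agreements"],
        "mcfa_variance_pct": block["mcfa"]["sets"],
    }

(args.results / "attribute_comparison.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
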