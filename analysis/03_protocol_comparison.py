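"""Compare classification under the SH and FN protocols.

Reads the recording container, extracts 5-ms waveforms and the 22 AP
attributes per protocol, clusters each with the UMAP-graph + Louvain method,
and writes the cross-protocol agreement statistics (ARI/AMI), the cluster-
likelihood matrices and the per-protocol labels under ``results/``.

Usage: python analysis/03_protocol_comparison.py [--results results] [--seed S]
"""

import argparse
import json
import logging
from pathlib import Path

import pandas as pd

from neuroclass.io import load_dataset
from neuroclass.pipeline import PipelineConfig, run_protocol_comparison

logging.disable(logging.WARNING)

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
ap.add_argument("--seed", type=int, default=0)
args = ap.parse_args()

dataset = load_dataset(args.results / "recordings.h5")
config = PipelineConfig(n_neighbors=min(20, len(dataset) // 2))
report = run_protocol_comparison(dataset, config, seed=args.seed)

summary = {"seed": args.seed, "skipped_cells": report["skipped"]}
for name in ("waveforms", "ap_attributes"):
    block = report[name]
    summary[name] = {
        "agreement": block["agreement"],
        "n_clusters_sh": int(block["result_a"].n_clusters),
        "n_clusters_fn": int(block["result_b"].n_clusters),
    }
    block["likelihood"].to_csv(args.results / f"likelihood_{name}.csv")
    pd.DataFrame({
        "cell_id": block["cells"],
        "sh_cluster": block["result_a"].labels,
        "fn_cluster": block["result_b"].labels,
    }).to_csv(args.results / f"labels_{name}.csv", index=False)
summary["ecg_vs_louvain"] = report["ecg"]["vs_louvain"]

(args.results / "protocol_comparison.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
print("Low cross-protocol ARI/AMI indicates protocol-dependent classification;"
      " on the synthetic population both protocols probe the same generative"
      " parameters, so agreement is typically higher than in real recordings.")
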