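"""Fit the GLIF model to every FN recording in the container.

Reads ``results/recordings.h5``, runs the three-step fit per cell, writes one
row per cell (the six clustering parameters, subthreshold R^2, exclusion flag)
to ``results/glif_fits.csv``, and reports recovery errors against the
generative ground truth stored in the container.

Usage: python analysis/02_fit_glif.py [--results results]
"""

import argparse
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from neuroclass.datatypes import CLUSTERING_PARAM_NAMES
from neuroclass.glif_fit import FitError, fit_glif
from neuroclass.io import load_dataset

logging.disable(logging.WARNING)

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
args = ap.parse_args()

dataset = load_dataset(args.results / "recordings.h5")

rows = []
for cell_id, protos in sorted(dataset.items()):
    rec = protos.get("FN")
    if rec is None:
        continue
    try:
        fit = fit_glif(rec)
    except FitError as e:
        print(f"  {cell_id}: fit failed ({e})")
        continue
    row = dict(zip(CLUSTERING_PARAM_NAMES, fit.clustering_vector()))
    row.update(cell_id=cell_id, r2=fit.r2, excluded=fit.excluded)
    truth = rec.meta.get("params")
    if truth is not None:
        row["C_err_pct"] = 100 * abs(fit.params.C - truth.C) / truth.C
        row["gL_err_pct"] = 100 * abs(fit.params.g_L - truth.g_L) / truth.g_L
        row["Vreset_err_mV"] = abs(fit.params.V_reset - truth.V_reset)
    rows.append(row)

table = pd.DataFrame(rows).set_index("cell_id")
table.to_csv(args.results / "glif_fits.csv")
kept = (~table.excluded).sum()
print(f"fitted {len(table)} cells; {kept} pass the R^2 > 0.7 filter")
print(f"median subthreshold R^2: {table.r2.median():.4f}")
if "C_err_pct" in table:
    print(f"median |C error|: {table.C_err_pct.median():.2f}%  "
          f"|g_L error|: {table.gL_err_pct.median():.2f}%  "
          f"|V_reset error|: {table.Vreset_err_mV.median():.3f} mV")
print(f"wrote {args.results / 'glif_fits.csv'}")
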