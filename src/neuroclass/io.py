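"""HDF5 recording container.

Layout:

    /cells/<id>/<protocol>/V            membrane potential (mV)
    /cells/<id>/<protocol>/I            injected current (pA)
    /cells/<id>/<protocol>/spike_times  ms
        attrs: dt, class_label, params (JSON), stimulus metadata
    SH sweeps are stored as SH/sweep<k>.

Generative GLIF parameters are serialized as a JSON string attribute so a
container round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .datatypes import CurrentTrace, GLIFParams, KernelBasis, Recording

__all__ = ["save_dataset", "load_dataset"]


def _params_to_json(p: GLIFParams) -> str:
    return json.dumps({
        "C": p.C, "g_L": p.g_L, "E_L": p.E_L, "V_reset": p.V_reset,
        "VT_star": p.VT_star, "delta_V": p.delta_V, "lambda0": p.lambda0,
        "t_ref": p.t_ref,
        "eta_edges": p.eta_basis.edges.tolist(),
        "eta_coeffs": p.eta_coeffs.tolist(),
        "gamma_edges": p.gamma_basis.edges.tolist(),
        "gamma_coeffs": p.gamma_coeffs.tolist(),
        "spike_template": p.spike_template,
    })


def _params_from_json(s: str) -> GLIFParams:
    d = json.loads(s)
    return GLIFParams(
        C=d["C"], g_L=d["g_L"], E_L=d["E_L"], V_reset=d["V_reset"],
        VT_star=d["VT_star"], delta_V=d["delta_V"], lambda0=d["lambda0"],
        t_ref=d["t_ref"],
        eta_basis=KernelBasis(np.array(d["eta_edges"])),
        eta_coeffs=np.array(d["eta_coeffs"]),
        gamma_basis=KernelBasis(np.array(d["gamma_edges"])),
        gamma_coeffs=np.array(d["gamma_coeffs"]),
        spike_template=d["spike_template"],
    )


def _write_recording(grp: h5py.Group, rec: Recording) -> None:
    grp.create_dataset("V", data=rec.V, compression="gzip")
    grp.create_dataset("I", data=rec.I.values, compression="gzip")
    grp.create_dataset("spike_times", data=rec.spike_times)
    grp.attrs["dt"] = rec.dt
    grp.attrs["protocol_tag"] = rec.I.protocol_tag
    grp.attrs["baseline"] = rec.I.baseline
    grp.attrs["scale"] = rec.I.scale
    grp.attrs["stim_meta"] = json.dumps(
        {k: v for k, v in rec.I.meta.items() if not isinstance(v, np.ndarray)}
    )
    if "class_label" in rec.meta:
        grp.attrs["class_label"] = rec.meta["class_label"]
    if isinstance(rec.meta.get("params"), GLIFParams):
        grp.attrs["params"] = _params_to_json(rec.meta["params"])


def _read_recording(grp: h5py.Group) -> Recording:
    dt = float(grp.attrs["dt"])
    current = CurrentTrace(
        values=grp["I"][:], dt=dt,
        baseline=float(grp.attrs.get("baseline", 0.0)),
        scale=float(grp.attrs.get("scale", 1.0)),
        protocol_tag=str(grp.attrs.get("protocol_tag", "FN")),
        meta=json.loads(grp.attrs.get("stim_meta", "{}")),
    )
    meta = {}
    if "class_label" in grp.attrs:
        meta["class_label"] = str(grp.attrs["class_label"])
    if "params" in grp.attrs:
        meta["params"] = _params_from_json(grp.attrs["params"])
    return Recording(V=grp["V"][:], I=current, dt=dt,
                     spike_times=grp["spike_times"][:], meta=meta)


def save_dataset(path: str | Path, dataset: dict) -> None:
    """Write {cell_id: {"FN": Recording, "SH": [Recording, ...]}} to HDF5."""
    with h5py.File(path, "w") as fh:
        cells = fh.create_group("cells")
        for cell_id, protos in dataset.items():
            cg = cells.create_group(cell_id)
            if "FN" in protos:
                _write_recording(cg.create_group("FN"), protos["FN"])
            if "SH" in protos:
                sg = cg.create_group("SH")
                for i, rec in enumerate(protos["SH"]):
                    _write_recording(sg.create_group(f"sweep{i}"), rec)


def load_dataset(path: str | Path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        for cell_id, cg in fh["cells"].items():
            protos = {}
            if "FN" in cg:
                rec = _read_recording(cg["FN"])
                rec.meta["cell_id"] = cell_id
                protos["FN"] = rec
            if "SH" in cg:
                sweeps = []
                for name in sorted(cg["SH"], key=lambda s: int(s.removeprefix("sweep"))):
                    rec = _read_recording(cg["SH"][name])
                    rec.meta["cell_id"] = cell_id
                    sweeps.append(rec)
                protos["SH"] = sweeps
            out[cell_id] = protos
    return out
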