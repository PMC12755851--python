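"""Headline analyses: cross-protocol classification comparison and the
four-attribute-set comparison with MCFA variance decomposition.

Both entry points are pure functions of (dataset, config, seed): re-running
with the same inputs reproduces the same labels and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering as gc
from .features import (
    AP_FEATURE_NAMES,
    ap_feature_vector,
    compute_sta,
    detect_spikes,
    extract_waveforms,
    feature_dict_to_vector,
)
from .glif_fit import FitError, fit_glif
from .mcfa import fit_em, variance_report

__all__ = [
    "PipelineConfig",
    "cluster_features",
    "compare_feature_tables",
    "run_protocol_comparison",
    "run_attribute_comparison",
]


@dataclass
class PipelineConfig:
    n_neighbors: int = 20
    min_dist: float = 0.1
    resolution: float = 1.0
    scan_resolutions: bool = False
    n_repeats: int = 25
    subsample_frac: float = 0.9
    ecg_k: int = 16
    ecg_w_star: float = 0.05
    r2_threshold: float = 0.7
    # putative E/I split rule: a waveform cluster is labelled inhibitory when
    # its median firing rate exceeds rate_threshold (Hz) AND its median AP
    # half-width is below width_threshold (ms)
    rate_threshold: float = 10.0
    width_threshold: float = 0.5
    mcfa_d: int = 4
    train_window: float = 100_000.0
    extra: dict = field(default_factory=dict)


def cluster_features(
    X: np.ndarray, seed: int = 0, config: PipelineConfig | None = None,
) -> gc.ClusterResult:
    """Standard clustering path: preprocess -> UMAP kNN graph -> (optional
    resolution scan) -> Louvain."""
    config = config or PipelineConfig()
    Xp = gc.preprocess(X)
    n_neighbors = min(config.n_neighbors, Xp.shape[0] - 1)
    graph = gc.build_graph(Xp, n_neighbors=n_neighbors,
                           min_dist=config.min_dist, seed=seed)
    if config.scan_resolutions:
        gamma, table = gc.select_resolution(
            graph, n_repeats=config.n_repeats,
            subsample_frac=config.subsample_frac, seed=seed)
    else:
        gamma, table = config.resolution, None
    result = gc.louvain(graph, resolution=gamma, seed=seed, n_repeats=5)
    result.stability = table
    result.meta["preprocessed"] = Xp
    result.meta["graph"] = graph
    return result


def _mean_waveforms(dataset: dict, protocol: str, pre: float, post: float) -> pd.DataFrame:
    rows = {}
    for cell_id, protos in dataset.items():
        if protocol not in protos:
            continue
        recs = protos[protocol] if isinstance(protos[protocol], list) else [protos[protocol]]
        wfs = []
        for rec in recs:
            spikes = detect_spikes(rec.V, rec.dt)
            ws = extract_waveforms(rec.V, rec.dt, spikes, pre, post)
            if not ws.empty:
                wfs.append(ws.waveforms)
        if wfs:
            rows[cell_id] = np.vstack(wfs).mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")


def _ap_features(dataset: dict, protocol: str) -> pd.DataFrame:
    rows = {}
    for cell_id, protos in dataset.items():
        if protocol not in protos:
            continue
        feats = ap_feature_vector(protos[protocol], protocol_tag=protocol)
        if not feats["incomplete"]:
            rows[cell_id] = feature_dict_to_vector(feats)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(AP_FEATURE_NAMES))


def compare_feature_tables(X_a: pd.DataFrame, X_b: pd.DataFrame, seed: int,
             config: PipelineConfig) -> dict:
    """Cluster two feature matrices over the shared cell roster and compare."""
    common = X_a.index.intersection(X_b.index)
    X_a, X_b = X_a.loc[common], X_b.loc[common]
    res_a = cluster_features(X_a.to_numpy(), seed=seed, config=config)
    res_b = cluster_features(X_b.to_numpy(), seed=seed + 1, config=config)
    likelihood = gc.cluster_likelihood(res_a.labels, res_b.labels)
    agreement = gc.compare_labelings(res_a.labels, res_b.labels)
    cosine = gc.cosine_summary(
        res_a.meta["preprocessed"], res_a.labels,
        res_b.meta["preprocessed"], res_b.labels,
    )
    return {
        "cells": list(common), "result_a": res_a, "result_b": res_b,
        "likelihood": likelihood, "agreement": agreement, "cosine": cosine,
    }


def run_protocol_comparison(dataset: dict, config: PipelineConfig | None = None,
                            seed: int = 0) -> dict:
    """Compare classification under the SH and FN protocols.

    Extracts 5-ms waveforms (2 ms pre / 3 ms post) and the 22 AP attributes
    per protocol for every cell recorded under both, clusters each matrix,
    and reports per-protocol labels, the cross-protocol likelihood matrix,
    ARI/AMI, cosine-similarity summaries and an ECG consensus cross-check on
    the FN waveform graph.  Cells missing either protocol are listed under
    ``skipped``.
    """
    config = config or PipelineConfig()
    paired = {c: p for c, p in dataset.items() if "FN" in p and "SH" in p}
    skipped = sorted(set(dataset) - set(paired))

    wf_fn = _mean_waveforms(paired, "FN", 2.0, 3.0)
    wf_sh = _mean_waveforms(paired, "SH", 2.0, 3.0)
    ap_fn = _ap_features(paired, "FN")
    ap_sh = _ap_features(paired, "SH")

    report = {"skipped": skipped}
    report["waveforms"] = compare_feature_tables(wf_sh, wf_fn, seed, config)
    report["ap_attributes"] = compare_feature_tables(ap_sh, ap_fn, seed + 100, config)

    # ECG cross-check on the FN waveform graph
    graph = report["waveforms"]["result_b"].meta["graph"]
    ecg_res = gc.ecg(graph, k=config.ecg_k, w_star=config.ecg_w_star, seed=seed)
    report["ecg"] = {
        "result": ecg_res,
        "vs_louvain": gc.compare_labelings(
            report["waveforms"]["result_b"].labels, ecg_res.labels),
    }
    return report




def run_attribute_comparison(dataset: dict, config: PipelineConfig | None = None,
                             seed: int = 0) -> dict:
    """Four-attribute-set comparison within putative E/I classes under FN.

    1. Cluster 10-ms mean waveforms; label clusters with median firing rate
       above ``rate_threshold`` and median half-width below
       ``width_threshold`` as putatively inhibitory.
    2. Per class, build the AP-attribute, passive (GLIF six-vector,
       R^2-filtered), adaptation-current and STA sets; cluster each.
    3. Report cross-attribute agreements (ARI/AMI, likelihood matrices) and
       the MCFA shared/private variance decomposition over the four sets.
    """
    config = config or PipelineConfig()
    fn = {c: p for c, p in dataset.items() if "FN" in p}

    wf = _mean_waveforms(fn, "FN", 5.0, 5.0)
    wf_res = cluster_features(wf.to_numpy(), seed=seed, config=config)

    # per-cell firing rate and spike width (interpolated threshold-crossing
    # width; robust to the sampling grid, unlike a raw half-width readout)
    ap_all = _ap_features(fn, "FN")
    rates, widths = {}, {}
    for cell_id in wf.index:
        rec = fn[cell_id]["FN"]
        spikes = detect_spikes(rec.V, rec.dt)
        rates[cell_id] = len(spikes) / (rec.duration / 1000.0)
        widths[cell_id] = (
            ap_all.loc[cell_id, "width_median"] if cell_id in ap_all.index else np.nan
        )
    rates = pd.Series(rates)[wf.index]
    widths = pd.Series(widths)[wf.index]
    ei = pd.Series("E", index=wf.index)
    for c in np.unique(wf_res.labels):
        members = wf.index[wf_res.labels == c]
        if (rates[members].median() > config.rate_threshold
                and widths[members].median() < config.width_threshold):
            ei[members] = "I"

    # attribute sets over all FN cells
    ap = ap_all
    passive, eta, sta, r2s = {}, {}, {}, {}
    fit_failures = {}
    for cell_id, protos in fn.items():
        rec = protos["FN"]
        try:
            fit = fit_glif(rec, train_window=config.train_window,
                           r2_threshold=config.r2_threshold)
        except FitError as e:
            fit_failures[cell_id] = str(e)
            continue
        r2s[cell_id] = fit.r2
        if not fit.excluded:
            passive[cell_id] = fit.clustering_vector()
        eta[cell_id] = fit.eta_samples(rec.dt)
        spikes = detect_spikes(rec.V, rec.dt)
        try:
            sta[cell_id] = compute_sta(rec.I, spikes).values
        except ValueError:
            pass
    sets = {
        "AP": ap.dropna(),
        "passive": pd.DataFrame.from_dict(passive, orient="index"),
        "eta": pd.DataFrame.from_dict(eta, orient="index"),
        "STA": pd.DataFrame.from_dict(sta, orient="index"),
    }

    report = {
        "ei_labels": ei, "waveform_result": wf_res, "r2": pd.Series(r2s),
        "fit_failures": fit_failures, "firing_rates": rates,
        "half_widths": widths,
    }
    if (ei == "I").all() or (ei == "E").all():
        classes = [("all", ei.index)]
    else:
        classes = [("E", ei.index[ei == "E"]), ("I", ei.index[ei == "I"])]

    report["per_class"] = {}
    for label, members in classes:
        cls_sets = {k: v.loc[v.index.intersection(members)] for k, v in sets.items()}
        common = None
        for v in cls_sets.values():
            common = v.index if common is None else common.intersection(v.index)
        if len(common) < 3:
            report["per_class"][label] = {"error": "too few cells after filtering"}
            continue
        cls_sets = {k: v.loc[common] for k, v in cls_sets.items()}
        results = {}
        for name, mat in cls_sets.items():
            if mat.shape[1] < 2 or len(common) < 5:
                continue
            results[name] = cluster_features(mat.to_numpy(), seed=seed + hash(name) % 1000,
                                             config=config)
        agreements = {}
        names = list(results)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                agreements[f"{a}|{b}"] = gc.compare_labelings(
                    results[a].labels, results[b].labels)
        d = min(config.mcfa_d, len(common) - 1)
        model = fit_em([m.to_numpy() for m in cls_sets.values()], d=d, seed=seed)
        var = variance_report(model, set_names=list(cls_sets))
        report["per_class"][label] = {
            "n_cells": len(common), "cluster_results": results,
            "agreements": agreements, "mcfa": var, "mcfa_model": model,
        }
    return report
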