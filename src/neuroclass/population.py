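"""Ground-truth synthetic populations of GLIF neurons.

Generates two-class (E-like / I-like) populations with class-specific spike
templates, adaptation kernels and frozen-noise time constants, and produces
paired FN/SH recordings so every pipeline stage can be exercised without the
experimental dataset.  Archetype parameter tables live in shipped YAML
profiles (``population_default`` at study scale, ``test_scale`` reduced).

Also provides a direct generator for the MCFA model (shared + private factors
+ diagonal noise) used by the factor-analysis recovery tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import GLIFParams, KernelBasis, Recording
from .glif_sim import simulate_glif
from .stimuli import default_fn_current, generate_sh_protocol

__all__ = [
    "PopulationConfig",
    "GroundTruth",
    "load_profile",
    "sample_population",
    "generate_dataset",
    "generate_mcfa_testdata",
]


@dataclass
class PopulationConfig:
    n_neurons: int
    classes: list[dict]
    protocols: dict
    master_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c["weight"] for c in self.classes)
        if not np.isclose(total, 1.0):
            raise ValueError(f"class weights must sum to 1, got {total}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            n_neurons=raw["n_neurons"], classes=raw["classes"],
            protocols=raw["protocols"], master_seed=raw.get("master_seed", 0),
        )


def load_profile(name: str = "population_default") -> PopulationConfig:
    """Load a shipped YAML profile (``population_default`` or ``test_scale``)."""
    ref = importlib.resources.files("neuroclass") / "configs" / f"{name}.yaml"
    with importlib.resources.as_file(ref) as path:
        return PopulationConfig.from_yaml(path)


@dataclass
class GroundTruth:
    table: pd.DataFrame  # cell_id, class_label, seed
    params: list[GLIFParams]
    config: PopulationConfig = None

    def __len__(self) -> int:
        return len(self.params)


def _class_counts(weights: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation so exact fractions give exact counts."""
    raw = weights * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _draw(spec, rng) -> float:
    if isinstance(spec, dict):
        return float(rng.normal(spec["mean"], spec.get("sd", 0.0)))
    return float(spec)


def sample_population(config: PopulationConfig,
                      eta_basis: KernelBasis | None = None,
                      gamma_basis: KernelBasis | None = None) -> GroundTruth:
    """Draw per-neuron GLIF parameters from the class mixture.

    Adaptation (eta) and threshold-movement (gamma) coefficients follow an
    exponential profile amplitude * exp(-t_mid / tau) evaluated at the basis
    bin midpoints; E-like archetypes have larger, slower kernels.
    """
    if eta_basis is None:
        eta_basis = KernelBasis.default()
    if gamma_basis is None:
        gamma_basis = KernelBasis.default()
    rng = np.random.default_rng(config.master_seed)
    weights = np.array([c["weight"] for c in config.classes])
    counts = _class_counts(weights, config.n_neurons)

    eta_mid = (eta_basis.edges[:-1] + eta_basis.edges[1:]) / 2.0
    gamma_mid = (gamma_basis.edges[:-1] + gamma_basis.edges[1:]) / 2.0

    rows, params = [], []
    cell = 0
    for cls, n_c in zip(config.classes, counts):
        for _ in range(n_c):
            p = cls["params"]
            draws = {k: _draw(p[k], rng) for k in p}
            draws["C"] = max(draws["C"], 20.0)
            draws["g_L"] = max(draws["g_L"], 1.0)
            draws["delta_V"] = max(draws["delta_V"], 0.2)
            a0 = max(_draw(cls["eta"]["amplitude"], rng), 0.0)
            g0 = max(_draw(cls["gamma"]["amplitude"], rng), 0.0)
            width = max(_draw(cls["template"]["width"], rng), 0.1)
            gp = GLIFParams(
                C=draws["C"], g_L=draws["g_L"], E_L=draws["E_L"],
                V_reset=draws["V_reset"], VT_star=draws["VT_star"],
                delta_V=draws["delta_V"],
                eta_basis=eta_basis,
                eta_coeffs=a0 * np.exp(-eta_mid / cls["eta"]["tau"]),
                gamma_basis=gamma_basis,
                gamma_coeffs=g0 * np.exp(-gamma_mid / cls["gamma"]["tau"]),
                spike_template={"peak": cls["template"]["peak"], "width": width},
            )
            seed = int(rng.integers(2**31))
            rows.append({
                "cell_id": f"cell{cell:04d}", "class_label": cls["label"],
                "seed": seed, "fn_tau": cls["fn_tau"],
                "baseline_margin": cls.get("baseline_margin", 40.0),
            })
            params.append(gp)
            cell += 1
    return GroundTruth(table=pd.DataFrame(rows), params=params, config=config)


def generate_dataset(
    truth: GroundTruth,
    config: PopulationConfig | None = None,
    protocols: tuple[str, ...] = ("FN", "SH"),
) -> dict:
    """Per neuron, one FN recording (class-appropriate hidden-state tau) and
    one SH sweep set.  Returns {cell_id: {"FN": Recording, "SH": [Recording]}}.

    Each cell's frozen-noise current uses its own presynaptic population,
    seeded by the cell's seed, so the stimulus realization is reproducible
    per cell.
    """
    if len(truth) == 0:
        raise ValueError("empty population")
    config = config or truth.config
    fn_cfg = config.protocols["fn"]
    sh_cfg = config.protocols["sh"]
    dataset = {}
    for row, gp in zip(truth.table.itertuples(), truth.params):
        out = {}
        cell_seed = int(row.seed)
        if "FN" in protocols:
            baseline = gp.g_L * (gp.VT_star - gp.E_L) - row.baseline_margin
            current = default_fn_current(
                tau=row.fn_tau, duration=fn_cfg["duration"], dt=fn_cfg["dt"],
                baseline=baseline, target_sd=fn_cfg.get("target_sd", 50.0),
                n_units=fn_cfg.get("n_units", 1000), seed=cell_seed,
            )
            rec = simulate_glif(gp, current, seed=cell_seed + 1)
            rec.meta.update(cell_id=row.cell_id, class_label=row.class_label,
                            protocol_tag="FN")
            out["FN"] = rec
        if "SH" in protocols:
            steps = generate_sh_protocol(
                step_min=sh_cfg["step_min"], step_max=sh_cfg["step_max"],
                n_steps=sh_cfg["n_steps"], step_duration=sh_cfg["step_duration"],
                holding_potential=sh_cfg["holding_potential"], dt=fn_cfg["dt"],
            )
            sweeps = []
            for i, step in enumerate(steps):
                r = simulate_glif(gp, step, seed=cell_seed + 2 + i)
                r.meta.update(cell_id=row.cell_id, class_label=row.class_label,
                              protocol_tag="SH")
                sweeps.append(r)
            out["SH"] = sweeps
        dataset[row.cell_id] = out
    return dataset


def generate_mcfa_testdata(
    N: int,
    d: int,
    k_list: list[int],
    P_list: list[int],
    variance_split=(0.6, 0.3, 0.1),
    seed: int = 0,
):
    """Draw attribute sets directly from the shared/private factor model.

    Every feature's variance decomposes exactly as ``variance_split``
    (shared, private, residual): loading rows are rescaled to the target norms
    so the model-implied per-feature variance is exactly 1.  A list of
    per-set triples gives each attribute set its own split (e.g. a
    private-dominated STA set next to shared-dominated feature sets).

    Returns (Ys, truth) with truth = {"z", "x", "W", "L", "psi"}.
    """
    splits = (list(variance_split) if isinstance(variance_split[0], (tuple, list))
              else [variance_split] * len(P_list))
    if len(splits) != len(P_list):
        raise ValueError("need one variance split per attribute set")
    for sp in splits:
        if not np.isclose(sum(sp), 1.0):
            raise ValueError("each variance split must sum to 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((N, d))
    Ys, Ws, Ls, xs, psis = [], [], [], [], []
    for P_m, k_m, (s, p, r) in zip(P_list, k_list, splits):
        W = rng.standard_normal((P_m, d))
        W *= np.sqrt(s) / np.linalg.norm(W, axis=1, keepdims=True)
        if k_m > 0:
            L = rng.standard_normal((P_m, k_m))
            L *= np.sqrt(p) / np.linalg.norm(L, axis=1, keepdims=True)
            x = rng.standard_normal((N, k_m))
        else:
            L = np.zeros((P_m, 0))
            x = np.zeros((N, 0))
            r = r + p  # no private factor: its share folds into the residual
        psi = np.full(P_m, r)
        Y = z @ W.T + x @ L.T + rng.standard_normal((N, P_m)) * np.sqrt(r)
        Ys.append(Y); Ws.append(W); Ls.append(L); xs.append(x); psis.append(psi)
    return Ys, {"z": z, "x": xs, "W": Ws, "L": Ls, "psi": psis}
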