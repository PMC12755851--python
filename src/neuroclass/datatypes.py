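"""Shared containers for traces, stimuli, model parameters and recordings.

Unit conventions used throughout the package: time in ms, voltage in mV,
current in pA, capacitance in pF, conductance in nS, rates in Hz.  With these
units pA/pF = mV/ms, so the membrane equation integrates without conversion
factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "HiddenStateTrace",
    "PresynapticPopulation",
    "CurrentTrace",
    "KernelBasis",
    "GLIFParams",
    "Recording",
]


@dataclass
class HiddenStateTrace:
    """Binary hidden state of the frozen-noise input (0 = off, 1 = on)."""

    states: np.ndarray
    dt: float
    tau: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("hidden states must be binary")

    def __len__(self) -> int:
        return self.states.size

    def dwell_times(self) -> np.ndarray:
        """Durations (ms) of completed constant-state stretches."""
        change = np.flatnonzero(np.diff(self.states)) + 1
        if change.size < 2:
            return np.empty(0)
        return np.diff(change) * self.dt


@dataclass
class PresynapticPopulation:
    """Poisson units whose hidden-state-modulated activity sums into the FN current.

    Mixing weights are fixed to ``w_i = ln(q_on_i / q_off_i)``: units firing
    more in the on-state contribute positively, off-preferring units negatively.
    """

    q_on: np.ndarray
    q_off: np.ndarray
    kernel_tau: float = 5.0

    def __post_init__(self) -> None:
        self.q_on = np.atleast_1d(np.asarray(self.q_on, dtype=float))
        self.q_off = np.atleast_1d(np.asarray(self.q_off, dtype=float))
        if self.q_on.shape != self.q_off.shape:
            raise ValueError("q_on and q_off must have the same shape")
        if (self.q_on <= 0).any() or (self.q_off <= 0).any():
            raise ValueError("unit rates must be strictly positive")
        if self.kernel_tau <= 0:
            raise ValueError("kernel_tau must be positive")

    @property
    def n_units(self) -> int:
        return self.q_on.size

    @property
    def weights(self) -> np.ndarray:
        return np.log(self.q_on / self.q_off)

    @classmethod
    def sample(
        cls,
        n_units: int = 1000,
        q_off_range: tuple[float, float] = (1.0, 10.0),
        gain_range: tuple[float, float] = (0.5, 2.0),
        kernel_tau: float = 5.0,
        seed: int | np.random.Generator = 0,
    ) -> "PresynapticPopulation":
        """Draw per-unit rates: q_off ~ U(range), q_on = q_off * gain, gain ~ U(range)."""
        rng = np.random.default_rng(seed)
        q_off = rng.uniform(*q_off_range, size=n_units)
        q_on = q_off * rng.uniform(*gain_range, size=n_units)
        return cls(q_on=q_on, q_off=q_off, kernel_tau=kernel_tau)


@dataclass
class CurrentTrace:
    """Injected-current trace with its generation metadata."""

    values: np.ndarray
    dt: float
    baseline: float = 0.0
    scale: float = 1.0
    protocol_tag: str = "FN"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("current contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size * self.dt


@dataclass
class KernelBasis:
    """Rectangular basis functions partitioning [0, support) ms.

    ``edges`` has K+1 strictly increasing breakpoints starting at 0; basis
    function k is the indicator of ``[edges[k], edges[k+1])``.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.size < 2:
            raise ValueError("need at least two edges")
        if self.edges[0] != 0:
            raise ValueError("edges must start at 0")
        if (np.diff(self.edges) <= 0).any():
            raise ValueError("edges must be strictly increasing")

    @property
    def n_basis(self) -> int:
        return self.edges.size - 1

    @property
    def support(self) -> float:
        return float(self.edges[-1])

    @classmethod
    def default(cls, support: float = 500.0, n_basis: int = 10, first_edge: float = 10.0) -> "KernelBasis":
        # Log-spaced interior edges: fine near the spike where kernels vary
        # fastest.  The first interior edge sits beyond the refractory +
        # spike-exclusion window so every basis column is observable in the
        # subthreshold regression.
        interior = np.geomspace(first_edge, support, n_basis)
        return cls(edges=np.concatenate(([0.0], interior)))

    def kernel_samples(self, coeffs: np.ndarray, dt: float) -> np.ndarray:
        """Evaluate sum_k coeffs[k] f_k(t) on the sample grid t = 0, dt, 2dt, ..."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.size != self.n_basis:
            raise ValueError("coefficient count must match basis size")
        n = int(round(self.support / dt))
        t = np.arange(n) * dt
        idx = np.searchsorted(self.edges, t, side="right") - 1
        out = np.zeros(n)
        valid = (idx >= 0) & (idx < self.n_basis)
        out[valid] = coeffs[idx[valid]]
        return out

    def convolve_spikes(self, spike_samples: np.ndarray, n: int, dt: float) -> np.ndarray:
        """Spike-history design columns matching the simulator's causal
        convention: kernels act from the sample after emission, so column k at
        sample t counts past spikes with (t - t_hat - 1)*dt in
        [edges[k], edges[k+1]).  A spike never contributes to its own bin."""
        cols = np.zeros((n, self.n_basis))
        lo = np.round(self.edges[:-1] / dt).astype(int) + 1
        hi = np.round(self.edges[1:] / dt).astype(int) + 1
        for s in np.asarray(spike_samples, dtype=int):
            for k in range(self.n_basis):
                a, b = s + lo[k], min(s + hi[k], n)
                if a < n and b > a:
                    cols[a:b, k] += 1.0
        return cols


@dataclass
class GLIFParams:
    """Full generative parameter set of the generalized leaky integrate-and-fire model."""

    C: float  # pF
    g_L: float  # nS
    E_L: float  # mV
    V_reset: float  # mV
    VT_star: float  # mV
    delta_V: float  # mV
    lambda0: float = 1.0  # Hz
    t_ref: float = 4.0  # ms
    eta_basis: Optional[KernelBasis] = None
    eta_coeffs: Optional[np.ndarray] = None  # pA
    gamma_basis: Optional[KernelBasis] = None
    gamma_coeffs: Optional[np.ndarray] = None  # mV
    spike_template: Optional[dict] = None  # {"peak": mV, "width": ms}

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_L <= 0 or self.delta_V <= 0 or self.t_ref <= 0:
            raise ValueError("C, g_L, delta_V and t_ref must be positive")
        if self.eta_basis is None:
            self.eta_basis = KernelBasis.default()
        if self.eta_coeffs is None:
            self.eta_coeffs = np.zeros(self.eta_basis.n_basis)
        if self.gamma_basis is None:
            self.gamma_basis = KernelBasis.default()
        if self.gamma_coeffs is None:
            self.gamma_coeffs = np.zeros(self.gamma_basis.n_basis)
        self.eta_coeffs = np.asarray(self.eta_coeffs, dtype=float)
        self.gamma_coeffs = np.asarray(self.gamma_coeffs, dtype=float)

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L (ms)."""
        return self.C / self.g_L

    def clustering_vector(self) -> np.ndarray:
        """The six passive/threshold parameters used for classification:
        (g_L, delta_V, C, VT_star, E_L, V_reset)."""
        return np.array([self.g_L, self.delta_V, self.C, self.VT_star, self.E_L, self.V_reset])


CLUSTERING_PARAM_NAMES = ("g_L", "delta_V", "C", "VT_star", "E_L", "V_reset")


@dataclass
class Recording:
    """Paired membrane-potential and injected-current trace for one trial."""

    V: np.ndarray
    I: CurrentTrace
    dt: float
    spike_times: np.ndarray  # ms, strictly increasing
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.V.size != len(self.I):
            raise ValueError("V and I must have equal length")
        if self.spike_times.size > 1 and (np.diff(self.spike_times) <= 0).any():
            raise ValueError("spike_times must be strictly increasing")

    @property
    def duration(self) -> float:
        return self.V.size * self.dt

    @property
    def spike_samples(self) -> np.ndarray:
        return np.round(self.spike_times / self.dt).astype(int)
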