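"""Forward simulation of the generalized leaky integrate-and-fire (GLIF) model.

Membrane equation (units: pF, nS, mV, pA, ms; pA/pF = mV/ms):

    C dV/dt = -g_L (V - E_L) - sum_j eta(t - t_j) + I(t)

Spikes are emitted stochastically with conditional intensity

    lambda(t) = lambda0 * exp((V(t) - VT(t)) / delta_V),
    VT(t)     = VT* + sum_j gamma(t - t_j),

and per-step spike probability 1 - exp(-lambda dt).  On a spike the voltage is
clamped to V_reset for the refractory period t_ref, and the spike-triggered
adaptation current eta and threshold movement gamma are added to their running
sums.  Optionally a stereotyped action-potential template is pasted over the
refractory window (peak at the spike sample, ending exactly at V_reset at
t + t_ref) so that downstream peak detection and waveform features see
suprathreshold spikes; the template never alters the recorded spike times.
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit

from .datatypes import CurrentTrace, GLIFParams, Recording

__all__ = ["simulate_glif", "integrate_subthreshold", "make_spike_template"]

logger = logging.getLogger(__name__)


@njit(cache=True)
def _glif_loop(I, dt, C, gL, EL, Vreset, VTstar, dV, lam0, tref_n,
               eta_kernel, gamma_kernel, uniforms, V0):  # pragma: no cover - jitted
    n = I.size
    V = np.empty(n)
    V[0] = V0
    eta_acc = np.zeros(n + eta_kernel.size + 1)
    gamma_acc = np.zeros(n + gamma_kernel.size + 1)
    spikes = np.empty(n, dtype=np.int64)
    n_spk = 0
    ref = 0
    max_hazard = 0.0
    for t in range(n - 1):
        if ref > 0:
            V[t + 1] = Vreset
            ref -= 1
            continue
        lam = lam0 * np.exp(min((V[t] - (VTstar + gamma_acc[t])) / dV, 30.0))
        hazard = lam * dt / 1000.0
        if hazard > max_hazard:
            max_hazard = hazard
        p = 1.0 - np.exp(-lam * dt / 1000.0)
        if uniforms[t] < p:
            spikes[n_spk] = t
            n_spk += 1
            ref = tref_n - 1
            V[t + 1] = Vreset
            for k in range(eta_kernel.size):
                eta_acc[t + 1 + k] += eta_kernel[k]
            for k in range(gamma_kernel.size):
                gamma_acc[t + 1 + k] += gamma_kernel[k]
        else:
            dvdt = (-gL * (V[t] - EL) - eta_acc[t] + I[t]) / C
            V[t + 1] = V[t] + dt * dvdt
    return V, spikes[:n_spk], gamma_acc[:n], max_hazard


@njit(cache=True)
def _subthreshold_loop(I, dt, C, gL, EL, Vreset, tref_n, eta_kernel,
                       spike_samples, V0):  # pragma: no cover - jitted
    n = I.size
    V = np.empty(n)
    V[0] = V0
    eta_acc = np.zeros(n + eta_kernel.size + 1)
    for j in range(spike_samples.size):
        s = spike_samples[j]
        for k in range(eta_kernel.size):
            if s + 1 + k < eta_acc.size:
                eta_acc[s + 1 + k] += eta_kernel[k]
    ref = 0
    idx = 0
    for t in range(n - 1):
        if idx < spike_samples.size and t == spike_samples[idx]:
            idx += 1
            ref = tref_n - 1
            V[t + 1] = Vreset
            continue
        if ref > 0:
            V[t + 1] = Vreset
            ref -= 1
            continue
        dvdt = (-gL * (V[t] - EL) - eta_acc[t] + I[t]) / C
        V[t + 1] = V[t] + dt * dvdt
    return V


def make_spike_template(
    dt: float,
    t_ref: float,
    v_reset: float,
    threshold: float,
    peak: float = 30.0,
    width: float = 1.0,
    lead_slope: float = 12.0,
    lead_drop: float = 5.0,
) -> tuple[np.ndarray, int]:
    """Stereotyped AP waveform pasted at spike times.

    Piecewise linear: a slow lead rising at ``lead_slope`` mV/ms (safely below
    the 25 mV/ms threshold criterion at any sampling rate) from ``lead_drop``
    mV below threshold, a fast depolarization from threshold to ``peak`` over
    width/2, repolarization back to threshold over width/2, then linear decay
    to ``v_reset`` reached exactly at peak + t_ref (so reset extraction at the
    refractory offset is exact).  Returns (samples, peak_index); the peak
    index is aligned with the emission sample so recorded spike times coincide
    with the voltage maximum.  The first suprathreshold-slope sample sits
    exactly at ``threshold``, making the measured AP threshold, width and
    amplitude equal their nominal values.
    """
    n_half = max(int(round(width / 2.0 / dt)), 1)
    n_post = int(round(t_ref / dt))
    n_lead = max(int(np.ceil(lead_drop / (lead_slope * dt))), 1)
    rise0 = threshold - lead_slope * dt * np.arange(n_lead, 0, -1)
    rise1 = np.linspace(threshold, peak, n_half, endpoint=False)
    fall = np.linspace(peak, threshold, n_half + 1)[1:]
    n_settle = n_post - n_half
    settle = np.linspace(threshold, v_reset, max(n_settle, 1) + 1)[1:]
    template = np.concatenate([rise0, rise1, [peak], fall, settle])
    return template, n_lead + n_half


def simulate_glif(
    params: GLIFParams,
    current: CurrentTrace,
    seed: int | np.random.Generator = 0,
    V0: float | None = None,
    paste_template: bool = True,
) -> Recording:
    """Simulate the GLIF model driven by ``current``; reproducible under seed.

    Returns a Recording whose meta carries the generating parameters and the
    internal threshold trace VT(t) (for threshold-dynamics assertions).
    """
    I = current.values
    if I.size and not np.isfinite(I).all():
        raise ValueError("current contains NaN/inf")
    dt = current.dt
    rng = np.random.default_rng(seed)
    uniforms = rng.random(max(I.size, 1))
    eta_kernel = params.eta_basis.kernel_samples(params.eta_coeffs, dt)
    gamma_kernel = params.gamma_basis.kernel_samples(params.gamma_coeffs, dt)
    tref_n = int(round(params.t_ref / dt))
    v0 = params.E_L if V0 is None else V0

    if I.size == 0:
        return Recording(V=np.empty(0), I=current, dt=dt, spike_times=np.empty(0), meta={})

    V, spike_samples, gamma_trace, max_hazard = _glif_loop(
        I.astype(np.float64), dt, params.C, params.g_L, params.E_L,
        params.V_reset, params.VT_star, params.delta_V, params.lambda0,
        tref_n, eta_kernel, gamma_kernel, uniforms, v0,
    )
    # coarse-dt guard: the realized per-step hazard should stay well below 1
    if max_hazard > 0.2:
        logger.warning("lambda*dt reached %.3f (> 0.2); integration grid may be too coarse",
                       max_hazard)

    if paste_template and params.spike_template is not None and spike_samples.size:
        tpl = dict(params.spike_template)
        template, peak_idx = make_spike_template(
            dt, params.t_ref, params.V_reset, params.VT_star,
            peak=tpl.get("peak", 30.0), width=tpl.get("width", 1.0),
        )
        for s in spike_samples:
            a = s - peak_idx
            b = a + template.size
            ta, tb = 0, template.size
            if a < 0:
                ta, a = -a, 0
            if b > V.size:
                tb -= b - V.size
                b = V.size
            if tb > ta:
                V[a:b] = template[ta:tb]

    return Recording(
        V=V,
        I=current,
        dt=dt,
        spike_times=spike_samples * dt,
        meta={
            "params": params,
            "threshold_trace": params.VT_star + gamma_trace,
            "protocol_tag": current.protocol_tag,
        },
    )


def integrate_subthreshold(
    I: np.ndarray,
    dt: float,
    spike_samples: np.ndarray,
    C: float,
    g_L: float,
    E_L: float,
    V_reset: float,
    t_ref: float,
    eta_kernel: np.ndarray,
    V0: float | None = None,
) -> np.ndarray:
    """Deterministic integration of the membrane equation with spikes imposed
    at the given samples (clamp to V_reset for t_ref, add eta).  Used by the
    fitter to reconstruct the model subthreshold voltage on the data's spike
    train."""
    tref_n = int(round(t_ref / dt))
    v0 = E_L if V0 is None else V0
    return _subthreshold_loop(
        np.asarray(I, dtype=np.float64), dt, C, g_L, E_L, V_reset, tref_n,
        np.asarray(eta_kernel, dtype=np.float64),
        np.asarray(spike_samples, dtype=np.int64), v0,
    )
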