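"""Stimulation protocols: frozen-noise (FN) and step-and-hold (SH) currents.

The FN current emulates the summed input from a population of presynaptic
Poisson units (default 1000) whose rates switch between an "on" and an "off"
level following a binary hidden state.  The hidden state is a symmetric
two-state Markov chain with exponential dwell times of mean tau (250 ms for
slow, 50 ms for fast inputs).  Each unit's spike train is convolved with a
causal exponential kernel (5 ms decay, unit amplitude at the spike) and the
trains are mixed with weights w_i = ln(q_on_i / q_off_i), so the summed trace
transiently encodes the hidden state.  The result is scaled and offset before
injection.

The SH protocol is the conventional characterization stimulus: rectangular
depolarizing steps of increasing amplitude (default 10 steps, 500 ms,
40-400 pA) from a -70 mV holding potential.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .datatypes import CurrentTrace, HiddenStateTrace, PresynapticPopulation

__all__ = [
    "generate_hidden_state",
    "generate_fn_current",
    "generate_sh_protocol",
    "default_fn_current",
]


def generate_hidden_state(
    tau: float, duration: float, dt: float, seed: int | np.random.Generator = 0
) -> HiddenStateTrace:
    """Simulate the binary hidden state as a symmetric two-state Markov chain.

    Each sample switches state with probability dt/tau, giving exponential
    dwell times with mean tau in both states.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    if n == 0:
        return HiddenStateTrace(states=np.empty(0, dtype=np.int8), dt=dt, tau=tau)
    p_switch = min(dt / tau, 1.0)
    start = rng.integers(0, 2)
    flips = rng.random(n - 1) < p_switch
    states = (start + np.concatenate(([0], np.cumsum(flips)))) % 2
    return HiddenStateTrace(states=states.astype(np.int8), dt=dt, tau=tau)


def generate_fn_current(
    pop: PresynapticPopulation,
    hidden: HiddenStateTrace,
    baseline: float = 0.0,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> CurrentTrace:
    """Frozen-noise current from the hidden-state-modulated Poisson population.

    Per unit, spikes are drawn at rate q_on (Hz) in on-samples and q_off in
    off-samples, binned at hidden.dt; the weighted spike histogram is then
    convolved with the exponential kernel exp(-t/kernel_tau) and mapped
    through ``scale * signal + baseline``.
    """
    rng = np.random.default_rng(seed)
    n = len(hidden)
    dt = hidden.dt
    weights = pop.weights
    acc = np.zeros(n)
    if n > 0:
        on_idx = np.flatnonzero(hidden.states == 1)
        off_idx = np.flatnonzero(hidden.states == 0)
        t_on = on_idx.size * dt / 1000.0  # s
        t_off = off_idx.size * dt / 1000.0
        for i in range(pop.n_units):
            w = weights[i]
            if w == 0.0:
                # zero-weight units cannot contribute; skip their draws to
                # keep the q_on == q_off case exactly equal to baseline
                continue
            if on_idx.size:
                n_sp = rng.poisson(pop.q_on[i] * t_on)
                if n_sp:
                    np.add.at(acc, on_idx[rng.integers(0, on_idx.size, n_sp)], w)
            if off_idx.size:
                n_sp = rng.poisson(pop.q_off[i] * t_off)
                if n_sp:
                    np.add.at(acc, off_idx[rng.integers(0, off_idx.size, n_sp)], w)
        # causal exponential kernel, amplitude 1 at the spike sample:
        # y[t] = x[t] + exp(-dt/tau_k) * y[t-1]
        a = np.exp(-dt / pop.kernel_tau)
        acc = lfilter([1.0], [1.0, -a], acc)
    values = scale * acc + baseline
    return CurrentTrace(
        values=values,
        dt=dt,
        baseline=baseline,
        scale=scale,
        protocol_tag="FN",
        meta={"tau": hidden.tau, "n_units": pop.n_units, "kernel_tau": pop.kernel_tau},
    )


def default_fn_current(
    tau: float,
    duration: float,
    dt: float = 0.05,
    baseline: float = 0.0,
    target_sd: float = 50.0,
    n_units: int = 1000,
    seed: int = 0,
) -> CurrentTrace:
    """Convenience generator: hidden state + sampled population, with the
    multiplicative scale chosen so the fluctuating part has SD ``target_sd`` pA."""
    rng = np.random.default_rng(seed)
    hidden = generate_hidden_state(tau, duration, dt, rng)
    pop = PresynapticPopulation.sample(n_units=n_units, seed=rng)
    raw = generate_fn_current(pop, hidden, baseline=0.0, scale=1.0, seed=rng)
    sd = raw.values.std()
    scale = target_sd / sd if sd > 0 else 1.0
    values = scale * raw.values + baseline
    return CurrentTrace(
        values=values, dt=dt, baseline=baseline, scale=scale,
        protocol_tag="FN", meta=dict(raw.meta, target_sd=target_sd),
    )


def generate_sh_protocol(
    step_min: float = 40.0,
    step_max: float = 400.0,
    n_steps: int = 10,
    step_duration: float = 500.0,
    holding_potential: float = -70.0,
    dt: float = 0.05,
    pad_pre: float = 100.0,
    pad_post: float = 100.0,
) -> list[CurrentTrace]:
    """Step-and-hold sweep set: equally spaced rectangular pulses.

    Returns one CurrentTrace per step, amplitudes from step_min to step_max
    inclusive, each with ``pad_pre``/``pad_post`` ms of zero current around the
    pulse.  Step metadata (amplitude, onset, duration, holding potential) is
    carried in ``meta``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if step_max < step_min:
        raise ValueError("step_max must be >= step_min")
    if n_steps == 1:
        amplitudes = np.array([step_max])
    else:
        amplitudes = np.linspace(step_min, step_max, n_steps)
    n_pre = int(round(pad_pre / dt))
    n_step = int(round(step_duration / dt))
    n_post = int(round(pad_post / dt))
    traces = []
    for amp in amplitudes:
        values = np.concatenate(
            [np.zeros(n_pre), np.full(n_step, amp), np.zeros(n_post)]
        )
        traces.append(
            CurrentTrace(
                values=values,
                dt=dt,
                baseline=0.0,
                scale=1.0,
                protocol_tag="SH",
                meta={
                    "amplitude": float(amp),
                    "onset": pad_pre,
                    "step_duration": step_duration,
                    "holding_potential": holding_potential,
                },
            )
        )
    return traces
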