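# Default two-class synthetic population.
#
# Archetypes emulate the putative excitatory / inhibitory split of layer 2/3
# cortex: E-like cells have broad spikes, low firing rates, strong slow
# adaptation currents and slow (250 ms) frozen-noise input; I-like cells have
# narrow spikes, high rates, weak fast adaptation and fast (50 ms) input.
# baseline_margin (pA) sets how far below threshold the mean drive sits:
# baseline = g_L * (VT* - E_L) - margin.  Values are calibrated so that under
# the default drive (fluctuation SD 50 pA) E-like cells fire below 5 Hz and
# I-like cells above 10 Hz.
n_neurons: 312
master_seed: 0
classes:
  - label: E
    weight: 0.5961538461538461   # 186/312
    fn_tau: 250.0
    baseline_margin: 70.0
    params:
      C:       {mean: 180.0, sd: 25.0}
      g_L:     {mean: 8.0,   sd: 1.2}
      E_L:     {mean: -72.0, sd: 1.5}
      V_reset: {mean: -62.0, sd: 1.5}
      VT_star: {mean: -45.0, sd: 1.5}
      delta_V: {mean: 1.0,   sd: 0.15}
    eta:
      amplitude: {mean: 35.0, sd: 8.0}   # pA at t=0
      tau: 150.0                          # ms decay of the kernel profile
    gamma:
      amplitude: {mean: 5.0, sd: 1.0}    # mV at t=0
      tau: 80.0
    template:
      peak: 32.0
      width: {mean: 1.0, sd: 0.08}        # ms above threshold
  - label: I
    weight: 0.40384615384615385  # 126/312
    fn_tau: 50.0
    baseline_margin: 15.0
    params:
      C:       {mean: 90.0,  sd: 15.0}
      g_L:     {mean: 9.0,   sd: 1.5}
      E_L:     {mean: -68.0, sd: 1.5}
      V_reset: {mean: -60.0, sd: 1.5}
      VT_star: {mean: -46.0, sd: 1.5}
      delta_V: {mean: 0.8,   sd: 0.1}
    eta:
      amplitude: {mean: 10.0, sd: 3.0}
      tau: 40.0
    gamma:
      amplitude: {mean: 2.0, sd: 0.5}
      tau: 30.0
    template:
      peak: 30.0
      width: {mean: 0.35, sd: 0.04}
protocols:
  fn:
    duration: 360000.0   # ms
    dt: 0.05             # ms (20 kHz)
    target_sd: 50.0      # pA fluctuation SD
    n_units: 1000
  sh:
    step_min: 40.0
    step_max: 400.0
    n_steps: 10
    step_duration: 500.0
    holding_potential: -70.0
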