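# Methods

This note documents the models, the choices made where the design was open,
the synthetic-data conditions, and what the tests do and do not establish.
Units throughout: time in ms, voltage in mV, current in pA, capacitance in pF,
conductance in nS, rates in Hz (with these units pA/pF = mV/ms).

## Frozen-noise stimulus

The FN current emulates the summed input of a presynaptic population. A
binary hidden state switches as a symmetric two-state Markov chain with
per-sample switch probability `dt/τ`, giving exponential dwell times with
mean τ in both states; the study's two conditions are τ = 250 ms (slow, used
for putative excitatory cells) and τ = 50 ms (fast). The source text gives
only the single time constant, so the symmetric chain — the simplest chain
with one stated constant — is used. Each of `n_units` (default 1000) Poisson
units fires at `q_on` in the on state and `q_off` in the off state; the unit
rate distributions are not specified in the source, so defaults are
`q_off ~ U(1, 10) Hz` and `q_on = q_off·g` with `g ~ U(0.5, 2)` per unit,
giving a mixture of on- and off-preferring units and hence signed weights
`w_i = ln(q_on_i/q_off_i)`. Spike trains are convolved with a causal
exponential kernel `exp(−t/5 ms)` of unit amplitude at the spike and summed
with the weights. The result is an affine map `scale·s(t) + baseline`; the
default scale is chosen per trace so the fluctuating part has a target SD of
50 pA, a realistic somatic drive for the cell sizes used, and the baseline is
set per neuron (below). Implementation note: spike placement is done
segment-wise (Poisson counts over total on/off time, uniform placement over
the matching samples) and the kernel applied as a single-pole recursive
filter, which is exactly equivalent to per-spike convolution and fast enough
for 360-s, 20-kHz traces.

The SH protocol is 10 rectangular depolarizing steps, 40–400 pA in equal
increments, 500 ms each, from a −70 mV holding potential, padded with 100 ms
of zero current on either side.

## GLIF model and simulation

Membrane equation `C dV/dt = −g_L(V−E_L) − Ση(t−t̂_j) + I(t)` with escape
noise `λ(t) = λ0·exp((V−VT(t))/ΔV)` (λ0 fixed at 1 Hz for fitting), per-step
spike probability `1 − exp(−λ dt)`, moving threshold
`VT(t) = VT* + Σγ(t−t̂_j)`, and a refractory period t_ref = 4 ms. Both η and
γ are sums of K = 10 rectangular basis functions with log-spaced edges over a
500-ms support — fine near the spike where the kernels vary fastest. The
first interior edge is placed at 10 ms so that no basis bin lies wholly
inside the spike-exclusion window of the fit, which would make its regression
column unobservable.

Integration is forward Euler at dt = 0.05 ms (20 kHz) in a numba-compiled
loop. Convention, applied identically in simulation and fitting: on a spike
at sample t̂ the voltage is clamped to V_reset over `(t̂, t̂+t_ref]`,
integration resumes from V_reset, no hazard is evaluated inside the open
interval `(t̂, t̂+t_ref)`, and the spike-triggered kernels take effect from
the sample after emission (a spike never modulates its own emission
probability). If the realized per-step hazard `λ·dt` exceeds 0.2 anywhere, a
warning is logged that the grid is too coarse for the hazard being simulated.

The forward model does not produce action-potential shapes (the escape-noise
formulation only emits spike times), but downstream feature extraction needs
suprathreshold waveforms, so a stereotyped template is pasted at each spike:
a slow lead rising at 12 mV/ms (safely below the 25 mV/ms threshold
criterion at any sampling rate), a linear rise from VT* to the peak over half
the nominal width, a symmetric fall, and a linear settle reaching V_reset
exactly at peak + t_ref. The template peak sits at the emission sample, so
detected peak times equal simulator spike times, the measured threshold,
width and amplitude equal their nominal values, and reset-voltage extraction
at peak + t_ref is exact. Pasting never alters the recorded spike times or
the hidden dynamics.

## Three-step fit

1. **Reset voltage**: all spike waveforms are aligned on the peak and
   averaged; V_reset is the average voltage at peak + t_ref. t_ref must be
   below the minimum ISI.
2. **Subthreshold regression**: the forward-difference V̇ is regressed by
   OLS on `[V, 1, I, c_1 … c_K]`, where `c_k(t)` counts past spikes whose lag
   falls in basis bin k. Samples inside `(t̂−5 ms, t̂+t_ref)` around every
   spike are excluded. The injected current is included as a regressor with
   coefficient 1/C — without it C is not identifiable from V̇ — and the
   remaining coefficients map to `g_L = −β_V·C`, `E_L = β_1/(−β_V)`,
   `a_k = −β_k·C`. History columns with no support in the training rows
   (e.g. on a spike-free trace) are treated as structurally absent with zero
   coefficients rather than failing the fit; genuine collinearity raises an
   error naming the columns.
3. **Threshold likelihood**: the model subthreshold voltage is reconstructed
   by integrating the fitted passive dynamics with the data's spike train
   imposed, and `(ΔV, VT*, γ_p)` maximize the point-process log-likelihood
   `Σ_spikes x_tᵀθ − ΔT Σ_Ω exp(x_tᵀθ)` in the log-linear coordinates
   `θ = (1/ΔV, logλ0 − VT*/ΔV, −γ_p/ΔV)`, where the objective is a concave
   Poisson-GLM likelihood. Newton iterations with step halving; convergence
   when the per-bin gradient norm falls below 1e−8 (200-iteration cap, the
   voltage column centered for conditioning, ΔT = dt in seconds since λ is in
   Hz). At least 10 spikes are required; below that the MLE is
   ill-conditioned.

A 100-s training window from the start of the trial is used for both the
subthreshold and the threshold stage. Goodness of fit is the variance
explained R² of the subthreshold voltage on the exclusion-filtered samples;
fits with R² ≤ 0.7 are flagged excluded (but still returned). The clustering
vector is `(g_L, ΔV, C, VT*, E_L, V_reset)`.

## Feature extraction

Spikes are voltage peaks ≥ 20 mV with a minimum separation of 4 ms
(80 samples at 20 kHz). A printed separation of 80 ms would make the < 3 ms
ISI exclusion rule for waveforms unreachable, so the sample-unit reading is
used; the value is configurable. Waveform cuts are 2 ms + 3 ms around the
peak for the cross-protocol comparison and 5 ms + 5 ms for the E/I analysis;
spikes adjacent to an ISI < 3 ms are discarded (non-bursting shapes only).
The spike threshold is the voltage where dV/dt first reaches 25 mV/ms in a
5-ms window before the peak; width is the time between the threshold
crossings flanking the peak (linearly interpolated between samples);
amplitude is peak minus threshold. The 22 AP attributes and their fixed
order are listed in `features.AP_FEATURE_NAMES`; SH trials pool the spikes
of all steps for the descriptive statistics, take count/rate from the
highest step and first-spike quantities from the lowest spiking step, an
interpretation noted here because the source does not state whether sweeps
are pooled or concatenated. The STA is the mean 100-ms stimulus window
preceding each spike (spikes without a full window dropped), z-scored and
scaled to unit L2 norm; no whitening or regularization.

## Graph clustering

Feature matrices are preprocessed by column z-scoring (population SD;
zero-variance columns dropped with a warning) followed by row L2
normalization. The clustering substrate is the symmetrized UMAP fuzzy
simplicial kNN graph (n_neighbors = 20, min_dist = 0.1 recorded for the
optional plotting embedding, which is never used for clustering). Louvain
community detection is delegated to networkx; the reported modularity is
always re-evaluated directly from its definition on the returned labels,
using symmetrized strengths for the degree-product null (the directed-degree
notation of the source reduces to this on an undirected graph). The
resolution is selected by the stability scan: for each γ in 0–5 (step 0.5),
25 Louvain runs on random 90% node subsamples, recording mean/SD of Q and of
the cluster count; the selected γ maximizes mean Q over γ > 0 (γ = 0 has a
degenerate single-community optimum and is excluded; figure legends in the
source mention 80% subsampling while the text says 90% — the default is 0.9,
configurable). ECG consensus uses k level-1 partitions (the first yield of
`louvain_partitions`), reweights each edge by its co-clustering frequency
floored at w* off the graph's 2-core, and runs a final Louvain on the
reweighted graph. Likelihood matrices, ARI/AMI (scikit-learn), cosine
summaries (within-group blocks averaged over the strict upper triangle) and
the E-E/I-I/E-I similarity groups feed the downstream statistics; omnibus
tests themselves (Welch's ANOVA etc.) are left to standard libraries.

## MCFA

The shared/private factor model (z shared across sets, x_m private,
diagonal residuals) is fitted by EM on the equivalent joint factor model
with structured loadings, preserving the structural zeros in a per-set
M-step, so the marginal likelihood is non-decreasing. All posterior and
likelihood algebra uses the Woodbury identity (only N×P and q×q arrays), so
the full-dimensional STA (2000) and adaptation-current (10000) sets are
tractable. Initialization: W from the top-d pooled principal components
(per-set blocks), L from per-set residual PCs, Ψ from residual diagonals —
the source's "average variance constraint" initialization is under-specified,
and recovery is insensitive to this choice at the tested conditions.
Residual variances are floored at 1e−4 (standardized scale): exactly
duplicated features (the adaptation-current vector is piecewise constant
over basis bins) otherwise drive ψ → 0 and destabilize the E-step; the floor
can nudge the monotonicity bound by ~1e−5 relative, which is the tolerance
on the monotonicity assertion. Convergence: relative likelihood gain below
1e−6 (cap 500 iterations). Shared-dimension selection counts
correlation-matrix eigenvalues above a threshold: the printed rule
`1 + p/N` (default, for fidelity to the source) and the standard
Marchenko–Pastur bulk edge `(1+√(p/N))²` are both implemented and reported.
Private dimensions default to 1 for sets with ≤ 10 features (the six passive
parameters) and 2 otherwise. Feature importance S_d is the mean pairwise
Pearson correlation across sets of the single-mode posterior means
`E[z|y_m] = Y_m(W_mW_mᵀ + L_mL_mᵀ + Ψ_m)⁻¹W_m`; the printed normalization is
ambiguous about where Ψ enters, and the standard Gaussian posterior is used.
Variance percentages are taken against the per-set total model variance, so
the shared/private/residual triple sums to 100 exactly.

## Synthetic population

Archetype tables live in the shipped YAML profiles. E-like cells: C ≈ 180 pF,
g_L ≈ 8 nS, broad 1.0-ms spikes, strong slow adaptation (35 pA amplitude,
150-ms decay), slow FN input (τ = 250 ms). I-like: C ≈ 90 pF, narrow 0.35-ms
spikes, weak fast adaptation (10 pA, 40 ms), fast input (τ = 50 ms). The
per-neuron FN baseline is `g_L(VT* − E_L) − margin` with class margins
(70 pA E, 15 pA I) calibrated once so that under the default 50-pA drive
E-like cells fire below 5 Hz and I-like above 10 Hz, mirroring the
broad/narrow–slow/fast phenotype convention. The study-scale profile is 312
neurons split 186/126; the test-scale profile (20 neurons, 10 s FN at 5 kHz)
exercises every stage quickly. Ground-truth class labels are generator
labels, not molecular identities.

What the synthetic data do not emulate: measurement noise, electrode drift,
bursting, recording artifacts, and any dissociation between protocols beyond
what the GLIF dynamics produce — on synthetic cells both protocols probe the
same generative parameters, so cross-protocol agreement is typically higher
than in real recordings. Passing tests therefore establish correctness of the
machinery (simulation, fitting, statistics), not the empirical claims about
cortical neurons. The protocol-dependence and STA-privacy headlines are
checked on feature-level constructions that encode those structures by
design.

## Problem sizes and numerical choices

The validation analyses run at reduced sizes chosen to keep the full suite
fast while leaving the statistics well-determined: 20 neurons × 100 s for
the round-trip recovery test (10 × 60 s in the acceptance script), 2400 s of
white noise (~30k spikes) for the STA–filter check, N = 400 for clustering
recovery, N = 500 for MCFA recovery. Recovery tolerances mirror the
identifiability of each quantity: passive parameters are recovered almost
exactly on noiseless data (OLS on an exact linear relation), while ΔV and
VT* carry Monte-Carlo error from the point process (1 mV / 20% at ~100 s of
data). The STA–filter correlation threshold (0.9) holds in the LN-style
regime (no adaptation, reset at the operating point, soft threshold
ΔV ≳ σ_V); with strong reset or a hard threshold the STA acquires a
derivative-like component and decays faster than the membrane filter — a
real property of integrate-and-fire encoders, not an estimator artifact.

## Known limitations

- The Poisson-GLM threshold fit can assign spurious weight to the earliest γ
  basis bins when few short ISIs constrain them; VT* and ΔV are unaffected.
- The E/I split rule (cluster median rate > 10 Hz AND median width < 0.5 ms)
  operationalizes a qualitative description; borderline cells land on either
  side at short trial lengths.
- ECG on weakly structured graphs fragments more than multi-level Louvain;
  it is used as the cross-check it is meant to be, not as the primary
  clustering.
- The HDF5 container stores one FN trial and one SH sweep set per cell;
  multi-trial designs (drug conditions, repeats) are out of scope.
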