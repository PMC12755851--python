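"""Three-step GLIF fitting from a current/voltage recording.

Step 1 extracts the reset voltage from the spike-triggered average waveform at
peak + t_ref.  Step 2 recovers the passive parameters and the adaptation
current eta by ordinary least squares on the voltage derivative in the
subthreshold regime (spike windows excised).  Step 3 recovers the threshold
parameters (VT*, delta_V, gamma) by maximizing the point-process likelihood of
the observed spike train given the reconstructed model voltage; in the
log-linear parametrization theta = (1/delta_V, ..., -gamma_p/delta_V) the
objective is a concave Poisson-GLM log-likelihood, solved by Newton's method.

Design-matrix note: the subthreshold regression includes the injected current
as a regressor with coefficient 1/C; without it the capacitance is not
identifiable from the voltage derivative.  The remaining coefficients map to
g_L = -beta_V * C, E_L = beta_1 / (-beta_V), a_k = -beta_k * C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GLIFParams, KernelBasis, Recording
from .glif_sim import integrate_subthreshold

__all__ = [
    "SubthresholdFit",
    "ThresholdFit",
    "extract_reset_voltage",
    "fit_subthreshold",
    "fit_threshold",
    "subthreshold_r2",
    "fit_glif",
]

PRE_SPIKE_EXCLUSION = 5.0  # ms removed before each spike peak in V_data^sub


class FitError(RuntimeError):
    pass


@dataclass
class SubthresholdFit:
    C: float
    g_L: float
    E_L: float
    eta_coeffs: np.ndarray
    eta_basis: KernelBasis
    r2: float
    v_reset: float
    t_ref: float
    design_columns: tuple = ()


@dataclass
class ThresholdFit:
    delta_V: float
    VT_star: float
    gamma_coeffs: np.ndarray
    gamma_basis: KernelBasis
    loglik: float
    converged: bool
    n_iter: int = 0
    grad_norm: float = np.nan


def _exclusion_mask(n: int, dt: float, spike_samples: np.ndarray, t_ref: float,
                    pre: float = PRE_SPIKE_EXCLUSION) -> np.ndarray:
    """True at samples kept for subthreshold fitting: t outside
    (t_hat - pre, t_hat + t_ref) around every spike peak (open interval)."""
    keep = np.ones(n, dtype=bool)
    pre_n = int(np.ceil(pre / dt)) - 1
    post_n = int(np.ceil(t_ref / dt)) - 1
    for s in spike_samples:
        a = max(s - pre_n, 0)
        b = min(s + post_n + 1, n)
        keep[a:b] = False
    return keep


def extract_reset_voltage(rec: Recording, t_ref: float = 4.0) -> float:
    """Average all spike waveforms aligned on the peak; return V at peak + t_ref."""
    spikes = rec.spike_samples
    if spikes.size == 0:
        raise FitError("no spikes: reset voltage is not applicable")
    if spikes.size > 1:
        min_isi = np.diff(rec.spike_times).min()
        if t_ref >= min_isi:
            raise FitError(
                f"t_ref={t_ref} ms must be below the minimum ISI ({min_isi:.3f} ms)"
            )
    off = int(round(t_ref / rec.dt))
    idx = spikes + off
    idx = idx[idx < rec.V.size]
    if idx.size == 0:
        raise FitError("no spike has a full t_ref window inside the trace")
    return float(rec.V[idx].mean())


def fit_subthreshold(
    rec: Recording,
    eta_basis: KernelBasis | None = None,
    t_ref: float = 4.0,
    train_window: float = 100_000.0,
    v_reset: float | None = None,
) -> SubthresholdFit:
    """OLS regression of the voltage forward-difference on [V, 1, I, spike basis]."""
    if eta_basis is None:
        eta_basis = KernelBasis.default()
    dt = rec.dt
    n_train = min(int(round(train_window / dt)), rec.V.size)
    V = rec.V[:n_train]
    I = rec.I.values[:n_train]
    spikes = rec.spike_samples
    spikes_in = spikes[spikes < n_train]

    vdot = (V[1:] - V[:-1]) / dt  # mV/ms; last sample dropped
    keep = _exclusion_mask(n_train, dt, spikes_in, t_ref)
    rows = keep[:-1] & keep[1:]

    cols = eta_basis.convolve_spikes(spikes_in, n_train, dt)
    names = ("V", "const", "I") + tuple(f"eta_{k}" for k in range(eta_basis.n_basis))
    X = np.column_stack([V, np.ones(n_train), I, cols])[:-1][rows]
    y = vdot[rows]

    # spike-history columns with no support in the training rows (e.g. a
    # spike-free trace) are structurally absent: their coefficients are 0
    active = np.ones(X.shape[1], dtype=bool)
    active[3:] = np.abs(X[:, 3:]).max(axis=0) > 0
    Xa = X[:, active]
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        names_a = [nm for nm, a in zip(names, active) if a]
        raise FitError(f"rank-deficient design (rank {rank} < {Xa.shape[1]}); "
                       f"collinear columns among: {names_a}")

    beta = np.zeros(X.shape[1])
    beta[active], *_ = np.linalg.lstsq(Xa, y, rcond=None)
    beta_V, beta_1, beta_I = beta[0], beta[1], beta[2]
    if beta_I == 0:
        raise FitError("current coefficient is zero; C unidentifiable")
    C = 1.0 / beta_I
    g_L = -beta_V * C
    E_L = beta_1 / (-beta_V)
    a_k = -beta[3:] * C

    if v_reset is None:
        v_reset = extract_reset_voltage(rec, t_ref) if spikes.size else E_L

    fit = SubthresholdFit(
        C=C, g_L=g_L, E_L=E_L, eta_coeffs=a_k, eta_basis=eta_basis,
        r2=np.nan, v_reset=v_reset, t_ref=t_ref, design_columns=names,
    )
    params = GLIFParams(
        C=C, g_L=g_L, E_L=E_L, V_reset=v_reset, VT_star=0.0, delta_V=1.0,
        t_ref=t_ref, eta_basis=eta_basis, eta_coeffs=a_k,
    )
    sub_rec = Recording(V=V, I=type(rec.I)(values=I, dt=dt), dt=dt,
                        spike_times=spikes_in * dt)
    fit.r2 = subthreshold_r2(sub_rec, params)
    return fit


def subthreshold_r2(rec: Recording, params: GLIFParams) -> float:
    """Variance explained (1 - SSE/SST) of the subthreshold voltage, with the
    same spike-exclusion windows as the subthreshold fit."""
    dt = rec.dt
    spikes = rec.spike_samples
    eta_kernel = params.eta_basis.kernel_samples(params.eta_coeffs, dt)
    v_model = integrate_subthreshold(
        rec.I.values, dt, spikes, params.C, params.g_L, params.E_L,
        params.V_reset, params.t_ref, eta_kernel, V0=rec.V[0],
    )
    keep = _exclusion_mask(rec.V.size, dt, spikes, params.t_ref)
    data = rec.V[keep]
    model = v_model[keep]
    sst = np.sum((data - data.mean()) ** 2)
    if sst == 0:
        raise FitError("zero-variance subthreshold data: R^2 undefined")
    sse = np.sum((data - model) ** 2)
    return float(1.0 - sse / sst)


def _poisson_loglik(theta, X, y, dT):
    eta = np.clip(X @ theta, -700.0, 700.0)
    mu = dT * np.exp(eta)
    ll = float(y @ eta - mu.sum())
    grad = X.T @ (y - mu)
    return ll, grad, mu


def fit_threshold(
    rec: Recording,
    sub: SubthresholdFit,
    gamma_basis: KernelBasis | None = None,
    lambda0: float = 1.0,
    t_ref: float = 4.0,
    train_window: float = 100_000.0,
    min_spikes: int = 10,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ThresholdFit:
    """Maximum-likelihood threshold parameters given the subthreshold fit.

    The objective sum_spikes x_t.theta - dT sum_Omega exp(x_t.theta) is
    concave in theta = (1/delta_V, intercept, -gamma_p/delta_V); Newton
    iterations with step halving; convergence on the per-bin gradient norm.
    """
    if gamma_basis is None:
        gamma_basis = KernelBasis.default()
    dt = rec.dt
    n_train = min(int(round(train_window / dt)), rec.V.size)
    spikes = rec.spike_samples
    spikes_in = spikes[spikes < n_train]
    if spikes_in.size < min_spikes:
        raise FitError(f"threshold fit needs >= {min_spikes} spikes, got {spikes_in.size}")

    eta_kernel = sub.eta_basis.kernel_samples(sub.eta_coeffs, dt)
    v_model = integrate_subthreshold(
        rec.I.values[:n_train], dt, spikes_in, sub.C, sub.g_L, sub.E_L,
        sub.v_reset, t_ref, eta_kernel, V0=rec.V[0],
    )

    # Omega excludes the open refractory window (t_hat, t_hat + t_ref), during
    # which the simulator evaluates no hazard; the spike bin itself is
    # retained and carries the spike count.
    tref_n = int(round(t_ref / dt))
    keep = np.ones(n_train, dtype=bool)
    for s in spikes_in:
        keep[s + 1: min(s + tref_n, n_train)] = False
    y = np.zeros(n_train)
    y[spikes_in] = 1.0

    cols = gamma_basis.convolve_spikes(spikes_in, n_train, dt)
    v_c = v_model.mean()
    X = np.column_stack([v_model - v_c, np.ones(n_train), cols])[keep]
    y = y[keep]
    dT = dt / 1000.0  # s; lambda in Hz

    # init: delta_V = 2 mV, intercept matching the mean rate, gamma = 0
    theta = np.zeros(X.shape[1])
    theta[0] = 0.5
    theta[1] = np.log(max(y.sum(), 1.0) / (dT * y.size))
    ll, grad, mu = _poisson_loglik(theta, X, y, dT)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H = -(X.T * mu) @ X
        try:
            step = np.linalg.solve(H - 1e-12 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            step = grad / max(mu.sum(), 1.0)
        step = -step
        new = theta + step
        ll_new, grad_new, mu_new = _poisson_loglik(new, X, y, dT)
        n_half = 0
        while ll_new < ll and n_half < 50:
            step *= 0.5
            new = theta + step
            ll_new, grad_new, mu_new = _poisson_loglik(new, X, y, dT)
            n_half += 1
        theta, ll, grad, mu = new, ll_new, grad_new, mu_new
        if np.linalg.norm(grad) / y.size < tol:
            converged = True
            break
    if not converged:
        raise FitError(
            f"threshold MLE did not converge in {max_iter} iterations "
            f"(per-bin gradient norm {np.linalg.norm(grad) / y.size:.3e})"
        )
    if theta[0] <= 0:
        raise FitError("non-positive 1/delta_V at the optimum")

    delta_V = 1.0 / theta[0]
    intercept = theta[1] - theta[0] * v_c  # undo the centering of V
    VT_star = (np.log(lambda0) - intercept) * delta_V
    gamma = -theta[2:] * delta_V
    return ThresholdFit(
        delta_V=float(delta_V), VT_star=float(VT_star), gamma_coeffs=gamma,
        gamma_basis=gamma_basis, loglik=ll, converged=converged, n_iter=it,
        grad_norm=float(np.linalg.norm(grad) / y.size),
    )


def threshold_objective(theta: np.ndarray, rec: Recording, sub: SubthresholdFit,
                        gamma_basis: KernelBasis, t_ref: float = 4.0,
                        train_window: float = 100_000.0) -> float:
    """Evaluate the threshold log-likelihood at an arbitrary GLM-coordinate
    point (for optimality spot checks)."""
    dt = rec.dt
    n_train = min(int(round(train_window / dt)), rec.V.size)
    spikes_in = rec.spike_samples[rec.spike_samples < n_train]
    eta_kernel = sub.eta_basis.kernel_samples(sub.eta_coeffs, dt)
    v_model = integrate_subthreshold(
        rec.I.values[:n_train], dt, spikes_in, sub.C, sub.g_L, sub.E_L,
        sub.v_reset, t_ref, eta_kernel, V0=rec.V[0],
    )
    tref_n = int(round(t_ref / dt))
    keep = np.ones(n_train, dtype=bool)
    for s in spikes_in:
        keep[s + 1: min(s + tref_n, n_train)] = False
    y = np.zeros(n_train)
    y[spikes_in] = 1.0
    cols = gamma_basis.convolve_spikes(spikes_in, n_train, dt)
    X = np.column_stack([v_model, np.ones(n_train), cols])[keep]
    ll, _, _ = _poisson_loglik(np.asarray(theta, float), X, y[keep], dt / 1000.0)
    return ll


@dataclass
class GLIFFitResult:
    params: GLIFParams
    sub: SubthresholdFit
    thr: ThresholdFit | None
    r2: float
    excluded: bool
    errors: dict = field(default_factory=dict)

    def clustering_vector(self) -> np.ndarray:
        return self.params.clustering_vector()

    def eta_samples(self, dt: float) -> np.ndarray:
        return self.params.eta_basis.kernel_samples(self.params.eta_coeffs, dt)


def fit_glif(
    rec: Recording,
    eta_basis: KernelBasis | None = None,
    gamma_basis: KernelBasis | None = None,
    t_ref: float = 4.0,
    train_window: float = 100_000.0,
    lambda0: float = 1.0,
    r2_threshold: float = 0.7,
    min_spikes: int = 10,
) -> GLIFFitResult:
    """Full pipeline: reset voltage -> subthreshold OLS -> threshold MLE.

    Recordings whose subthreshold R^2 falls at or below ``r2_threshold`` are
    flagged ``excluded`` but still returned.  Threshold-stage failures (too few
    spikes, non-convergence) are recorded in ``errors['threshold']`` with
    placeholder threshold parameters.
    """
    try:
        v_reset = extract_reset_voltage(rec, t_ref)
    except FitError as e:
        raise FitError(f"reset-voltage stage: {e}") from e
    try:
        sub = fit_subthreshold(rec, eta_basis, t_ref, train_window, v_reset=v_reset)
    except FitError as e:
        raise FitError(f"subthreshold stage: {e}") from e
    errors = {}
    thr = None
    try:
        thr = fit_threshold(rec, sub, gamma_basis, lambda0, t_ref,
                            train_window, min_spikes)
        delta_V, VT_star = thr.delta_V, thr.VT_star
        gamma_coeffs = thr.gamma_coeffs
        gb = thr.gamma_basis
    except FitError as e:
        errors["threshold"] = str(e)
        delta_V, VT_star = np.nan, np.nan
        gb = gamma_basis if gamma_basis is not None else KernelBasis.default()
        gamma_coeffs = np.full(gb.n_basis, np.nan)

    params = GLIFParams(
        C=sub.C, g_L=sub.g_L, E_L=sub.E_L, V_reset=v_reset,
        VT_star=VT_star if np.isfinite(VT_star) else 0.0,
        delta_V=delta_V if np.isfinite(delta_V) and delta_V > 0 else 1.0,
        lambda0=lambda0, t_ref=t_ref,
        eta_basis=sub.eta_basis, eta_coeffs=sub.eta_coeffs,
        gamma_basis=gb, gamma_coeffs=gamma_coeffs,
    )
    if not np.isfinite(VT_star):
        params.VT_star = np.nan
        params.delta_V = np.nan
    return GLIFFitResult(
        params=params, sub=sub, thr=thr, r2=sub.r2,
        excluded=bool(sub.r2 <= r2_threshold), errors=errors,
    )
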