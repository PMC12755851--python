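"""Multi-set correlation and factor analysis (MCFA).

Generative model over M attribute sets observed on the same N neurons:

    z_n ~ N(0, I_d)                     shared factor
    x_n^m ~ N(0, I_{k_m})               private factor of set m
    y_n^m ~ N(W_m z_n + L_m x_n^m, Psi_m),  Psi_m diagonal

Fitting is by EM on the equivalent joint factor model with latent
u = (z, x_1, ..., x_M) and structured loadings Lambda = [W, blockdiag(L)]
whose structural zeros are preserved in the per-set M-step, so the marginal
log-likelihood is non-decreasing.  All likelihood and posterior algebra uses
the Woodbury identity so only N x P and q x q arrays are formed (q = d + sum
k_m), which keeps the full-dimensional attribute sets (P up to ~10^4)
tractable.

On standardized inputs (each feature z-scored) the per-feature unit variance
decomposes into sum_d W_m(j,d)^2 (shared) + sum_k L_m(j,k)^2 (private) +
psi_mj (residual), which is what :func:`variance_report` tabulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MCFAModel",
    "standardize_sets",
    "select_shared_dim",
    "fit_em",
    "variance_report",
    "feature_importance",
]


@dataclass
class MCFAModel:
    d: int
    k_list: list[int]
    W: list[np.ndarray]  # per set, P_m x d
    L: list[np.ndarray]  # per set, P_m x k_m
    Psi: list[np.ndarray]  # per set, diagonal entries (P_m,)
    z_hat: np.ndarray  # N x d posterior shared scores
    x_hat: list[np.ndarray]  # per set, N x k_m
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False

    @property
    def M(self) -> int:
        return len(self.W)

    @property
    def loglik(self) -> float:
        return float(self.loglik_path[-1]) if self.loglik_path.size else np.nan


def standardize_sets(Ys: list[np.ndarray]) -> list[np.ndarray]:
    """Per-feature z-scoring (population SD) of every attribute set."""
    out = []
    for Y in Ys:
        Y = np.asarray(Y, dtype=float)
        sd = Y.std(axis=0)
        sd[sd == 0] = 1.0
        out.append((Y - Y.mean(axis=0)) / sd)
    return out


def select_shared_dim(
    Y: np.ndarray | list[np.ndarray], rule: str = "as_printed",
) -> int:
    """Count correlation-matrix eigenvalues above the noise threshold.

    ``as_printed`` uses lambda_m = 1 + p/N; ``mp_edge`` uses the
    Marchenko-Pastur bulk edge (1 + sqrt(p/N))^2, the statistically standard
    choice.  A list of sets is pooled by horizontal concatenation.
    """
    if isinstance(Y, (list, tuple)):
        Y = np.hstack([np.asarray(y, dtype=float) for y in Y])
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if n < 2:
        raise ValueError("need at least two samples")
    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Y - Y.mean(axis=0)) / sd
    # eigenvalues of the correlation matrix = squared singular values / N
    svals = np.linalg.svd(Z, compute_uv=False)
    evals = svals**2 / n
    ratio = p / n
    if rule == "as_printed":
        lam = 1.0 + ratio
    elif rule == "mp_edge":
        lam = (1.0 + np.sqrt(ratio)) ** 2
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return int(np.sum(evals > lam))


def _marginal_loglik(Y, Lam, psi, q):
    """N(0, Lam Lam^T + diag(psi)) log-likelihood via Woodbury."""
    n, p = Y.shape
    inv_psi = 1.0 / psi
    B = Lam * inv_psi[:, None]  # Psi^-1 Lam
    Mq = np.eye(q) + Lam.T @ B
    sign, logdet_M = np.linalg.slogdet(Mq)
    logdet = np.sum(np.log(psi)) + logdet_M
    YB = Y @ B  # N x q
    quad = np.sum(Y**2 * inv_psi) - np.einsum(
        "ij,jk,ik->", YB, np.linalg.inv(Mq), YB
    )
    return -0.5 * (n * p * np.log(2 * np.pi) + n * logdet + quad)


def fit_em(
    Ys: list[np.ndarray],
    d: int,
    k_list: list[int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    standardize: bool = True,
) -> MCFAModel:
    """EM fit of the shared/private factor model.

    Private dimensions default to the study's settings: 1 for a
    low-dimensional set (P_m <= 10, e.g. the six passive parameters), else 2.
    The marginal log-likelihood is asserted non-decreasing each iteration
    (within numerical tolerance); violation raises, as it would indicate an
    implementation defect.
    """
    if d < 1:
        raise ValueError("shared dimension d must be >= 1")
    Ys = [np.asarray(Y, dtype=float) for Y in Ys]
    N = Ys[0].shape[0]
    if any(Y.shape[0] != N for Y in Ys):
        raise ValueError("all sets must share the neuron roster")
    if standardize:
        Ys = standardize_sets(Ys)
    M = len(Ys)
    Ps = [Y.shape[1] for Y in Ys]
    if k_list is None:
        k_list = [1 if p <= 10 else 2 for p in Ps]
    if any(k < 0 for k in k_list):
        raise ValueError("private dimensions must be >= 0")
    q = d + sum(k_list)
    P = sum(Ps)
    Y = np.hstack(Ys)
    rng = np.random.default_rng(seed)

    # --- initialization: pooled top-d PCs for W, per-set residual PCs for L
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    W0 = Vt[:d].T * (S[:d] / np.sqrt(N))
    Z0 = U[:, :d] * np.sqrt(N)
    offsets = np.cumsum([0] + Ps)
    W = [W0[offsets[m]: offsets[m + 1]] for m in range(M)]
    L, Psi = [], []
    for m in range(M):
        R = Ys[m] - Z0 @ W[m].T
        k = k_list[m]
        if k > 0:
            Ur, Sr, Vr = np.linalg.svd(R, full_matrices=False)
            Lm = Vr[:k].T * (Sr[:k] / np.sqrt(N))
        else:
            Lm = np.zeros((Ps[m], 0))
        L.append(Lm)
        resid = np.maximum(R.var(axis=0) - np.sum(Lm**2, axis=1), 1e-4)
        Psi.append(resid)
    # tiny jitter decorrelates exactly degenerate inits
    W = [w + 1e-8 * rng.standard_normal(w.shape) for w in W]

    # latent index bookkeeping: u = (z, x_1, ..., x_M)
    priv = []
    o = d
    for k in k_list:
        priv.append(slice(o, o + k))
        o += k

    def assemble():
        Lam = np.zeros((P, q))
        psi = np.concatenate(Psi)
        for m in range(M):
            Lam[offsets[m]: offsets[m + 1], :d] = W[m]
            Lam[offsets[m]: offsets[m + 1], priv[m]] = L[m]
        return Lam, psi

    lls = []
    converged = False
    EU = None
    for it in range(max_iter):
        Lam, psi = assemble()
        ll = _marginal_loglik(Y, Lam, psi, q)
        if lls and ll < lls[-1] - 1e-5 * max(1.0, abs(lls[-1])):
            # the residual-variance floor (needed for exactly collinear
            # features) can nudge the bound; beyond this tolerance it is a bug
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{lls[-1]:.6f} -> {ll:.6f}"
            )
        done = bool(lls) and (ll - lls[-1]) < tol * max(1.0, abs(ll))
        lls.append(ll)
        if done:
            converged = True
            break

        # E-step: posterior moments of u | y
        inv_psi = 1.0 / psi
        B = Lam * inv_psi[:, None]
        Mq = np.eye(q) + Lam.T @ B
        Minv = np.linalg.inv(Mq)
        EU = Y @ B @ Minv  # N x q
        Suu = N * Minv + EU.T @ EU  # sum_n E[u u^T]

        # M-step per set, preserving the structural zeros
        for m in range(M):
            idx = np.r_[np.arange(d), np.arange(priv[m].start, priv[m].stop)]
            EU_m = EU[:, idx]
            S_m = Suu[np.ix_(idx, idx)]
            cross = Ys[m].T @ EU_m  # P_m x (d + k_m)
            Lam_m = np.linalg.solve(S_m, cross.T).T
            W[m] = Lam_m[:, :d]
            L[m] = Lam_m[:, d:]
            resid = (np.sum(Ys[m]**2, axis=0) - np.sum(Lam_m * cross, axis=1)) / N
            Psi[m] = np.maximum(resid, 1e-4)

    Lam, psi = assemble()
    if EU is None:  # max_iter == 1 edge case
        inv_psi = 1.0 / psi
        B = Lam * inv_psi[:, None]
        Minv = np.linalg.inv(np.eye(q) + Lam.T @ B)
        EU = Y @ B @ Minv
    return MCFAModel(
        d=d, k_list=list(k_list), W=W, L=L, Psi=Psi,
        z_hat=EU[:, :d], x_hat=[EU[:, priv[m]] for m in range(M)],
        loglik_path=np.array(lls), converged=converged,
    )


def variance_report(model: MCFAModel, set_names: list[str] | None = None) -> dict:
    """Shared/private/residual variance percentages per attribute set, plus the
    per-shared-dimension contribution of each set.

    Percentages are relative to the per-set total model variance
    (sum_j sum_d W^2 + sum_k L^2 + psi), which equals P_m on standardized data
    up to EM tolerance; the triple therefore sums to 100 exactly.
    """
    names = set_names or [f"set{m}" for m in range(model.M)]
    report = {"sets": {}, "per_dimension": {}}
    for m, name in enumerate(names):
        shared = float(np.sum(model.W[m] ** 2))
        private = float(np.sum(model.L[m] ** 2))
        residual = float(np.sum(model.Psi[m]))
        total = shared + private + residual
        report["sets"][name] = {
            "shared_pct": 100.0 * shared / total,
            "private_pct": 100.0 * private / total,
            "residual_pct": 100.0 * residual / total,
        }
        report["per_dimension"][name] = (
            100.0 * np.sum(model.W[m] ** 2, axis=0) / total
        ).tolist()
    return report


def feature_importance(model: MCFAModel, Ys: list[np.ndarray],
                       standardize: bool = True) -> np.ndarray:
    """Cross-set agreement S_d of the shared factors.

    For each set, the single-mode posterior mean Z_hat_m = E[z | y_m] is
    computed under that set's marginal model N(0, W W^T + L L^T + Psi); S_d is
    the mean pairwise Pearson correlation of column d across sets (in [-1, 1];
    1 when every set carries the same shared signal).
    """
    Ys = [np.asarray(Y, dtype=float) for Y in Ys]
    if standardize:
        Ys = standardize_sets(Ys)
    Zs = []
    for m in range(model.M):
        Lam = np.hstack([model.W[m], model.L[m]])
        psi = model.Psi[m]
        q = Lam.shape[1]
        inv_psi = 1.0 / psi
        B = Lam * inv_psi[:, None]
        Minv = np.linalg.inv(np.eye(q) + Lam.T @ B)
        # Sigma_m^-1 W = (Psi^-1 - B Minv B^T) W  via Woodbury
        SW = model.W[m] * inv_psi[:, None] - B @ (Minv @ (B.T @ model.W[m]))
        Zs.append(Ys[m] @ SW)
    S = np.empty(model.d)
    for dd in range(model.d):
        cols = [Z[:, dd] for Z in Zs]
        sds = [c.std() for c in cols]
        if any(s == 0 for s in sds):
            S[dd] = np.nan
            continue
        corrs = []
        for a in range(model.M):
            for b in range(a + 1, model.M):
                corrs.append(np.corrcoef(cols[a], cols[b])[0, 1])
        S[dd] = float(np.mean(corrs)) if corrs else np.nan
    return S
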