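"""Structured coupled matrix-tensor factorization (sCMTF) of EEG and fMRI.

The EEG spectrogram tensor ``X`` (time x frequency x channel) is modeled as
a rank-R canonical polyadic decomposition (CPD) with temporal, spectral and
spatial signatures ``S, G, M``.  The BOLD matrix ``Y`` (time x ROI) shares
the temporal signatures through region-specific hemodynamic convolution::

    X ~ sum_r s_r o g_r o m_r
    Y ~ sum_r sum_k (H_k s_r) o (b_k * v_r)  +  N P^T

where ``H_k`` is the Toeplitz convolution operator of the k-th adaptive HRF
basis function, ``b_k`` (column k of B) holds source-independent basis
weights per ROI, ``v_r`` the source amplitudes per ROI (Khatri-Rao
constraint: (R+K)·Iv spatial parameters instead of R·K·Iv) and ``N P^T`` a
rank-Q uncoupled term absorbing structured fMRI-only nuisance.

All free variables (S, G, M, V, B, the HRF parameters theta, N, P) are
estimated by L-BFGS minimization of the regularized cost

    J = beta_x ||X - Xhat||_F^2 + beta_y ||Y - Yhat||_F^2
        + gamma_x ||lambda_x||_1 + gamma_y ||lambda_y||_1

with source amplitudes lambda_x,r = ||s_r|| ||g_r|| ||m_r|| and
lambda_y,r = sum_k ||b_k * v_r||, from multiple restarts initialized by a
CPD of the EEG tensor alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .hrf import (
    HRFBasis,
    HRFParams,
    LagGrid,
    basis_from_thetas,
    default_basis,
    hrf_from_params,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SCMTFConfig",
    "SCMTFSolution",
    "cpd_eeg",
    "cp_tensor",
    "congruence",
    "model_predict",
    "scmtf_cost",
    "fit_scmtf",
    "calibrate",
    "select_ied_component",
    "select_model",
]

# box constraints keeping the double-gamma parameters in a sane regime
THETA_BOUNDS = [(1.05, 30.0), (0.05, 10.0), (1.05, 40.0), (0.05, 10.0), (0.0, 5.0)]


@dataclass
class SCMTFConfig:
    """Hyperparameters of the sCMTF fit.

    Data-fit weights default to ``1/||X||_F^2`` and ``1/||Y||_F^2`` so both
    modalities contribute equally; the l1 weights default to
    ``0.001 * (beta_x ||X||^2 + beta_y ||Y||^2) / R`` — strong enough to
    suppress degenerate components, well below the per-component fit gain
    (an l1 weight of the order of the fMRI fit share would zero out the
    coupled BOLD term entirely).
    """

    R: int = 2
    K: int = 3
    Q: int = 2
    beta_x: float | None = None
    beta_y: float | None = None
    gamma_x: float | None = None
    gamma_y: float | None = None
    n_inits: int = 50
    max_iter: int = 2000
    tol: float = 1e-8
    seed: int | None = None
    t_pre: float = 10.0
    t_post: float = 22.0
    init_sigma: float = 0.1  # relative perturbation of restarts

    def __post_init__(self) -> None:
        if self.R < 1 or self.K < 1 or self.Q < 0:
            raise ValueError("require R >= 1, K >= 1, Q >= 0")
        for w in (self.beta_x, self.beta_y, self.gamma_x, self.gamma_y):
            if w is not None and w < 0:
                raise ValueError("weights must be >= 0")

    def resolve_weights(self, X: np.ndarray, Y: np.ndarray) -> tuple[float, float, float, float]:
        nx2 = float(np.sum(X**2))
        ny2 = float(np.sum(Y**2))
        bx = self.beta_x if self.beta_x is not None else (1.0 / nx2 if nx2 > 0 else 1.0)
        by = self.beta_y if self.beta_y is not None else (1.0 / ny2 if ny2 > 0 else 1.0)
        scale = 0.001 * (bx * nx2 + by * ny2) / self.R
        gx = self.gamma_x if self.gamma_x is not None else scale
        gy = self.gamma_y if self.gamma_y is not None else scale
        return bx, by, gx, gy


@dataclass
class SCMTFSolution:
    """One fitted factor set.

    The model read-out is ``Xhat = sum_r lambda_x[r] s_r o g_r o m_r`` and
    ``Yhat = sum_k (H_k S)(b_k * V)^T + N P^T``.  Solutions straight from the
    optimizer carry ``lambda_x = 1`` with unnormalized factors; ``calibrate``
    moves the amplitudes into ``lambda_x`` and fixes sign conventions without
    changing the model output.
    """

    S: np.ndarray
    G: np.ndarray
    M: np.ndarray
    V: np.ndarray
    B: np.ndarray
    basis: HRFBasis
    N: np.ndarray
    P: np.ndarray
    cost: float
    lambda_x: np.ndarray
    lambda_y: np.ndarray
    converged: bool = True
    calibrated: bool = False

    @property
    def R(self) -> int:
        return self.S.shape[1]

    @property
    def shapes(self) -> tuple[int, int, int, int]:
        return self.S.shape[0], self.G.shape[0], self.M.shape[0], self.V.shape[0]

    def roi_hrfs(self) -> np.ndarray:
        """Per-ROI HRF waveforms (Iv x n_lags)."""
        return self.B @ self.basis.waveforms


# ---------------------------------------------------------------------------
# CPD of the EEG tensor (initialization and EEG-only reduction)
# ---------------------------------------------------------------------------

def cp_tensor(S: np.ndarray, G: np.ndarray, M: np.ndarray,
              weights: np.ndarray | None = None) -> np.ndarray:
    """Compose the rank-R trilinear tensor sum_r w_r s_r o g_r o m_r."""
    if weights is None:
        return np.einsum("ir,jr,kr->ijk", S, G, M, optimize=True)
    return np.einsum("r,ir,jr,kr->ijk", weights, S, G, M, optimize=True)


def _hosvd_init(X: np.ndarray, R: int, rng: np.random.Generator) -> list[np.ndarray]:
    factors = []
    for mode in range(3):
        unf = np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)
        u, _, _ = np.linalg.svd(unf, full_matrices=False)
        f = u[:, :R]
        if f.shape[1] < R:  # rank exceeds mode dimension: pad randomly
            pad = rng.standard_normal((f.shape[0], R - f.shape[1]))
            f = np.hstack([f, pad / np.linalg.norm(pad, axis=0)])
        factors.append(f)
    return factors


def cpd_eeg(
    X: np.ndarray,
    R: int,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-9,
    n_restarts: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-R CPD of the EEG tensor by alternating least squares.

    Initialized from the truncated HOSVD (plus random restarts); iterates
    until the relative fit change drops below ``tol``.  Factors are returned
    unnormalized.  A non-converged best iterate is returned with a log
    warning rather than raising.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a third-order tensor")
    if R > min(X.shape):
        logger.warning("R=%d exceeds the smallest tensor dimension %d", R, min(X.shape))
    rng = np.random.default_rng(seed)
    norm_x = np.linalg.norm(X)
    best, best_err = None, np.inf
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            S, G, M = _hosvd_init(X, R, rng)
        else:
            S, G, M = (rng.standard_normal((d, R)) for d in X.shape)
        prev_err = np.inf
        converged = False
        for _ in range(max_iter):
            # mode-wise normal-equation updates
            S = np.linalg.solve(
                ((G.T @ G) * (M.T @ M)).T,
                np.einsum("ijk,jr,kr->ir", X, G, M, optimize=True).T,
            ).T
            G = np.linalg.solve(
                ((S.T @ S) * (M.T @ M)).T,
                np.einsum("ijk,ir,kr->jr", X, S, M, optimize=True).T,
            ).T
            M = np.linalg.solve(
                ((S.T @ S) * (G.T @ G)).T,
                np.einsum("ijk,ir,jr->kr", X, S, G, optimize=True).T,
            ).T
            err = np.linalg.norm(X - cp_tensor(S, G, M)) / max(norm_x, 1e-300)
            if abs(prev_err - err) < tol * max(prev_err, 1.0):
                converged = True
                break
            prev_err = err
        if not converged:
            # common for over-specified ranks, where ALS crawls; the best
            # iterate is still returned and refined downstream
            logger.info("CPD restart %d not converged (rel. error %.3e)", restart, err)
        if err < best_err:
            best, best_err = (S.copy(), G.copy(), M.copy()), err
        if best_err < 1e-12:
            break
    return best


def congruence(
    factors_a: list[np.ndarray], factors_b: list[np.ndarray]
) -> tuple[float, np.ndarray]:
    """Greedy-matched mean congruence between two factor sets.

    For every component of set ``a`` the product over modes of the absolute
    column cosines against each component of set ``b`` is computed; pairs are
    matched greedily (best first).  Returns (mean matched product, matching).
    """
    R = factors_a[0].shape[1]

    def unit(F):
        n = np.linalg.norm(F, axis=0, keepdims=True)
        return F / np.where(n > 0, n, 1.0)

    prod = np.ones((R, factors_b[0].shape[1]))
    for Fa, Fb in zip(factors_a, factors_b):
        prod *= np.abs(unit(Fa).T @ unit(Fb))
    match = np.full(R, -1)
    used = np.zeros(prod.shape[1], dtype=bool)
    work = prod.copy()
    for _ in range(min(R, prod.shape[1])):
        i, j = np.unravel_index(np.argmax(np.where(used[None, :], -1, work)), work.shape)
        match[i] = j
        used[j] = True
        work[i, :] = -1
    score = float(np.mean([prod[i, match[i]] for i in range(R) if match[i] >= 0]))
    return score, match


# ---------------------------------------------------------------------------
# Model prediction and cost
# ---------------------------------------------------------------------------

def _convolve_sources(waves: np.ndarray, S: np.ndarray, offset: int) -> np.ndarray:
    """Stack H_k S for all k: returns (K, Is, R)."""
    Is = S.shape[0]
    K = waves.shape[0]
    out = np.empty((K, Is, S.shape[1]))
    for k in range(K):
        for r in range(S.shape[1]):
            out[k, :, r] = np.convolve(waves[k], S[:, r])[offset : offset + Is]
    return out


def _adjoint_convolve(wave: np.ndarray, F: np.ndarray, offset: int) -> np.ndarray:
    """Apply H_k^T to every column of F (Is x m)."""
    Is = F.shape[0]
    start = wave.size - 1 - offset
    rev = wave[::-1]
    out = np.empty_like(F)
    for j in range(F.shape[1]):
        out[:, j] = np.convolve(rev, F[:, j])[start : start + Is]
    return out


def model_predict(sol: SCMTFSolution) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct (Xhat, Yhat) from a solution (Eq. form in module docstring)."""
    Xhat = cp_tensor(sol.S, sol.G, sol.M, sol.lambda_x)
    Is = sol.S.shape[0]
    Z = _convolve_sources(sol.basis.waveforms, sol.S, sol.basis.grid.n_pre)
    Yhat = np.zeros((Is, sol.V.shape[0]))
    for k in range(sol.basis.K):
        Yhat += Z[k] @ (sol.B[:, k : k + 1] * sol.V).T
    if sol.N.size and sol.P.size:
        Yhat += sol.N @ sol.P.T
    return Xhat, Yhat


def _lambdas(sol: SCMTFSolution) -> tuple[np.ndarray, np.ndarray]:
    lx = sol.lambda_x * (
        np.linalg.norm(sol.S, axis=0)
        * np.linalg.norm(sol.G, axis=0)
        * np.linalg.norm(sol.M, axis=0)
    )
    ly = np.zeros(sol.R)
    for r in range(sol.R):
        ly[r] = sum(
            np.linalg.norm(sol.B[:, k] * sol.V[:, r]) for k in range(sol.B.shape[1])
        )
    return lx, ly


def scmtf_cost(
    sol: SCMTFSolution, X: np.ndarray, Y: np.ndarray, config: SCMTFConfig
) -> float:
    """Evaluate the regularized cost J for a solution on data (X, Y)."""
    bx, by, gx, gy = config.resolve_weights(X, Y)
    Xhat, Yhat = model_predict(sol)
    lx, ly = _lambdas(sol)
    return float(
        bx * np.sum((X - Xhat) ** 2)
        + by * np.sum((Y - Yhat) ** 2)
        + gx * np.sum(np.abs(lx))
        + gy * np.sum(np.abs(ly))
    )


# ---------------------------------------------------------------------------
# Joint optimization
# ---------------------------------------------------------------------------

class _Packer:
    """Flatten/unflatten the free variables for L-BFGS."""

    def __init__(self, Is, Ig, Im, Iv, R, K, Q):
        self.shapes = {
            "S": (Is, R), "G": (Ig, R), "M": (Im, R),
            "V": (Iv, R), "B": (Iv, K),
            "N": (Is, Q), "P": (Iv, Q),
            "theta": (K, 5),
        }
        self.slices = {}
        start = 0
        for name, shp in self.shapes.items():
            size = int(np.prod(shp))
            self.slices[name] = slice(start, start + size)
            start += size
        self.size = start

    def pack(self, **arrays) -> np.ndarray:
        z = np.empty(self.size)
        for name, shp in self.shapes.items():
            z[self.slices[name]] = np.asarray(arrays[name]).reshape(-1)
        return z

    def unpack(self, z: np.ndarray) -> dict[str, np.ndarray]:
        return {
            name: z[self.slices[name]].reshape(shp)
            for name, shp in self.shapes.items()
        }


def _make_objective(X, Y, config: SCMTFConfig, grid: LagGrid, packer: _Packer):
    bx, by, gx, gy = config.resolve_weights(X, Y)
    offset = grid.n_pre
    K = packer.shapes["theta"][0]
    eps = 1e-12

    def waveform(theta_row):
        return hrf_from_params(HRFParams(tuple(theta_row)), grid)

    def objective(z):
        v = packer.unpack(z)
        S, G, M, V, B, N, P, theta = (
            v["S"], v["G"], v["M"], v["V"], v["B"], v["N"], v["P"], v["theta"]
        )
        waves = np.stack([waveform(theta[k]) for k in range(K)])
        Z = _convolve_sources(waves, S, offset)
        W = [B[:, k : k + 1] * V for k in range(K)]
        Yc = np.zeros_like(Y)
        for k in range(K):
            Yc += Z[k] @ W[k].T
        NP = N @ P.T if N.size else 0.0
        F = Y - Yc - NP
        E = X - cp_tensor(S, G, M)

        ns = np.linalg.norm(S, axis=0)
        ng = np.linalg.norm(G, axis=0)
        nm = np.linalg.norm(M, axis=0)
        lam_x = ns * ng * nm
        bv_norms = np.stack(
            [np.linalg.norm(W[k], axis=0) for k in range(K)]
        )  # K x R
        J = (
            bx * np.sum(E**2)
            + by * np.sum(F**2)
            + gx * np.sum(lam_x)
            + gy * np.sum(bv_norms)
        )

        # --- gradients -----------------------------------------------------
        dS = -2.0 * bx * np.einsum("ijk,jr,kr->ir", E, G, M, optimize=True)
        dG = -2.0 * bx * np.einsum("ijk,ir,kr->jr", E, S, M, optimize=True)
        dM = -2.0 * bx * np.einsum("ijk,ir,jr->kr", E, S, G, optimize=True)
        for k in range(K):
            dS += -2.0 * by * _adjoint_convolve(waves[k], F @ W[k], offset)
        # l1 terms on lambda_x
        dS += gx * (ng * nm / np.maximum(ns, eps)) * S
        dG += gx * (ns * nm / np.maximum(ng, eps)) * G
        dM += gx * (ns * ng / np.maximum(nm, eps)) * M

        dV = np.zeros_like(V)
        dB = np.zeros_like(B)
        for k in range(K):
            dWk = -2.0 * by * (F.T @ Z[k])  # Iv x R
            dV += dWk * B[:, k : k + 1]
            dB[:, k] = np.sum(dWk * V, axis=1)
            # l1 on lambda_y
            denom = np.maximum(bv_norms[k], eps)
            dV += gy * (B[:, k : k + 1] ** 2) * V / denom
            dB[:, k] += gy * np.sum((V**2) * B[:, k : k + 1] / denom, axis=1)

        dN = -2.0 * by * (F @ P) if N.size else np.zeros_like(N)
        dP = -2.0 * by * (F.T @ N) if P.size else np.zeros_like(P)

        # theta gradient: central finite differences on the Y-fit term
        dtheta = np.zeros_like(theta)
        for k in range(K):
            F_rest = F + Z[k] @ W[k].T  # Y - NP - other components
            for j in range(5):
                h = 1e-4 * max(abs(theta[k, j]), 1.0)
                tplus = theta[k].copy(); tplus[j] += h
                tminus = theta[k].copy(); tminus[j] = max(tminus[j] - h, 1e-6)
                hh = tplus[j] - tminus[j]
                Jp = np.sum((F_rest - _convolve_sources(
                    waveform(tplus)[None], S, offset)[0] @ W[k].T) ** 2)
                Jm = np.sum((F_rest - _convolve_sources(
                    waveform(tminus)[None], S, offset)[0] @ W[k].T) ** 2)
                dtheta[k, j] = by * (Jp - Jm) / hh
        grad = packer.pack(S=dS, G=dG, M=dM, V=dV, B=dB, N=dN, P=dP, theta=dtheta)
        return J, grad

    return objective


def _init_restart(
    X, Y, config: SCMTFConfig, grid: LagGrid, cpd_factors, theta0, rng, perturb: bool
):
    """Initial values for one restart: CPD-shared S,G,M; LS-based V,B; SVD N,P."""
    S, G, M = (f.copy() for f in cpd_factors)
    K, R, Q = config.K, config.R, config.Q
    Iv = Y.shape[1]
    sigma = config.init_sigma

    theta = np.array(theta0, dtype=float)
    if perturb:
        theta = theta * (1.0 + sigma * rng.standard_normal(theta.shape))
        # spread the latencies of the non-canonical basis functions across
        # the whole lag support (incl. the acausal range): L-BFGS adjusts
        # HRF shapes locally but rarely moves a gamma mode by many seconds
        span = (grid.n_lags - 1) * grid.dt
        for k in range(1, K):
            mode = rng.uniform(0.0, span)
            theta[k, 0] = 1.0 + mode * theta[k, 1]
    theta = np.clip(theta, [b[0] for b in THETA_BOUNDS], [b[1] for b in THETA_BOUNDS])

    waves = np.stack(
        [hrf_from_params(HRFParams(tuple(theta[k])), grid) for k in range(K)]
    )
    Z = _convolve_sources(waves, S, grid.n_pre)
    B = np.zeros((Iv, K))
    B[:, 0] = 1.0
    if K > 1:
        B[:, 1:] = 0.1
    if perturb:
        B += sigma * rng.standard_normal(B.shape)
    # alternating per-ROI least squares: V given B, then B given V, then V
    V = np.zeros((Iv, R))
    for _ in range(2):
        for iv in range(Iv):
            D = np.einsum("k,kir->ir", B[iv], Z)
            V[iv], *_ = np.linalg.lstsq(D, Y[:, iv], rcond=None)
        for iv in range(Iv):
            D = np.stack([Z[k] @ V[iv] for k in range(K)], axis=1)
            b_iv, *_ = np.linalg.lstsq(D, Y[:, iv], rcond=None)
            if np.all(np.isfinite(b_iv)) and np.any(b_iv):
                B[iv] = b_iv
    for iv in range(Iv):
        D = np.einsum("k,kir->ir", B[iv], Z)
        V[iv], *_ = np.linalg.lstsq(D, Y[:, iv], rcond=None)
    if perturb:
        V *= 1.0 + sigma * rng.standard_normal(V.shape)
    Yc = np.zeros_like(Y)
    for k in range(K):
        Yc += Z[k] @ (B[:, k : k + 1] * V).T
    resid = Y - Yc
    if Q > 0:
        u, s, vt = np.linalg.svd(resid, full_matrices=False)
        N = u[:, :Q] * s[:Q]
        P = vt[:Q].T
        if perturb:
            N *= 1.0 + sigma * rng.standard_normal(N.shape)
            P *= 1.0 + sigma * rng.standard_normal(P.shape)
    else:
        N = np.zeros((Y.shape[0], 0))
        P = np.zeros((Iv, 0))
    return dict(S=S, G=G, M=M, V=V, B=B, N=N, P=P, theta=theta)


def _rebalance(v: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Renormalize along the cost-invariant scale manifolds.

    The cost is exactly invariant under (i) the CP scale split between
    s_r, g_r, m_r (with v_r compensating the temporal scale), (ii) a global
    exchange B -> B/c, V -> cV, and (iii) N -> cN, P -> P/c.  Left alone,
    quasi-Newton steps drift along these flat directions until one block
    collapses and the l1 kinks destroy conditioning; rebalancing between
    optimizer cycles restores it without changing the model output.
    """
    S, G, M, V, B, N, P = (
        v["S"].copy(), v["G"].copy(), v["M"].copy(), v["V"].copy(),
        v["B"].copy(), v["N"].copy(), v["P"].copy(),
    )
    eps = 1e-300
    for r in range(S.shape[1]):
        ns, ng, nm = (np.linalg.norm(A[:, r]) for A in (S, G, M))
        lam = ns * ng * nm
        if lam < eps:
            continue
        target = lam ** (1.0 / 3.0)
        S[:, r] *= target / ns
        V[:, r] *= ns / target  # keep the coupled fMRI term unchanged
        G[:, r] *= target / ng
        M[:, r] *= target / nm
    nb, nv = np.linalg.norm(B), np.linalg.norm(V)
    if nb > eps and nv > eps:
        c = np.sqrt(nv / nb)
        B *= c
        V /= c
    if N.size and P.size:
        nn, npn = np.linalg.norm(N), np.linalg.norm(P)
        if nn > eps and npn > eps:
            c = np.sqrt(npn / nn)
            N *= c
            P /= c
    return dict(S=S, G=G, M=M, V=V, B=B, N=N, P=P, theta=v["theta"].copy())


def fit_scmtf(
    X,
    Y,
    config: SCMTFConfig | None = None,
    s_ref: np.ndarray | None = None,
    tr: float | None = None,
) -> list[SCMTFSolution]:
    """Fit the sCMTF from multiple initializations; solutions sorted by cost.

    ``X`` / ``Y`` may be raw arrays or the SpectrogramTensor / BOLDMatrix
    containers (``tr`` is then taken from the container).  Each restart runs
    cycles of L-BFGS over all free variables, with exact rebalancing of the
    scale-ambiguous blocks between cycles, until the relative cost change
    falls below ``config.tol`` or ``config.max_iter`` total iterations.
    Restarts that diverge are discarded with a log entry.
    """
    config = config or SCMTFConfig()
    if hasattr(X, "values"):
        tr = tr or X.tr
        X = X.values
    if hasattr(Y, "values"):
        tr = tr or Y.tr
        Y = Y.values
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"EEG tensor ({X.shape[0]} TRs) and BOLD matrix ({Y.shape[0]} TRs) "
            "are not time-aligned"
        )
    if tr is None:
        raise ValueError("tr (repetition time, s) is required")
    Is, Ig, Im = X.shape
    Iv = Y.shape[1]
    R, K, Q = config.R, config.K, config.Q
    grid = LagGrid(config.t_pre, config.t_post, tr)
    rng = np.random.default_rng(config.seed)

    cpd_factors = cpd_eeg(X, R, seed=int(rng.integers(2**31)))
    theta0 = np.array([p.theta for p in default_basis(grid, K).params])
    packer = _Packer(Is, Ig, Im, Iv, R, K, Q)
    objective = _make_objective(X, Y, config, grid, packer)

    bounds = [(None, None)] * packer.slices["theta"].start
    bounds += THETA_BOUNDS * K

    solutions = []
    for init in range(config.n_inits):
        start = _init_restart(
            X, Y, config, grid, cpd_factors, theta0, rng, perturb=init > 0
        )
        z = packer.pack(**start)
        prev_cost = np.inf
        budget = config.max_iter
        failed = False
        success = False
        try:
            while budget > 0:
                res = optimize.minimize(
                    objective,
                    z,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={
                        "maxiter": min(300, budget),
                        "ftol": config.tol,
                        "gtol": 1e-12,
                        "maxcor": 20,
                    },
                )
                budget -= max(res.nit, 1)
                z = packer.pack(**_rebalance(packer.unpack(res.x)))
                if not np.isfinite(res.fun):
                    failed = True
                    break
                if prev_cost - res.fun < config.tol * max(abs(res.fun), 1.0):
                    success = True
                    break
                prev_cost = res.fun
        except (FloatingPointError, np.linalg.LinAlgError) as err:
            logger.warning("restart %d discarded (%s)", init, err)
            continue
        if failed:
            logger.warning("restart %d discarded (non-finite cost)", init)
            continue
        res_fun, res_x = float(res.fun), z
        v = packer.unpack(res_x)
        basis = basis_from_thetas([tuple(t) for t in v["theta"]], grid)
        sol = SCMTFSolution(
            S=v["S"], G=v["G"], M=v["M"], V=v["V"], B=v["B"], basis=basis,
            N=v["N"], P=v["P"], cost=res_fun,
            lambda_x=np.ones(R), lambda_y=np.zeros(R),
            converged=success,
        )
        sol.lambda_y = _lambdas(sol)[1]
        lam = _lambdas(sol)[0]
        if lam.max() > 0 and np.any(lam < 1e-6 * lam.max()):
            logger.warning("restart %d produced a near-degenerate component", init)
        solutions.append(sol)
        logger.info("restart %d: J=%.6g converged=%s", init, res.fun, sol.converged)
    if not solutions:
        raise RuntimeError("all sCMTF restarts failed")
    solutions.sort(key=lambda s: s.cost)
    return solutions


# ---------------------------------------------------------------------------
# Calibration and selection
# ---------------------------------------------------------------------------

def calibrate(sol: SCMTFSolution) -> SCMTFSolution:
    """Resolve scale and sign ambiguities without changing the model output.

    Columns of S, G, M become unit-norm with amplitudes moved to lambda_x;
    the compensating temporal scale goes into V so Yhat is unchanged.  Signs:
    g_r and m_r have their largest-magnitude entry positive (flips pushed to
    s_r, and mirrored in v_r); each ROI HRF's main lobe is positive (flips
    shared between the B row and the V row); basis waveforms are unit-norm
    with scales absorbed into B.  Idempotent.
    """
    S, G, M = sol.S.copy(), sol.G.copy(), sol.M.copy()
    V, B = sol.V.copy(), sol.B.copy()
    lam_x = sol.lambda_x.copy().astype(float)

    basis, scales = sol.basis.normalized()
    B *= scales[None, :]

    hrfs = B @ basis.waveforms
    for iv in range(B.shape[0]):
        w = hrfs[iv]
        if w.any() and w[np.argmax(np.abs(w))] < 0:
            B[iv] *= -1.0
            V[iv] *= -1.0

    eps = 1e-300
    for r in range(S.shape[1]):
        ns = np.linalg.norm(S[:, r])
        ng = np.linalg.norm(G[:, r])
        nm = np.linalg.norm(M[:, r])
        lam_x[r] *= ns * ng * nm
        if ns > eps:
            S[:, r] /= ns
            V[:, r] *= ns
        if ng > eps:
            G[:, r] /= ng
        if nm > eps:
            M[:, r] /= nm
        sg = np.sign(G[np.argmax(np.abs(G[:, r])), r]) or 1.0
        sm = np.sign(M[np.argmax(np.abs(M[:, r])), r]) or 1.0
        G[:, r] *= sg
        M[:, r] *= sm
        S[:, r] *= sg * sm
        V[:, r] *= sg * sm

    out = replace(
        sol, S=S, G=G, M=M, V=V, B=B, basis=basis,
        lambda_x=lam_x, calibrated=True,
    )
    out.lambda_y = _lambdas(out)[1]
    return out


def select_ied_component(
    sol: SCMTFSolution, s_ref: np.ndarray
) -> tuple[int, float]:
    """Pick the source whose temporal signature best tracks the IED envelope.

    Returns (index, Pearson correlation); ties break to the lowest index.
    """
    s_ref = np.asarray(s_ref, dtype=float)
    if s_ref.shape[0] != sol.S.shape[0]:
        raise ValueError("reference envelope length must equal Is")
    if s_ref.std() == 0:
        raise ValueError("reference envelope is constant")
    ref = (s_ref - s_ref.mean()) / s_ref.std()
    corrs = np.zeros(sol.R)
    for r in range(sol.R):
        s = sol.S[:, r]
        if s.std() > 0:
            corrs[r] = float(np.mean(ref * (s - s.mean()) / s.std()))
    best = int(np.argmax(corrs))
    if np.sum(np.isclose(corrs, corrs[best])) > 1:
        logger.info("IED component tie at correlation %.4f; lowest index kept", corrs[best])
    return best, float(corrs[best])


def select_model(
    solutions_by_rank: dict[int, list[SCMTFSolution]],
    s_ref: np.ndarray,
    X: np.ndarray | None = None,
    Y: np.ndarray | None = None,
    stability_threshold: float = 0.9,
    relevance_threshold: float = 0.3,
    plateau_threshold: float = 0.3,
    n_top: int = 5,
) -> tuple[int, SCMTFSolution, list[dict]]:
    """Choose the number of sources R from candidate fits.

    Per rank the score table holds: stability (mean pairwise factor
    congruence among the ``n_top`` lowest-cost restarts), relevance (best
    IED-envelope correlation among those restarts) and parsimony (the
    relative cost gain obtained by moving to the next candidate rank; a
    rank sitting before the fit elbow, i.e. with gain above
    ``plateau_threshold``, is not parsimonious because more sources are
    still clearly needed).  The smallest R with stability >= 0.9,
    relevance >= 0.3 and next-rank gain below the plateau threshold wins;
    if none qualifies, the R with maximal relevance.
    """
    if not solutions_by_rank:
        raise ValueError("no candidate solutions")
    table = []
    for R in sorted(solutions_by_rank):
        sols = sorted(solutions_by_rank[R], key=lambda s: s.cost)[:n_top]
        if not sols:
            continue
        # score in canonical form: the sign conventions matter for the
        # (signed) IED-envelope correlation
        sols = [s if s.calibrated else calibrate(s) for s in sols]
        if len(sols) == 1:
            stability = 1.0
        else:
            pairs = []
            for i in range(len(sols)):
                for j in range(i + 1, len(sols)):
                    c, _ = congruence(
                        [sols[i].S, sols[i].G, sols[i].M],
                        [sols[j].S, sols[j].G, sols[j].M],
                    )
                    pairs.append(c)
            stability = float(np.mean(pairs))
        relevance = max(select_ied_component(s, s_ref)[1] for s in sols)
        table.append(
            {
                "R": R,
                "stability": stability,
                "relevance": relevance,
                "best_cost": sols[0].cost,
                "n_solutions": len(solutions_by_rank[R]),
            }
        )
    for i, row in enumerate(table):
        if i + 1 < len(table):
            row["next_gain"] = (
                (row["best_cost"] - table[i + 1]["best_cost"])
                / max(row["best_cost"], 1e-300)
            )
        else:
            row["next_gain"] = 0.0  # largest candidate: no further gain known
    qualified = [
        row for row in table
        if row["stability"] >= stability_threshold
        and row["relevance"] >= relevance_threshold
        and row["next_gain"] < plateau_threshold
    ]
    chosen = min(qualified, key=lambda r: r["R"]) if qualified else max(
        table, key=lambda r: r["relevance"]
    )
    R_hat = chosen["R"]
    best = min(solutions_by_rank[R_hat], key=lambda s: s.cost)
    for row in table:
        row["selected"] = row["R"] == R_hat
    return R_hat, best, table
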