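"""Hemodynamic response model: double-gamma waveforms and Toeplitz convolution.

Each HRF basis function is a difference of two gamma densities controlled by
five parameters ``theta = (a1, b1, a2, b2, c)``::

    f(t) = Gamma(a1)^-1 b1^a1 t^(a1-1) exp(-b1 t)
         - c * Gamma(a2)^-1 b2^a2 t^(a2-1) exp(-b2 t)

sampled on a lag grid that extends ``t_pre`` seconds *before* the neural
event (acausal support, to allow BOLD changes that precede the EEG correlate)
and ``t_post`` seconds after.  The argument ``t`` of the gamma terms runs
from the start of the grid, so waveforms may peak at negative lags; the
mapping from grid position to lag is carried by the Toeplitz operator's
``offset``.

Convolution of a TR-sampled source time course with an HRF is a banded
Toeplitz matrix multiplication; ``ToeplitzOp`` implements it matrix-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "HRFParams",
    "LagGrid",
    "HRFBasis",
    "ToeplitzOp",
    "hrf_from_params",
    "toeplitz_apply",
    "toeplitz_apply_adjoint",
    "toeplitz_matrix",
    "roi_hrf",
    "default_basis",
    "CANONICAL_THETA",
    "DELAYED_THETA",
    "DISPERSED_THETA",
]

# initial parameter sets for a K=3 basis: canonical, delayed, dispersed
CANONICAL_THETA = (6.0, 1.0, 16.0, 1.0, 1.0 / 6.0)
DELAYED_THETA = (8.0, 1.0, 16.0, 1.0, 1.0 / 6.0)
DISPERSED_THETA = (6.0, 0.8, 16.0, 1.0, 1.0 / 6.0)


@dataclass(frozen=True)
class HRFParams:
    """Five parameters of a double-gamma HRF waveform."""

    theta: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.theta, dtype=float)
        if t.shape != (5,):
            raise ValueError("theta must have exactly 5 entries")
        if np.any(t[:4] <= 0):
            raise ValueError("shape/rate parameters theta[0:4] must be > 0")
        if t[4] < 0:
            raise ValueError("undershoot ratio theta[4] must be >= 0")
        if not np.all(np.isfinite(t)):
            raise ValueError("theta must be finite")


@dataclass(frozen=True)
class LagGrid:
    """Sampling grid for HRF waveforms: lags in [-t_pre, t_post], step dt (s)."""

    t_pre: float = 10.0
    t_post: float = 22.0
    dt: float = 2.2

    def __post_init__(self) -> None:
        if self.t_pre < 0 or self.t_post < 0:
            raise ValueError("t_pre and t_post must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n_pre(self) -> int:
        return int(round(self.t_pre / self.dt))

    @property
    def n_post(self) -> int:
        return int(round(self.t_post / self.dt))

    @property
    def n_lags(self) -> int:
        return self.n_pre + self.n_post + 1

    @property
    def lags(self) -> np.ndarray:
        """Lag (s) of every grid sample; negative lags are acausal."""
        return (np.arange(self.n_lags) - self.n_pre) * self.dt


def _gamma_density(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """Gamma density with shape a, rate b; zero for t <= 0."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        a * np.log(b) + (a - 1.0) * np.log(tp) - b * tp - special.gammaln(a)
    )
    return out


def hrf_from_params(params: HRFParams, grid: LagGrid) -> np.ndarray:
    """Sample the double-gamma waveform f(t; theta) on ``grid``.

    ``t`` is measured from the grid origin (the most acausal sample), so the
    main lobe lands at lag ``mode - t_pre``; t <= 0 evaluates to zero.
    """
    a1, b1, a2, b2, c = params.theta
    t = np.arange(grid.n_lags, dtype=float) * grid.dt
    w = _gamma_density(t, a1, b1) - c * _gamma_density(t, a2, b2)
    if not np.all(np.isfinite(w)):
        raise ValueError("HRF waveform is not finite for the given parameters")
    return w


@dataclass(frozen=True)
class ToeplitzOp:
    """Banded Toeplitz convolution operator.

    ``apply`` computes the full discrete convolution of ``kernel`` with the
    input, advanced by ``offset`` samples and truncated to ``length``
    entries.  ``offset`` equals the number of acausal kernel samples, so
    kernel sample ``j`` acts at lag ``j - offset``.
    """

    kernel: np.ndarray
    offset: int
    length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernel", np.asarray(self.kernel, dtype=float))
        if self.kernel.ndim != 1:
            raise ValueError("kernel must be 1-D")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not (0 <= self.offset < self.kernel.size + self.length):
            raise ValueError("offset out of range for kernel/length")


def toeplitz_apply(op: ToeplitzOp, s: np.ndarray) -> np.ndarray:
    """Apply the Toeplitz operator to a series (or to each column of a matrix)."""
    s = np.asarray(s, dtype=float)
    if s.shape[0] != op.length:
        raise ValueError(f"series length {s.shape[0]} != operator length {op.length}")
    if s.ndim == 1:
        full = np.convolve(op.kernel, s)
        return full[op.offset : op.offset + op.length]
    out = np.empty_like(s)
    for j in range(s.shape[1]):
        out[:, j] = toeplitz_apply(op, s[:, j])
    return out


def toeplitz_apply_adjoint(op: ToeplitzOp, f: np.ndarray) -> np.ndarray:
    """Apply the transpose of the materialized Toeplitz matrix (correlation)."""
    f = np.asarray(f, dtype=float)
    if f.shape[0] != op.length:
        raise ValueError("input length mismatch")
    # (H^T f)[t] = sum_j kernel[j] * f[t + j - offset]
    if f.ndim == 1:
        full = np.convolve(op.kernel[::-1], f)
        start = op.kernel.size - 1 - op.offset
        return full[start : start + op.length]
    out = np.empty_like(f)
    for j in range(f.shape[1]):
        out[:, j] = toeplitz_apply_adjoint(op, f[:, j])
    return out


def toeplitz_matrix(op: ToeplitzOp) -> np.ndarray:
    """Materialize the operator as a dense (length x length) matrix."""
    H = np.zeros((op.length, op.length))
    for i in range(op.length):
        for t in range(op.length):
            j = i - t + op.offset
            if 0 <= j < op.kernel.size:
                H[i, t] = op.kernel[j]
    return H


@dataclass
class HRFBasis:
    """K HRF basis waveforms sampled on a shared lag grid."""

    waveforms: np.ndarray  # K x n_lags
    params: list[HRFParams]
    grid: LagGrid
    _ops: list[ToeplitzOp] | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return self.waveforms.shape[0]

    def operators(self, length: int) -> list[ToeplitzOp]:
        """Toeplitz operators H_k for series of the given length (cached)."""
        if self._ops is None or self._ops[0].length != length:
            self._ops = [
                ToeplitzOp(self.waveforms[k], self.grid.n_pre, length)
                for k in range(self.K)
            ]
        return self._ops

    def normalized(self) -> tuple["HRFBasis", np.ndarray]:
        """Unit-norm copy; returns (basis, scales) with scales[k] = ||h_k||."""
        scales = np.linalg.norm(self.waveforms, axis=1)
        safe = np.where(scales > 0, scales, 1.0)
        return (
            HRFBasis(self.waveforms / safe[:, None], list(self.params), self.grid),
            scales,
        )


def basis_from_thetas(thetas: list[tuple[float, ...]], grid: LagGrid) -> HRFBasis:
    params = [HRFParams(tuple(t)) for t in thetas]
    waves = np.stack([hrf_from_params(p, grid) for p in params])
    return HRFBasis(waves, params, grid)


def default_basis(grid: LagGrid, K: int = 3) -> HRFBasis:
    """Default initialization basis: canonical, delayed, dispersed shapes.

    The nominal parameter sets describe gamma terms whose argument starts at
    the neural event; on a grid with acausal support the origin sits
    ``n_pre * dt`` seconds earlier, so both gamma shapes are translated by
    that much (``a -> a + t_pre_eff * b`` shifts a gamma mode by t_pre_eff
    while approximately preserving its width).  The initial waveforms thus
    peak at their usual causal latencies; the optimizer is free to move them
    into the acausal range.
    """
    thetas = [CANONICAL_THETA, DELAYED_THETA, DISPERSED_THETA][:K]
    while len(thetas) < K:  # extra functions: progressively more delayed
        base = list(CANONICAL_THETA)
        base[0] += 2.0 * (len(thetas) - 2)
        thetas.append(tuple(base))
    shift = grid.n_pre * grid.dt
    shifted = [
        (a1 + shift * b1, b1, a2 + shift * b2, b2, c)
        for a1, b1, a2, b2, c in thetas
    ]
    return basis_from_thetas(shifted, grid)


def roi_hrf(basis: HRFBasis, b_iv: np.ndarray) -> np.ndarray:
    """Compose a single ROI's HRF waveform from basis coefficients."""
    b_iv = np.asarray(b_iv, dtype=float)
    if b_iv.shape != (basis.K,):
        raise ValueError(f"expected {basis.K} coefficients, got {b_iv.shape}")
    if not np.all(np.isfinite(b_iv)):
        raise ValueError("coefficients must be finite")
    return b_iv @ basis.waveforms


def export_basis(basis: HRFBasis, tsv_path, json_path=None) -> None:
    """Write basis waveforms as TSV (lag column + one column per waveform)
    and, optionally, the theta parameter sets as JSON."""
    import json
    from pathlib import Path

    header = "lag_s\t" + "\t".join(f"h{k + 1}" for k in range(basis.K))
    table = np.column_stack([basis.grid.lags, basis.waveforms.T])
    np.savetxt(tsv_path, table, delimiter="\t", header=header, comments="")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([list(p.theta) for p in basis.params], indent=2)
        )


def export_roi_hrfs(B: np.ndarray, basis: HRFBasis, tsv_path) -> None:
    """Write per-ROI HRF waveforms (one column per ROI) as TSV."""
    hrfs = np.asarray(B) @ basis.waveforms
    header = "lag_s\t" + "\t".join(f"roi{i}" for i in range(hrfs.shape[0]))
    np.savetxt(
        tsv_path,
        np.column_stack([basis.grid.lags, hrfs.T]),
        delimiter="\t",
        header=header,
        comments="",
    )
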