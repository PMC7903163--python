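"""Multi-channel Wiener filter (MWF) enhancement of interictal discharges.

The filter is trained on annotated IED segments: with ``Rxx`` the covariance
of the time-delay-embedded EEG during IEDs and ``Rnn`` outside them, the
SNR-optimal filter is ``W = Rxx^-1 (Rxx - Rnn)``.  It is computed through a
generalized eigenvalue decomposition of ``(Rxx, Rnn)`` and truncated to the
generalized eigenvalues > 1, which enforces positive semidefiniteness of the
estimated IED covariance ``Rxx - Rnn``.

The module also derives the per-TR broadband power envelope of the filtered
EEG, used downstream as the reference time course for identifying the
IED-related source.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "EmbeddedEEG",
    "WienerFilter",
    "delay_embed",
    "estimate_mwf",
    "apply_mwf",
    "center_block",
    "broadband_envelope",
]


@dataclass
class EEGRecording:
    """Multichannel EEG with IED annotations.

    signals : channels x samples, each channel standardized to unit std
    ied_mask : per-sample boolean, True inside annotated IED segments
    """

    signals: np.ndarray
    fs: float
    channel_labels: list[str] | None = None
    ied_mask: np.ndarray | None = None
    tr: float | None = None

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.ied_mask is not None:
            self.ied_mask = np.asarray(self.ied_mask, dtype=bool)
            if self.ied_mask.shape != (self.signals.shape[1],):
                raise ValueError("ied_mask length must equal number of samples")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i}" for i in range(self.signals.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def standardized(self) -> "EEGRecording":
        """Copy with each channel divided by its standard deviation."""
        std = self.signals.std(axis=1, keepdims=True)
        std[std == 0] = 1.0
        return EEGRecording(
            self.signals / std, self.fs, list(self.channel_labels),
            None if self.ied_mask is None else self.ied_mask.copy(), self.tr,
        )


@dataclass
class EmbeddedEEG:
    """Time-delay-embedded EEG: lags -tau..+tau of each channel stacked."""

    signals: np.ndarray  # (Im*(2 tau + 1)) x samples
    tau: int
    n_channels: int
    ied_mask: np.ndarray | None = None

    @property
    def valid(self) -> slice:
        """Interior samples where no lag runs off the array."""
        n = self.signals.shape[1]
        return slice(self.tau, n - self.tau if self.tau else n)


@dataclass
class WienerFilter:
    """Spatiotemporal MWF weights (embedded dim x embedded dim)."""

    weights: np.ndarray
    tau: int
    gevd_rank: int
    eigenvalues: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("filter weights must be finite")
        if self.gevd_rank > self.weights.shape[0]:
            raise ValueError("rank cannot exceed embedded dimension")


def delay_embed(rec: EEGRecording, tau: int) -> EmbeddedEEG:
    """Stack lagged copies x[t - tau] ... x[t] ... x[t + tau] of every channel.

    Rows are ordered lag by lag (most negative first), channels contiguous
    within each lag.  Boundary samples are zero-padded; covariance estimation
    later excludes them via ``EmbeddedEEG.valid``.
    """
    if tau < 0 or int(tau) != tau:
        raise ValueError("tau must be a nonnegative integer")
    tau = int(tau)
    x = rec.signals
    im, n = x.shape
    if n <= 2 * tau:
        raise ValueError(f"tau={tau} leaves no valid interior samples (n={n})")
    rows = np.zeros((im * (2 * tau + 1), n))
    for i, lag in enumerate(range(-tau, tau + 1)):
        block = rows[i * im : (i + 1) * im]
        if lag < 0:
            block[:, -lag:] = x[:, :lag]
        elif lag > 0:
            block[:, :-lag] = x[:, lag:]
        else:
            block[:] = x
    return EmbeddedEEG(rows, tau, im, None if rec.ied_mask is None else rec.ied_mask)


def _covariance(x: np.ndarray, shrinkage: float) -> np.ndarray:
    c = (x @ x.T) / x.shape[1]
    c += shrinkage * (np.trace(c) / c.shape[0]) * np.eye(c.shape[0])
    return c


def estimate_mwf(
    emb: EmbeddedEEG,
    ied_mask: np.ndarray | None = None,
    shrinkage: float = 1e-6,
) -> WienerFilter:
    """Estimate the MWF via GEVD of (Rxx, Rnn).

    Rxx is the embedded-signal covariance during IED segments, Rnn outside
    them.  With the generalized eigenpairs ``Rxx u = d Rnn u`` the filter is
    ``W = U diag(max(1 - 1/d, 0)) U^-1``, keeping only directions with
    ``d > 1`` (positive IED power after background subtraction).
    """
    if not (0 <= shrinkage <= 1):
        raise ValueError("shrinkage must lie in [0, 1]")
    mask = emb.ied_mask if ied_mask is None else np.asarray(ied_mask, dtype=bool)
    if mask is None:
        raise ValueError("an IED mask is required to estimate the MWF")
    if mask.shape != (emb.signals.shape[1],):
        raise ValueError("mask length must equal number of samples")
    valid = np.zeros_like(mask)
    valid[emb.valid] = True
    x_ied = emb.signals[:, mask & valid]
    x_bkg = emb.signals[:, (~mask) & valid]
    dim = emb.signals.shape[0]
    if x_ied.shape[1] < dim:
        raise ValueError(
            f"only {x_ied.shape[1]} IED samples for a {dim}-dim covariance; "
            "annotate more IED segments or reduce tau"
        )
    if x_bkg.shape[1] < dim:
        raise ValueError(
            f"only {x_bkg.shape[1]} background samples for a {dim}-dim covariance"
        )
    rxx = _covariance(x_ied, shrinkage)
    rnn = _covariance(x_bkg, shrinkage)
    try:
        d, u = linalg.eigh(rxx, rnn)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "GEVD failed: background covariance is singular; increase the "
            "shrinkage parameter or record more background EEG"
        ) from err
    order = np.argsort(d)[::-1]
    d, u = d[order], u[:, order]
    gains = np.where(d > 1.0, 1.0 - 1.0 / np.maximum(d, 1e-300), 0.0)
    rank = int(np.sum(d > 1.0))
    # U^-1 = U^T Rnn because U^T Rnn U = I
    weights = u @ (gains[:, None] * (u.T @ rnn))
    logger.info("MWF estimated: embedded dim %d, GEVD rank %d", dim, rank)
    return WienerFilter(weights, emb.tau, rank, eigenvalues=d)


def apply_mwf(filt: WienerFilter, emb: EmbeddedEEG) -> np.ndarray:
    """Filter the embedded EEG: returns W^T x_tilde (embedded dim x samples)."""
    if filt.weights.shape[0] != emb.signals.shape[0]:
        raise ValueError(
            f"filter dim {filt.weights.shape[0]} != embedded dim {emb.signals.shape[0]}"
        )
    return filt.weights.T @ emb.signals


def center_block(filtered: np.ndarray, n_channels: int, tau: int) -> np.ndarray:
    """Extract the lag-0 block of a filtered embedded signal (channel space)."""
    if filtered.shape[0] != n_channels * (2 * tau + 1):
        raise ValueError("row count inconsistent with n_channels and tau")
    start = n_channels * tau
    return filtered[start : start + n_channels]


def broadband_envelope(filtered: np.ndarray, fs: float, tr: float) -> np.ndarray:
    """Per-TR broadband power of the filtered EEG, summed over channels.

    Entry i is the total mean-squared amplitude (summed over all filtered
    output channels) in the i-th nonoverlapping TR window.
    """
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    win = int(round(fs * tr))
    n_win = filtered.shape[1] // win
    if n_win < 1:
        raise ValueError("signal shorter than one TR window")
    x = filtered[:, : n_win * win].reshape(filtered.shape[0], n_win, win)
    return np.sum(np.mean(x**2, axis=2), axis=0)


def mask_from_intervals(
    intervals: np.ndarray, fs: float, n_samples: int
) -> np.ndarray:
    """Boolean per-sample mask from (start, stop) annotation times in seconds."""
    intervals = np.atleast_2d(np.asarray(intervals, dtype=float))
    mask = np.zeros(n_samples, dtype=bool)
    for start, stop in intervals:
        i0, i1 = int(np.floor(start * fs)), int(np.ceil(stop * fs))
        if i1 <= 0 or i0 >= n_samples:
            warnings.warn(f"annotation [{start}, {stop}] s outside the recording")
            continue
        mask[max(i0, 0) : min(i1, n_samples)] = True
    return mask
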