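"""Tensorization: EEG spectrogram tensor and parcellated, cleaned BOLD matrix.

The enhanced EEG is converted into a third-order ``time x frequency x
channel`` tensor by Thomson multitaper spectral estimation on nonoverlapping
TR-length segments, with squared Fourier magnitudes averaged into 1-Hz bins
(1-40 Hz by default).  Each (frequency, channel) fiber is log-transformed
and z-scored over time so that every channel and frequency contributes
equally and the decomposition focuses on relative power changes.

The fMRI side is confound-regressed, band-pass filtered (0.008-0.20 Hz),
averaged within atlas parcels and z-scored per region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrogramTensor",
    "BOLDMatrix",
    "multitaper_spectrogram",
    "normalize_spectrogram",
    "build_confound_matrix",
    "regress_confounds",
    "bandpass_bold",
    "parcellate",
]


@dataclass
class SpectrogramTensor:
    """Time x frequency x channel EEG power tensor, TR-synchronized."""

    values: np.ndarray  # Is x Ig x Im
    freqs: np.ndarray  # center frequencies (Hz)
    tr: float
    channel_labels: list[str] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("spectrogram tensor must be 3-D (time, freq, channel)")
        if len(self.freqs) != self.values.shape[1]:
            raise ValueError("freqs length must match the frequency axis")


@dataclass
class BOLDMatrix:
    """Time x ROI matrix of z-scored average BOLD signals."""

    values: np.ndarray  # Is x Iv
    roi_ids: np.ndarray
    tr: float
    dropped_rois: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BOLD matrix must be 2-D (time, ROI)")
        self.roi_ids = np.asarray(self.roi_ids)
        if len(self.roi_ids) != self.values.shape[1]:
            raise ValueError("roi_ids length must match the ROI axis")


def multitaper_spectrogram(
    eeg: np.ndarray,
    fs: float,
    tr: float,
    fmin: float = 1.0,
    fmax: float = 40.0,
    nw: float = 3.5,
    channel_labels: list[str] | None = None,
) -> SpectrogramTensor:
    """Multitaper power spectrogram on nonoverlapping TR-length segments.

    Parameters
    ----------
    eeg : channels x samples array (enhanced EEG).
    nw : time-bandwidth product of the DPSS tapers.

    Returns the unnormalized tensor with 1-Hz bins centered on the integers
    ``fmin..fmax``; one time point per complete TR segment.
    """
    from mne.time_frequency import psd_array_multitaper

    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    if fmax >= fs / 2:
        raise ValueError(f"fmax={fmax} Hz requires fs > {2 * fmax} Hz (got {fs})")
    seg_len = int(round(fs * tr))
    if seg_len < fs:  # fewer samples than 1 s cannot resolve 1-Hz bins
        warnings.warn("TR segment shorter than 1 s; 1-Hz bins are unreliable")
    n_ch, n_samp = eeg.shape
    n_seg = n_samp // seg_len
    if n_seg < 1:
        raise ValueError("signal shorter than one TR segment")
    segs = eeg[:, : n_seg * seg_len].reshape(n_ch, n_seg, seg_len).transpose(1, 0, 2)
    bandwidth = 2.0 * nw / tr  # full taper bandwidth in Hz
    psd, freqs = psd_array_multitaper(
        segs, sfreq=fs, fmin=max(fmin - 0.5, 0.0), fmax=fmax + 0.5,
        bandwidth=bandwidth, adaptive=False, normalization="full", verbose="error",
    )
    centers = np.arange(np.ceil(fmin), np.floor(fmax) + 1)
    tensor = np.zeros((n_seg, centers.size, n_ch))
    for g, c in enumerate(centers):
        sel = (freqs >= c - 0.5) & (freqs < c + 0.5)
        if not np.any(sel):
            raise ValueError(f"no spectral estimates fall in the {c} Hz bin")
        tensor[:, g, :] = psd[:, :, sel].mean(axis=2)
    return SpectrogramTensor(tensor, centers, tr, channel_labels)


def normalize_spectrogram(tensor: SpectrogramTensor, log: bool = True) -> SpectrogramTensor:
    """Log-transform and z-score each (frequency, channel) fiber along time.

    The log step is skipped (with a warning) when the input contains
    non-positive values, e.g. when the tensor is already normalized; the
    z-scoring alone is then idempotent.  Constant fibers are set to zero.
    """
    x = tensor.values
    if log:
        if np.all(x > 0):
            x = np.log(x)
        else:
            warnings.warn(
                "non-positive values present; skipping the log transform "
                "(input may already be normalized)"
            )
    mean = x.mean(axis=0, keepdims=True)
    std = x.std(axis=0, keepdims=True)
    flat = std[0] < 1e-15 * np.maximum(np.abs(mean[0]), 1.0)
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant fiber(s) set to zero")
    std_safe = np.where(std < 1e-300, 1.0, std)
    z = (x - mean) / std_safe
    z[:, flat] = 0.0
    return SpectrogramTensor(
        z, tensor.freqs, tensor.tr, tensor.channel_labels, normalized=True
    )


def build_confound_matrix(
    n_scans: int,
    motion: np.ndarray | None = None,
    scrub_threshold: float = 1.0,
    compcor_signals: np.ndarray | None = None,
    n_compcor: int = 5,
    extra: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble nuisance regressors.

    motion : n_scans x 6 rigid-body parameters (first three = translations,
        mm).  Expanded with squares and first differences.  Scan-to-scan
        translation displacement beyond ``scrub_threshold`` mm adds a unit
        indicator ("scrubbing") regressor per flagged volume.
    compcor_signals : n_scans x n_voxels CSF/WM time series; their first
        ``n_compcor`` principal components are appended.
    """
    cols = [np.ones((n_scans, 1))]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_scans:
            raise ValueError("motion parameters must have one row per scan")
        deriv = np.diff(motion, axis=0, prepend=motion[:1])
        cols += [motion, motion**2, deriv]
        disp = np.abs(np.diff(motion[:, :3], axis=0)).max(axis=1)
        flagged = np.flatnonzero(disp > scrub_threshold) + 1
        for idx in flagged:
            e = np.zeros((n_scans, 1))
            e[idx] = 1.0
            cols.append(e)
        if flagged.size:
            logger.info("scrubbing %d high-motion volumes", flagged.size)
    if compcor_signals is not None:
        sig = np.asarray(compcor_signals, dtype=float)
        sig = sig - sig.mean(axis=0)
        _, _, vt = np.linalg.svd(sig, full_matrices=False)
        n_pc = min(n_compcor, vt.shape[0])
        cols.append(sig @ vt[:n_pc].T)
    if extra is not None:
        cols.append(np.atleast_2d(np.asarray(extra, dtype=float)))
    return np.hstack(cols)


def regress_confounds(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize time series against confound regressors (plus intercept).

    Collinear confound columns are dropped with a warning (QR with column
    pivoting); the residual of the least-squares projection is returned.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    c = np.atleast_2d(np.asarray(confounds, dtype=float))
    if c.shape[0] != y.shape[0]:
        raise ValueError("confounds and series must have the same number of scans")
    has_intercept = np.any(
        np.all(np.isclose(c, c[0:1]), axis=0) & (np.abs(c[0]) > 0)
    )
    if not has_intercept:
        c = np.hstack([np.ones((c.shape[0], 1)), c])
    u, s, _ = np.linalg.svd(c, full_matrices=False)
    tol = s[0] * max(c.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < c.shape[1]:
        warnings.warn(
            f"confound matrix is rank-deficient ({rank}/{c.shape[1]}); "
            "collinear columns dropped"
        )
    q = u[:, :rank]
    resid = y - q @ (q.T @ y)
    return resid[:, 0] if squeeze else resid


def bandpass_bold(
    series: np.ndarray, tr: float, low: float = 0.008, high: float = 0.20, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis."""
    nyq = 0.5 / tr
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high={high} Hz must be below Nyquist {nyq:.4f} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=0)


def parcellate(
    bold: np.ndarray, atlas: np.ndarray, tr: float, zscore: bool = True
) -> BOLDMatrix:
    """Average 4-D BOLD (x, y, z, t) within integer atlas parcels.

    Empty parcels (labels present in the atlas but with no finite voxels, or
    labels missing entirely) are dropped with a warning; the surviving label
    order is recorded in ``roi_ids`` so maps can be re-expanded later.
    """
    bold = np.asarray(bold, dtype=float)
    atlas = np.asarray(atlas)
    if bold.ndim != 4:
        raise ValueError("BOLD input must be 4-D (x, y, z, time)")
    if atlas.shape != bold.shape[:3]:
        raise ValueError("atlas and BOLD must share the same voxel grid")
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("atlas contains no positive labels")
    n_t = bold.shape[3]
    flat = bold.reshape(-1, n_t)
    lab_flat = atlas.reshape(-1)
    cols, kept, dropped = [], [], []
    for lab in labels:
        vox = lab_flat == lab
        if not np.any(vox):
            dropped.append(lab)
            continue
        ts = flat[vox].mean(axis=0)
        if not np.all(np.isfinite(ts)) or ts.std() == 0:
            dropped.append(lab)
            continue
        cols.append(ts)
        kept.append(lab)
    if not cols:
        raise ValueError("no atlas label overlaps usable BOLD voxels")
    if dropped:
        warnings.warn(f"dropped {len(dropped)} empty/degenerate parcel(s): {dropped}")
    y = np.column_stack(cols)
    if zscore:
        y = (y - y.mean(axis=0)) / y.std(axis=0)
    return BOLDMatrix(y, np.asarray(kept), tr, np.asarray(dropped, dtype=int))
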