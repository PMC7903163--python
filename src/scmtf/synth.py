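"""Model-faithful synthetic EEG-fMRI datasets with known ground truth.

The generator draws factor matrices for the trilinear EEG model and the
hemodynamically coupled BOLD model, composes both data arrays exactly from
those factors, and adds controlled noise.  One source is an "IED" source: a
smoothed Poisson spike train with a low-frequency spectral signature and a
focal topography.  A configurable subset of ROIs (the planted epileptogenic
zone) receives a deviant HRF whose main lobe peaks *before* the EEG event
(acausal), emulating the BOLD changes that have been reported to precede
interictal discharges; all other ROIs get a causal, canonical-like HRF.

A raw multichannel EEG realization with template spikes at the spike-train
times is emitted as well, so the Wiener-filter stage can be tested end to
end.  Same seed, same dataset, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .core import SCMTFSolution, model_predict
from .hrf import LagGrid, basis_from_thetas
from .mwf import EEGRecording
from .tensorize import BOLDMatrix, SpectrogramTensor

__all__ = ["SyntheticGroundTruth", "SyntheticDataset", "generate_dataset"]

# double-gamma parameters of the two generating basis functions, expressed
# on a grid whose origin sits t_pre seconds before the event:
#   normal   : main lobe ~+5 s after the event (causal, canonical-like)
#   deviant  : main lobe ~-6 s (acausal), as planted in the zone ROIs
NORMAL_THETA = (9.0, 0.5, 22.0, 1.0, 0.15)
DEVIANT_THETA = (4.0, 0.6, 10.0, 1.0, 0.1)


@dataclass
class SyntheticGroundTruth:
    """True factors and generation parameters of a synthetic dataset."""

    S0: np.ndarray
    G0: np.ndarray
    M0: np.ndarray
    V0: np.ndarray
    B0: np.ndarray
    theta0: np.ndarray  # K x 5
    N0: np.ndarray
    P0: np.ndarray
    spike_train: np.ndarray  # per-TR IED counts
    zone_mask: np.ndarray  # boolean per ROI
    snr_eeg: float
    snr_fmri: float
    seed: int | None
    grid: LagGrid = field(default=None)

    @property
    def ied_source(self) -> int:
        return 0

    def solution(self) -> SCMTFSolution:
        """Wrap the true factors as an (uncalibrated) solution object."""
        basis = basis_from_thetas([tuple(t) for t in self.theta0], self.grid)
        R = self.S0.shape[1]
        return SCMTFSolution(
            S=self.S0, G=self.G0, M=self.M0, V=self.V0, B=self.B0,
            basis=basis, N=self.N0, P=self.P0, cost=np.nan,
            lambda_x=np.ones(R), lambda_y=np.zeros(R),
        )


@dataclass
class SyntheticDataset:
    tensor: SpectrogramTensor
    bold: BOLDMatrix
    eeg: EEGRecording
    truth: SyntheticGroundTruth


def _smooth_standardize(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    y = np.convolve(x, kernel, mode="same")
    y = y - y.mean()
    s = y.std()
    return y / (s if s > 0 else 1.0)


def _noise_for_snr(rng, shape, signal_power: float, snr_db: float) -> np.ndarray:
    sigma = np.sqrt(signal_power / 10.0 ** (snr_db / 10.0))
    return sigma * rng.standard_normal(shape)


def _spike_template(fs: float, duration: float = 0.3) -> np.ndarray:
    """Spike-and-slow-wave-like template: one cycle of a Ricker wavelet."""
    n = max(int(round(duration * fs)), 5)
    t = np.linspace(-1.0, 1.0, n)
    a = 0.35
    tpl = (1 - (t / a) ** 2) * np.exp(-(t**2) / (2 * a**2))
    return tpl / np.abs(tpl).max()


def generate_dataset(
    Is: int = 270,
    Iv: int = 50,
    Ig: int = 20,
    Im: int = 16,
    R: int = 2,
    K: int = 2,
    Q: int = 1,
    tr: float = 2.2,
    snr_eeg: float = 10.0,
    snr_fmri: float = 10.0,
    spike_rate_per_min: float = 2.0,
    zone_fraction: float = 0.1,
    deviant_theta: tuple = DEVIANT_THETA,
    fs_raw: float = 200.0,
    raw_spike_snr: float = 0.0,
    t_pre: float = 10.0,
    t_post: float = 22.0,
    seed: int | None = None,
) -> SyntheticDataset:
    """Generate a coupled EEG-fMRI dataset from the generative model.

    Defaults emulate a ten-minute single-run interictal session: Is=270 TRs
    of 2.2 s, 50 ROIs, a 20-bin spectral axis, 16 channels, R=2 sources of
    which the first is the IED source (Poisson spikes at 2/min), K=2 HRF
    basis functions (one causal canonical-like, one acausal deviant), a
    rank-Q uncoupled fMRI nuisance, and 10 dB additive Gaussian noise in
    both modalities.  ``zone_fraction`` of the ROIs form the planted zone
    with the deviant HRF and strong IED coupling.
    """
    if R < 1 or K < 1 or Q < 0 or min(Is, Iv, Ig, Im) < 2:
        raise ValueError("inconsistent sizes")
    rng = np.random.default_rng(seed)
    grid = LagGrid(t_pre, t_post, tr)

    # --- temporal signatures ---------------------------------------------
    rate_per_tr = spike_rate_per_min * tr / 60.0
    spike_train = rng.poisson(rate_per_tr, size=Is)
    S0 = np.empty((Is, R))
    S0[:, 0] = _smooth_standardize(spike_train.astype(float), np.array([0.25, 1.0, 0.5]))
    for r in range(1, R):
        S0[:, r] = _smooth_standardize(rng.standard_normal(Is), np.ones(7) / 7.0)

    # --- spectral signatures ----------------------------------------------
    f = np.arange(Ig, dtype=float)
    G0 = np.empty((Ig, R))
    G0[:, 0] = np.exp(-f / 3.0) + 0.02  # IED: low-frequency dominant
    for r in range(1, R):
        center = rng.uniform(0.3, 0.9) * Ig
        G0[:, r] = np.exp(-((f - center) ** 2) / (2 * 2.5**2)) + 0.02
    G0 /= np.linalg.norm(G0, axis=0)

    # --- EEG topographies ---------------------------------------------------
    ch = np.arange(Im, dtype=float)
    M0 = np.empty((Im, R))
    focus = rng.integers(0, Im)
    M0[:, 0] = np.exp(-((ch - focus) ** 2) / (2 * 1.5**2)) + 0.05  # focal
    for r in range(1, R):
        M0[:, r] = np.abs(
            np.convolve(rng.standard_normal(Im), np.ones(5) / 5.0, mode="same")
        ) + 0.1
    M0 /= np.linalg.norm(M0, axis=0)
    M0 *= 3.0  # EEG source amplitudes

    # --- zone and HRF coefficients -----------------------------------------
    n_zone = int(round(zone_fraction * Iv))
    zone = np.zeros(Iv, dtype=bool)
    zone[rng.choice(Iv, size=n_zone, replace=False)] = True
    theta0 = np.array([NORMAL_THETA, deviant_theta] + [
        (6.0 + 2 * k, 0.8, 20.0, 1.0, 0.1) for k in range(K - 2)
    ][: max(K - 2, 0)])[:K]
    basis = basis_from_thetas([tuple(t) for t in theta0], grid)
    B0 = np.zeros((Iv, K))
    B0[:, 0] = 1.0 + 0.05 * rng.standard_normal(Iv)
    if K > 1:
        B0[:, 1] = 0.05 * rng.standard_normal(Iv)
        B0[zone, 0] = 0.15 + 0.05 * rng.standard_normal(n_zone)
        B0[zone, 1] = 1.0 + 0.05 * rng.standard_normal(n_zone)

    # --- fMRI spatial signatures -------------------------------------------
    # every region couples to the shared sources at unit scale (brain-wide
    # resting fluctuations); zone ROIs additionally carry strong IED coupling
    V0 = rng.standard_normal((Iv, R))
    V0[zone, 0] = 2.5 + 0.3 * rng.standard_normal(n_zone)

    # --- nuisance -----------------------------------------------------------
    if Q > 0:
        N0 = np.column_stack(
            [_smooth_standardize(rng.standard_normal(Is), np.ones(11) / 11.0)
             for _ in range(Q)]
        )
        P0 = 0.7 * rng.standard_normal((Iv, Q))
    else:
        N0 = np.zeros((Is, 0))
        P0 = np.zeros((Iv, 0))

    truth = SyntheticGroundTruth(
        S0, G0, M0, V0, B0, theta0, N0, P0, spike_train, zone,
        snr_eeg, snr_fmri, seed, grid,
    )

    # --- compose data exactly from the model, then add noise ----------------
    Xc, Yhat = model_predict(truth.solution())
    Yc = Yhat - (N0 @ P0.T if Q > 0 else 0.0)  # coupled part only
    X = Xc + _noise_for_snr(rng, Xc.shape, float(np.mean(Xc**2)), snr_eeg)
    Y = Yhat + _noise_for_snr(rng, Yhat.shape, float(np.mean(Yc**2)), snr_fmri)

    tensor = SpectrogramTensor(X, np.arange(1, Ig + 1), tr, normalized=True)
    bold = BOLDMatrix(Y, np.arange(1, Iv + 1), tr)

    # --- raw EEG with template spikes for the MWF stage ----------------------
    n_samp = int(round(Is * tr * fs_raw))
    bg = rng.standard_normal((Im, n_samp))
    # mild low-pass to mimic 1/f-ish background, then unit std per channel
    b, a = sp_signal.butter(2, 45.0 / (fs_raw / 2.0), btype="low")
    bg = sp_signal.lfilter(b, a, bg, axis=1)
    bg /= bg.std(axis=1, keepdims=True)
    tpl = _spike_template(fs_raw)
    topo = M0[:, 0] / np.abs(M0[:, 0]).max()
    amp = np.sqrt(10.0 ** (raw_spike_snr / 10.0) / np.mean(tpl**2))
    raw = bg.copy()
    ied_mask = np.zeros(n_samp, dtype=bool)
    win = int(round(tr * fs_raw))
    for i in np.flatnonzero(spike_train > 0):
        for _ in range(int(spike_train[i])):
            start = i * win + int(rng.integers(0, max(win - tpl.size, 1)))
            stop = min(start + tpl.size, n_samp)
            raw[:, start:stop] += amp * np.outer(topo, tpl[: stop - start])
            ied_mask[start:stop] = True
    eeg = EEGRecording(raw, fs_raw, ied_mask=ied_mask, tr=tr)

    return SyntheticDataset(tensor, bold, eeg, truth)
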