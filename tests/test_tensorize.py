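"""Spectrogram tensorization and BOLD preprocessing."""

import numpy as np
import pytest

from scmtf.tensorize import (
    SpectrogramTensor,
    bandpass_bold,
    build_confound_matrix,
    multitaper_spectrogram,
    normalize_spectrogram,
    parcellate,
    regress_confounds,
)


class TestMultitaper:
    fs, tr = 200.0, 2.2

    def test_pure_sinusoid_concentrates_power(self):
        t = np.arange(int(self.fs * self.tr * 10)) / self.fs
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        spec = multitaper_spectrogram(x, self.fs, self.tr)
        assert spec.values.shape == (10, 40, 1)
        p = spec.values.mean(axis=0)[:, 0]
        bin10 = p[np.where(spec.freqs == 10)[0][0]]
        bin20 = p[np.where(spec.freqs == 20)[0][0]]
        assert bin10 / bin20 > 100

    def test_zero_signal_zero_tensor(self):
        x = np.zeros((2, int(self.fs * self.tr * 4)))
        spec = multitaper_spectrogram(x, self.fs, self.tr)
        assert np.allclose(spec.values, 0.0)

    def test_default_band_has_40_bins(self, rng):
        x = rng.standard_normal((1, int(self.fs * self.tr * 3)))
        spec = multitaper_spectrogram(x, self.fs, self.tr, fmin=1, fmax=40)
        assert spec.values.shape[1] == 40
        assert np.array_equal(spec.freqs, np.arange(1, 41))

    def test_low_fs_rejected(self, rng):
        x = rng.standard_normal((1, 1000))
        with pytest.raises(ValueError):
            multitaper_spectrogram(x, fs=60.0, tr=self.tr, fmax=40.0)


class TestNormalize:
    def test_fibers_standardized(self, rng):
        vals = np.exp(rng.standard_normal((30, 5, 4)))
        out = normalize_spectrogram(SpectrogramTensor(vals, np.arange(1, 6), 2.2))
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10
        assert np.abs(out.values.std(axis=0) - 1).max() < 1e-10

    def test_channel_scale_equalized(self, rng):
        base = np.exp(rng.standard_normal((40, 3, 1)))
        vals = np.concatenate([base, 10.0 * base], axis=2)
        out = normalize_spectrogram(SpectrogramTensor(vals, np.arange(1, 4), 2.2))
        assert np.allclose(out.values[:, :, 0], out.values[:, :, 1], atol=1e-10)

    def test_log2_fiber_hand_case(self):
        # fiber (1, 2, 4) -> log2 (0, 1, 2) -> z-scores (-1, 0, 1)*sqrt(3/2);
        # z-scoring makes the log base irrelevant
        vals = np.array([1.0, 2.0, 4.0])[:, None, None]
        out = normalize_spectrogram(SpectrogramTensor(vals, [1.0], 2.2))
        z = (np.log2([1.0, 2.0, 4.0]) - 1.0) / np.std(np.log2([1.0, 2.0, 4.0]))
        assert np.allclose(out.values[:, 0, 0], z, atol=1e-12)
        assert np.allclose(z, np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5))

    def test_constant_fiber_zeroed_with_warning(self):
        vals = np.ones((10, 2, 1))
        vals[:, 1, 0] = np.exp(np.arange(10))
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_spectrogram(SpectrogramTensor(vals, [1, 2], 2.2))
        assert np.allclose(out.values[:, 0, 0], 0.0)

    def test_idempotent(self, rng):
        vals = np.exp(rng.standard_normal((25, 4, 3)))
        once = normalize_spectrogram(SpectrogramTensor(vals, np.arange(1, 5), 2.2))
        with pytest.warns(UserWarning, match="log"):
            twice = normalize_spectrogram(once)
        assert np.allclose(once.values, twice.values, atol=1e-8)


class TestConfounds:
    def test_confound_column_removed(self, rng):
        c = rng.standard_normal((200, 3))
        y = 2.5 * c[:, 1]
        resid = regress_confounds(y, c)
        assert np.abs(resid).max() < 1e-8

    def test_orthogonal_series_kept(self, rng):
        c = np.sin(np.arange(300))[:, None]
        y = rng.standard_normal(300)
        resid = regress_confounds(y, c)
        # unchanged up to the projection on intercept + one sinusoid
        assert np.corrcoef(resid, y - y.mean())[0, 1] > 0.99

    def test_planted_signal_recovered(self, rng):
        n = 500
        # smooth sub-millimeter head drift; regress the 6 raw parameters
        motion = 0.3 * np.cumsum(rng.standard_normal((n, 6)), axis=0) / np.sqrt(n)
        signal = np.sin(2 * np.pi * 23 * np.arange(n) / n)
        y = signal + 0.7 * motion[:, 0]
        resid = regress_confounds(y, motion)
        assert np.corrcoef(resid, signal)[0, 1] > 0.99
        # the full expansion (squares, derivatives) keeps most of it too
        conf = build_confound_matrix(n, motion=motion)
        resid_full = regress_confounds(y, conf)
        assert np.corrcoef(resid_full, signal)[0, 1] > 0.95

    def test_collinear_columns_warn(self, rng):
        c = rng.standard_normal((100, 2))
        c = np.hstack([c, c[:, :1] * 2.0])
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_confounds(rng.standard_normal(100), c)

    def test_scrubbing_regressors(self):
        motion = np.zeros((50, 6))
        motion[20, 0] = 2.0  # 2 mm jump at scan 20
        conf = build_confound_matrix(50, motion=motion, scrub_threshold=1.0)
        # intercept + 18 motion-derived + 2 scrub indicators (jump up and back)
        indicators = conf[:, 19:]
        assert indicators.shape[1] == 2
        assert indicators[20, 0] == 1.0 and indicators[21, 1] == 1.0

    def test_compcor_components(self, rng):
        sig = rng.standard_normal((80, 40))
        conf = build_confound_matrix(80, compcor_signals=sig, n_compcor=5)
        assert conf.shape == (80, 6)  # intercept + 5 PCs


class TestBandpass:
    tr = 2.2

    def test_inband_preserved(self):
        t = np.arange(1000) * self.tr
        x = np.sin(2 * np.pi * 0.1 * t)
        y = bandpass_bold(x, self.tr)
        mid = slice(200, 800)
        assert np.abs(y[mid]).max() > 0.95

    def test_stopband_attenuated(self):
        t = np.arange(1000) * self.tr
        x = np.sin(2 * np.pi * 0.002 * t)  # below 0.008 Hz
        y = bandpass_bold(x, self.tr)
        assert np.abs(y[200:800]).max() < 0.25

    def test_dc_removed(self):
        y = bandpass_bold(np.full(500, 3.0), self.tr)
        assert np.abs(y).max() < 1e-6

    def test_band_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError):
            bandpass_bold(rng.standard_normal(100), self.tr, high=0.25)


class TestParcellate:
    def test_label_average_and_zscore(self, rng):
        a = rng.standard_normal(30)
        bold = np.zeros((2, 2, 1, 30))
        bold[0, 0, 0] = a
        bold[1, 0, 0] = a
        bold[0, 1, 0] = rng.standard_normal(30)
        atlas = np.array([[[1], [2]], [[1], [0]]])
        mat = parcellate(bold, atlas, tr=2.2)
        assert np.array_equal(mat.roi_ids, [1, 2])
        az = (a - a.mean()) / a.std()
        assert np.allclose(mat.values[:, 0], az)
        assert np.allclose(mat.values.mean(axis=0), 0.0, atol=1e-12)

    def test_empty_parcel_dropped(self, rng):
        bold = rng.standard_normal((2, 2, 1, 20))
        atlas = np.zeros((2, 2, 1), dtype=int)
        atlas[0, 0, 0] = 1
        atlas[1, 1, 0] = 7
        mat = parcellate(bold, atlas, tr=2.2)
        assert list(mat.roi_ids) == [1, 7]
        with pytest.raises(ValueError):
            parcellate(bold, np.zeros((2, 2, 1), dtype=int), tr=2.2)

    def test_linearity_of_averaging(self, rng):
        # parcel average commutes with voxelwise linear mixing within a parcel
        bold = rng.standard_normal((3, 1, 1, 25))
        atlas = np.full((3, 1, 1), 4)
        m1 = parcellate(bold, atlas, tr=2.2, zscore=False)
        mixed = np.einsum("ij,jxyt->ixyt", np.full((3, 3), 1 / 3.0), bold)
        m2 = parcellate(mixed, atlas, tr=2.2, zscore=False)
        assert np.allclose(m1.values, m2.values, atol=1e-12)
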