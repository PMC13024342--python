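"""Time-domain, frequency-domain, wavelet and standardization extractors."""

import numpy as np
import pytest
from scipy import signal

from neuroflow.features import (
    Standardizer,
    dwt_features,
    frequency_domain_features,
    spectral_entropy,
    standardize,
    time_domain_features,
)
from neuroflow.recording import EEGRecording

import pandas as pd


def _named(fv):
    return dict(zip(fv.names, fv.values))


class TestTimeDomain:
    def test_constant_channel_statistics(self):
        rec = EEGRecording(np.full((1, 100), 5.0), fs=100, channel_names=("c",))
        d = _named(time_domain_features(rec))
        assert d["mean_c"] == 5 and d["peak_c"] == 5 and d["rms_c"] == 5
        assert d["var_c"] == 0 and d["std_c"] == 0
        assert d["skew_c"] == 0 and d["kurt_c"] == 0  # convention

    def test_alternating_channel_symmetry(self):
        rec = EEGRecording(np.array([[1.0, -1, 1, -1]]), fs=4, channel_names=("c",))
        d = _named(time_domain_features(rec))
        assert d["mean_c"] == 0 and d["rms_c"] == 1 and d["peak_c"] == 1

    def test_19_channel_vector_length_is_133(self, noise_recording):
        assert len(time_domain_features(noise_recording)) == 133

    def test_feature_major_stacking(self, noise_recording):
        fv = time_domain_features(noise_recording)
        assert fv.names[0] == "mean_Fp1" and fv.names[19] == "peak_Fp1"


class TestFrequencyDomain:
    def test_pure_alpha_sine(self, sine_recording):
        d = _named(frequency_domain_features(sine_recording))
        assert d["relpow_alpha_Fp1"] >= 0.99
        assert abs(d["median_freq_Fp1"] - 10.0) <= 0.5  # one PSD bin at 2 s windows

    def test_sine_against_brute_force_periodogram(self, sine_recording):
        """Independent oracle: direct Welch-bin integration of band power
        and cumulative-sum median frequency."""
        rec = sine_recording
        nperseg = int(2 * rec.fs)
        f, p = signal.welch(rec.data[0], rec.fs, window="hann",
                            nperseg=nperseg, noverlap=nperseg // 2)
        df = f[1] - f[0]
        powers = {}
        for name, lo, hi in (("delta", .5, 4), ("theta", 4, 8), ("alpha", 8, 13),
                             ("beta", 13, 30), ("gamma", 30, 100)):
            powers[name] = sum(pv * df for fv, pv in zip(f, p) if lo <= fv < hi)
        total = sum(powers.values())
        sel = [(fv, pv) for fv, pv in zip(f, p) if 0.5 <= fv < 100]
        csum = np.cumsum([pv for _, pv in sel])
        med = sel[int(np.argmax(csum >= csum[-1] / 2))][0]
        d = _named(frequency_domain_features(rec))
        for name in powers:
            assert d[f"relpow_{name}_Fp1"] == pytest.approx(
                powers[name] / total, abs=1e-10
            )
        assert d["median_freq_Fp1"] == pytest.approx(med, abs=1e-10)

    def test_white_noise_relative_powers_track_bandwidths(self):
        rng = np.random.default_rng(7)
        rec = EEGRecording(rng.normal(size=(1, 500 * 60)), 500, ("c",))
        d = _named(frequency_domain_features(rec))
        widths = {"delta": 3.5, "theta": 4, "alpha": 5, "beta": 17, "gamma": 70}
        total = sum(widths.values())
        for band, w in widths.items():
            assert abs(d[f"relpow_{band}_c"] - w / total) < 0.05
        assert d["spec_entropy_c"] > 0.9

    def test_19_channel_vector_length_is_190(self, noise_recording):
        assert len(frequency_domain_features(noise_recording)) == 190

    def test_relative_powers_sum_to_one(self, noise_recording):
        d = _named(frequency_domain_features(noise_recording))
        for ch in noise_recording.channel_names:
            s = sum(d[f"relpow_{b}_{ch}"] for b in
                    ("delta", "theta", "alpha", "beta", "gamma"))
            assert s == pytest.approx(1.0, abs=1e-9)


class TestSpectralEntropy:
    def test_flat_spectrum_is_one(self):
        for k in (2, 5, 100):
            assert spectral_entropy(np.ones(k)) == pytest.approx(1.0)

    def test_point_mass_is_zero(self):
        assert spectral_entropy(np.array([0, 0, 3.0, 0])) == 0.0

    def test_hand_computed_three_bin_value(self):
        # -(0.5 log2 0.5 + 2 * 0.25 log2 0.25) / log2 3 = 1.5 / 1.585
        assert spectral_entropy(np.array([0.5, 0.25, 0.25])) == pytest.approx(
            0.9464, abs=1e-3
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spectral_entropy(np.zeros(4))
        with pytest.raises(ValueError):
            spectral_entropy(np.array([1.0]))


class TestDWT:
    def test_19_channel_vector_length_is_342(self, noise_recording):
        assert len(dwt_features(noise_recording)) == 342

    def test_zero_signal_gives_zero_features(self):
        rec = EEGRecording(np.zeros((1, 256)), 100, ("c",))
        assert np.all(dwt_features(rec).values == 0)

    def test_energy_conservation_under_periodization(self, noise_recording):
        fv = _named(dwt_features(noise_recording))
        for i, ch in enumerate(noise_recording.channel_names):
            sub = sum(fv[f"{b}_energy_{ch}"] for b in
                      ("A5", "D5", "D4", "D3", "D2", "D1"))
            direct = (noise_recording.data[i] ** 2).sum()
            assert sub == pytest.approx(direct, rel=1e-8)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            dwt_features(EEGRecording(np.zeros((1, 16)), 100, ("c",)))


class TestStandardize:
    def test_training_rows_have_zero_mean_unit_std(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(3, 2, (50, 4)))
        out, _ = standardize(df)
        np.testing.assert_allclose(out.mean(), 0, atol=1e-9)
        np.testing.assert_allclose(out.std(ddof=0), 1, atol=1e-9)

    def test_heldout_rows_use_training_statistics(self):
        rng = np.random.default_rng(2)
        train = pd.DataFrame(rng.normal(size=(30, 3)))
        held = pd.DataFrame(rng.normal(size=(5, 3)))
        scaler = Standardizer().fit(train)
        manual = (held.to_numpy() - train.to_numpy().mean(0)) / train.to_numpy().std(0)
        np.testing.assert_allclose(scaler.transform(held).to_numpy(), manual)

    def test_refit_on_standardized_data_is_idempotent(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(5, 3, (40, 4)))
        once, _ = standardize(df)
        twice, _ = standardize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)

    def test_zero_variance_feature_warns_and_survives(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 4, 4]})
        with pytest.warns(UserWarning):
            out, _ = standardize(df)
        assert np.all(np.isfinite(out.to_numpy()))
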