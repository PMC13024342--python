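"""Handcrafted EEG biomarkers: time-domain statistics, frequency-domain
spectral descriptors, and discrete-wavelet sub-band features.

Conventions (the quantities are standard; conventions are stated once):

* peak = maximum absolute amplitude; variance/std are population (ddof 0);
  skewness is sample skewness and kurtosis is excess kurtosis, both defined
  as 0 for a constant signal;
* PSD is Welch with 2 s Hann windows and 50 % overlap; band power is
  rectangular bin integration over [f_lo, f_hi); the gamma upper edge is
  capped at the Nyquist frequency;
* the DWT uses the db4 wavelet, 5 levels, periodization boundary mode (so
  sub-band energies sum to the signal energy exactly);
* feature vectors stack feature-major for the time and frequency domains
  (all means first, then all peaks, ...) and channel-major for the wavelet
  domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal, stats

from .recording import DEFAULT_BANDS, BandSet, EEGRecording

__all__ = [
    "FeatureVector",
    "time_domain_features",
    "frequency_domain_features",
    "spectral_entropy",
    "dwt_features",
    "Standardizer",
    "standardize",
]

_EPS = 1e-12


@dataclass
class FeatureVector:
    """Named numeric feature vector for one subject."""

    values: np.ndarray
    names: list[str]
    domain_tag: str
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.subject_id)


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

_TIME_STATS = ("mean", "peak", "var", "std", "skew", "kurt", "rms")


def time_domain_features(rec: EEGRecording) -> FeatureVector:
    """Seven per-channel statistics stacked feature-major.

    For C channels the result has length 7*C (133 for the 19-channel
    montage): all means first, then all peaks, and so on.
    """
    x = rec.data
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    std = x.std(axis=1)
    const = std < _EPS
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skew = stats.skew(x, axis=1)
        kurt = stats.kurtosis(x, axis=1)
    skew = np.where(const, 0.0, skew)
    kurt = np.where(const, 0.0, kurt)
    rows = {
        "mean": x.mean(axis=1),
        "peak": np.abs(x).max(axis=1),
        "var": x.var(axis=1),
        "std": std,
        "skew": skew,
        "kurt": kurt,
        "rms": np.sqrt((x**2).mean(axis=1)),
    }
    values = np.concatenate([rows[s] for s in _TIME_STATS])
    names = [f"{s}_{ch}" for s in _TIME_STATS for ch in rec.channel_names]
    return FeatureVector(values, names, "time", rec.subject_id)


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------


def spectral_entropy(psd_bins: np.ndarray) -> float:
    """Shannon entropy of the normalized PSD, scaled to [0, 1] by log K.

    1 means a flat spectrum; 0 a single spectral line. Base-invariant.
    """
    p = np.asarray(psd_bins, dtype=np.float64)
    if p.size < 2:
        raise ValueError("need at least 2 PSD bins")
    if np.any(p < 0):
        raise ValueError("PSD bins must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero PSD")
    p = p / total
    nz = p[p > 0]
    h = -(nz * np.log(nz)).sum()
    return float(h / np.log(p.size))


def _welch_psd(rec: EEGRecording) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(int(2 * rec.fs), rec.n_samples)
    freqs, psd = signal.welch(
        rec.data, fs=rec.fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, axis=1,
    )
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Rectangular bin integration of the PSD over [lo, hi)."""
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return psd[:, mask].sum(axis=1) * df


_FREQ_STATS = (
    "relpow_delta", "relpow_theta", "relpow_alpha", "relpow_beta",
    "relpow_gamma", "ratio_theta_alpha", "ratio_delta_alpha",
    "ratio_slow_fast", "median_freq", "spec_entropy",
)


def frequency_domain_features(
    rec: EEGRecording, bands: BandSet = DEFAULT_BANDS
) -> FeatureVector:
    """Ten spectral descriptors per channel, stacked feature-major.

    Per channel: five relative band powers, theta/alpha and delta/alpha
    absolute-power ratios, the slow/fast ratio (delta+theta)/(alpha+beta),
    the median frequency, and the normalized spectral entropy. Length
    10*C (190 for the 19-channel montage).
    """
    freqs, psd = _welch_psd(rec)
    nyq = rec.fs / 2
    power = {}
    for name, lo, hi in bands.bands:
        hi = min(hi, nyq)
        if lo >= nyq:
            power[name] = np.zeros(rec.n_channels)
            continue
        power[name] = _band_power(freqs, psd, lo, hi)
    total = sum(power.values())
    if np.any(total < _EPS):
        warnings.warn("near-zero total band power; epsilon guard applied")
    total = np.maximum(total, _EPS)

    def guard(x):
        return np.maximum(x, _EPS)

    cols = {f"relpow_{n}": power[n] / total for n in bands.names}
    cols["ratio_theta_alpha"] = power["theta"] / guard(power["alpha"])
    cols["ratio_delta_alpha"] = power["delta"] / guard(power["alpha"])
    cols["ratio_slow_fast"] = (power["delta"] + power["theta"]) / guard(
        power["alpha"] + power["beta"]
    )

    # analyzed range: lowest band edge to the capped upper edge
    f_lo = bands.bands[0][1]
    f_hi = min(bands.bands[-1][2], nyq)
    mask = (freqs >= f_lo) & (freqs < f_hi)
    f_an, p_an = freqs[mask], psd[:, mask]
    csum = np.cumsum(p_an, axis=1)
    half = csum[:, -1:] / 2
    med_idx = np.argmax(csum >= half, axis=1)
    cols["median_freq"] = f_an[med_idx]
    cols["spec_entropy"] = np.array([spectral_entropy(row) for row in p_an])

    values = np.concatenate([cols[s] for s in _FREQ_STATS])
    names = [f"{s}_{ch}" for s in _FREQ_STATS for ch in rec.channel_names]
    return FeatureVector(values, names, "frequency", rec.subject_id)


# ---------------------------------------------------------------------------
# time-frequency (DWT)
# ---------------------------------------------------------------------------

_SUBBANDS = ("A5", "D5", "D4", "D3", "D2", "D1")


def _coef_entropy(c: np.ndarray) -> float:
    """Shannon entropy of the normalized squared-coefficient distribution.

    Zero by convention for an all-zero sub-band (0*log 0 := 0).
    """
    e = c**2
    total = e.sum()
    if total <= 0:
        return 0.0
    p = e / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def dwt_features(
    rec: EEGRecording, wavelet: str = "db4", levels: int = 5
) -> FeatureVector:
    """Per-channel db4 5-level wavelet sub-band features, channel-major.

    For each sub-band (A5, D5..D1): energy, coefficient standard deviation,
    and Shannon entropy of the squared-coefficient distribution — 18 values
    per channel (342 for the 19-channel montage). Periodization boundary
    handling makes the sub-band energies sum exactly to the signal energy.
    """
    min_len = 2**levels
    if rec.n_samples < min_len:
        raise ValueError(f"need >= {min_len} samples for {levels}-level DWT")
    values, names = [], []
    for ch, name in zip(rec.data, rec.channel_names):
        coeffs = pywt.wavedec(ch, wavelet, level=levels, mode="periodization")
        # coeffs = [A5, D5, D4, D3, D2, D1]
        for band, c in zip(_SUBBANDS, coeffs):
            values += [float((c**2).sum()), float(c.std()), _coef_entropy(c)]
            names += [f"{band}_energy_{name}", f"{band}_std_{name}", f"{band}_entropy_{name}"]
    return FeatureVector(np.array(values), names, "timefreq", rec.subject_id)


# ---------------------------------------------------------------------------
# z-score standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Z-score standardization with statistics frozen on the training rows."""

    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)

    def fit(self, table: pd.DataFrame) -> "Standardizer":
        x = table.to_numpy(dtype=np.float64)
        if x.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        if np.any(std < _EPS):
            warnings.warn("zero-variance feature(s); epsilon guard applied")
        self.scale_ = np.where(std < _EPS, 1.0, std)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        x = table.to_numpy(dtype=np.float64)
        return pd.DataFrame(
            (x - self.mean_) / self.scale_, index=table.index, columns=table.columns
        )

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


def standardize(
    table: pd.DataFrame, stats_from: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, Standardizer]:
    """Standardize `table` using statistics from `stats_from` (default: itself)."""
    scaler = Standardizer().fit(stats_from if stats_from is not None else table)
    return scaler.transform(table), scaler
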