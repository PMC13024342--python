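"""Phase Lag Index (PLI) functional connectivity and ROI-level summaries.

PLI between channels i and j is |<sign(sin(phi_i - phi_j))>|: the absolute
time average of the sign of the instantaneous phase difference. It is 0
when neither channel consistently leads the other (and, by construction,
for zero-lag coupling such as volume conduction) and 1 for a constant
phase lead. Phases come from the analytic signal of the band-passed data.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import signal

from .features import FeatureVector
from .recording import DEFAULT_ROI_MAP, ROI_NAMES, EEGRecording

__all__ = ["pli_matrix", "roi_connectivity", "ROI_PAIRS"]

#: Canonical unordered region-pair order (10 pairs for 5 ROIs).
ROI_PAIRS = tuple(combinations(ROI_NAMES, 2))


def pli_matrix(
    rec: EEGRecording, band: tuple[float, float] = (8.0, 13.0)
) -> np.ndarray:
    """Pairwise PLI over a frequency band (default: alpha, 8-13 Hz).

    Channels are band-pass filtered with a zero-phase FIR filter (order
    about 3*fs/f_lo), the Hilbert transform yields instantaneous phases,
    and one filter length of edge samples is discarded at each end before
    time-averaging. Returns a symmetric matrix in [0, 1] with zero diagonal.
    """
    lo, hi = band
    nyq = rec.fs / 2
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}) Hz")
    numtaps = int(3 * rec.fs / lo) | 1  # odd length for a type-I filter
    if rec.n_samples <= 3 * numtaps:
        raise ValueError("recording shorter than the filter transient")
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=rec.fs)
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    phases = np.angle(signal.hilbert(filtered, axis=1))
    phases = phases[:, numtaps:-numtaps]
    c = rec.n_channels
    pli = np.zeros((c, c))
    for i in range(c):
        for j in range(i + 1, c):
            v = np.abs(np.mean(np.sign(np.sin(phases[i] - phases[j]))))
            pli[i, j] = pli[j, i] = v
    return pli


def roi_connectivity(
    pli: np.ndarray,
    channel_names: tuple[str, ...],
    roi_map: dict[str, str] | None = None,
    subject_id: str = "",
) -> FeatureVector:
    """Mean PLI over all electrode pairs between each pair of regions.

    One value per unordered region pair in the canonical order
    (Frontal-Central, Frontal-Temporal, ..., Parietal-Occipital); 10
    values for the standard 5-region map.
    """
    use_default = roi_map is None
    roi_map = roi_map if roi_map is not None else DEFAULT_ROI_MAP
    unmapped = [ch for ch in channel_names if ch not in roi_map]
    if unmapped:
        raise ValueError(f"channels without a region: {unmapped}")
    # regions in canonical order; a custom map may cover fewer than five
    regions = [r for r in ROI_NAMES if r in {roi_map[ch] for ch in channel_names}]
    regions += sorted(
        {roi_map[ch] for ch in channel_names} - set(ROI_NAMES)
    )
    idx = {
        r: [i for i, ch in enumerate(channel_names) if roi_map[ch] == r]
        for r in regions
    }
    if use_default and len(regions) < len(ROI_NAMES):
        missing = set(ROI_NAMES) - set(regions)
        raise ValueError(f"regions with no channels: {sorted(missing)}")
    if len(regions) < 2:
        raise ValueError("need at least two regions with channels")
    values, names = [], []
    for ra, rb in combinations(regions, 2):
        block = pli[np.ix_(idx[ra], idx[rb])]
        values.append(float(block.mean()))
        names.append(f"pli_{ra}_{rb}")
    return FeatureVector(np.array(values), names, "pli", subject_id)
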