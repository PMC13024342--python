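"""EEG recording container, canonical frequency bands, and 10-20 ROI map.

A recording is a channels x samples float matrix in microvolts with a
sampling rate and ordered channel names. The default montage is the
19-electrode international 10-20 layout used by clinical resting-state
studies (Fp1 ... O2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CHANNELS_1020",
    "DEFAULT_BANDS",
    "DEFAULT_ROI_MAP",
    "BandSet",
    "EEGRecording",
    "load_recording",
]

#: Standard 19-channel 10-20 montage order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Standard 10-20 grouping into five regions of interest.
DEFAULT_ROI_MAP = {
    "Fp1": "Frontal", "Fp2": "Frontal", "F7": "Frontal", "F3": "Frontal",
    "Fz": "Frontal", "F4": "Frontal", "F8": "Frontal",
    "C3": "Central", "Cz": "Central", "C4": "Central",
    "T3": "Temporal", "T4": "Temporal", "T5": "Temporal", "T6": "Temporal",
    "P3": "Parietal", "Pz": "Parietal", "P4": "Parietal",
    "O1": "Occipital", "O2": "Occipital",
}

ROI_NAMES = ("Frontal", "Central", "Temporal", "Parietal", "Occipital")


@dataclass(frozen=True)
class BandSet:
    """Named, ordered, non-overlapping frequency intervals in Hz."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("gamma", 30.0, 100.0),
    )

    def __post_init__(self):
        prev_hi = -np.inf
        for name, lo, hi in self.bands:
            if hi <= lo:
                raise ValueError(f"band {name} has non-positive width")
            if lo < prev_hi:
                raise ValueError(f"band {name} overlaps its predecessor")
            prev_hi = hi

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)


DEFAULT_BANDS = BandSet()


@dataclass
class EEGRecording:
    """Multichannel EEG signal: channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = CHANNELS_1020
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def load_recording(
    path: str | Path,
    fs: float | None = None,
    channel_names: tuple[str, ...] | None = None,
    subject_id: str = "",
) -> EEGRecording:
    """Load a recording from EDF (via mne) or NPY/CSV with a JSON sidecar.

    For plain matrices the sidecar ``<stem>.json`` may hold ``{"fs": ...,
    "channel_names": [...]}``; explicit arguments override it.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency, only needed for EDF input

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        picks = list(channel_names) if channel_names else raw.ch_names
        raw.pick(picks)
        return EEGRecording(
            data=raw.get_data() * 1e6,  # volts -> microvolts
            fs=float(raw.info["sfreq"]),
            channel_names=tuple(raw.ch_names),
            subject_id=subject_id or path.stem,
        )
    if path.suffix.lower() == ".npy":
        data = np.load(path)
    else:
        data = np.loadtxt(path, delimiter=",")
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise ValueError("sampling rate not given and no sidecar JSON found")
    names = channel_names or meta.get("channel_names")
    if names is None:
        names = CHANNELS_1020 if data.shape[0] == 19 else tuple(
            f"ch{i}" for i in range(data.shape[0])
        )
    return EEGRecording(
        data=data, fs=float(fs), channel_names=tuple(names),
        subject_id=subject_id or path.stem,
    )
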