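"""Synthetic study data with the structure the pipeline assumes.

Two generators:

* ``generate_continuum_cohort`` — paired/unpaired feature cohorts whose
  class means lie on a 1-D latent disease continuum HC -> MCI -> AD,
  observed through per-modality affine maps plus isotropic Gaussian
  feature noise. Speech features exist for all three classes; EEG
  features only for AD and HC, mirroring the missing-MCI asymmetry of
  unpaired clinical corpora.
* ``generate_band_structured_eeg`` — multichannel band-structured EEG
  surrogates (one sinusoidal carrier per canonical band, random phases,
  white noise) with AD-like low-frequency power elevation or HC-like
  alpha dominance.

Per-subject random streams are derived from a counter-based seed
sequence, so enlarging a cohort never perturbs earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import CHANNELS_1020, EEGRecording

__all__ = [
    "InvalidSpecError",
    "ContinuumSpec",
    "SyntheticCohort",
    "BandPowerProfile",
    "ad_profile",
    "hc_profile",
    "generate_continuum_cohort",
    "generate_band_structured_eeg",
]

CLASSES = ("AD", "MCI", "HC")


class InvalidSpecError(ValueError):
    """Raised for non-finite or structurally invalid generator specs."""


def _default_affine(rng: np.random.Generator, d_in: int, d_out: int):
    """A well-conditioned random affine map (scaled Gaussian matrix + offset)."""
    mat = rng.normal(0, 1 / np.sqrt(d_in), (d_out, d_in))
    off = rng.normal(0, 0.1, d_out)
    return mat, off


@dataclass
class ContinuumSpec:
    """Generating model for a continuum cohort.

    The MCI anchor is the convex combination of the HC and AD anchors at
    ``mci_position`` (a free parameter of the generator, default 0.5: the
    midpoint of the continuum). Anchors and affine maps default to
    reproducible random draws from ``seed``. ``noise_sd`` may be a single
    float or a ``(speech, eeg)`` pair.
    """

    latent_dim: int = 8
    speech_dim: int = 128
    eeg_dim: int = 32
    mci_position: float = 0.5
    noise_sd: float | tuple[float, float] = 0.1
    n_per_class: int = 50
    seed: int = 0
    anchor_HC: np.ndarray | None = None
    anchor_AD: np.ndarray | None = None
    speech_map: tuple[np.ndarray, np.ndarray] | None = None
    eeg_map: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        if not 0 < self.mci_position < 1:
            raise InvalidSpecError("mci_position must lie strictly inside (0,1)")
        if min(self.latent_dim, self.speech_dim, self.eeg_dim) < 1:
            raise InvalidSpecError("all dimensions must be positive")
        if self.n_per_class < 1:
            raise InvalidSpecError("n_per_class must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(0,)))
        if self.anchor_HC is None:
            self.anchor_HC = rng.normal(0, 1, self.latent_dim)
        if self.anchor_AD is None:
            # separated anchors so the continuum has a well-defined direction
            self.anchor_AD = self.anchor_HC + rng.normal(0, 1, self.latent_dim) + 2.0
        self.anchor_HC = np.asarray(self.anchor_HC, dtype=np.float64)
        self.anchor_AD = np.asarray(self.anchor_AD, dtype=np.float64)
        if self.speech_map is None:
            self.speech_map = _default_affine(rng, self.latent_dim, self.speech_dim)
        if self.eeg_map is None:
            self.eeg_map = _default_affine(rng, self.latent_dim, self.eeg_dim)
        for arr in (
            self.anchor_HC, self.anchor_AD,
            *self.speech_map, *self.eeg_map,
        ):
            if not np.all(np.isfinite(arr)):
                raise InvalidSpecError("anchors and maps must be finite")
        if self.speech_map[0].shape != (self.speech_dim, self.latent_dim):
            raise InvalidSpecError("speech_map shape mismatch")
        if self.eeg_map[0].shape != (self.eeg_dim, self.latent_dim):
            raise InvalidSpecError("eeg_map shape mismatch")

    @property
    def anchor_MCI(self) -> np.ndarray:
        return self.anchor_HC + self.mci_position * (self.anchor_AD - self.anchor_HC)

    @property
    def noise_pair(self) -> tuple[float, float]:
        if isinstance(self.noise_sd, (tuple, list)):
            return float(self.noise_sd[0]), float(self.noise_sd[1])
        return float(self.noise_sd), float(self.noise_sd)


@dataclass
class SyntheticCohort:
    """Feature tables (with ``label`` column) plus the generating latents."""

    speech_features: pd.DataFrame
    eeg_features: pd.DataFrame
    true_latents: pd.DataFrame
    spec: ContinuumSpec

    def __post_init__(self):
        if "MCI" in set(self.eeg_features["label"]):
            raise InvalidSpecError("EEG table must never contain the MCI label")

    def speech_matrix(self) -> np.ndarray:
        return self.speech_features.drop(columns="label").to_numpy()

    def eeg_matrix(self) -> np.ndarray:
        return self.eeg_features.drop(columns="label").to_numpy()


def _apply(affine, z):
    mat, off = affine
    return mat @ z + off


def generate_continuum_cohort(spec: ContinuumSpec) -> SyntheticCohort:
    """Draw a cohort around affine images of the continuum anchors.

    Speech rows are drawn for all three classes, EEG rows for AD and HC
    only. Each subject gets its own counter-derived random stream.
    """
    sd_speech, sd_eeg = spec.noise_pair
    anchors = {"AD": spec.anchor_AD, "MCI": spec.anchor_MCI, "HC": spec.anchor_HC}
    counter = 0
    speech_rows, eeg_rows, latent_rows = [], [], []
    for modality, dim, affine, sd, classes in (
        ("speech", spec.speech_dim, spec.speech_map, sd_speech, CLASSES),
        ("eeg", spec.eeg_dim, spec.eeg_map, sd_eeg, ("AD", "HC")),
    ):
        for cls in classes:
            base = _apply(affine, anchors[cls])
            for i in range(spec.n_per_class):
                counter += 1
                rng = np.random.default_rng(
                    np.random.SeedSequence(spec.seed, spawn_key=(counter,))
                )
                x = base + sd * rng.normal(0, 1, dim)
                row = dict(zip([f"f{k}" for k in range(dim)], x))
                row["label"] = cls
                (speech_rows if modality == "speech" else eeg_rows).append(row)
                lat = dict(zip([f"z{k}" for k in range(spec.latent_dim)], anchors[cls]))
                lat.update(label=cls, modality=modality)
                latent_rows.append(lat)
    return SyntheticCohort(
        speech_features=pd.DataFrame(speech_rows),
        eeg_features=pd.DataFrame(eeg_rows),
        true_latents=pd.DataFrame(latent_rows),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# band-structured EEG surrogates
# ---------------------------------------------------------------------------

#: One carrier per canonical band, placed inside its analysis interval so
#: band attribution by the frequency-domain extractor is unambiguous.
CARRIER_HZ = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 15.0, "gamma": 35.0}


@dataclass(frozen=True)
class BandPowerProfile:
    """Per-band carrier amplitudes (uV) and a group tag."""

    amplitudes: dict = field(
        default_factory=lambda: {b: 1.0 for b in CARRIER_HZ}
    )
    group: str = "HC-like"

    def __post_init__(self):
        amps = np.array([self.amplitudes.get(b, 0.0) for b in CARRIER_HZ])
        if np.any(amps < 0) or not np.any(amps > 0):
            raise InvalidSpecError("amplitudes must be >= 0 with at least one > 0")


def ad_profile() -> BandPowerProfile:
    """AD-like spectrum: delta/theta elevated, alpha suppressed."""
    return BandPowerProfile(
        {"delta": 2.0, "theta": 1.5, "alpha": 0.5, "beta": 0.4, "gamma": 0.2},
        group="AD-like",
    )


def hc_profile() -> BandPowerProfile:
    """HC-like spectrum: alpha-dominant resting rhythm."""
    return BandPowerProfile(
        {"delta": 0.8, "theta": 0.8, "alpha": 2.0, "beta": 0.6, "gamma": 0.3},
        group="HC-like",
    )


def generate_band_structured_eeg(
    profile: BandPowerProfile,
    n_channels: int = 19,
    fs: float = 500.0,
    duration: float = 10.0,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> EEGRecording:
    """Sum of band-limited sinusoids plus white noise, per channel.

    Each channel carries one sinusoid per band (amplitude from the
    profile, phase uniform on [0, 2*pi) per channel per band) plus
    Gaussian white noise. Deterministic under ``seed``.
    """
    if duration < 4.0:
        raise InvalidSpecError("duration must be >= 4 s for the lowest band")
    if fs <= 2 * max(CARRIER_HZ.values()):
        raise InvalidSpecError("fs must exceed twice the highest carrier frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    data = np.zeros((n_channels, n))
    for band, f in CARRIER_HZ.items():
        amp = profile.amplitudes.get(band, 0.0)
        phases = rng.uniform(0, 2 * np.pi, n_channels)
        if amp > 0:
            data += amp * np.sin(2 * np.pi * f * t[None, :] + phases[:, None])
    if noise_sd > 0:
        data += noise_sd * rng.normal(0, 1, data.shape)
    names = CHANNELS_1020 if n_channels == 19 else tuple(
        f"ch{i}" for i in range(n_channels)
    )
    return EEGRecording(
        data=data, fs=fs, channel_names=names,
        subject_id=f"synthetic-{profile.group}-{seed}",
        label="AD" if profile.group.startswith("AD") else "HC",
    )
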