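"""Sample entropy and multiscale entropy (MSE) of EEG channels.

Sample entropy SampEn(m, r) = -ln(A/B), where B counts pairs of m-length
templates within Chebyshev tolerance r (strict inequality, self-matches
excluded) and A counts the same pairs extended to length m+1. MSE applies
SampEn to coarse-grained (non-overlapping window-averaged) versions of
the series over scale factors 1..20, with r fixed per channel from the
standard deviation of the original (scale-1) series, so the tolerance is
commensurate across scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import FeatureVector
from .recording import EEGRecording

__all__ = [
    "SampEnParams",
    "DegenerateSeriesError",
    "coarse_grain",
    "sample_entropy",
    "multiscale_entropy",
]


class DegenerateSeriesError(ValueError):
    """Raised when template matching degenerates (A or B is zero)."""


@dataclass(frozen=True)
class SampEnParams:
    """Embedding dimension, tolerance multiplier and scale range for MSE."""

    m: int = 2
    r_factor: float = 0.15
    scales: tuple[int, ...] = tuple(range(1, 21))
    on_degenerate: str = "fail"  # "fail" | "sentinel"

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if not self.scales or min(self.scales) < 1:
            raise ValueError("scales must be a nonempty set of integers >= 1")
        if self.on_degenerate not in ("fail", "sentinel"):
            raise ValueError("on_degenerate must be 'fail' or 'sentinel'")


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Average non-overlapping windows of length tau; output length floor(N/tau)."""
    x = np.asarray(x, dtype=np.float64)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    n = len(x) // tau
    if n == 0:
        raise ValueError(f"series of length {len(x)} too short for tau={tau}")
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def _count_pairs(x: np.ndarray, length: int, r: float, n_templates: int) -> int:
    """Number of template pairs (i<j) over the first `n_templates` windows of
    the given length whose Chebyshev distance is strictly below r."""
    w = sliding_window_view(x, length)[:n_templates]
    # pairwise Chebyshev distance via broadcasting; fine at the series
    # lengths MSE operates on (N/tau <= a few thousand)
    d = np.abs(w[:, None, :] - w[None, :, :]).max(axis=2)
    iu = np.triu_indices(n_templates, k=1)
    return int((d[iu] < r).sum())


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = -ln(A/B) with strict Chebyshev matching.

    If r is None it defaults to 0.15 times the series standard deviation.
    Raises DegenerateSeriesError when no matches exist at either length
    (e.g. a constant series collapses the tolerance).
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < m + 2:
        raise ValueError(f"series too short for m={m}")
    if r is None:
        r = 0.15 * x.std()
    if r <= 0:
        raise DegenerateSeriesError("tolerance r collapsed to zero")
    n_templates = len(x) - m  # same template count at both lengths
    b = _count_pairs(x, m, r, n_templates)
    a = _count_pairs(x, m + 1, r, n_templates)
    if b == 0 or a == 0:
        raise DegenerateSeriesError(f"no template matches (A={a}, B={b})")
    return float(-np.log(a / b))


def multiscale_entropy(
    rec: EEGRecording, params: SampEnParams = SampEnParams()
) -> FeatureVector:
    """SampEn of each channel's coarse-grained series at every scale.

    The tolerance r is fixed per channel as r_factor times the standard
    deviation of the original series. Output is channel-major with length
    n_channels * n_scales (380 for 19 channels, scales 1..20).
    """
    max_scale = max(params.scales)
    if rec.n_samples < max_scale * (params.m + 2):
        raise ValueError("recording too short for the requested scales")
    values, names = [], []
    for ch, name in zip(rec.data, rec.channel_names):
        r = params.r_factor * ch.std()
        for tau in params.scales:
            y = coarse_grain(ch, tau)
            try:
                se = sample_entropy(y, params.m, r)
            except DegenerateSeriesError:
                if params.on_degenerate == "fail":
                    raise
                se = np.nan
            values.append(se)
            names.append(f"mse_s{tau}_{name}")
    return FeatureVector(np.array(values), names, "mse", rec.subject_id)
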