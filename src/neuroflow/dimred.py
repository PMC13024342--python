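"""Dimensionality reduction: PCA by cumulative explained variance, and a
masked autoencoder (MAE) scored only on masked entries.

PCA retains the smallest number of components whose cumulative explained
variance ratio reaches the threshold (default 95 %). The MAE masks a
random 30 % of the entries of each input vector per batch, zero-fills
them at the encoder input, reconstructs through a 256-unit bottlenecked
encoder/decoder, and computes the MSE over the masked positions only;
training early-stops when the validation masked loss fails to improve
for 5 consecutive epochs.

The reduction presets used downstream (e.g. joint EEG features -> 32,
speech feature set -> 128) are plain arguments here; callers encode the
study configuration, not this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import nn

__all__ = [
    "PCAModel",
    "pca_fit",
    "MAEConfig",
    "MAEModel",
    "mae_train",
    "mae_encode",
    "REDUCTION_PRESETS",
]

#: Reference reduction map of the study pipeline: feature set ->
#: (method, input dim, reduced dim). PCA dims arise from the 95 % variance
#: rule on the study data; MAE dims were selected by downstream accuracy.
REDUCTION_PRESETS = {
    "time": ("pca", 133, 13),
    "frequency": ("pca", 190, 8),
    "timefreq": ("pca", 342, 37),
    "mse": ("pca", 380, 8),
    "psd_maps": ("mae", 1280, 16),
    "compare": ("mae", 6373, 32),
    "hubert": ("mae", 1024, 32),
    "tfidf": ("pca", 1000, 32),
    "bert": ("mae", 768, 64),
}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Fitted PCA: component matrix, means, ratios, retained count k."""

    components: np.ndarray
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int

    def transform(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = np.asarray(table, dtype=np.float64)
        return (x - self.mean) @ self.components[: self.k].T

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return z @ self.components[: self.k] + self.mean


def pca_fit(table: pd.DataFrame | np.ndarray, threshold: float = 0.95) -> PCAModel:
    """Fit PCA keeping the minimal k with cumulative variance >= threshold."""
    x = np.asarray(table, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    full = PCA(svd_solver="full").fit(x)
    ratios = full.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    return PCAModel(
        components=full.components_,
        mean=full.mean_,
        explained_variance_ratio=ratios,
        k=k,
    )


# ---------------------------------------------------------------------------
# masked autoencoder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MAEConfig:
    latent_dim: int = 32
    hidden: int = 256
    mask_ratio: float = 0.3
    dropout: float = 0.2
    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    weight_decay: float = 1e-4
    patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.mask_ratio < 1:
            raise ValueError("mask_ratio must lie in (0, 1)")


class _MAENet(nn.Module):
    def __init__(self, d_in: int, cfg: MAEConfig, rng: np.random.Generator):
        super().__init__()
        self.enc1 = nn.Linear(d_in, cfg.hidden, rng)
        self.enc_bn = nn.BatchNorm1d(cfg.hidden)
        self.enc_drop = nn.Dropout(cfg.dropout, rng)
        self.enc2 = nn.Linear(cfg.hidden, cfg.latent_dim, rng)
        self.dec1 = nn.Linear(cfg.latent_dim, cfg.hidden, rng)
        self.dec_bn = nn.BatchNorm1d(cfg.hidden)
        self.dec_drop = nn.Dropout(cfg.dropout, rng)
        self.dec2 = nn.Linear(cfg.hidden, d_in, rng)

    def encode(self, x: nn.Tensor) -> nn.Tensor:
        h = self.enc_drop(self.enc_bn(self.enc1(x)).relu())
        return self.enc2(h)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        z = self.encode(x)
        h = self.dec_drop(self.dec_bn(self.dec1(z)).relu())
        return self.dec2(h)


@dataclass
class MAEModel:
    """Trained MAE with its masked-loss history and stopping epoch."""

    net: _MAENet = field(repr=False)
    cfg: MAEConfig
    d_in: int
    history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


def masked_mse(recon: nn.Tensor, target: np.ndarray, mask: np.ndarray) -> nn.Tensor:
    """MSE restricted to masked positions (mask==1). Unmasked entries of the
    reconstruction cannot influence the value."""
    n_masked = max(mask.sum(), 1.0)
    diff = (recon - nn.Tensor(target)) * nn.Tensor(mask)
    return (diff**2).sum() * (1.0 / n_masked)


def mae_train(
    table: pd.DataFrame | np.ndarray,
    cfg: MAEConfig = MAEConfig(),
    validation: pd.DataFrame | np.ndarray | None = None,
) -> MAEModel:
    """Train the masked autoencoder; deterministic under ``cfg.seed``.

    If no validation table is given, a fraction of the rows (``val_fraction``)
    is held out for early stopping.
    """
    x = np.asarray(table, dtype=np.float64)
    n, d = x.shape
    if cfg.latent_dim >= d:
        raise ValueError("latent_dim must be smaller than the input dimension")
    rng = np.random.default_rng(cfg.seed)
    if validation is None:
        n_val = max(1, int(round(cfg.val_fraction * n)))
        perm = rng.permutation(n)
        x_val, x_train = x[perm[:n_val]], x[perm[n_val:]]
    else:
        x_train, x_val = x, np.asarray(validation, dtype=np.float64)
    if len(x_train) < 2:
        raise ValueError("not enough training rows")

    net = _MAENet(d, cfg, np.random.default_rng(rng.integers(2**31)))
    opt = nn.Adam(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    model = MAEModel(net=net, cfg=cfg, d_in=d)
    best_val, best_state, wait = np.inf, None, 0
    # fixed validation mask: the early-stopping signal is not resampled
    val_mask = (rng.random(x_val.shape) < cfg.mask_ratio).astype(np.float64)

    def masked_pass(batch: np.ndarray, train: bool, mask=None) -> nn.Tensor:
        if mask is None:
            mask = (rng.random(batch.shape) < cfg.mask_ratio).astype(np.float64)
        inp = nn.Tensor(batch * (1 - mask))
        net.train(train)
        return masked_mse(net(inp), batch, mask)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(x_train), cfg.batch_size):
            batch = x_train[order[start : start + cfg.batch_size]]
            if len(batch) < 2:
                continue  # BatchNorm needs >1 row
            loss = masked_pass(batch, train=True)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        model.history.append(float(np.mean(losses)))
        val_loss = masked_pass(x_val, train=False, mask=val_mask).item()
        model.val_history.append(val_loss)
        model.stopped_epoch = epoch + 1
        if val_loss < best_val - 1e-12:
            best_val, best_state, wait = val_loss, net.state_dict(), 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    return model


def mae_encode(model: MAEModel, table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Deterministic latent encoding (dropout disabled, running BN stats)."""
    x = np.asarray(table, dtype=np.float64)
    if x.shape[1] != model.d_in:
        raise ValueError(
            f"input has {x.shape[1]} columns, model expects {model.d_in}"
        )
    model.net.eval()
    return model.net.encode(nn.Tensor(x)).data
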