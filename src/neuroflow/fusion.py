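"""Two-stream fusion classifier with squeeze-and-excitation (SE) attention.

Two branch encoders map the speech features and the generated EEG-like
latent to 128 dimensions each; the concatenated 256-dim vector is
re-weighted channel-wise by an SE block (bottleneck ratio 8, i.e.
256 -> 32 -> 256 with a sigmoid gate) and classified by a 64-unit MLP
head. For flat feature vectors the SE "squeeze" over a singleton spatial
axis is the identity, so the gate is computed directly from the 256
channels. Configurable variants cover the ablation modes: a single
stream, or plain concatenation without SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .alignment import CLASS_ORDER, _CLS_IDX

__all__ = ["FusionConfig", "SEModule", "FusionNet", "se_reweight", "train_fusion"]


@dataclass(frozen=True)
class FusionConfig:
    branch_dim: int = 128
    se_ratio: int = 8
    mlp_hidden: int = 64
    dropout: float = 0.3
    use_se: bool = True
    batch_size: int = 16
    lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 200
    patience: int = 20
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if (2 * self.branch_dim) % self.se_ratio != 0:
            raise ValueError("se_ratio must divide the concatenated width")


class SEModule(nn.Module):
    """Channel attention: weights = sigmoid(W2 relu(W1 f)); output = weights*f."""

    def __init__(self, width: int, ratio: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(width, width // ratio, rng)
        self.fc2 = nn.Linear(width // ratio, width, rng)
        self.width = width

    def forward(self, f: nn.Tensor) -> nn.Tensor:
        if f.shape[1] != self.width:
            raise ValueError(f"expected width {self.width}, got {f.shape[1]}")
        w = self.fc2(self.fc1(f).relu()).sigmoid()
        return w * f

    def weights(self, f: np.ndarray) -> np.ndarray:
        return self.fc2(self.fc1(nn.Tensor(np.atleast_2d(f))).relu()).sigmoid().data


def se_reweight(f: np.ndarray, se: SEModule) -> np.ndarray:
    """Functional form of the SE gate on a plain array."""
    f = np.atleast_2d(np.asarray(f, dtype=np.float64))
    return se.weights(f) * f


class _Branch(nn.Module):
    def __init__(self, d_in, d_out, dropout, rng):
        super().__init__()
        self.fc = nn.Linear(d_in, d_out, rng)
        self.bn = nn.BatchNorm1d(d_out)
        self.drop = nn.Dropout(dropout, rng)

    def forward(self, x):
        return self.drop(self.bn(self.fc(x)).relu())


class FusionNet(nn.Module):
    """Branch encoders -> concat -> (SE) -> MLP head -> 3-class probabilities.

    With ``d_latent=None`` the network degenerates to a single-stream
    classifier over the first input (used by the latent-only ablation).
    """

    def __init__(self, d_speech: int, d_latent: int | None, cfg: FusionConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.branch_s = _Branch(d_speech, cfg.branch_dim, cfg.dropout, rng)
        self.branch_l = (
            _Branch(d_latent, cfg.branch_dim, cfg.dropout, rng)
            if d_latent is not None
            else None
        )
        width = cfg.branch_dim * (2 if d_latent is not None else 1)
        self.concat_width = width
        self.se = SEModule(width, cfg.se_ratio, rng) if cfg.use_se else None
        self.fc1 = nn.Linear(width, cfg.mlp_hidden, rng)
        self.bn = nn.BatchNorm1d(cfg.mlp_hidden)
        self.drop = nn.Dropout(cfg.dropout, rng)
        self.fc2 = nn.Linear(cfg.mlp_hidden, 3, rng)

    def logits(self, x_s: nn.Tensor, x_l: nn.Tensor | None) -> nn.Tensor:
        h = self.branch_s(x_s)
        if self.branch_l is not None:
            if x_l is None:
                raise ValueError("second stream required by this network")
            h = nn.concat([h, self.branch_l(x_l)], axis=1)
        if self.se is not None:
            h = self.se(h)
        return self.fc2(self.drop(self.bn(self.fc1(h)).relu()))

    def forward(self, x_s, x_l=None) -> np.ndarray:
        """Class probabilities (rows sum to 1)."""
        xs = nn.Tensor(np.atleast_2d(np.asarray(x_s, dtype=np.float64)))
        xl = (
            nn.Tensor(np.atleast_2d(np.asarray(x_l, dtype=np.float64)))
            if x_l is not None
            else None
        )
        logits = self.logits(xs, xl).data
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x_s, x_l=None) -> np.ndarray:
        p = self.forward(x_s, x_l)
        return np.array([CLASS_ORDER[i] for i in p.argmax(axis=1)])


def train_fusion(
    x_speech: np.ndarray,
    x_latent: np.ndarray | None,
    y: np.ndarray,
    cfg: FusionConfig = FusionConfig(),
    val: tuple | None = None,
) -> FusionNet:
    """Train the fusion head with Adam, plateau lr halving and early stopping.

    ``val`` is an optional ``(x_speech, x_latent, y)`` triple monitored for
    early stopping (patience 20) and learning-rate reduction; without it a
    10 % split of the training rows is held out.
    """
    x_speech = np.asarray(x_speech, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed + 7)
    if val is None:
        n_val = max(1, int(round(0.1 * len(y))))
        perm = rng.permutation(len(y))
        vi, ti = perm[:n_val], perm[n_val:]
        val = (
            x_speech[vi],
            x_latent[vi] if x_latent is not None else None,
            y[vi],
        )
        x_speech, y = x_speech[ti], y[ti]
        x_latent = x_latent[ti] if x_latent is not None else None

    net = FusionNet(
        x_speech.shape[1],
        x_latent.shape[1] if x_latent is not None else None,
        cfg,
    )
    opt = nn.Adam(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    y_idx = np.array([_CLS_IDX[c] for c in y])
    yv_idx = np.array([_CLS_IDX[c] for c in val[2]])
    best, best_state, wait, plateau_wait = np.inf, None, 0, 0
    lr = cfg.lr
    for _ in range(cfg.epochs):
        order = rng.permutation(len(y))
        net.train()
        for start in range(0, len(y), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            if len(sel) < 2:
                continue
            xs = nn.Tensor(x_speech[sel])
            xl = nn.Tensor(x_latent[sel]) if x_latent is not None else None
            loss = nn.softmax_cross_entropy(net.logits(xs, xl), y_idx[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
        net.eval()
        xvs = nn.Tensor(val[0])
        xvl = nn.Tensor(val[1]) if val[1] is not None else None
        val_loss = nn.softmax_cross_entropy(net.logits(xvs, xvl), yv_idx).item()
        if val_loss < best - 1e-12:
            best, best_state, wait, plateau_wait = val_loss, net.state_dict(), 0, 0
        else:
            wait += 1
            plateau_wait += 1
            if plateau_wait >= cfg.plateau_patience:
                lr *= cfg.plateau_factor
                opt.lr = lr
                plateau_wait = 0
            if wait >= cfg.patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    return net
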