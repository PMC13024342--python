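"""Conditional Rectified Flow between Gaussian noise and aligned EEG latents.

The model learns a velocity field v(x_t, t, c) along straight-line paths
x_t = t*x1 + (1-t)*x0 between standard-normal noise x0 and data x1,
conditioned on an aligned speech latent c. Training minimizes the
flow-matching objective — the mean squared error between the predicted
velocity and the constant path derivative (x1 - x0). Sampling integrates
the learned ODE dx = v dt with a few Euler steps (N = 10 by default);
the straight-path construction is what makes so few steps sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "VelocityNetConfig",
    "FlowTrainConfig",
    "FlowModel",
    "interpolate_state",
    "flow_matching_loss",
    "euler_sample",
    "train_flow",
    "generate_for_table",
]


@dataclass(frozen=True)
class VelocityNetConfig:
    state_dim: int = 128
    cond_dim: int = 128
    hidden: int = 256
    n_res_blocks: int = 3


@dataclass(frozen=True)
class FlowTrainConfig:
    epochs: int = 500
    lr: float = 1e-3
    batch_size: int = 32
    n_steps: int = 10  # Euler steps at sampling time
    seed: int = 0


class _ResBlock(nn.Module):
    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(width, width, rng)
        self.fc2 = nn.Linear(width, width, rng)
        self.norm = nn.LayerNorm(width)

    def forward(self, h: nn.Tensor) -> nn.Tensor:
        return self.norm(h + self.fc2(self.fc1(h).silu()).silu())


class VelocityNet(nn.Module):
    """v(x_t, t, c): state/time/condition embeddings summed, then residual
    blocks with layer normalization, then a linear output projection."""

    def __init__(self, cfg: VelocityNetConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        h = cfg.hidden
        self.x_proj = nn.Linear(cfg.state_dim, h, rng)
        self.t_fc1 = nn.Linear(1, h, rng)
        self.t_fc2 = nn.Linear(h, h, rng)
        self.c_fc1 = nn.Linear(cfg.cond_dim, h, rng)
        self.c_fc2 = nn.Linear(h, h, rng)
        self.blocks = [_ResBlock(h, rng) for _ in range(cfg.n_res_blocks)]
        self.out = nn.Linear(h, cfg.state_dim, rng)

    def forward(self, x: nn.Tensor, t: np.ndarray, c: nn.Tensor) -> nn.Tensor:
        t = np.asarray(t, dtype=np.float64).reshape(-1, 1)
        t_emb = self.t_fc2(self.t_fc1(nn.Tensor(t)).silu()).silu()
        c_emb = self.c_fc2(self.c_fc1(c).silu()).silu()
        h = self.x_proj(x) + t_emb + c_emb
        for blk in self.blocks:
            h = blk(h)
        return self.out(h)

    def velocity(self, x: np.ndarray, t: float | np.ndarray, c: np.ndarray) -> np.ndarray:
        """Inference-time velocity on plain arrays."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        c = np.atleast_2d(np.asarray(c, dtype=np.float64))
        t = np.broadcast_to(np.asarray(t, dtype=np.float64), (x.shape[0],))
        return self.forward(nn.Tensor(x), t, nn.Tensor(c)).data


@dataclass
class FlowModel:
    net: VelocityNet = field(repr=False)
    cfg: FlowTrainConfig
    history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# the flow primitives
# ---------------------------------------------------------------------------


def interpolate_state(x0: np.ndarray, x1: np.ndarray, t: float) -> np.ndarray:
    """Straight-line interpolation x_t = t*x1 + (1-t)*x0."""
    if not 0 <= t <= 1:
        raise ValueError("t must lie in [0, 1]")
    x0, x1 = np.asarray(x0, dtype=np.float64), np.asarray(x1, dtype=np.float64)
    if x0.shape != x1.shape:
        raise ValueError("x0 and x1 must have equal shapes")
    return t * x1 + (1 - t) * x0


def flow_matching_loss(v_pred, x0: np.ndarray, x1: np.ndarray):
    """Mean over batch and dimensions of |v_pred - (x1 - x0)|^2.

    The paper's squared Euclidean norm leaves the reduction unstated; this
    implementation divides by batch * dim (so a per-coordinate offset of
    2 in 2-D gives 2.0). Multiply by dim to recover the per-sample
    squared-norm convention.
    """
    target = np.asarray(x1, dtype=np.float64) - np.asarray(x0, dtype=np.float64)
    if isinstance(v_pred, nn.Tensor):
        return ((v_pred - nn.Tensor(target)) ** 2).mean()
    return float(((np.asarray(v_pred) - target) ** 2).mean())


def euler_sample(
    model: FlowModel | VelocityNet,
    c: np.ndarray,
    x0: np.ndarray,
    n_steps: int | None = None,
) -> np.ndarray:
    """Integrate dx = v(x, t, c) dt with N explicit Euler steps.

    x_{k+1} = x_k + (1/N) * v(x_k, k/N, c) for k = 0..N-1. Deterministic
    given the model, condition and starting point.
    """
    net = model.net if isinstance(model, FlowModel) else model
    if n_steps is None:
        n_steps = model.cfg.n_steps if isinstance(model, FlowModel) else 10
    if n_steps < 1:
        raise ValueError("need at least one Euler step")
    net.eval()
    x = np.atleast_2d(np.asarray(x0, dtype=np.float64)).copy()
    squeeze = np.asarray(x0).ndim == 1
    c = np.atleast_2d(np.asarray(c, dtype=np.float64))
    for k in range(n_steps):
        x = x + net.velocity(x, k / n_steps, c) / n_steps
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite state at Euler step {k}")
    return x[0] if squeeze else x


# ---------------------------------------------------------------------------
# training and generation
# ---------------------------------------------------------------------------


def train_flow(
    speech_latents: np.ndarray,
    speech_labels: np.ndarray,
    eeg_latents: np.ndarray,
    eeg_labels: np.ndarray,
    net_cfg: VelocityNetConfig | None = None,
    cfg: FlowTrainConfig = FlowTrainConfig(),
) -> FlowModel:
    """Fit the conditional velocity field on aligned latent tables.

    Each epoch pairs every EEG latent (the transport target x1) with a
    random same-class speech latent as the condition c; t ~ Uniform[0,1]
    and x0 ~ N(0, I) are drawn fresh per batch from a stream split off
    the training seed. Deterministic under ``cfg.seed``.
    """
    speech_latents = np.asarray(speech_latents, dtype=np.float64)
    eeg_latents = np.asarray(eeg_latents, dtype=np.float64)
    speech_labels, eeg_labels = np.asarray(speech_labels), np.asarray(eeg_labels)
    common = set(speech_labels) & set(eeg_labels)
    if not common:
        raise ValueError("no classes shared between speech and EEG latents")
    if net_cfg is None:
        net_cfg = VelocityNetConfig(
            state_dim=eeg_latents.shape[1], cond_dim=speech_latents.shape[1]
        )
    net = VelocityNet(net_cfg, seed=cfg.seed)
    opt = nn.Adam(net.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)  # t / x0 / pairing stream
    model = FlowModel(net=net, cfg=cfg)

    by_class = {
        c: np.flatnonzero(speech_labels == c) for c in common
    }
    usable = np.flatnonzero(np.isin(eeg_labels, list(common)))
    for _ in range(cfg.epochs):
        cond_idx = np.array(
            [rng.choice(by_class[eeg_labels[i]]) for i in usable]
        )
        order = rng.permutation(len(usable))
        losses = []
        for start in range(0, len(usable), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            x1 = eeg_latents[usable[sel]]
            c = speech_latents[cond_idx[sel]]
            t = rng.uniform(0, 1, len(sel))
            x0 = rng.normal(0, 1, x1.shape)
            xt = t[:, None] * x1 + (1 - t[:, None]) * x0
            net.train()
            v = net(nn.Tensor(xt), t, nn.Tensor(c))
            loss = flow_matching_loss(v, x0, x1)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        model.history.append(float(np.mean(losses)))
    net.eval()
    return model


def generate_for_table(
    model: FlowModel,
    speech_latents: np.ndarray | pd.DataFrame,
    seed: int = 0,
    n_steps: int | None = None,
) -> np.ndarray:
    """One generated EEG-like latent per speech row (x0 ~ N(0,I) under seed)."""
    if isinstance(speech_latents, pd.DataFrame):
        speech_latents = speech_latents.drop(
            columns="label", errors="ignore"
        ).to_numpy(dtype=np.float64)
    speech_latents = np.asarray(speech_latents, dtype=np.float64)
    if speech_latents.shape[1] != model.net.cfg.cond_dim:
        raise ValueError(
            f"condition width {speech_latents.shape[1]} != "
            f"cond_dim {model.net.cfg.cond_dim}"
        )
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0, 1, (len(speech_latents), model.net.cfg.state_dim))
    return euler_sample(model, speech_latents, x0, n_steps)
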