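"""Cross-modal feature alignment into a shared 128-dim subspace.

Two modality encoders (speech, EEG) map heterogeneous feature tables into
one latent space, trained jointly with four losses:

* weighted cross-entropy classification (3 classes, weights = reciprocal
  class proportions of the speech training fold);
* center loss — mean Euclidean distance of latents to their class
  centers (first power), with the centers updated by a dedicated SGD
  optimizer rather than the main Adam step;
* consistency loss — MSE between same-class mean latents of the two
  modalities, triggered only for classes present in both modality
  batches and never for MCI (EEG has no MCI data);
* domain-adversarial loss — a binary modality discriminator behind a
  gradient-reversal layer whose factor ramps from 0 to a ceiling
  (default 0.1) over training.

Because EEG cohorts lack MCI recordings, pseudo-MCI anchors are
synthesized per batch by convex interpolation between same-batch AD and
HC latents with a Beta-distributed mixing coefficient; they act as a
spatial regularizer (down-weighted classification toward the MCI label
and center attraction toward the MCI center).

Total loss: L = L_cls + lam_center*L_center + lam_domain*L_domain
+ lam_consist*L_consist (default weights 0.05 / 0.1 / 5.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "CLASS_ORDER",
    "AlignmentConfig",
    "AlignmentModel",
    "LossReport",
    "weighted_cross_entropy",
    "center_loss",
    "consistency_loss",
    "pseudo_mci",
    "total_loss",
    "grl_schedule",
    "paired_batches",
    "train_alignment",
    "encode",
]

CLASS_ORDER = ("AD", "HC", "MCI")
_CLS_IDX = {c: i for i, c in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class AlignmentConfig:
    subspace_dim: int = 128
    speech_hidden: int = 256
    eeg_hidden: int | None = None  # None: 64 for narrow input, 512 for wide
    dropout: float = 0.2
    lambda_center: float = 0.05
    lambda_domain: float = 0.1
    lambda_consist: float = 5.0
    grl_ceiling: float = 0.1
    grl_ramp: str = "linear"  # or "sigmoid" (DANN-style)
    lr: float = 1e-3
    weight_decay: float = 1e-3
    lr_step: int = 30
    lr_gamma: float = 0.5
    epochs: int = 200
    batch_size: int = 64
    beta_a: float = 2.0
    beta_b: float = 2.0
    center_lr: float = 0.5
    pseudo_cls_weight: float = 0.5  # down-weighting of pseudo-MCI in L_cls
    use_pseudo_in_cls: bool = True
    use_pseudo_in_center: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda_center, self.lambda_domain, self.lambda_consist) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.subspace_dim <= 0:
            raise ValueError("subspace_dim must be positive")
        if min(self.beta_a, self.beta_b) <= 0:
            raise ValueError("Beta parameters must be positive")

    def resolve_eeg_hidden(self, d_eeg: int) -> int:
        if self.eeg_hidden is not None:
            return self.eeg_hidden
        return 64 if d_eeg <= 128 else 512


@dataclass
class LossReport:
    """Per-step loss components; total satisfies the weighted-sum identity."""

    cls: float
    center: float
    domain: float
    consist: float
    total: float
    consistency_skipped: bool = False


class _Encoder(nn.Module):
    """Two fully connected layers with batch-norm, ReLU and dropout between."""

    def __init__(self, d_in, hidden, d_out, dropout, rng):
        super().__init__()
        self.fc1 = nn.Linear(d_in, hidden, rng)
        self.bn = nn.BatchNorm1d(hidden)
        self.drop = nn.Dropout(dropout, rng)
        self.fc2 = nn.Linear(hidden, d_out, rng)
        self.d_in = d_in

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc2(self.drop(self.bn(self.fc1(x)).relu()))


class AlignmentModel(nn.Module):
    """Speech/EEG encoders + shared classifier + domain discriminator + centers."""

    def __init__(self, d_speech: int, d_eeg: int, cfg: AlignmentConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.speech_encoder = _Encoder(
            d_speech, cfg.speech_hidden, cfg.subspace_dim, cfg.dropout, rng
        )
        self.eeg_encoder = _Encoder(
            d_eeg, cfg.resolve_eeg_hidden(d_eeg), cfg.subspace_dim, cfg.dropout, rng
        )
        self.classifier = nn.Linear(cfg.subspace_dim, 3, rng)
        self.disc1 = nn.Linear(cfg.subspace_dim, 64, rng)
        self.disc2 = nn.Linear(64, 1, rng)
        # class centers live outside the main optimizer (separate SGD update)
        self.centers = nn.Tensor(np.zeros((3, cfg.subspace_dim)))

    def parameters(self):
        return [p for p in super().parameters() if p is not self.centers]

    def encode_batch(self, x: nn.Tensor, modality: str) -> nn.Tensor:
        enc = self.speech_encoder if modality == "speech" else self.eeg_encoder
        return enc(x)

    def discriminate(self, z: nn.Tensor, lam: float) -> nn.Tensor:
        h = self.disc1(nn.grad_reverse(z, lam)).relu()
        return self.disc2(h)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def class_proportions(labels: np.ndarray) -> dict[str, float]:
    labels = np.asarray(labels)
    return {c: float((labels == c).mean()) for c in CLASS_ORDER}


def weighted_cross_entropy(
    logits: nn.Tensor,
    labels: np.ndarray,
    proportions: dict[str, float],
    extra_sample_weight: np.ndarray | None = None,
) -> nn.Tensor:
    """Cross-entropy with per-class weight 1/proportion, batch-normalized."""
    labels = np.asarray(labels)
    missing = [c for c in np.unique(labels) if proportions.get(c, 0) <= 0]
    if missing:
        raise ValueError(f"no class proportion for {missing}")
    idx = np.array([_CLS_IDX[c] for c in labels])
    w = np.array([1.0 / proportions[c] for c in labels])
    if extra_sample_weight is not None:
        w = w * extra_sample_weight
    return nn.softmax_cross_entropy(logits, idx, w)


def center_loss(z: nn.Tensor, labels: np.ndarray, centers: nn.Tensor) -> nn.Tensor:
    """Mean Euclidean (first-power) distance of latents to their class center."""
    idx = np.array([_CLS_IDX[c] for c in np.asarray(labels)])
    onehot = np.zeros((len(idx), centers.shape[0]))
    onehot[np.arange(len(idx)), idx] = 1.0
    sel = nn.Tensor(onehot) @ centers
    d2 = ((z - sel) ** 2).sum(axis=1)
    return ((d2 + 1e-12) ** 0.5).mean()


def center_gradient(z: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Closed-form gradient of the (unweighted) center loss w.r.t. the centers."""
    idx = np.array([_CLS_IDX[c] for c in np.asarray(labels)])
    grad = np.zeros_like(centers)
    n = len(idx)
    for k in range(centers.shape[0]):
        mask = idx == k
        if not mask.any():
            continue
        diff = centers[k] - z[mask]
        dist = np.sqrt((diff**2).sum(axis=1) + 1e-12)
        grad[k] = (diff / dist[:, None]).sum(axis=0) / n
    return grad


def consistency_loss(
    z_speech: nn.Tensor,
    y_speech: np.ndarray,
    z_eeg: nn.Tensor,
    y_eeg: np.ndarray,
) -> tuple[nn.Tensor, bool]:
    """MSE between same-class mean latents of the two modalities.

    Averaged over classes present in both batches; MCI never contributes.
    Returns (loss, skipped) where skipped is True when no class overlaps.
    """
    y_speech, y_eeg = np.asarray(y_speech), np.asarray(y_eeg)
    shared = sorted(
        (set(y_speech) & set(y_eeg)) - {"MCI"},
        key=CLASS_ORDER.index,
    )
    if not shared or z_eeg.shape[0] == 0 or z_speech.shape[0] == 0:
        return nn.Tensor(0.0), True
    terms = []
    for c in shared:
        ms, me = y_speech == c, y_eeg == c
        mean_s = (nn.Tensor(ms.astype(float)[None, :] / ms.sum()) @ z_speech)
        mean_e = (nn.Tensor(me.astype(float)[None, :] / me.sum()) @ z_eeg)
        terms.append(((mean_s - mean_e) ** 2).mean())
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms)), False


def pseudo_mci(z_ad, z_hc, alpha: float):
    """Convex interpolation z = alpha*z_AD + (1-alpha)*z_HC (exact)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    if isinstance(z_ad, nn.Tensor):
        return z_ad * alpha + z_hc * (1 - alpha)
    return alpha * np.asarray(z_ad) + (1 - alpha) * np.asarray(z_hc)


def total_loss(
    l_cls: nn.Tensor, l_center: nn.Tensor, l_domain: nn.Tensor,
    l_consist: nn.Tensor, cfg: AlignmentConfig,
) -> nn.Tensor:
    return (
        l_cls
        + cfg.lambda_center * l_center
        + cfg.lambda_domain * l_domain
        + cfg.lambda_consist * l_consist
    )


def grl_schedule(epoch: int, epochs: int, cfg: AlignmentConfig) -> float:
    """Adaptation factor: 0 at training start, ceiling at the final epoch."""
    frac = epoch / max(epochs - 1, 1)
    if cfg.grl_ramp == "sigmoid":
        return cfg.grl_ceiling * (2.0 / (1.0 + np.exp(-10 * frac)) - 1.0)
    return cfg.grl_ceiling * frac


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------


def paired_batches(
    n_speech: int, n_eeg: int, batch_size: int, rng: np.random.Generator
):
    """Asymmetric parallel loading: one pass over the speech rows (shuffled),
    EEG indices cycled through an independently reshuffled iterator."""
    speech_order = rng.permutation(n_speech)
    eeg_order = rng.permutation(n_eeg)
    ptr = 0
    for start in range(0, n_speech, batch_size):
        sb = speech_order[start : start + batch_size]
        take = min(batch_size, n_eeg)
        eb = []
        while len(eb) < take:
            if ptr >= n_eeg:
                eeg_order = rng.permutation(n_eeg)
                ptr = 0
            eb.append(eeg_order[ptr])
            ptr += 1
        yield sb, np.array(eb)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y = table["label"].to_numpy()
    x = table.drop(columns="label").to_numpy(dtype=np.float64)
    return x, y


def train_alignment(
    speech_table: pd.DataFrame,
    eeg_table: pd.DataFrame,
    cfg: AlignmentConfig = AlignmentConfig(),
) -> tuple[AlignmentModel, list[LossReport]]:
    """Train the alignment network; deterministic under ``cfg.seed``.

    ``speech_table`` must contain all three classes; ``eeg_table`` only AD
    and HC. Returns the trained model and the per-epoch loss history.
    """
    xs, ys = _split_xy(speech_table)
    xe, ye = _split_xy(eeg_table)
    if not set(CLASS_ORDER) <= set(ys):
        raise ValueError("speech training data must contain AD, HC and MCI")
    if not set(ye) <= {"AD", "HC"}:
        raise ValueError("EEG labels must be AD/HC only")

    cfg_props = class_proportions(ys)  # speech fold proportions only
    model = AlignmentModel(xs.shape[1], xe.shape[1], cfg)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[LossReport] = []

    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * cfg.lr_gamma ** (epoch // cfg.lr_step)
        lam = grl_schedule(epoch, cfg.epochs, cfg)
        ep = dict(cls=[], center=[], domain=[], consist=[], total=[])
        skipped_any = False
        for sb, eb in paired_batches(len(xs), len(xe), cfg.batch_size, rng):
            model.train()
            zs = model.encode_batch(nn.Tensor(xs[sb]), "speech")
            ze = model.encode_batch(nn.Tensor(xe[eb]), "eeg")
            ysb, yeb = ys[sb], ye[eb]

            # pseudo-MCI anchors from same-batch AD/HC latents (both modalities)
            z_all = nn.concat([zs, ze], axis=0)
            y_all = np.concatenate([ysb, yeb])
            ad_idx = np.flatnonzero(y_all == "AD")
            hc_idx = np.flatnonzero(y_all == "HC")
            n_pseudo = min(len(ad_idx), len(hc_idx))
            pseudo = None
            if n_pseudo > 0:
                pick_ad = rng.choice(ad_idx, n_pseudo, replace=False)
                pick_hc = rng.choice(hc_idx, n_pseudo, replace=False)
                sel_ad = np.zeros((n_pseudo, z_all.shape[0]))
                sel_hc = np.zeros((n_pseudo, z_all.shape[0]))
                sel_ad[np.arange(n_pseudo), pick_ad] = 1.0
                sel_hc[np.arange(n_pseudo), pick_hc] = 1.0
                alphas = rng.beta(cfg.beta_a, cfg.beta_b, (n_pseudo, 1))
                alphas = np.clip(alphas, 1e-6, 1 - 1e-6)
                pseudo = (nn.Tensor(alphas) * (nn.Tensor(sel_ad) @ z_all)
                          + nn.Tensor(1 - alphas) * (nn.Tensor(sel_hc) @ z_all))

            # classification loss over labeled latents (+ down-weighted pseudo)
            cls_z, cls_y, extra_w = z_all, y_all, np.ones(len(y_all))
            if pseudo is not None and cfg.use_pseudo_in_cls:
                cls_z = nn.concat([z_all, pseudo], axis=0)
                cls_y = np.concatenate([y_all, ["MCI"] * n_pseudo])
                extra_w = np.concatenate(
                    [extra_w, np.full(n_pseudo, cfg.pseudo_cls_weight)]
                )
            logits = model.classifier(cls_z)
            l_cls = weighted_cross_entropy(logits, cls_y, cfg_props, extra_w)

            # center loss (latents + optionally pseudo toward the MCI center)
            cen_z, cen_y = z_all, y_all
            if pseudo is not None and cfg.use_pseudo_in_center:
                cen_z = nn.concat([z_all, pseudo], axis=0)
                cen_y = np.concatenate([y_all, ["MCI"] * n_pseudo])
            l_center = center_loss(cen_z, cen_y, model.centers)

            # domain-adversarial loss: speech=0, EEG=1
            d_logits = model.discriminate(z_all, lam)
            d_targets = np.concatenate(
                [np.zeros(zs.shape[0]), np.ones(ze.shape[0])]
            )[:, None]
            l_domain = nn.binary_cross_entropy_with_logits(d_logits, d_targets)

            l_consist, skipped = consistency_loss(zs, ysb, ze, yeb)
            skipped_any = skipped_any or skipped

            loss = total_loss(l_cls, l_center, l_domain, l_consist, cfg)
            opt.zero_grad()
            model.centers.grad = None
            loss.backward()
            opt.step()
            # dedicated SGD update of the class centers (closed-form gradient
            # of the unweighted center loss on detached latents)
            model.centers.data -= cfg.center_lr * center_gradient(
                cen_z.data, cen_y, model.centers.data
            )

            for key, val in zip(
                ("cls", "center", "domain", "consist", "total"),
                (l_cls, l_center, l_domain, l_consist, loss),
            ):
                ep[key].append(val.item())
        history.append(
            LossReport(
                cls=float(np.mean(ep["cls"])),
                center=float(np.mean(ep["center"])),
                domain=float(np.mean(ep["domain"])),
                consist=float(np.mean(ep["consist"])),
                total=float(np.mean(ep["total"])),
                consistency_skipped=skipped_any,
            )
        )
    model.eval()
    return model, history


def encode(
    model: AlignmentModel, table: pd.DataFrame | np.ndarray, modality: str
) -> np.ndarray:
    """Deterministic inference-time encoding into the shared subspace."""
    if modality not in ("speech", "eeg"):
        raise ValueError("modality must be 'speech' or 'eeg'")
    if isinstance(table, pd.DataFrame):
        x = table.drop(columns="label", errors="ignore").to_numpy(dtype=np.float64)
    else:
        x = np.asarray(table, dtype=np.float64)
    enc = model.speech_encoder if modality == "speech" else model.eeg_encoder
    if x.shape[1] != enc.d_in:
        raise ValueError(
            f"{modality} encoder expects {enc.d_in} features, got {x.shape[1]}"
        )
    model.eval()
    return model.encode_batch(nn.Tensor(x), modality).data


def predict_classes(model: AlignmentModel, z: np.ndarray) -> np.ndarray:
    """Class labels from the alignment classifier head."""
    logits = model.classifier(nn.Tensor(z)).data
    return np.array([CLASS_ORDER[i] for i in logits.argmax(axis=1)])


def predict_proba(model: AlignmentModel, z: np.ndarray) -> np.ndarray:
    logits = model.classifier(nn.Tensor(z)).data
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)
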