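"""End-to-end pipeline: cross-validation protocol and ablation modes.

The evaluation protocol mirrors an unpaired two-corpus design: stratified
5-fold cross-validation on the speech training table only, with a fixed
4:1 EEG train/validation split reused unchanged across folds, and the
whole procedure repeated under several random seeds with independently
initialized models. Aggregation is mean +/- SD over folds, then over
seeds.

Ablation modes (each a runnable stage sequence):

==================  =====================================================
align               alignment network alone; its classifier head scores
                    held-out speech latents
align+noise         SE fusion of aligned speech latents with standard
                    normal noise in place of generated latents
flow-only           no alignment: the flow is conditioned on the raw
                    (standardized) speech features and transports noise
                    to EEG feature space; SE fusion of speech features
                    with the generated latents
latent-only         alignment + flow, classifying generated latents alone
align+flow-concat   alignment + flow, fusion by plain concatenation
                    (no SE gate)
align+flow+attention  the full model
==================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import alignment as al
from . import flow as fl
from .features import Standardizer
from .fusion import FusionConfig, train_fusion
from .metrics import MetricsReport, aggregate, metrics

__all__ = ["MODES", "CVProtocol", "PipelineConfig", "run_fold", "cross_validate", "run_pipeline"]

MODES = (
    "align",
    "align+noise",
    "flow-only",
    "latent-only",
    "align+flow-concat",
    "align+flow+attention",
)


@dataclass(frozen=True)
class CVProtocol:
    n_folds: int = 5
    eeg_val_fraction: float = 0.2  # fixed 4:1 split, constant across folds
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class PipelineConfig:
    """Hyperparameters for every stage; epochs scale the problem size."""

    align: al.AlignmentConfig = field(default_factory=al.AlignmentConfig)
    flow: fl.FlowTrainConfig = field(default_factory=fl.FlowTrainConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    #: ODE samples averaged per subject: the latent fed to the fusion head is
    #: a Monte-Carlo estimate of the conditional mean over the noise prior,
    #: which removes most of the single-draw sampling variance at inference.
    n_gen_samples: int = 5


def _xy(table: pd.DataFrame):
    return table.drop(columns="label").to_numpy(dtype=np.float64), table[
        "label"
    ].to_numpy()


def _standardized(train: pd.DataFrame, val: pd.DataFrame):
    cols = [c for c in train.columns if c != "label"]
    scaler = Standardizer().fit(train[cols])
    out_tr = scaler.transform(train[cols]).assign(label=train["label"])
    out_va = scaler.transform(val[cols]).assign(label=val["label"])
    return out_tr, out_va


def run_fold(
    speech_train: pd.DataFrame,
    speech_val: pd.DataFrame,
    eeg_train: pd.DataFrame,
    eeg_val: pd.DataFrame,
    mode: str,
    cfg: PipelineConfig,
    seed: int,
) -> MetricsReport:
    """Train the stage sequence of ``mode`` on the fold's training data and
    evaluate on the speech validation rows."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    # leakage guard: training and validation subjects must be disjoint
    if set(speech_train.index) & set(speech_val.index):
        raise RuntimeError("speech train/validation subject overlap")
    if set(eeg_train.index) & set(eeg_val.index):
        raise RuntimeError("EEG train/validation subject overlap")

    rng = np.random.default_rng(seed)
    speech_train, speech_val = _standardized(speech_train, speech_val)
    eeg_train, eeg_val = _standardized(eeg_train, eeg_val)
    xs_va, ys_va = _xy(speech_val)
    xs_tr, ys_tr = _xy(speech_train)

    needs_alignment = mode != "flow-only"
    if needs_alignment:
        a_cfg = replace(cfg.align, seed=seed)
        model, _ = al.train_alignment(speech_train, eeg_train, a_cfg)
        z_tr = al.encode(model, speech_train, "speech")
        z_va = al.encode(model, speech_val, "speech")
        ze_tr = al.encode(model, eeg_train, "eeg")
    else:
        z_tr, z_va = xs_tr, xs_va
        ze_tr, _ = _xy(eeg_train)

    if mode == "align":
        y_pred = al.predict_classes(model, z_va)
        return metrics(ys_va, y_pred, al.predict_proba(model, z_va))

    if mode == "align+noise":
        lat_tr = rng.normal(0, 1, (len(z_tr), z_tr.shape[1]))
        lat_va = rng.normal(0, 1, (len(z_va), z_va.shape[1]))
    else:
        f_cfg = replace(cfg.flow, seed=seed)
        ye_tr = eeg_train["label"].to_numpy()
        flow_model = fl.train_flow(z_tr, ys_tr, ze_tr, ye_tr, cfg=f_cfg)
        k = max(cfg.n_gen_samples, 1)
        lat_tr = np.mean(
            [fl.generate_for_table(flow_model, z_tr, seed=seed + i) for i in range(k)],
            axis=0,
        )
        lat_va = np.mean(
            [fl.generate_for_table(flow_model, z_va, seed=seed + k + i) for i in range(k)],
            axis=0,
        )

    fu_cfg = replace(
        cfg.fusion,
        seed=seed,
        use_se=(mode != "align+flow-concat"),
    )
    if mode == "latent-only":
        net = train_fusion(lat_tr, None, ys_tr, fu_cfg)
        proba = net(lat_va)
        y_pred = net.predict(lat_va)
    else:
        net = train_fusion(z_tr, lat_tr, ys_tr, fu_cfg)
        proba = net(z_va, lat_va)
        y_pred = net.predict(z_va, lat_va)
    return metrics(ys_va, y_pred, proba)


def cross_validate(
    speech_table: pd.DataFrame,
    eeg_table: pd.DataFrame,
    mode: str = "align+flow+attention",
    cfg: PipelineConfig = PipelineConfig(),
    protocol: CVProtocol = CVProtocol(),
    seed: int = 0,
) -> dict:
    """Stratified k-fold on the speech table with a fixed EEG split.

    Returns fold assignments, per-fold reports, and the mean +/- SD
    aggregate across folds.
    """
    y = speech_table["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < protocol.n_folds).any():
        raise ValueError("every class needs at least n_folds speech samples")
    skf = StratifiedKFold(n_splits=protocol.n_folds, shuffle=True, random_state=seed)
    eeg_tr_idx, eeg_va_idx = train_test_split(
        np.arange(len(eeg_table)),
        test_size=protocol.eeg_val_fraction,
        stratify=eeg_table["label"],
        random_state=seed,
    )
    eeg_train = eeg_table.iloc[eeg_tr_idx]
    eeg_val = eeg_table.iloc[eeg_va_idx]

    reports, folds = [], []
    for k, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        report = run_fold(
            speech_table.iloc[tr], speech_table.iloc[va],
            eeg_train, eeg_val, mode, cfg, seed=seed * 1000 + k,
        )
        reports.append(report)
        folds.append({"fold": k, "train_idx": tr, "val_idx": va})
    return {
        "mode": mode,
        "folds": folds,
        "reports": reports,
        "aggregate": aggregate(reports),
        "eeg_split": (eeg_tr_idx, eeg_va_idx),
    }


def run_pipeline(
    speech_table: pd.DataFrame,
    eeg_table: pd.DataFrame,
    mode: str = "align+flow+attention",
    cfg: PipelineConfig = PipelineConfig(),
    protocol: CVProtocol = CVProtocol(),
) -> dict:
    """Repeat cross-validation under each protocol seed and aggregate twice:
    mean +/- SD over folds within a seed, then over the per-seed means."""
    per_seed = []
    for s in protocol.seeds:
        per_seed.append(cross_validate(speech_table, eeg_table, mode, cfg, protocol, seed=s))
    acc_means = np.array([r["aggregate"]["accuracy"][0] for r in per_seed])
    f1_means = np.array([r["aggregate"]["macro_f1"][0] for r in per_seed])
    return {
        "mode": mode,
        "per_seed": per_seed,
        "accuracy_mean": float(acc_means.mean()),
        "accuracy_sd": float(acc_means.std()),
        "macro_f1_mean": float(f1_means.mean()),
        "macro_f1_sd": float(f1_means.std()),
    }
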