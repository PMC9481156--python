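"""Training loop, losses, model selection, metrics and replicate management.

Training follows the study protocol: a three-class (NB/Del/Div) weighted
softmax-cross-entropy loss with weights set to the inverse training-set fate
proportions, Adam at lr = 1e-4, one parameter update per window graph per
epoch (optionally followed by an update on the corresponding null graph with
the neutral-baseline MSE loss), and model selection at the epoch with the
best test-set macro-F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, precision_score, recall_score, roc_auc_score

from . import nn
from .gnn_core import FateGNN, GraphBatch, ModelConfig, build_batch, build_window_batch
from .track_graph import TARGET_FATES, Window, extract_target_subgraph

__all__ = [
    "TrainConfig",
    "EvalReport",
    "TrainResult",
    "class_weights",
    "weighted_ce_loss",
    "baseline_mse_loss",
    "prepare_batches",
    "train",
    "evaluate",
    "replicate_train",
]

FATE_NAMES = TARGET_FATES  # ("NB", "Del", "Div")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 2000
    baseline_loss: bool = True
    n_replicates: int = 6
    seed: int = 0
    eval_every: int = 1


@dataclass
class EvalReport:
    """Per-label one-vs-rest AUC, macro-F1, recall/precision, confusion."""

    auc: dict
    macro_f1: float
    recall: dict
    precision: dict
    confusion: np.ndarray
    loss: float
    epoch: int = -1

    def mean_auc(self) -> float:
        vals = [v for v in self.auc.values() if v is not None]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class TrainResult:
    model: FateGNN
    best_state: dict
    best_epoch: int
    best_report: EvalReport
    history: list = field(default_factory=list)  # (epoch, train_loss, EvalReport)

    def best_model(self) -> FateGNN:
        m = FateGNN(self.model.config, seed=self.model.seed)
        m.load_state_arrays(self.best_state)
        return m


def class_weights(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Inverse fate proportions of the training targets."""
    counts = np.bincount(labels, minlength=n_classes)
    if (counts == 0).any():
        missing = [FATE_NAMES[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"fate class(es) {missing} absent from the training set")
    props = counts / counts.sum()
    return 1.0 / props


def weighted_ce_loss(logits: nn.Tensor, labels: np.ndarray, weights: np.ndarray) -> nn.Tensor:
    return nn.weighted_cross_entropy(logits, labels, weights)


def baseline_mse_loss(logits_null: nn.Tensor) -> nn.Tensor:
    """Mean squared distance of the null-graph softmax scores from 1/3."""
    return nn.mse_to_uniform(logits_null)


def prepare_batches(
    windows: list[Window], model_config: ModelConfig, per_target: bool = False
) -> list[GraphBatch]:
    """One batch per window with at least one valid target.

    Whole-window batches share the computation across targets and are used
    whenever they are exact: always for the non-cell-external variants, and
    for cell_external at ns = 1 through the shared zero-receiver evaluation.
    ``per_target=True`` forces per-target subgraph batches, which attribution
    needs (integrated gradients are pooled per target subgraph) and which
    cover cell_external at ns > 1.
    """
    batches = []
    for w in windows:
        targets = w.targets()
        if not targets:
            continue
        if model_config.variant == "cell_external" and (per_target or model_config.ns != 1):
            subs = [extract_target_subgraph(w, t, model_config.ns) for t in targets]
            batches.append(build_batch(subs, nt=len(w.frames), ns=model_config.ns))
        elif model_config.variant == "cell_external":
            batches.append(build_window_batch(w, targets, external=True))
        elif per_target:
            subs = [extract_target_subgraph(w, t, model_config.ns) for t in targets]
            batches.append(build_batch(subs, nt=len(w.frames), ns=model_config.ns))
        else:
            batches.append(build_window_batch(w, targets))
    return batches


def evaluate(model: FateGNN, batches: list[GraphBatch], weights: np.ndarray | None = None) -> EvalReport:
    """Score a model on prepared batches (eval mode, dropout off)."""
    probs, labels = [], []
    loss_terms = []
    for b in batches:
        logits = model.forward(b, train=False)
        p = nn.softmax(logits).data
        probs.append(p)
        labels.append(b.labels)
        if weights is not None:
            loss_terms.append(float(weighted_ce_loss(logits, b.labels, weights).data))
    probs = np.vstack(probs)
    labels = np.concatenate(labels)
    preds = probs.argmax(axis=1)
    auc = {}
    for i, name in enumerate(FATE_NAMES):
        binary = (labels == i).astype(int)
        if binary.min() == binary.max():
            auc[name] = None  # class absent: AUC undefined, excluded from averages
        else:
            auc[name] = float(roc_auc_score(binary, probs[:, i]))
    present = sorted(set(labels.tolist()) | set(preds.tolist()))
    return EvalReport(
        auc=auc,
        macro_f1=float(f1_score(labels, preds, labels=list(range(3)), average="macro", zero_division=0)),
        recall={FATE_NAMES[i]: float(r) for i, r in zip(range(3), recall_score(labels, preds, labels=list(range(3)), average=None, zero_division=0))},
        precision={FATE_NAMES[i]: float(p) for i, p in zip(range(3), precision_score(labels, preds, labels=list(range(3)), average=None, zero_division=0))},
        confusion=confusion_matrix(labels, preds, labels=list(range(3))),
        loss=float(np.mean(loss_terms)) if loss_terms else float("nan"),
    )


def train(
    train_windows: list[Window],
    test_windows: list[Window],
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int | None = None,
    batches: tuple[list[GraphBatch], list[GraphBatch]] | None = None,
) -> TrainResult:
    """Train one model replicate and return the best-macro-F1 checkpoint.

    Within an epoch the training windows are visited in a fixed order; each
    contributes a cross-entropy update and, if enabled, a null-graph MSE
    update.  Test metrics are recorded every ``eval_every`` epochs and the
    parameters at the best test macro-F1 are kept (the study's selection
    rule; an optimistic-bias choice retained for fidelity).
    """
    seed = train_config.seed if seed is None else seed
    if batches is None:
        batches = (prepare_batches(train_windows, model_config), prepare_batches(test_windows, model_config))
    train_batches, test_batches = batches
    if not train_batches:
        raise ValueError("no training windows with valid targets")
    all_labels = np.concatenate([b.labels for b in train_batches])
    weights = class_weights(all_labels)

    model = FateGNN(model_config, seed=seed)
    opt = nn.Adam(model.parameters(), lr=train_config.lr)
    rng = np.random.Generator(np.random.SFC64(seed + 1))  # dropout stream

    result = TrainResult(model=model, best_state=model.copy_state(), best_epoch=0,
                         best_report=None)
    best_f1 = -np.inf
    for epoch in range(1, train_config.epochs + 1):
        ce_sum = 0.0
        for b in train_batches:
            logits = model.forward(b, train=True, rng=rng)
            loss = weighted_ce_loss(logits, b.labels, weights)
            ce_sum += float(loss.data) * b.n_targets
            nn.backward(loss)
            opt.step()
            opt.zero_grad()
            if train_config.baseline_loss:
                logits0 = model.forward(b, features=b.null_features(), train=True, rng=rng)
                loss0 = baseline_mse_loss(logits0)
                nn.backward(loss0)
                opt.step()
                opt.zero_grad()
        if epoch % train_config.eval_every == 0 or epoch == train_config.epochs:
            report = evaluate(model, test_batches, weights)
            report.epoch = epoch
            train_loss = ce_sum / sum(b.n_targets for b in train_batches)
            result.history.append((epoch, train_loss, report))
            if report.macro_f1 > best_f1:
                best_f1 = report.macro_f1
                result.best_epoch = epoch
                result.best_state = model.copy_state()
                result.best_report = report
    return result


def replicate_train(
    train_windows: list[Window],
    test_windows: list[Window],
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> list[TrainResult]:
    """Independently seeded replicates (the study averages over six)."""
    batches = (prepare_batches(train_windows, model_config), prepare_batches(test_windows, model_config))
    return [
        train(train_windows, test_windows, model_config, train_config,
              seed=train_config.seed + 1000 * r, batches=batches)
        for r in range(train_config.n_replicates)
    ]


def summarize_replicates(results: list[TrainResult]) -> dict:
    """Mean and standard deviation of the best-epoch metrics across replicates."""
    out = {}
    for name in FATE_NAMES:
        vals = [r.best_report.auc[name] for r in results if r.best_report.auc[name] is not None]
        out[f"auc_{name}"] = (float(np.mean(vals)), float(np.std(vals))) if vals else (None, None)
    f1s = [r.best_report.macro_f1 for r in results]
    out["macro_f1"] = (float(np.mean(f1s)), float(np.std(f1s)))
    return out
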