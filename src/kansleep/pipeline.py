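"""Two-stage training protocol and cross-validation orchestration.

Training is deliberately split in two stages:

1. *Extractor stage* — the dual-stream CNN is trained end-to-end on single
   epochs with a temporary two-layer softmax head (cross-entropy).
2. *Classifier stage* — the extractor is frozen, features for every epoch
   are materialized once, and the KAN (optionally followed by the GRU over
   sequences of consecutive epochs) plus the affine stage head are trained
   on the cached features.

Ablation variants are pure configuration:

- A: extractor + GRU with the two-layer MLP head (no KAN, no MLP trunk);
- B: extractor + KAN without temporal context (``use_gru=False``);
- C: a fixed-rectifier MLP mirroring the KAN width plan replaces the KAN;
- D: the full model (KAN + GRU).

Balancing strategies are applied to training folds only (evaluation folds
can be balanced too via ``balance_eval``, off by default).  Everything is
deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .balancing import apply_strategy
from .evaluation import (
    ConfusionMatrix,
    FoldSpec,
    cohen_kappa,
    compute_metrics,
    confusion_from_labels,
    make_folds,
)
from .extractor import ExtractorParams, alt_features
from .gru import GRUParams, GRUSequence, HeadParams
from .io import EpochedDataset
from .kan import KANStack, SplineGrid
from .nn.ops import Adam, Linear, ReLU, cross_entropy, softmax
from .stages import N_STAGES


@dataclass
class PipelineConfig:
    channel_plan: list = field(default_factory=lambda: [("EEG_C3", "EEG"),
                                                        ("EMG_chin", "EMG")])
    strategy: str = "none"            # none | focus | focus+oversample | undersample
    feature_mode: str = "CNN"         # CNN | DE | STFT | statistic
    classifier: str = "kan"           # kan | mlp | none
    use_gru: bool = True
    sequence_len: int = 20            # consecutive epochs per GRU window (10 min)
    kan_hidden: tuple = (128, 64)
    stage1_steps: int = 500
    stage1_batch: int = 32
    stage1_lr: float = 1e-3
    stage2_steps: int = 400
    stage2_batch: int = 8             # sequences per step
    stage2_lr: float = 3e-3
    seed: int = 0
    balance_eval: bool = False
    output_dir: str | None = None

    def validate(self) -> None:
        if self.feature_mode not in ("CNN", "DE", "STFT", "statistic"):
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        if self.classifier not in ("kan", "mlp", "none"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.sequence_len < 1:
            raise ValueError("sequence_len must be >= 1")
        for b in (self.stage1_steps, self.stage2_steps):
            if b < 0:
                raise ValueError("training budgets must be >= 0")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["channel_plan"] = [list(c) for c in self.channel_plan]
        d["kan_hidden"] = list(self.kan_hidden)
        return d


def ablation_config(base: PipelineConfig, variant: str) -> PipelineConfig:
    """Variant A/B/C/D as config diffs from the base configuration."""
    table = {
        "A": dict(classifier="none", use_gru=True),
        "B": dict(classifier="kan", use_gru=False),
        "C": dict(classifier="mlp", use_gru=True),
        "D": dict(classifier="kan", use_gru=True),
    }
    if variant not in table:
        raise ValueError(f"unknown ablation variant {variant!r}")
    return replace(base, **table[variant])


# ---------------------------------------------------------------------------
# stage-2 classifier model

class _MLPTrunk:
    """Fixed-rectifier trunk used by variants A (1 layer) and C (2 layers)."""

    def __init__(self, widths, rng):
        self.layers = []
        for i in range(len(widths) - 1):
            self.layers += [Linear(widths[i], widths[i + 1], rng), ReLU()]

    def params(self):
        out = []
        for li, layer in enumerate(self.layers):
            out.extend((f"mlp{li}.{n}", p, g) for n, p, g in layer.params())
        return out

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class SequenceClassifier:
    """Stage-2 model: trunk (KAN/MLP/affine) -> optional GRU -> stage head."""

    def __init__(self, feat_dim: int, config: PipelineConfig, seed: int):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 208]))
        widths = [feat_dim, *config.kan_hidden]
        if config.classifier == "kan":
            self.trunk = KANStack(widths, SplineGrid(), seed=seed)
        elif config.classifier == "mlp":
            self.trunk = _MLPTrunk(widths, rng)
        else:  # variant A: single affine+rectifier map into the GRU
            self.trunk = _MLPTrunk([feat_dim, widths[-1]], rng)
        self.trunk_kind = config.classifier
        self.use_gru = config.use_gru
        self.out_width = widths[-1]
        if self.use_gru:
            self.gru = GRUSequence(GRUParams(self.out_width, 32, rng))
            self.head = HeadParams(32, N_STAGES, rng)
        else:
            self.gru = None
            self.head = HeadParams(self.out_width, N_STAGES, rng)

    def params(self):
        out = list(self.trunk.params())
        if self.gru is not None:
            out.extend(self.gru.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self):
        for _, __, g in self.params():
            g[...] = 0.0

    def forward(self, xs: np.ndarray, training: bool = False) -> np.ndarray:
        """``xs``: (B, T, F) feature sequences -> logits (B, T, 5)."""
        b, t, f = xs.shape
        z = self.trunk.forward(xs.reshape(b * t, f), training)
        z = np.asarray(z, dtype=np.float64).reshape(b, t, self.out_width)
        self._bt = (b, t)
        h = self.gru.forward(z, training) if self.gru is not None else z
        return self.head.forward(h, training).reshape(b, t, N_STAGES)

    def backward(self, dlogits: np.ndarray) -> None:
        b, t = self._bt
        dh = self.head.backward(dlogits)
        if self.gru is not None:
            dh = self.gru.backward(dh)
        self.trunk.backward(dh.reshape(b * t, -1))

    def predict(self, features: np.ndarray, sequence_len: int) -> np.ndarray:
        """Stage codes for one recording's (L, F) feature matrix."""
        l = features.shape[0]
        preds = np.empty(l, dtype=np.int64)
        for start in range(0, l, sequence_len):
            chunk = features[start:start + sequence_len]
            logits = self.forward(chunk[None], training=False)[0]
            preds[start:start + len(chunk)] = softmax(logits).argmax(axis=1)
        return preds


# ---------------------------------------------------------------------------
# feature materialization

def _epoch_features(ds: EpochedDataset, config: PipelineConfig,
                    extractor: ExtractorParams | None) -> np.ndarray:
    if config.feature_mode == "CNN":
        assert extractor is not None
        # batched inference keeps memory bounded
        chunks = [extractor.forward_batch(ds.epochs[i:i + 128].astype(np.float32))
                  for i in range(0, ds.n_epochs, 128)]
        return np.concatenate(chunks, axis=0).astype(np.float64)
    return np.stack([
        alt_features(ds.epochs[i], config.feature_mode, fs=ds.fs)
        for i in range(ds.n_epochs)
    ])


# ---------------------------------------------------------------------------
# two-stage training

def train_extractor(
    extractor: ExtractorParams,
    epochs: np.ndarray,
    labels: np.ndarray,
    steps: int,
    batch: int,
    lr: float,
    seed: int,
) -> list[float]:
    """Stage 1: extractor + temporary two-layer softmax head, cross-entropy.

    Returns the loss trace.  The temporary head is discarded afterwards;
    only the branch weights matter downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 106]))
    feat_dim = epochs.shape[1] * extractor.features_per_channel(epochs.shape[2])
    head1 = Linear(feat_dim, 64, rng)
    act = ReLU()
    head2 = Linear(64, N_STAGES, rng)
    head2.w *= 0.1  # start near-uniform so early steps shape the extractor
    pairs = [(p, g) for _, p, g in extractor.params()]
    pairs += [(p, g) for _, p, g in head1.params() + head2.params()]
    opt = Adam(pairs, lr=lr)
    n = len(labels)
    trace = []
    for _ in range(steps):
        idx = rng.choice(n, size=min(batch, n), replace=False)
        xb = epochs[idx].astype(np.float32)
        feats = extractor.forward_batch(xb, training=True)
        logits = head2.forward(act.forward(head1.forward(feats, True), True), True)
        loss, dlogits = cross_entropy(logits, labels[idx])
        if not np.isfinite(loss):
            raise FloatingPointError("divergent stage-1 loss")
        trace.append(loss)
        opt.zero_grad()
        dfeat = head1.backward(act.backward(head2.backward(dlogits)))
        extractor.backward_batch(dfeat)
        opt.step()
    return trace


def _make_windows(features: np.ndarray, labels: np.ndarray, seq_len: int):
    """Chop one recording's selected epochs into non-overlapping windows."""
    windows = []
    n = len(labels)
    for start in range(0, n - seq_len + 1, seq_len):
        windows.append((features[start:start + seq_len],
                        labels[start:start + seq_len]))
    if not windows and n:  # recording shorter than one window
        windows.append((features, labels))
    return windows


def train_two_stage(
    config: PipelineConfig,
    data: dict[str, EpochedDataset],
    fold: FoldSpec,
) -> tuple[dict, dict]:
    """Train on ``fold.train_ids``, evaluate on ``fold.test_ids``.

    Returns ``(model_bundle, report)`` where the bundle carries the frozen
    extractor, feature standardization stats and the fitted classifier, and
    the report carries the test confusion matrix and metric block.
    """
    config.validate()
    missing = [i for i in fold.train_ids + fold.val_ids + fold.test_ids
               if i not in data]
    if missing:
        raise KeyError(f"recordings not provided: {missing}")

    # training selection (balancing on training folds only)
    plans = {
        rid: apply_strategy(data[rid].labels, config.strategy, config.seed, rid)
        for rid in fold.train_ids
    }
    train_epochs = np.concatenate(
        [data[rid].epochs[plans[rid].kept_indices] for rid in fold.train_ids])
    train_labels = np.concatenate(
        [data[rid].labels[plans[rid].kept_indices] for rid in fold.train_ids])
    if len(train_labels) == 0:
        raise ValueError("empty training set after balancing")

    # stage 1
    extractor = None
    stage1_trace: list[float] = []
    if config.feature_mode == "CNN":
        extractor = ExtractorParams(seed=config.seed)
        stage1_trace = train_extractor(
            extractor, train_epochs, train_labels,
            config.stage1_steps, config.stage1_batch, config.stage1_lr,
            config.seed)

    # materialize features per recording (frozen extractor)
    feats = {rid: _epoch_features(data[rid], config, extractor) for rid in data}
    feat_dim = next(iter(feats.values())).shape[1]

    # standardize features with training-selection statistics
    train_feats = np.concatenate(
        [feats[rid][plans[rid].kept_indices] for rid in fold.train_ids])
    mu = train_feats.mean(axis=0)
    sd = np.maximum(train_feats.std(axis=0), 1e-8)

    def norm(f):
        return (f - mu) / sd

    # stage 2
    model = SequenceClassifier(feat_dim, config, config.seed)
    windows = []
    for rid in fold.train_ids:
        sel = plans[rid].kept_indices
        windows.extend(_make_windows(norm(feats[rid][sel]), data[rid].labels[sel],
                                     config.sequence_len))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 207]))
    pairs = [(p, g) for _, p, g in model.params()]
    opt = Adam(pairs, lr=config.stage2_lr)
    full = [w for w in windows if w[0].shape[0] == config.sequence_len] or windows
    stage2_trace: list[float] = []
    for _ in range(config.stage2_steps):
        idx = rng.choice(len(full), size=min(config.stage2_batch, len(full)),
                         replace=False)
        xb = np.stack([full[i][0] for i in idx])
        yb = np.stack([full[i][1] for i in idx])
        logits = model.forward(xb, training=True)
        loss, dflat = cross_entropy(logits.reshape(-1, N_STAGES), yb.ravel())
        if not np.isfinite(loss):
            raise FloatingPointError("divergent stage-2 loss")
        stage2_trace.append(loss)
        model.zero_grad()
        model.backward(dflat.reshape(logits.shape))
        opt.step()

    # evaluation on the held-out recordings
    cm = ConfusionMatrix(np.zeros((N_STAGES, N_STAGES), dtype=np.int64))
    for rid in fold.test_ids:
        labels = data[rid].labels
        f = norm(feats[rid])
        if config.balance_eval and config.strategy != "none":
            sel = apply_strategy(labels, config.strategy, config.seed + 1, rid
                                 ).kept_indices
        else:
            sel = np.arange(len(labels))
        preds = model.predict(f, config.sequence_len)
        cm = cm + confusion_from_labels(labels[sel], preds[sel])

    metrics = compute_metrics(cm)
    report = {
        "fold": fold.index,
        "confusion": cm.counts.tolist(),
        "accuracy": metrics["accuracy"],
        "macro_f1": metrics["macro_f1"],
        "kappa": cohen_kappa(cm),
        "stage1_final_loss": stage1_trace[-1] if stage1_trace else None,
        "stage1_initial_loss": stage1_trace[0] if stage1_trace else None,
        "stage2_final_loss": stage2_trace[-1] if stage2_trace else None,
        "stage2_initial_loss": stage2_trace[0] if stage2_trace else None,
    }
    bundle = {
        "extractor": extractor,
        "feat_mean": mu,
        "feat_std": sd,
        "model": model,
        "plans": plans,
        "config": config,
    }
    return bundle, report


def run_crossval(
    config: PipelineConfig,
    data: dict[str, EpochedDataset],
    fold_mode: str = "simple2",
) -> dict:
    """Train/evaluate every fold; emit per-fold and pooled metric report.

    Asserts the leakage guard on every fold: no test recording contributes
    any epoch to a training selection plan.  A failed fold writes a
    resumable state file (when ``config.output_dir`` is set) and re-raises.
    """
    ids = sorted(data)
    folds = make_folds(ids, fold_mode, seed=config.seed)
    fold_reports = []
    pooled = ConfusionMatrix(np.zeros((N_STAGES, N_STAGES), dtype=np.int64))
    for fold in folds:
        try:
            bundle, report = train_two_stage(config, data, fold)
        except Exception:
            if config.output_dir:
                state = {"completed_folds": [r["fold"] for r in fold_reports],
                         "failed_fold": fold.index}
                Path(config.output_dir).mkdir(parents=True, exist_ok=True)
                (Path(config.output_dir) / "crossval_state.json").write_text(
                    json.dumps(state, sort_keys=True))
            raise
        # leakage guard: balancing plans must never touch a test recording
        assert not (set(bundle["plans"]) & set(fold.test_ids)), \
            "test recording leaked into a training selection plan"
        fold_reports.append(report)
        pooled = pooled + ConfusionMatrix(np.array(report["confusion"]))

    metrics = compute_metrics(pooled)
    report = {
        "config": config.to_dict(),
        "fold_mode": fold_mode,
        "folds": fold_reports,
        "pooled_confusion": pooled.counts.tolist(),
        "pooled_accuracy": metrics["accuracy"],
        "pooled_macro_f1": metrics["macro_f1"],
        "pooled_kappa": cohen_kappa(pooled),
        "mean_accuracy": float(np.mean([r["accuracy"] for r in fold_reports])),
        "mean_macro_f1": float(np.mean([r["macro_f1"] for r in fold_reports])),
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "crossval_report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1))
    return report
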