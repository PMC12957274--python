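"""Class-balancing strategies over per-epoch stage label sequences.

Overnight recordings are dominated by wake epochs at the edges (lights on
before and after sleep) and by N2 within sleep, which biases a classifier
toward the majority stages.  Three selection strategies address this, each
returning a :class:`SelectionPlan` of epoch indices rather than data, so
they compose with any data source and are auditable:

- *sleep-state focus*: keep only 30 min (60 epochs) of wake on each side of
  the first/last non-wake epoch; interior wake is untouched.
- *oversampling*: after focus trimming, raise every present class to the
  recording's majority-class count by duplicating existing epoch indices
  (sampling with replacement, seeded); all original indices are retained.
- *undersampling*: down-sample every present class, without replacement, to
  the minimum present-class count, applied to the full label set.

Plans are deterministic given (labels, strategy, seed).  Balancing is meant
for training folds; evaluation folds are left untouched by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stages import N_STAGES, Stage

#: 30 minutes of 30-s epochs
EDGE_WAKE_EPOCHS = 60


@dataclass
class SelectionPlan:
    recording_id: str
    kept_indices: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.kept_indices)


def _class_counts(labels: np.ndarray) -> np.ndarray:
    return np.bincount(labels, minlength=N_STAGES)


def sleep_state_focus(labels, recording_id: str = "") -> SelectionPlan:
    """Trim edge wake to at most 60 epochs on each side of the sleep period.

    Keeps the contiguous range ``max(0, a-60) .. min(L-1, b+60)`` where ``a``
    and ``b`` are the first and last non-wake epochs.  An all-wake recording
    yields an empty plan with a warning.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    non_wake = np.nonzero(labels != int(Stage.W))[0]
    if non_wake.size == 0:
        warnings.warn(f"recording {recording_id!r} contains no sleep epochs",
                      stacklevel=2)
        return SelectionPlan(recording_id, np.empty(0, np.int64), "focus")
    a, b = int(non_wake[0]), int(non_wake[-1])
    lo = max(0, a - EDGE_WAKE_EPOCHS)
    hi = min(len(labels) - 1, b + EDGE_WAKE_EPOCHS)
    return SelectionPlan(recording_id, np.arange(lo, hi + 1), "focus")


def oversample(labels, seed: int = 0, recording_id: str = "") -> SelectionPlan:
    """Focus-trim, then duplicate minority-class epochs up to the majority.

    Every class present after trimming is raised to the majority-class count
    by sampling its existing indices uniformly with replacement; the
    original indices are all retained (the plan is a superset of the focus
    plan).
    """
    labels = np.asarray(labels, dtype=np.int64)
    focus = sleep_state_focus(labels, recording_id)
    base = focus.kept_indices
    if base.size == 0:
        return SelectionPlan(recording_id, base, "focus+oversample")
    counts = _class_counts(labels[base])
    target = int(counts.max())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 412]))
    extra: list[np.ndarray] = []
    for cls in range(N_STAGES):
        n = int(counts[cls])
        if n == 0 or n == target:
            continue
        pool = base[labels[base] == cls]
        extra.append(rng.choice(pool, size=target - n, replace=True))
    kept = np.concatenate([base] + extra) if extra else base
    return SelectionPlan(recording_id, kept, "focus+oversample")


def undersample(labels, seed: int = 0, recording_id: str = "") -> SelectionPlan:
    """Down-sample every present class to the minimum present-class count.

    Applied to the full label sequence (no focus trimming); sampling is
    without replacement, so the plan is a duplicate-free subset.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    counts = _class_counts(labels)
    present = np.nonzero(counts)[0]
    target = int(counts[present].min())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 413]))
    kept: list[np.ndarray] = []
    for cls in present:
        pool = np.nonzero(labels == cls)[0]
        if len(pool) == target:
            kept.append(pool)
        else:
            kept.append(np.sort(rng.choice(pool, size=target, replace=False)))
    return SelectionPlan(recording_id, np.sort(np.concatenate(kept)), "undersample")


def apply_strategy(labels, strategy: str, seed: int = 0,
                   recording_id: str = "") -> SelectionPlan:
    """Dispatch on strategy name: none | focus | focus+oversample | undersample."""
    labels = np.asarray(labels, dtype=np.int64)
    if strategy == "none":
        return SelectionPlan(recording_id, np.arange(len(labels)), "none")
    if strategy == "focus":
        return sleep_state_focus(labels, recording_id)
    if strategy in ("focus+oversample", "oversample"):
        return oversample(labels, seed, recording_id)
    if strategy == "undersample":
        return undersample(labels, seed, recording_id)
    raise ValueError(f"unknown balancing strategy {strategy!r}")
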