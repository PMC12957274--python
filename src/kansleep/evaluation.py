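"""Confusion-matrix metrics and subject-/session-independent CV splits.

All reported numbers derive from a 5x5 contingency table (rows = true
stage, columns = predicted stage, order W, N1, N2, N3, REM): per-class
precision/recall/F1, overall accuracy, macro F1 (unweighted mean of the
defined per-class F1s), and Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = trace/total,  p_e = sum_c row_c * col_c / total^2.

Fold generation supports the two benchmark protocols — 25 folds over 50
subjects with disjoint test pairs, and 10 folds over 153 sessions with test
sets of 15 or 16 — plus a generic k-fold for synthetic cohorts.  Within
every fold the train/validation/test id sets are pairwise disjoint and
cover all ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .stages import N_STAGES, STAGE_NAMES


@dataclass
class ConfusionMatrix:
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_STAGES, N_STAGES):
            raise ValueError("confusion matrix must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion_from_labels(truth, pred) -> ConfusionMatrix:
    """Tally ``counts[i, j] = #{t : truth_t = i, pred_t = j}``."""
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction lengths differ")
    for name, arr in (("truth", truth), ("prediction", pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= N_STAGES):
            raise ValueError(f"{name} contains a label outside the five stages")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (truth, pred), 1)
    return ConfusionMatrix(counts)


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class precision/recall/F1 plus accuracy and macro F1.

    Classes absent from both margins yield ``nan`` entries and are excluded
    from the macro mean.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, np.nan)
        recall = np.where(row > 0, diag / row, np.nan)
        f1 = np.where(
            np.nan_to_num(precision) + np.nan_to_num(recall) > 0,
            2 * np.nan_to_num(precision) * np.nan_to_num(recall)
            / (np.nan_to_num(precision) + np.nan_to_num(recall)),
            np.nan,
        )
        f1 = np.where(np.isnan(precision) & np.isnan(recall), np.nan, f1)
    defined = ~np.isnan(f1)
    return {
        "accuracy": float(diag.sum() / total),
        "macro_f1": float(np.nanmean(f1)) if defined.any() else float("nan"),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "per_class_defined": defined,
    }


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement of the table; in ``[-1, 1]``."""
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("degenerate table: expected agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def metric_block(cm: ConfusionMatrix) -> str:
    """Human-readable metric report used by the ``evaluate`` CLI."""
    m = compute_metrics(cm)
    try:
        kappa = f"{cohen_kappa(cm):.3f}"
    except ValueError:  # single-cell table: chance agreement is 1
        kappa = "undefined"
    lines = [
        f"epochs scored : {cm.total}",
        f"accuracy      : {m['accuracy']:.3f}",
        f"macro F1      : {m['macro_f1']:.3f}",
        f"Cohen's kappa : {kappa}",
        "",
        "stage  precision  recall     F1",
    ]
    for i, name in enumerate(STAGE_NAMES):
        p, r, f = m["precision"][i], m["recall"][i], m["f1"][i]

        def fmt(v):
            return "  --  " if np.isnan(v) else f"{v:.3f}"

        lines.append(f"{name:<5}  {fmt(p):>9}  {fmt(r):>6}  {fmt(f):>5}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# plain-text confusion tables

def read_confusion_table(path) -> ConfusionMatrix:
    """Read a 5x5 count table: comment lines ignored, optional row names."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] in STAGE_NAMES:
            parts = parts[1:]
        rows.append([int(v) for v in parts[:N_STAGES]])
    if len(rows) != N_STAGES:
        raise ValueError(f"expected 5 count rows, found {len(rows)}")
    return ConfusionMatrix(np.array(rows))


def write_confusion_table(path, cm: ConfusionMatrix, comment: str = "") -> None:
    with Path(path).open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("# rows = true stage, columns = predicted; order W N1 N2 N3 REM\n")
        for name, row in zip(STAGE_NAMES, cm.counts):
            fh.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# cross-validation splits

@dataclass
class FoldSpec:
    index: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        tr, va, te = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if tr & va or tr & te or va & te:
            raise ValueError("fold id sets must be pairwise disjoint")


def make_folds(ids: list[str], mode: str, seed: int = 0) -> list[FoldSpec]:
    """Generate subject-/session-independent cross-validation folds.

    - ``isruc25``: exactly 50 subject ids -> 25 folds whose 2-subject test
      sets form a seeded partition (every subject tested exactly once);
      2 validation subjects drawn from the remainder per fold.
    - ``sleepedf10``: exactly 153 session ids -> 10 folds with test sizes
      16,16,16,15,...,15 partitioning the sessions; 13 (resp. 14)
      validation sessions when the test set has 16 (resp. 15).
    - ``simple<k>`` (e.g. ``simple2``): generic k-fold over any id count,
      one id per fold reserved for validation when possible.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 515]))
    perm = [ids[i] for i in rng.permutation(len(ids))]

    if mode == "isruc25":
        if len(ids) != 50:
            raise ValueError("isruc25 mode requires exactly 50 subject ids")
        test_sets = [perm[2 * i:2 * i + 2] for i in range(25)]
        n_val = 2
    elif mode == "sleepedf10":
        if len(ids) != 153:
            raise ValueError("sleepedf10 mode requires exactly 153 session ids")
        sizes = [16, 16, 16] + [15] * 7
        test_sets, pos = [], 0
        for s in sizes:
            test_sets.append(perm[pos:pos + s])
            pos += s
        n_val = None  # per-fold: 13 when test has 16, else 14
    elif mode.startswith("simple"):
        k = int(mode[len("simple"):])
        if not 2 <= k <= len(ids):
            raise ValueError(f"cannot make {k} folds from {len(ids)} ids")
        test_sets = [list(chunk) for chunk in np.array_split(perm, k)]
        n_val = 1 if len(ids) >= 3 * k else 0
    else:
        raise ValueError(f"unknown fold mode {mode!r}")

    folds = []
    for fi, test in enumerate(test_sets):
        remainder = [s for s in perm if s not in set(test)]
        nv = n_val if n_val is not None else (13 if len(test) == 16 else 14)
        val_idx = rng.permutation(len(remainder))[:nv]
        val = [remainder[i] for i in sorted(val_idx)]
        train = [s for s in remainder if s not in set(val)]
        folds.append(FoldSpec(fi, train, val, list(test)))
    return folds
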