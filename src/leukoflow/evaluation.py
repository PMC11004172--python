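"""Cohort splitting, 5-fold cross-validation and one-vs-rest diagnostic metrics.

The evaluation protocol holds out a stratified test fraction (default 20%),
divides the remaining training samples into k = 5 stratified folds for
cross-validation, and reports per-diagnosis one-vs-rest confusion counts with
accuracy, sensitivity, specificity and F1. Percentages are displayed rounded
half-up to one decimal with the underlying fraction strings ("x/y") retained,
matching clinical reporting style.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .errors import (
    DegenerateCounts,
    LeakageError,
    StratificationError,
    UnknownLabel,
)
from .vocab import DIAGNOSES, N_DIAGNOSES


@dataclass
class FoldSplit:
    """A held-out test set plus k stratified cross-validation folds."""

    k: int
    assignments: dict[str, int]  # training sample_id -> fold index
    test_ids: list[str]
    seed: int
    stratified: bool = True

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]

    @property
    def train_ids(self) -> list[str]:
        return list(self.assignments)


def split_cohort(
    manifest: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
    k: int = 5,
) -> FoldSplit:
    """Deterministic stratified train/test split plus k-fold assignment.

    Raises :class:`StratificationError` when a diagnosis stratum is smaller
    than k (or than 2 for the test split) under stratification.
    """
    ids = manifest["sample_id"].to_numpy()
    diag = manifest["diagnosis"].to_numpy()
    if len(set(ids)) != len(ids):
        raise LeakageError("duplicate sample ids in manifest")
    bad = set(diag) - set(DIAGNOSES)
    if bad:
        raise UnknownLabel(f"unknown diagnoses {sorted(bad)}")

    if test_fraction == 0:
        train_idx = np.arange(len(ids))
        test_idx = np.array([], dtype=int)
    elif stratify:
        counts = pd.Series(diag).value_counts()
        if (counts < 2).any():
            raise StratificationError(
                f"every stratum needs >= 2 samples, got {counts.to_dict()}"
            )
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=test_fraction, random_state=seed
        )
        (train_idx, test_idx), = splitter.split(ids.reshape(-1, 1), diag)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(ids))
        n_test = int(np.ceil(test_fraction * len(ids)))
        test_idx, train_idx = perm[:n_test], perm[n_test:]

    train_ids, train_diag = ids[train_idx], diag[train_idx]
    if stratify:
        train_counts = pd.Series(train_diag).value_counts()
        if (train_counts < k).any():
            raise StratificationError(
                f"every training stratum needs >= k={k} samples, "
                f"got {train_counts.to_dict()}"
            )
        kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        assignments = {}
        for fold, (_, val_idx) in enumerate(
            kf.split(train_ids.reshape(-1, 1), train_diag)
        ):
            for i in val_idx:
                assignments[train_ids[i]] = fold
    else:
        assignments = {s: i % k for i, s in enumerate(train_ids)}

    return FoldSplit(
        k=k,
        assignments=assignments,
        test_ids=list(ids[test_idx]),
        seed=seed,
        stratified=stratify,
    )


def confusion_counts(
    y_true, y_pred, target_class: str
) -> tuple[int, int, int, int]:
    """One-vs-rest confusion counts (TP, FP, FN, TN) for one diagnosis."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise UnknownLabel("label vectors must be aligned")
    for v in np.unique(np.concatenate([t, p])):
        if v not in DIAGNOSES:
            raise UnknownLabel(f"label {v!r} outside {DIAGNOSES}")
    if target_class not in DIAGNOSES:
        raise UnknownLabel(f"target {target_class!r} outside {DIAGNOSES}")
    tp = int(np.sum((t == target_class) & (p == target_class)))
    fp = int(np.sum((t != target_class) & (p == target_class)))
    fn = int(np.sum((t == target_class) & (p != target_class)))
    tn = int(np.sum((t != target_class) & (p != target_class)))
    return tp, fp, fn, tn


def metrics_from_counts(
    tp: int, fp: int, fn: int, tn: int
) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity and F1 from one-vs-rest counts.

    Undefined ratios (zero denominators) are reported as None, never NaN.
    """
    for v in (tp, fp, fn, tn):
        if v < 0 or int(v) != v:
            raise DegenerateCounts("counts must be non-negative integers")
    n = tp + fp + fn + tn
    if n < 1:
        raise DegenerateCounts("all confusion counts are zero")
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else None
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
    }


def percent(x: float | None, decimals: int = 1) -> str:
    """Percentage rounded half-up, e.g. 0.7619 -> '76.2%'; None -> 'n/a'."""
    if x is None:
        return "n/a"
    q = Decimal(1).scaleb(-decimals)
    return f"{Decimal(str(100 * x)).quantize(q, rounding=ROUND_HALF_UP)}%"


@dataclass
class MetricsReport:
    """Per-diagnosis one-vs-rest metrics plus the full 5x5 confusion matrix."""

    rows: list[dict]
    confusion: np.ndarray  # 5 x 5, true x predicted, DIAGNOSES order
    n_test: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.to_frame().copy()
        for col in ("f1", "accuracy", "sensitivity", "specificity"):
            df[col] = df[col].map(lambda v: percent(None if pd.isna(v) else v))
        df["sensitivity_fraction"] = [
            f"{r['tp']}/{r['tp'] + r['fn']}" for r in self.rows
        ]
        df["specificity_fraction"] = [
            f"{r['tn']}/{r['tn'] + r['fp']}" for r in self.rows
        ]
        df.to_csv(path, index=False)
        return path

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_test": self.n_test,
                "rows": self.rows,
                "confusion": self.confusion.tolist(),
            }
        )

    def pretty(self) -> str:
        lines = [f"{'Disease':<10}{'F1':>8}{'Accuracy':>10}{'Sens.':>8}{'Spec.':>8}"]
        for r in self.rows:
            lines.append(
                f"{r['class']:<10}"
                f"{percent(r['f1']):>8}"
                f"{percent(r['accuracy']):>10}"
                f"{percent(r['sensitivity']):>8}"
                f"{percent(r['specificity']):>8}"
            )
        return "\n".join(lines)


def report_from_predictions(y_true, y_pred) -> MetricsReport:
    """Build the full per-class report from aligned diagnosis vectors."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    confusion = np.zeros((N_DIAGNOSES, N_DIAGNOSES), dtype=int)
    for ti, pi in zip(t, p):
        confusion[DIAGNOSES.index(ti), DIAGNOSES.index(pi)] += 1
    rows = []
    for c in DIAGNOSES:
        tp, fp, fn, tn = confusion_counts(t, p, c)
        m = metrics_from_counts(tp, fp, fn, tn)
        rows.append(
            {
                "class": c,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "support": tp + fn,
                **m,
            }
        )
    return MetricsReport(rows=rows, confusion=confusion, n_test=len(t))


def evaluate_predictions(
    split: FoldSplit,
    test_manifest: pd.DataFrame,
    y_pred,
) -> MetricsReport:
    """Report on the held-out test set; hard-fails on train/test overlap."""
    test_ids = set(test_manifest["sample_id"])
    overlap = test_ids & set(split.train_ids)
    if overlap:
        raise LeakageError(f"train/test overlap: {sorted(overlap)[:5]} ...")
    return report_from_predictions(test_manifest["diagnosis"].to_numpy(), y_pred)
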