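"""Person-aware splits, leave-one-person-out folds, and block-level metrics.

Metrics are computed at the block level: each smoothed block probability is
thresholded and compared against the block's majority truth label.  The
precision-recall curve sweeps thresholds over the unique probability values
and its area is integrated trapezoidally over recall.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .device_io import Dataset, Recording
from .windowing import Hyperparameters, classify, make_block_arrays, smooth_predict

__all__ = [
    "EvalReport",
    "split_per_person",
    "lopo_folds",
    "confusion_counts",
    "f1_score",
    "pr_curve",
    "report_from_probs",
    "evaluate_stream",
    "detect_events",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Block-level evaluation summary plus the full prediction trace."""

    f1: float
    precision: float
    recall: float
    auc: float
    pr_points: list  # (recall, precision) pairs sorted by recall
    confusion: dict  # tp / fp / fn / tn
    trace_truth: np.ndarray
    trace_prob: np.ndarray
    n_blocks: int

    def to_dict(self, include_trace: bool = True) -> dict:
        out = {
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "auc": self.auc,
            "pr_points": [[float(r), float(p)] for r, p in self.pr_points],
            "confusion": {k: int(v) for k, v in self.confusion.items()},
            "n_blocks": int(self.n_blocks),
        }
        if include_trace:
            out["trace"] = {
                "truth": [int(v) for v in self.trace_truth],
                "prob": [round(float(v), 6) for v in self.trace_prob],
            }
        return out

    def to_json(self, path, include_trace: bool = True) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(self.to_dict(include_trace), sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return path


def split_per_person(
    ds: Dataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Per-subject recording-level split.

    For every subject the trial recordings are shuffled (seeded) and
    partitioned so the training share of that subject's samples is as close as
    possible to ``train_fraction``.  Synchronized wrist pairs (same subject,
    activity and trial) always land on the same side to avoid leakage.
    Returns ``(train_recordings, test_recordings)``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for subject in ds.subjects:
        recs = [r for r in ds if r.subject_id == subject]
        groups: dict = {}
        for rec in recs:
            groups.setdefault(rec.key, []).append(rec)
        keys = sorted(groups)
        if len(keys) == 1:
            warnings.warn(
                f"subject {subject!r} has a single trial; assigning it to train",
                stacklevel=2,
            )
            train.extend(groups[keys[0]])
            continue
        order = rng.permutation(len(keys))
        sizes = np.array([sum(len(r) for r in groups[keys[i]]) for i in order], float)
        total = sizes.sum()
        cumulative = np.cumsum(sizes)
        # choose the cut whose train share is closest to the target fraction
        best_cut = int(np.argmin(np.abs(cumulative / total - train_fraction))) + 1
        best_cut = min(best_cut, len(keys) - 1)  # keep both sides nonempty
        for j, i in enumerate(order):
            (train if j < best_cut else test).extend(groups[keys[i]])
    return train, test


def lopo_folds(ds: Dataset) -> list[tuple[list, list]]:
    """Leave-one-person-out folds: one ``(train, test)`` pair per subject."""
    subjects = ds.subjects
    if len(subjects) < 2:
        raise ValueError("leave-one-person-out requires at least 2 subjects")
    folds = []
    for subject in subjects:
        test = [r for r in ds if r.subject_id == subject]
        train = [r for r in ds if r.subject_id != subject]
        folds.append((train, test))
    return folds


def confusion_counts(pred, truth) -> dict:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return {
        "tp": int((pred & truth).sum()),
        "fp": int((pred & ~truth).sum()),
        "fn": int((~pred & truth).sum()),
        "tn": int((~pred & ~truth).sum()),
    }


def f1_score(pred, truth) -> float:
    """F1 = 2TP / (2TP + FP + FN); defined as 0 when the denominator is 0."""
    c = confusion_counts(pred, truth)
    denom = 2 * c["tp"] + c["fp"] + c["fn"]
    return 0.0 if denom == 0 else 2.0 * c["tp"] / denom


def pr_curve(probs, truth) -> tuple[list, float]:
    """Precision-recall points over unique-probability thresholds, plus AUC.

    A point is computed for every unique probability value ``t`` with the
    decision rule ``prob >= t``; points are sorted by recall and the curve is
    anchored at ``(recall=0, precision of the lowest-recall point)`` before
    trapezoidal integration over recall.
    """
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    if probs.shape != truth.shape:
        raise ValueError("probs and truth must have equal length")
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    n_pos = int(truth.sum())
    if n_pos == 0:
        warnings.warn("truth contains no positives; PR curve undefined", stacklevel=2)
        return [], 0.0
    order = np.argsort(-probs, kind="stable")
    sorted_p = probs[order]
    sorted_t = truth[order]
    tp_cum = np.cumsum(sorted_t)
    fp_cum = np.cumsum(~sorted_t)
    # last occurrence of each distinct threshold in descending order
    distinct = np.flatnonzero(np.diff(sorted_p, append=-np.inf))
    tp = tp_cum[distinct]
    fp = fp_cum[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # ascending recall; at tied recall keep the higher precision first so the
    # curve drops vertically after the trapezoid segment
    points = sorted(zip(recall.tolist(), precision.tolist()), key=lambda rp: (rp[0], -rp[1]))
    recalls = np.array([0.0] + [r for r, _ in points])
    precisions = np.array([points[0][1]] + [p for _, p in points])
    auc = float(np.trapezoid(precisions, recalls))
    return [(float(r), float(p)) for r, p in points], auc


def report_from_probs(
    smoothed_probs, truth, hp: Hyperparameters
) -> EvalReport:
    """Assemble a full report from smoothed block probabilities and truths."""
    smoothed_probs = np.asarray(smoothed_probs, dtype=np.float64)
    truth = np.asarray(truth).astype(np.int8)
    pred = classify(smoothed_probs, hp)
    c = confusion_counts(pred, truth)
    precision = c["tp"] / (c["tp"] + c["fp"]) if (c["tp"] + c["fp"]) else 0.0
    recall = c["tp"] / (c["tp"] + c["fn"]) if (c["tp"] + c["fn"]) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        points, auc = pr_curve(smoothed_probs, truth)
    return EvalReport(
        f1=f1_score(pred, truth),
        precision=precision,
        recall=recall,
        auc=auc,
        pr_points=points,
        confusion=c,
        trace_truth=truth,
        trace_prob=smoothed_probs,
        n_blocks=len(truth),
    )


def stream_probs(model, recordings, hp: Hyperparameters) -> tuple[np.ndarray, np.ndarray]:
    """Per-recording block probabilities, median-smoothed within each stream,
    concatenated with their block truth labels."""
    from .model import predict_blocks  # local import to avoid a cycle

    all_probs: list = []
    all_truth: list = []
    for rec in recordings:
        X, y, _ = make_block_arrays(rec, hp)
        if X.shape[0] == 0:
            continue
        probs = predict_blocks(model, X)
        all_probs.append(smooth_predict(probs, hp))
        all_truth.append(y)
    if not all_probs:
        raise ValueError("no recording long enough to produce a block")
    return np.concatenate(all_probs), np.concatenate(all_truth)


def evaluate_stream(model, recordings, hp: Hyperparameters) -> EvalReport:
    """Full pipeline: blocks -> probabilities -> smoothing -> decisions.

    Smoothing is applied within each recording (streams do not bleed into one
    another); the report concatenates all per-recording traces.
    """
    devices = {rec.device.name for rec in recordings}
    if len(devices) > 1:
        raise ValueError(f"recordings mix device profiles: {sorted(devices)}")
    probs, truth = stream_probs(model, recordings, hp)
    return report_from_probs(probs, truth, hp)


def detect_events(pred) -> int:
    """Count maximal runs of consecutive positive predictions."""
    pred = np.asarray(pred).astype(np.int8)
    if pred.size == 0:
        return 0
    rises = int(pred[0]) + int((np.diff(pred) == 1).sum())
    return rises
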