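"""Dual-wrist fusion: combine synchronized left- and right-wrist smoothed
probabilities into one fall decision.

The default rule averages the two smoothed probability streams before the
single 0.4 threshold is applied (simplest symmetric rule); ``max`` fusion is
available as an alternative (equivalent, at any common threshold, to OR-ing
the per-wrist decisions, so ``"or"`` is accepted as an alias).
"""
from __future__ import annotations

import logging

import numpy as np

from .device_io import Dataset
from .errors import AlignmentError
from .evaluation import (
    EvalReport,
    evaluate_stream,
    lopo_folds,
    report_from_probs,
    stream_probs,
)
from .model import Model, ModelSpec, build, predict_blocks, train
from .transfer import transfer_train
from .windowing import Hyperparameters, make_block_arrays, smooth_predict

__all__ = ["FUSION_RULES", "ensemble_predict", "evaluate_ensemble", "lopo_compare"]

logger = logging.getLogger(__name__)

FUSION_RULES = ("mean", "max", "or")


def ensemble_predict(
    left_probs, right_probs, hp: Hyperparameters, rule: str = "mean"
) -> np.ndarray:
    """Fuse two time-aligned smoothed probability sequences.

    ``mean``: elementwise average.  ``max``/``or``: elementwise maximum.
    The sequences must be block-aligned and of equal length.
    """
    if rule not in FUSION_RULES:
        raise ValueError(f"rule must be one of {FUSION_RULES}")
    left = np.asarray(left_probs, dtype=np.float64)
    right = np.asarray(right_probs, dtype=np.float64)
    if left.shape != right.shape:
        raise AlignmentError(
            f"wrist probability sequences differ in length: {left.shape} vs {right.shape}"
        )
    for arr in (left, right):
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
    if rule == "mean":
        return (left + right) / 2.0
    return np.maximum(left, right)


def _paired_recordings(recordings):
    """Group recordings into synchronized (left, right) pairs by trial key."""
    by_key: dict = {}
    for rec in recordings:
        by_key.setdefault(rec.key, {})[rec.wrist] = rec
    pairs = []
    for key in sorted(by_key):
        wrists = by_key[key]
        if set(wrists) != {"left", "right"}:
            raise AlignmentError(f"trial {key} is missing a wrist recording")
        pairs.append((wrists["left"], wrists["right"]))
    return pairs


def evaluate_ensemble(
    left_model: Model,
    right_model: Model,
    recordings,
    hp: Hyperparameters,
    rule: str = "mean",
) -> EvalReport:
    """Evaluate the two-wrist ensemble on synchronized paired recordings."""
    fused_all, truth_all = [], []
    for left_rec, right_rec in _paired_recordings(recordings):
        XL, yL, _ = make_block_arrays(left_rec, hp)
        XR, yR, _ = make_block_arrays(right_rec, hp)
        if XL.shape[0] == 0:
            continue
        if XL.shape[0] != XR.shape[0]:
            raise AlignmentError(
                f"trial {left_rec.key}: wrists yield different block counts"
            )
        left_sm = smooth_predict(predict_blocks(left_model, XL), hp)
        right_sm = smooth_predict(predict_blocks(right_model, XR), hp)
        fused_all.append(ensemble_predict(left_sm, right_sm, hp, rule=rule))
        truth_all.append(yL)
    if not fused_all:
        raise ValueError("no paired recording long enough to produce a block")
    return report_from_probs(np.concatenate(fused_all), np.concatenate(truth_all), hp)


def _wrist_blocks(recordings, wrist, hp, step):
    xs, ys = [], []
    for rec in recordings:
        if rec.wrist != wrist:
            continue
        X, y, _ = make_block_arrays(rec, hp, step=step)
        if X.shape[0]:
            xs.append(X)
            ys.append(y.astype(np.float32))
    if not xs:
        raise ValueError(f"no {wrist}-wrist blocks available")
    return np.concatenate(xs), np.concatenate(ys)


def lopo_compare(
    dataset: Dataset,
    hp: Hyperparameters | None = None,
    epochs: int = 10,
    batch_size: int = 64,
    seed: int = 0,
    base_model: Model | None = None,
    finetune_epochs: int | None = None,
    train_step: int = 1,
    rule: str = "mean",
    variant: str = "improved",
) -> dict:
    """Leave-one-person-out comparison of the ensemble against each wrist.

    For every fold, one model per wrist is trained on that wrist's training
    data only (from scratch, or fine-tuned from ``base_model`` when given);
    the held-out subject is scored per wrist and with the fused ensemble.
    Returns mean F1 per arm plus the per-fold values.
    """
    hp = hp or dataset.device.default_hparams
    spec = ModelSpec(units=dataset.device.units_per_second, variant=variant)
    finetune_epochs = epochs if finetune_epochs is None else finetune_epochs
    per_fold: dict = {"left": [], "right": [], "ensemble": []}
    for k, (train_recs, test_recs) in enumerate(lopo_folds(dataset)):
        models = {}
        for w, wrist in enumerate(("left", "right")):
            blocks = _wrist_blocks(train_recs, wrist, hp, train_step)
            fold_seed = seed + 100 * k + w
            if base_model is None:
                m = build(spec, seed=fold_seed)
                train(m, blocks, epochs=epochs, batch_size=batch_size, seed=fold_seed)
            else:
                m = transfer_train(
                    base_model,
                    blocks,
                    epochs=finetune_epochs,
                    batch_size=batch_size,
                    seed=fold_seed,
                )
            models[wrist] = m
        for wrist in ("left", "right"):
            wrist_test = [r for r in test_recs if r.wrist == wrist]
            report = evaluate_stream(models[wrist], wrist_test, hp)
            per_fold[wrist].append(report.f1)
        ens = evaluate_ensemble(
            models["left"], models["right"], test_recs, hp, rule=rule
        )
        per_fold["ensemble"].append(ens.f1)
        logger.info(
            "fold %d: F1 left=%.3f right=%.3f ensemble=%.3f",
            k,
            per_fold["left"][-1],
            per_fold["right"][-1],
            per_fold["ensemble"][-1],
        )
    return {
        "f1_left": float(np.mean(per_fold["left"])),
        "f1_right": float(np.mean(per_fold["right"])),
        "f1_ensemble": float(np.mean(per_fold["ensemble"])),
        "per_fold": per_fold,
    }
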