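"""Source-to-target transfer: train on source, freeze the precursory layers,
fine-tune the head on the target, and compare against training from scratch.

"Precursory layers" defaults to the recurrent layer only: its weights are
kept bitwise identical to the source model's while the dense head (including
normalisation scale/shift) adapts to the target data.  Because the recurrent
layer accepts any sequence length, the target may use its own native window
size even when the devices sample at different rates.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .device_io import Dataset, DeviceProfile
from .evaluation import EvalReport, evaluate_stream, lopo_folds, split_per_person
from .model import Model, ModelSpec, build, predict_blocks, train
from .windowing import Hyperparameters, make_block_arrays

__all__ = ["FREEZE_CHOICES", "transfer_train", "run_protocol", "ProtocolResult"]

logger = logging.getLogger(__name__)

#: Which layers stay frozen during fine-tuning.
FREEZE_CHOICES = {
    "recurrent": frozenset({0}),
    "recurrent+dense1": frozenset({0, 1}),
}


def transfer_train(
    source_model: Model,
    target_blocks,
    epochs: int = 25,
    batch_size: int = 64,
    seed: int = 0,
    freeze: str = "recurrent",
    update_bn_stats: bool = True,
) -> Model:
    """Fine-tune a copy of ``source_model`` on target blocks with frozen
    precursory layers; the source model itself is left untouched."""
    if freeze not in FREEZE_CHOICES:
        raise ValueError(f"freeze must be one of {sorted(FREEZE_CHOICES)}")
    tuned = source_model.copy()
    tuned.training_meta = dict(source_model.training_meta)
    tuned.training_meta.update(
        {"transfer": {"freeze": freeze, "epochs": epochs, "seed": seed}}
    )
    if epochs == 0:
        return tuned
    return train(
        tuned,
        target_blocks,
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
        frozen_layers=FREEZE_CHOICES[freeze],
        update_bn_stats=update_bn_stats,
    )


def _dataset_blocks(recordings, hp: Hyperparameters, step: int | None = None):
    xs, ys = [], []
    for rec in recordings:
        X, y, _ = make_block_arrays(rec, hp, step=step)
        if X.shape[0]:
            xs.append(X)
            ys.append(y.astype(np.float32))
    if not xs:
        raise ValueError("no recording long enough to produce a block")
    return np.concatenate(xs), np.concatenate(ys)


def _hash_blocks(X: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(X, dtype=np.float32).tobytes()).hexdigest()


@dataclass
class ProtocolResult:
    """Paired outcome of the transfer-vs-scratch comparison."""

    split: str
    tl_reports: list  # one EvalReport per fold (single entry for 70/30)
    tfs_reports: list
    f1_tl: float  # mean over folds
    f1_tfs: float
    f1_diff: float
    test_hashes: list
    source_model: Model | None = None
    tl_models: list = field(default_factory=list)
    tfs_models: list = field(default_factory=list)

    def to_dict(self, include_trace: bool = False) -> dict:
        return {
            "split": self.split,
            "f1_tl": self.f1_tl,
            "f1_tfs": self.f1_tfs,
            "f1_diff": self.f1_diff,
            "n_folds": len(self.tl_reports),
            "tl_folds": [r.to_dict(include_trace) for r in self.tl_reports],
            "tfs_folds": [r.to_dict(include_trace) for r in self.tfs_reports],
        }


def run_protocol(
    source: Dataset,
    target: Dataset,
    hp_source: Hyperparameters | None = None,
    hp_target: Hyperparameters | None = None,
    split_strategy: str = "train_test_70_30",
    seed: int = 0,
    epochs: int = 15,
    finetune_epochs: int | None = None,
    source_epochs: int | None = None,
    batch_size: int = 64,
    train_step: int = 1,
    freeze: str = "recurrent",
    variant: str = "improved",
    class_weight: str | None = None,
    keep_models: bool = False,
) -> ProtocolResult:
    """Run the paired comparison: a model trained from scratch on the target
    training portion versus a source-pretrained model fine-tuned on the same
    portion, both evaluated on identical target test blocks.

    ``train_step`` subsamples the block starts used for *training* only
    (evaluation always uses the hyperparameter step); this trades a little
    training redundancy for speed on highly overlapping windows.
    ``source_epochs`` controls the source pretraining budget independently of
    the matched target-side budget (default: same as ``epochs``).
    """
    if split_strategy not in ("train_test_70_30", "leave_one_person_out"):
        raise ValueError(f"unknown split strategy {split_strategy!r}")
    hp_source = hp_source or source.device.default_hparams
    hp_target = hp_target or target.device.default_hparams
    finetune_epochs = epochs if finetune_epochs is None else finetune_epochs
    source_epochs = epochs if source_epochs is None else source_epochs

    spec_source = ModelSpec(units=source.device.units_per_second, variant=variant)
    spec_target = ModelSpec(units=target.device.units_per_second, variant=variant)

    logger.info("training source model on %d recordings", len(source))
    source_blocks = _dataset_blocks(source.recordings, hp_source, step=train_step)
    source_model = build(spec_source, seed=seed)
    train(
        source_model,
        source_blocks,
        epochs=source_epochs,
        batch_size=batch_size,
        seed=seed,
        class_weight=class_weight,
    )

    if split_strategy == "train_test_70_30":
        folds = [split_per_person(target, 0.7, seed=seed)]
    else:
        folds = lopo_folds(target)
        if len(folds) < 2:
            raise ValueError("leave_one_person_out requires at least 2 subjects")

    tl_reports: list[EvalReport] = []
    tfs_reports: list[EvalReport] = []
    test_hashes: list[str] = []
    tl_models: list[Model] = []
    tfs_models: list[Model] = []
    for k, (train_recs, test_recs) in enumerate(folds):
        train_blocks = _dataset_blocks(train_recs, hp_target, step=train_step)
        test_hashes.append(_hash_blocks(_dataset_blocks(test_recs, hp_target)[0]))

        tfs_model = build(spec_target, seed=seed + 1000 + k)
        train(
            tfs_model,
            train_blocks,
            epochs=epochs,
            batch_size=batch_size,
            seed=seed + 1000 + k,
            class_weight=class_weight,
        )
        tl_model = transfer_train(
            source_model,
            train_blocks,
            epochs=finetune_epochs,
            batch_size=batch_size,
            seed=seed + 2000 + k,
            freeze=freeze,
        )
        tl_reports.append(evaluate_stream(tl_model, test_recs, hp_target))
        tfs_reports.append(evaluate_stream(tfs_model, test_recs, hp_target))
        logger.info(
            "fold %d: F1(TL)=%.3f F1(TFS)=%.3f",
            k,
            tl_reports[-1].f1,
            tfs_reports[-1].f1,
        )
        if keep_models:
            tl_models.append(tl_model)
            tfs_models.append(tfs_model)

    f1_tl = float(np.mean([r.f1 for r in tl_reports]))
    f1_tfs = float(np.mean([r.f1 for r in tfs_reports]))
    return ProtocolResult(
        split=split_strategy,
        tl_reports=tl_reports,
        tfs_reports=tfs_reports,
        f1_tl=f1_tl,
        f1_tfs=f1_tfs,
        f1_diff=f1_tl - f1_tfs,
        test_hashes=test_hashes,
        source_model=source_model if keep_models else None,
        tl_models=tl_models,
        tfs_models=tfs_models,
    )
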