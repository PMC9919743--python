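"""Fixed-size data blocks, smoothed median prediction and the fall-threshold rule.

A classifier never sees a raw stream: the stream is cut into overlapping
``window_size x 3`` blocks, one probability is produced per block, the running
median over the last ``smooth_window`` block probabilities is the emitted fall
probability, and a strict threshold turns it into a binary decision.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Hyperparameters",
    "Block",
    "make_blocks",
    "make_block_arrays",
    "blocks_to_arrays",
    "block_label",
    "smooth_predict",
    "classify",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Windowing and decision hyperparameters.

    Attributes
    ----------
    window_size:
        Number of consecutive samples per classifier input block.
    step_size:
        Offset between the start indices of consecutive blocks.
    smooth_window:
        Number of trailing block probabilities whose median is emitted.
    fall_threshold:
        Strict probability cutoff above which a decision is "fall".
    """

    window_size: int
    step_size: int = 1
    smooth_window: int = 1
    fall_threshold: float = 0.4

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (1 <= self.step_size <= self.window_size):
            raise ValueError("step_size must satisfy 1 <= step_size <= window_size")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not (0.0 < self.fall_threshold < 1.0):
            raise ValueError("fall_threshold must lie strictly between 0 and 1")


@dataclass(frozen=True)
class Block:
    """One classifier input slice: ``window_size`` rows of (x, y, z) in g."""

    data: np.ndarray  # (window_size, 3) float32
    label: int
    start_index: int

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        if data.ndim != 2:
            raise ValueError("block data must be 2-D (window_size x channels)")
        object.__setattr__(self, "data", data)

    @property
    def window_size(self) -> int:
        return self.data.shape[0]


def block_label(entry_labels: Sequence[int]) -> int:
    """Label a block 1 iff at least half of its entries are labeled fall."""
    labels = np.asarray(entry_labels)
    if labels.size == 0:
        raise ValueError("entry_labels must be nonempty")
    return int(labels.mean() >= 0.5)


def make_block_arrays(
    rec, hp: Hyperparameters, step: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised block extraction.

    Returns ``(X, y, starts)`` where ``X`` has shape
    ``(n_blocks, window_size, 3)``, ``y`` holds the majority labels and
    ``starts`` the start sample index of each block.  Recordings shorter than
    one window yield zero blocks.
    """
    W = hp.window_size
    S = hp.step_size if step is None else int(step)
    if S < 1:
        raise ValueError("step must be >= 1")
    xyz = np.asarray(rec.xyz, dtype=np.float32)
    labels = np.asarray(rec.labels)
    N = xyz.shape[0]
    if N < W:
        return (
            np.empty((0, W, xyz.shape[1] if xyz.ndim == 2 else 3), dtype=np.float32),
            np.empty((0,), dtype=np.int8),
            np.empty((0,), dtype=np.int64),
        )
    starts = np.arange(0, N - W + 1, S, dtype=np.int64)
    windows = sliding_window_view(xyz, W, axis=0)  # (N-W+1, 3, W)
    X = np.ascontiguousarray(windows[starts].transpose(0, 2, 1))
    lab_windows = sliding_window_view(labels, W)[starts]
    y = (lab_windows.mean(axis=1) >= 0.5).astype(np.int8)
    return X, y, starts


def make_blocks(rec, hp: Hyperparameters, step: int | None = None) -> list[Block]:
    """Cut a recording into overlapping blocks.

    With ``N`` samples, window ``W`` and step ``S`` the block count is
    ``floor((N - W) / S) + 1`` for ``N >= W`` and 0 otherwise; consecutive
    blocks share exactly ``W - S`` entries.
    """
    X, y, starts = make_block_arrays(rec, hp, step=step)
    return [Block(X[i], int(y[i]), int(starts[i])) for i in range(len(starts))]


def blocks_to_arrays(blocks: Sequence[Block]) -> tuple[np.ndarray, np.ndarray]:
    """Stack blocks into ``(X, y)`` arrays; widths must agree."""
    if len(blocks) == 0:
        raise ValueError("no blocks to stack")
    widths = {b.data.shape[0] for b in blocks}
    if len(widths) != 1:
        raise ValueError(f"mixed block widths: {sorted(widths)}")
    X = np.stack([b.data for b in blocks]).astype(np.float32)
    y = np.asarray([b.label for b in blocks], dtype=np.float32)
    return X, y


def smooth_predict(block_probs: Sequence[float], hp: Hyperparameters) -> np.ndarray:
    """Trailing-median smoothing of block probabilities.

    ``out[i]`` is the median of ``block_probs[max(0, i-K+1) .. i]`` with
    ``K = hp.smooth_window``; at the start of the stream the median is taken
    over the available prefix.  A median over an even count is the mean of the
    two central order statistics.
    """
    p = np.asarray(block_probs, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("block_probs must be 1-D")
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    K = hp.smooth_window
    n = p.size
    if K == 1 or n <= 1:
        return p.copy()
    out = np.empty_like(p)
    head = min(K - 1, n)
    for i in range(head):
        out[i] = np.median(p[: i + 1])
    if n >= K:
        out[K - 1 :] = np.median(sliding_window_view(p, K), axis=1)
    return out


def classify(prob, hp: Hyperparameters):
    """Binary decision: 1 iff the probability strictly exceeds the threshold."""
    arr = np.asarray(prob, dtype=np.float64)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    result = (arr > hp.fall_threshold).astype(np.int8)
    if np.isscalar(prob) or arr.ndim == 0:
        return int(result)
    return result
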