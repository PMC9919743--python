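"""Label post-processing: peak-centred fall windows, programmatic multi-peak
location, ADL trimming and multi-trial segmentation.

The conventions implemented here mirror how collected files were prepared for
training: each fall trial keeps exactly one contiguous run of fall labels
centred on the acceleration-magnitude peak, and ADL files are trimmed to the
smallest multiple of a fixed unit (100 samples) that spans the activity.
"""
from __future__ import annotations

import math

import numpy as np

from .device_io import Recording

__all__ = [
    "FALL_WINDOW_WIDTH",
    "PEAK_LABEL_WIDTH",
    "relabel_fall_peak",
    "locate_fall_peaks",
    "trim_adl",
    "segment_trials",
]

#: Width in samples of a relabelled fall window (captures pre- and post-fall).
FALL_WINDOW_WIDTH = 100
#: Width used by the first-pass programmatic peak labeller.
PEAK_LABEL_WIDTH = 35


def _fall_window_bounds(center: int, width: int, n: int) -> tuple[int, int]:
    """Half-open [start, stop) of a width-sample window centred on ``center``,
    shifted inward at the recording boundaries so the width is preserved."""
    start = center - width // 2
    start = max(0, min(start, n - width))
    return start, start + width


def relabel_fall_peak(rec: Recording, width: int = FALL_WINDOW_WIDTH) -> Recording:
    """Relabel so exactly one ``width``-sample run of fall labels is centred on
    the magnitude argmax (earliest index on ties); everything else is 0."""
    if width < 1:
        raise ValueError("width must be >= 1")
    n = len(rec)
    if n == 0:
        raise ValueError("recording is empty")
    if width > n:
        raise ValueError(f"width {width} exceeds recording length {n}")
    center = int(np.argmax(rec.magnitudes))
    start, stop = _fall_window_bounds(center, width, n)
    labels = np.zeros(n, dtype=np.int8)
    labels[start:stop] = 1
    return rec.replace(labels=labels)


def locate_fall_peaks(rec: Recording, n_trials: int, width: int = PEAK_LABEL_WIDTH) -> list[int]:
    """Greedy non-maximum suppression over the magnitude signal.

    Repeatedly takes the global magnitude maximum among unexcluded samples and
    excludes all indices within ``width`` of it, until ``n_trials`` centres are
    found.  Returned centres are pairwise at least ``width`` apart, sorted
    ascending.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n = len(rec)
    if n < n_trials * width:
        raise ValueError(
            f"recording of {n} samples cannot host {n_trials} "
            f"non-overlapping windows of width {width}"
        )
    mags = rec.magnitudes.copy()
    centers: list[int] = []
    for _ in range(n_trials):
        if not np.isfinite(mags).any():
            raise ValueError(
                f"no candidate sample left for trial {len(centers) + 1} "
                f"(peaks closer than width={width})"
            )
        c = int(np.argmax(np.nan_to_num(mags, nan=-np.inf)))
        if not np.isfinite(mags[c]):
            raise ValueError(
                f"no candidate sample left for trial {len(centers) + 1}"
            )
        centers.append(c)
        lo, hi = max(0, c - width + 1), min(n, c + width)
        mags[lo:hi] = np.nan
    return sorted(centers)


def trim_adl(rec: Recording, unit: int = 100, deviation_g: float = 0.05) -> Recording:
    """Trim an ADL recording to the smallest multiple of ``unit`` samples that
    spans the activity, centred on the activity span and clipped to bounds.

    The activity span runs from the first to the last sample whose magnitude
    deviates from the per-recording median magnitude by more than
    ``deviation_g``.  All output labels are 0.
    """
    if unit < 1:
        raise ValueError("unit must be >= 1")
    n = len(rec)
    mags = rec.magnitudes
    active = np.flatnonzero(np.abs(mags - np.median(mags)) > deviation_g)
    if active.size == 0:
        raise ValueError("activity span is empty (signal never leaves baseline)")
    first, last = int(active[0]), int(active[-1])
    span = last - first + 1
    out_len = min(n, unit * math.ceil(span / unit))
    center = (first + last) // 2
    start = center - out_len // 2
    start = max(0, min(start, n - out_len))
    out = rec.slice(start, start + out_len)
    out.labels[:] = 0
    return out


def segment_trials(
    rec: Recording,
    n_trials: int,
    kind: str | None = None,
    width: int = PEAK_LABEL_WIDTH,
) -> list[Recording]:
    """Split a multi-trial file into ``n_trials`` recordings.

    Fall files are split at the midpoints between consecutive peak centres
    found by :func:`locate_fall_peaks`; ADL files are split at equal-length
    boundaries.  ``kind`` is ``"fall"`` or ``"adl"``; if omitted it is
    inferred from the labels / activity name.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n = len(rec)
    if kind is None:
        kind = "fall" if (rec.labels.any() or "fall" in rec.activity.lower()) else "adl"
    if kind not in ("fall", "adl"):
        raise ValueError("kind must be 'fall' or 'adl'")
    if n_trials == 1:
        return [rec.slice(0, n, trial=0)]
    if kind == "fall":
        centers = locate_fall_peaks(rec, n_trials, width=width)
        bounds = [0]
        for a, b in zip(centers[:-1], centers[1:]):
            bounds.append((a + b + 1) // 2)
        bounds.append(n)
    else:
        bounds = [round(i * n / n_trials) for i in range(n_trials + 1)]
    return [
        rec.slice(bounds[i], bounds[i + 1], trial=i) for i in range(n_trials)
    ]
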