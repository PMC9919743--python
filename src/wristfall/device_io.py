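"""Labelled accelerometer recordings and heterogeneous-device normalisation.

All in-memory acceleration values are expressed in g.  Each device profile
carries a multiplicative ``unit_scale`` applied when reading raw CSV files
(and divided out when writing), so that downstream computation never has to
care which hardware produced a recording.

CSV dialect: comma separated, header ``t_ms,x,y,z,label``, UTF-8, '.' decimal
separator.  Dataset directory layout::

    <dataset>/<subject_id>/<wrist>/<activity>_<trial>.csv
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .windowing import Hyperparameters

__all__ = [
    "DeviceProfile",
    "AccelSample",
    "Recording",
    "Dataset",
    "MSBAND",
    "HUAWEI",
    "METASENSOR",
    "PROFILES",
    "get_profile",
    "magnitude",
    "read_recording",
    "write_recording",
    "read_dataset",
    "write_dataset",
    "resample",
]

CSV_COLUMNS = ("t_ms", "x", "y", "z", "label")
WRISTS = ("left", "right")


def _default_hparams(sampling_hz: float) -> Hyperparameters:
    # Window of one second of samples, unit step, two-second smooth window,
    # strict 0.4 decision threshold.
    w = int(round(sampling_hz))
    return Hyperparameters(
        window_size=w, step_size=1, smooth_window=2 * w, fall_threshold=0.4
    )


@dataclass(frozen=True)
class DeviceProfile:
    """Per-hardware description driving normalisation and defaults."""

    name: str
    sampling_hz: float
    unit_scale: float
    wrists: frozenset = frozenset({"left"})
    default_hparams: Hyperparameters = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.unit_scale <= 0:
            raise ValueError("unit_scale must be positive")
        if not frozenset(self.wrists) <= frozenset(WRISTS):
            raise ValueError(f"wrists must be a subset of {WRISTS}")
        object.__setattr__(self, "wrists", frozenset(self.wrists))
        if self.default_hparams is None:
            object.__setattr__(
                self, "default_hparams", _default_hparams(self.sampling_hz)
            )
        if self.default_hparams.window_size != int(round(self.sampling_hz)):
            raise ValueError(
                "default window_size must equal one second of samples "
                f"({int(round(self.sampling_hz))}), got "
                f"{self.default_hparams.window_size}"
            )

    @property
    def units_per_second(self) -> int:
        return int(round(self.sampling_hz))


MSBAND = DeviceProfile("msband", 32.0, 1.0, frozenset({"left"}))
HUAWEI = DeviceProfile("huawei", 32.0, 1.0, frozenset({"left"}))
METASENSOR = DeviceProfile("metasensor", 50.0, 2.0, frozenset({"left", "right"}))

PROFILES = {p.name: p for p in (MSBAND, HUAWEI, METASENSOR)}


def get_profile(name: str, **overrides) -> DeviceProfile:
    """Look up a built-in profile, optionally overriding fields."""
    try:
        profile = PROFILES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown device profile {name!r}; known: {sorted(PROFILES)}"
        ) from None
    if overrides:
        if "sampling_hz" in overrides and "default_hparams" not in overrides:
            overrides.setdefault(
                "default_hparams", _default_hparams(overrides["sampling_hz"])
            )
        profile = dataclasses.replace(profile, **overrides)
    return profile


class AccelSample(NamedTuple):
    t_ms: float
    x: float
    y: float
    z: float
    label: int
    activity: str | None = None


def magnitude(sample) -> float:
    """Euclidean norm of a tri-axial acceleration sample, in g."""
    if hasattr(sample, "x"):
        x, y, z = sample.x, sample.y, sample.z
    else:
        x, y, z = sample
    return math.sqrt(x * x + y * y + z * z)


@dataclass
class Recording:
    """One subject/wrist/activity tri-axial labelled time series (values in g)."""

    subject_id: str
    wrist: str
    device: DeviceProfile
    activity: str
    t_ms: np.ndarray
    xyz: np.ndarray
    labels: np.ndarray
    trial: int = 0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.float64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.wrist not in WRISTS:
            raise ValueError(f"wrist must be one of {WRISTS}")
        n = self.t_ms.shape[0]
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must have shape (n_samples, 3)")
        if self.labels.shape != (n,):
            raise ValueError("labels must have shape (n_samples,)")
        if not np.isfinite(self.t_ms).all() or not np.isfinite(self.xyz).all():
            raise DataError("non-finite values in recording")
        bad = np.flatnonzero(~np.isin(self.labels, (0, 1)))
        if bad.size:
            raise DataError(f"labels must be 0 or 1 (row {bad[0] + 1})")
        if n > 1:
            nonmono = np.flatnonzero(np.diff(self.t_ms) <= 0)
            if nonmono.size:
                raise DataError(
                    "timestamps not strictly increasing at row "
                    f"{nonmono[0] + 2}"
                )

    def __len__(self) -> int:
        return int(self.t_ms.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.sqrt((self.xyz**2).sum(axis=1))

    def sample(self, i: int) -> AccelSample:
        return AccelSample(
            float(self.t_ms[i]),
            float(self.xyz[i, 0]),
            float(self.xyz[i, 1]),
            float(self.xyz[i, 2]),
            int(self.labels[i]),
            self.activity,
        )

    def samples(self) -> Iterator[AccelSample]:
        for i in range(len(self)):
            yield self.sample(i)

    def replace(self, **kwargs) -> "Recording":
        return dataclasses.replace(self, **kwargs)

    def slice(self, start: int, stop: int, trial: int | None = None) -> "Recording":
        return self.replace(
            t_ms=self.t_ms[start:stop].copy(),
            xyz=self.xyz[start:stop].copy(),
            labels=self.labels[start:stop].copy(),
            trial=self.trial if trial is None else trial,
        )

    @property
    def key(self) -> tuple:
        """Identity of one trial, shared across wrists of a synchronized pair."""
        return (self.subject_id, self.activity, self.trial)


@dataclass
class Dataset:
    """A nonempty collection of recordings sharing one device profile."""

    recordings: list

    def __post_init__(self) -> None:
        if not self.recordings:
            raise ValueError("a dataset must contain at least one recording")
        names = {rec.device.name for rec in self.recordings}
        if len(names) != 1:
            raise ValueError(f"mixed device profiles in one dataset: {sorted(names)}")

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    @property
    def device(self) -> DeviceProfile:
        return self.recordings[0].device

    @property
    def subjects(self) -> list:
        return sorted({rec.subject_id for rec in self.recordings})

    def by_subject(self) -> dict:
        out: dict = {}
        for rec in self.recordings:
            out.setdefault(rec.subject_id, []).append(rec)
        return out

    def select(self, wrist: str | None = None, subjects: Sequence[str] | None = None):
        recs = self.recordings
        if wrist is not None:
            recs = [r for r in recs if r.wrist == wrist]
        if subjects is not None:
            wanted = set(subjects)
            recs = [r for r in recs if r.subject_id in wanted]
        return recs

    def filter(self, **kwargs) -> "Dataset":
        recs = self.select(**kwargs)
        return Dataset(recs)


def _parse_labels(raw: pd.Series, path) -> np.ndarray:
    labels = np.empty(len(raw), dtype=np.int8)
    for i, value in enumerate(raw):
        if isinstance(value, str):
            s = value.strip()
            try:
                num = float(s)
            except ValueError:
                labels[i] = 1 if s.lower() == "fall" else 0
                continue
            value = num
        num = float(value)
        if num not in (0.0, 1.0):
            raise DataError(f"{path}: numeric label must be 0 or 1 (row {i + 1})")
        labels[i] = int(num)
    return labels


def read_recording(
    path,
    profile: DeviceProfile,
    *,
    subject_id: str | None = None,
    wrist: str | None = None,
    activity: str | None = None,
    trial: int | None = None,
) -> Recording:
    """Read one labelled CSV recording, converting raw values to g.

    Identity fields not given explicitly are inferred from the dataset layout
    ``<dataset>/<subject>/<wrist>/<activity>_<trial>.csv`` when possible.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"label": object})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(frame) == 0:
        raise FormatError(f"{path}: recording is empty")

    t_ms = frame["t_ms"].to_numpy(dtype=np.float64)
    nonmono = np.flatnonzero(np.diff(t_ms) <= 0)
    if nonmono.size:
        raise DataError(
            f"{path}: timestamps not strictly increasing at row {nonmono[0] + 2}"
        )
    xyz = frame[["x", "y", "z"]].to_numpy(dtype=np.float64) * profile.unit_scale
    labels = _parse_labels(frame["label"], path)

    stem = path.stem
    inferred_activity, inferred_trial = stem, 0
    if "_" in stem:
        head, tail = stem.rsplit("_", 1)
        if tail.isdigit():
            inferred_activity, inferred_trial = head, int(tail)
    parts = path.parts
    inferred_wrist = parts[-2] if len(parts) >= 2 and parts[-2] in WRISTS else "left"
    inferred_subject = parts[-3] if len(parts) >= 3 and parts[-2] in WRISTS else "s00"

    return Recording(
        subject_id=subject_id or inferred_subject,
        wrist=wrist or inferred_wrist,
        device=profile,
        activity=activity or inferred_activity,
        t_ms=t_ms,
        xyz=xyz,
        labels=labels,
        trial=inferred_trial if trial is None else trial,
    )


def _format_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else f"{t:.6f}"


def write_recording(rec: Recording, path) -> Path:
    """Write a recording back to raw device units; round-trips with read."""
    if len(rec) == 0:
        raise FormatError("refusing to write an empty recording")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    raw = rec.xyz / rec.device.unit_scale
    lines = ["t_ms,x,y,z,label"]
    for i in range(len(rec)):
        lines.append(
            f"{_format_time(rec.t_ms[i])},"
            f"{raw[i, 0]:.8f},{raw[i, 1]:.8f},{raw[i, 2]:.8f},"
            f"{int(rec.labels[i])}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_dataset(root, profile: DeviceProfile) -> Dataset:
    """Read a dataset directory laid out as ``<root>/<subject>/<wrist>/*.csv``."""
    root = Path(root)
    if not root.is_dir():
        raise FormatError(f"{root}: not a dataset directory")
    recordings = []
    for subject_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for wrist_dir in sorted(p for p in subject_dir.iterdir() if p.is_dir()):
            if wrist_dir.name not in WRISTS:
                raise FormatError(
                    f"{wrist_dir}: wrist directory must be one of {WRISTS}"
                )
            for csv_path in sorted(wrist_dir.glob("*.csv")):
                recordings.append(
                    read_recording(
                        csv_path,
                        profile,
                        subject_id=subject_dir.name,
                        wrist=wrist_dir.name,
                    )
                )
    if not recordings:
        raise FormatError(f"{root}: no recordings found")
    return Dataset(recordings)


def write_dataset(ds: Dataset, root) -> Path:
    root = Path(root)
    for rec in ds:
        write_recording(
            rec,
            root / rec.subject_id / rec.wrist / f"{rec.activity}_{rec.trial}.csv",
        )
    return root


def resample(rec: Recording, target_hz: float) -> Recording:
    """Linearly interpolate a recording onto a uniform grid at ``target_hz``.

    The grid spans ``[t_ms[0], t_ms[-1]]`` and contains
    ``floor(duration_s * target_hz) + 1`` samples.  Labels are copied from the
    nearest original sample (earlier sample on ties).
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if len(rec) < 2:
        raise ValueError("resample requires at least 2 samples")
    t = rec.t_ms
    duration_s = (t[-1] - t[0]) / 1000.0
    n_out = int(math.floor(duration_s * target_hz + 1e-9)) + 1
    new_t = t[0] + np.arange(n_out) * (1000.0 / target_hz)
    new_t[-1] = min(new_t[-1], t[-1])  # guard float overshoot at the end
    xyz = np.column_stack([np.interp(new_t, t, rec.xyz[:, k]) for k in range(3)])
    pos = np.interp(new_t, t, np.arange(len(rec), dtype=np.float64))
    frac = pos - np.floor(pos)
    idx = np.where(frac <= 0.5, np.floor(pos), np.ceil(pos)).astype(np.int64)
    return rec.replace(t_ms=new_t, xyz=xyz, labels=rec.labels[idx].copy())
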