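"""Synthetic labelled fall / ADL accelerometer recordings.

Every trial is first drawn as a *continuous-time script* (event times, spike
amplitudes, gravity orientations) that is independent of the recording
hardware; the script is then rendered at a device profile's sampling rate.
Rendering the same script with two different profiles therefore yields the
same event schedule at different rates — "same activity, different hardware"
is literal.  Paired wrists share one script and differ only by a per-wrist
amplitude scale and independent sensor noise.

Falls: a quiet pre-fall phase (gravity plus noise), a ~1 s cluster of 3-6
spikes whose dominant peak magnitude is drawn from [2.5, 3.5] g, then
post-impact stillness with a shifted gravity orientation.  Exactly 100
samples centred on the scripted peak are labelled fall.  ADLs are all
labelled 0 and have lengths that are multiples of 100 samples; the jacket
activity optionally contains a fall-like (>2 g) confounder cluster.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .device_io import Dataset, DeviceProfile, METASENSOR, Recording

__all__ = [
    "ACTIVITIES",
    "FALL_TYPES",
    "SyntheticConfig",
    "simulate_fall",
    "simulate_adl",
    "simulate_dataset",
]

FALL_TYPES = ("front", "back", "left", "right")
ACTIVITIES = ("walking", "waving", "drinking", "jacket", "sitting", "picking")

_FALL_LABEL_WIDTH = 100
_ADL_LENGTH_UNIT = 100


def _default_adl_menu() -> dict:
    return {name: 3 for name in ACTIVITIES}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; fully determines the dataset via ``seed``."""

    n_subjects: int = 8
    falls_per_subject: int = 20  # total per subject, cycled over FALL_TYPES
    adl_menu: dict = field(default_factory=_default_adl_menu)
    device: DeviceProfile = METASENSOR
    wrists: tuple = ("left",)
    confounder_rate: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.falls_per_subject < 0:
            raise ValueError("counts must be >= 0")
        if any(n < 0 for n in self.adl_menu.values()):
            raise ValueError("ADL trial counts must be >= 0")
        unknown = set(self.adl_menu) - set(ACTIVITIES)
        if unknown:
            raise ValueError(f"unknown activities in menu: {sorted(unknown)}")
        if not (0.0 <= self.confounder_rate <= 1.0):
            raise ValueError("confounder_rate must lie in [0, 1]")
        if set(self.wrists) not in ({"left"}, {"right"}, {"left", "right"}, set()):
            raise ValueError("wrists must be a subset of {'left', 'right'}")
        object.__setattr__(self, "wrists", tuple(sorted(self.wrists)))


# -- continuous-time scripts ----------------------------------------------


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rest_gravity(rng: np.random.Generator) -> np.ndarray:
    # mostly along +z (watch face up-ish), slightly perturbed
    v = np.array([0.0, 0.0, 1.0]) + 0.2 * rng.normal(size=3)
    return v / np.linalg.norm(v)


def _fall_script(rng: np.random.Generator) -> dict:
    # quiet lead-in, wobble, impact cluster, then little tail beyond the
    # labelled window so post-impact stillness is mostly labelled fall
    t_peak = float(rng.uniform(2.5, 4.5))
    duration = t_peak + float(rng.uniform(1.4, 1.9))
    main_mag = float(rng.uniform(2.5, 3.5))
    # Narrow spikes with >=0.15 s separation and a dominant snapped main peak
    # keep the sampled magnitude argmax exactly on the scripted peak sample.
    spikes = [
        {
            "t": t_peak,
            "target": main_mag,
            "sigma": float(rng.uniform(0.03, 0.045)),
            "dir": _unit_vector(rng),
            "snap": True,
        }
    ]
    # secondary spikes occupy disjoint time slots so their envelopes cannot
    # stack into a peak that out-grows the main one
    slots = np.array([-0.42, -0.30, -0.18, 0.18, 0.30, 0.42])
    n_secondary = int(rng.integers(2, 5))  # 3-5 spikes in total
    for offset in rng.permutation(slots)[:n_secondary]:
        spikes.append(
            {
                "t": t_peak + float(offset) + float(rng.uniform(-0.01, 0.01)),
                "target": float(rng.uniform(1.2, main_mag - 0.8)),
                "sigma": float(rng.uniform(0.02, 0.035)),
                "dir": _unit_vector(rng),
                "snap": False,
            }
        )
    # losing-balance wobble leading into the impact (faster than gait)
    wobble = {
        "axis": int(rng.integers(0, 3)),
        "amp": float(rng.uniform(0.3, 0.45)),
        "freq": float(rng.uniform(3.5, 5.0)),
        "phase": float(rng.uniform(0, 2 * np.pi)),
        "t0": t_peak - float(rng.uniform(1.6, 2.2)),
        "t1": t_peak - 0.15,
    }
    return {
        "kind": "fall",
        "duration_s": duration,
        "t_peak": t_peak,
        "gravity_pre": _rest_gravity(rng),
        "gravity_post": _unit_vector(rng),
        "change_dur": 0.3,
        "spikes": spikes,
        "oscillations": [wobble],
    }


def _adl_script(activity: str, rng: np.random.Generator, confounder_rate: float) -> dict:
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}; known: {ACTIVITIES}")
    duration = float(rng.uniform(2.0, 6.0))
    gravity = _rest_gravity(rng)
    script = {
        "kind": activity,
        "duration_s": duration,
        "t_peak": None,
        "gravity_pre": gravity,
        "gravity_post": None,
        "change_dur": 0.0,
        "spikes": [],
        "oscillations": [],
    }
    if activity == "walking":
        freq = float(rng.uniform(1.8, 2.2))
        script["oscillations"] = [
            {"axis": 0, "amp": 0.3, "freq": freq, "phase": float(rng.uniform(0, 2 * np.pi)),
             "t0": 0.0, "t1": duration},
            {"axis": 1, "amp": 0.2, "freq": 2 * freq, "phase": float(rng.uniform(0, 2 * np.pi)),
             "t0": 0.0, "t1": duration},
        ]
    elif activity == "waving":
        for _ in range(int(rng.integers(2, 5))):
            t0 = float(rng.uniform(0.0, max(duration - 1.0, 0.1)))
            script["oscillations"].append(
                {"axis": int(rng.integers(0, 3)), "amp": float(rng.uniform(0.3, 0.6)),
                 "freq": float(rng.uniform(0.8, 2.0)),
                 "phase": float(rng.uniform(0, 2 * np.pi)),
                 "t0": t0, "t1": min(duration, t0 + float(rng.uniform(0.5, 1.5)))}
            )
    elif activity == "drinking":
        script["oscillations"] = [
            {"axis": 2, "amp": 0.15, "freq": 0.3,
             "phase": float(rng.uniform(0, 2 * np.pi)), "t0": 0.0, "t1": duration}
        ]
        script["spikes"] = [
            {"t": float(rng.uniform(0.5, duration - 0.5)), "target": 1.25,
             "sigma": 0.15, "dir": _unit_vector(rng), "snap": False}
        ]
    elif activity in ("sitting", "picking"):
        script["spikes"] = [
            {"t": float(rng.uniform(0.5, duration - 0.5)),
             "target": float(rng.uniform(1.3, 1.7)),
             "sigma": float(rng.uniform(0.05, 0.1)),
             "dir": _unit_vector(rng), "snap": True}
        ]
    elif activity == "jacket":
        if rng.random() < confounder_rate:
            t_c = float(rng.uniform(1.0, duration - 1.0))
            main = float(rng.uniform(2.4, 2.8))
            script["spikes"] = [
                {"t": t_c, "target": main, "sigma": float(rng.uniform(0.04, 0.06)),
                 "dir": _unit_vector(rng), "snap": True}
            ]
            for _ in range(int(rng.integers(1, 4))):
                offset = float(rng.uniform(0.08, 0.4)) * (1 if rng.random() < 0.5 else -1)
                script["spikes"].append(
                    {"t": t_c + offset, "target": float(rng.uniform(1.4, main - 0.3)),
                     "sigma": float(rng.uniform(0.02, 0.05)),
                     "dir": _unit_vector(rng), "snap": False}
                )
        else:
            script["oscillations"] = [
                {"axis": int(rng.integers(0, 3)), "amp": 0.4,
                 "freq": float(rng.uniform(0.8, 1.5)),
                 "phase": float(rng.uniform(0, 2 * np.pi)),
                 "t0": 0.2, "t1": duration - 0.2}
            ]
    return script


# -- rendering -------------------------------------------------------------


def _gravity_track(script: dict, t: np.ndarray) -> np.ndarray:
    g_pre = np.asarray(script["gravity_pre"])
    g_post = script["gravity_post"]
    if g_post is None or script["t_peak"] is None:
        return np.tile(g_pre, (t.size, 1))
    g_post = np.asarray(g_post)
    t0 = script["t_peak"]
    blend = np.clip((t - t0) / max(script["change_dur"], 1e-9), 0.0, 1.0)[:, None]
    return (1.0 - blend) * g_pre + blend * g_post


def _render(
    script: dict,
    profile: DeviceProfile,
    noise_rng: np.random.Generator,
    noise_sd: float,
    wrist_scale: float = 1.0,
    wrist: str = "left",
    subject_id: str = "s00",
    activity: str | None = None,
    trial: int = 0,
) -> Recording:
    hz = profile.sampling_hz
    if script["kind"] == "fall":
        n = int(math.floor(script["duration_s"] * hz)) + 1
    else:
        n = _ADL_LENGTH_UNIT * max(
            1, math.ceil(script["duration_s"] * hz / _ADL_LENGTH_UNIT)
        )
    t = np.arange(n) / hz
    gravity = _gravity_track(script, t)
    sig = gravity.copy()
    for spike in script["spikes"]:
        ts = spike["t"]
        if spike["snap"]:
            ts = round(ts * hz) / hz  # land the peak exactly on a sample
        i_near = min(n - 1, max(0, int(round(ts * hz))))
        contribution = spike["target"] * spike["dir"] - gravity[i_near]
        envelope = np.exp(-((t - ts) ** 2) / (2.0 * spike["sigma"] ** 2))
        sig += wrist_scale * envelope[:, None] * contribution
    for osc in script["oscillations"]:
        window = ((t >= osc["t0"]) & (t <= osc["t1"])).astype(float)
        sig[:, osc["axis"]] += (
            wrist_scale
            * osc["amp"]
            * window
            * np.sin(2 * np.pi * osc["freq"] * t + osc["phase"])
        )
    sig += noise_rng.normal(0.0, noise_sd, size=(n, 3))

    labels = np.zeros(n, dtype=np.int8)
    if script["kind"] == "fall":
        width = min(_FALL_LABEL_WIDTH, n)
        center = int(round(script["t_peak"] * hz))
        start = max(0, min(center - width // 2, n - width))
        labels[start : start + width] = 1

    return Recording(
        subject_id=subject_id,
        wrist=wrist,
        device=profile,
        activity=activity or ("fall" if script["kind"] == "fall" else script["kind"]),
        t_ms=t * 1000.0,
        xyz=sig,
        labels=labels,
        trial=trial,
    )


# -- public operations -----------------------------------------------------


def simulate_fall(
    profile: DeviceProfile,
    rng: np.random.Generator,
    noise_sd: float = 0.05,
    **identity,
) -> Recording:
    """One simulated fall recording with a planted, exactly-100-sample fall
    window centred on the scripted magnitude peak."""
    script = _fall_script(rng)
    return _render(script, profile, rng, noise_sd, **identity)


def simulate_adl(
    activity: str,
    profile: DeviceProfile,
    rng: np.random.Generator,
    confounder_rate: float = 0.5,
    noise_sd: float = 0.05,
    **identity,
) -> Recording:
    """One simulated ADL recording (all labels 0, length a multiple of 100)."""
    script = _adl_script(activity, rng, confounder_rate)
    return _render(script, profile, rng, noise_sd, activity=activity, **identity)


def _trial_plan(cfg: SyntheticConfig) -> list[tuple[str, int]]:
    plan = []
    for j in range(cfg.falls_per_subject):
        plan.append((f"fall-{FALL_TYPES[j % len(FALL_TYPES)]}", j))
    for activity in ACTIVITIES:
        for k in range(cfg.adl_menu.get(activity, 0)):
            plan.append((activity, k))
    return plan


def simulate_dataset(cfg: SyntheticConfig) -> Dataset:
    """Generate a full per-subject dataset, optionally with paired wrists.

    Trial scripts depend only on ``(seed, subject, trial)`` — not on the
    device profile or wrist — so re-running with a different device yields the
    same event schedule at a different rate, and paired wrists share event
    times and waveform shape up to a per-wrist amplitude scale in [0.7, 1.3]
    and independent noise.
    """
    plan = _trial_plan(cfg)
    paired = len(cfg.wrists) == 2
    recordings = []
    for s in range(cfg.n_subjects):
        subject_id = f"s{s + 1:02d}"
        for plan_idx, (activity, trial) in enumerate(plan):
            script_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, s, plan_idx])
            )
            if activity.startswith("fall-"):
                script = _fall_script(script_rng)
            else:
                script = _adl_script(activity, script_rng, cfg.confounder_rate)
            scales = (
                script_rng.uniform(0.7, 1.3, size=2) if paired else np.ones(2)
            )
            for w, wrist in enumerate(cfg.wrists):
                noise_rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, s, plan_idx, w, 977])
                )
                recordings.append(
                    _render(
                        script,
                        cfg.device,
                        noise_rng,
                        cfg.noise_sd,
                        wrist_scale=float(scales[w]),
                        wrist=wrist,
                        subject_id=subject_id,
                        activity=activity,
                        trial=trial,
                    )
                )
    return Dataset(recordings)
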