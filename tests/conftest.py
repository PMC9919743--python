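import numpy as np
import pytest

from wristfall.device_io import MSBAND, METASENSOR, DeviceProfile, Recording
from wristfall.model import ModelSpec, build, train
from wristfall.synthetic import SyntheticConfig, simulate_dataset
from wristfall.transfer import _dataset_blocks


@pytest.fixture(scope="session")
def toy_profile() -> DeviceProfile:
    """A slow 10 Hz device so toy pipelines stay tiny."""
    return DeviceProfile("toyband", 10.0, 1.0, frozenset({"left", "right"}))


def make_recording(
    xyz,
    labels=None,
    t_ms=None,
    profile=MSBAND,
    subject="s01",
    wrist="left",
    activity="walking",
    trial=0,
):
    xyz = np.asarray(xyz, dtype=float)
    n = xyz.shape[0]
    if labels is None:
        labels = np.zeros(n, dtype=np.int8)
    if t_ms is None:
        t_ms = np.arange(n) * (1000.0 / profile.sampling_hz)
    return Recording(subject, wrist, profile, activity, t_ms, xyz, labels, trial)


@pytest.fixture()
def flat_recording():
    """200 samples of 1 g along z with a 3 g spike at index 100."""
    xyz = np.zeros((200, 3))
    xyz[:, 2] = 1.0
    xyz[100] = [0.0, 0.0, 3.0]
    return make_recording(xyz)


@pytest.fixture(scope="session")
def toy_dataset(toy_profile):
    """Small single-wrist synthetic dataset at 10 Hz (3 subjects)."""
    cfg = SyntheticConfig(
        n_subjects=3,
        falls_per_subject=3,
        adl_menu={"walking": 2, "sitting": 1, "jacket": 1},
        device=toy_profile,
        wrists=("left",),
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_model(toy_dataset, toy_profile):
    """A quickly trained 10-unit model shared across tests."""
    hp = toy_profile.default_hparams
    blocks = _dataset_blocks(toy_dataset.recordings, hp)
    model = build(ModelSpec(units=10), seed=7)
    train(model, blocks, epochs=8, batch_size=64, seed=7)
    return model
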