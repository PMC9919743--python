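import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristfall.device_io import (
    HUAWEI,
    MSBAND,
    METASENSOR,
    AccelSample,
    Dataset,
    DeviceProfile,
    get_profile,
    magnitude,
    read_dataset,
    read_recording,
    resample,
    write_dataset,
    write_recording,
)
from wristfall.errors import DataError, FormatError

from .conftest import make_recording


def write_csv(path, rows, header="t_ms,x,y,z,label"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestDeviceProfile:
    def test_builtin_profiles(self):
        assert MSBAND.sampling_hz == 32 and MSBAND.unit_scale == 1.0
        assert HUAWEI.sampling_hz == 32
        assert METASENSOR.sampling_hz == 50 and METASENSOR.unit_scale == 2.0
        assert METASENSOR.wrists == frozenset({"left", "right"})

    def test_default_hparams_window_is_one_second(self):
        for profile in (MSBAND, HUAWEI, METASENSOR):
            hp = profile.default_hparams
            assert hp.window_size == round(profile.sampling_hz)
            assert hp.step_size == 1
            assert hp.smooth_window == 2 * round(profile.sampling_hz)
            assert hp.fall_threshold == 0.4

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            DeviceProfile("bad", -1.0, 1.0)
        with pytest.raises(ValueError):
            DeviceProfile("bad", 32.0, 0.0)
        with pytest.raises(ValueError):
            DeviceProfile("bad", 32.0, 1.0, frozenset({"ankle"}))

    def test_get_profile_override(self):
        p = get_profile("huawei", sampling_hz=50.0)
        assert p.sampling_hz == 50.0
        assert p.default_hparams.window_size == 50
        with pytest.raises(KeyError):
            get_profile("fitbit")


class TestMagnitude:
    @pytest.mark.parametrize(
        "xyz,expected", [((0, 0, 0), 0.0), ((1, 0, 0), 1.0), ((3, 4, 0), 5.0)]
    )
    def test_examples(self, xyz, expected):
        assert magnitude(xyz) == pytest.approx(expected)

    def test_accepts_sample(self):
        s = AccelSample(0.0, 1.0, 2.0, 2.0, 0)
        assert magnitude(s) == pytest.approx(3.0)

    @given(
        st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
        st.permutations([0, 1, 2]),
        st.tuples(*[st.sampled_from([-1, 1]) for _ in range(3)]),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_and_sign_invariance(self, xyz, perm, signs):
        base = magnitude(xyz)
        shuffled = tuple(xyz[p] * s for p, s in zip(perm, signs))
        assert magnitude(shuffled) == pytest.approx(base, abs=1e-9)


class TestReadRecording:
    def test_identity_scaling(self, tmp_path):
        path = write_csv(tmp_path / "r.csv", ["0,0.1,0.2,0.3,0", "31,0.4,0.5,0.6,1", "62,0.7,0.8,0.9,0"])
        rec = read_recording(path, MSBAND)
        assert len(rec) == 3
        assert rec.labels.tolist() == [0, 1, 0]
        assert rec.xyz[0].tolist() == pytest.approx([0.1, 0.2, 0.3])

    def test_linear_scaling(self, tmp_path):
        path = write_csv(tmp_path / "r.csv", ["0,0.1,0.2,0.3,0", "20,0.4,0.5,0.6,1", "40,0.7,0.8,0.9,0"])
        doubled = get_profile("metasensor")
        rec = read_recording(path, doubled)
        assert rec.xyz[1].tolist() == pytest.approx([0.8, 1.0, 1.2])

    def test_non_monotone_timestamps(self, tmp_path):
        path = write_csv(tmp_path / "r.csv", ["0,0,0,1,0", "20,0,0,1,0", "10,0,0,1,0"])
        with pytest.raises(DataError, match="row 3"):
            read_recording(path, MSBAND)

    def test_missing_column(self, tmp_path):
        path = write_csv(tmp_path / "r.csv", ["0,0,0,0"], header="t_ms,x,y,label")
        with pytest.raises(FormatError, match="z"):
            read_recording(path, MSBAND)

    def test_activity_string_labels(self, tmp_path):
        path = write_csv(
            tmp_path / "r.csv",
            ["0,0,0,1,walking", "20,0,0,1,Fall", "40,0,0,1,drinking water"],
        )
        rec = read_recording(path, MSBAND)
        assert rec.labels.tolist() == [0, 1, 0]

    def test_bad_numeric_label(self, tmp_path):
        path = write_csv(tmp_path / "r.csv", ["0,0,0,1,2"])
        with pytest.raises(DataError):
            read_recording(path, MSBAND)

    def test_identity_inferred_from_layout(self, tmp_path):
        path = tmp_path / "ds" / "s03" / "right" / "waving_2.csv"
        path.parent.mkdir(parents=True)
        write_csv(path, ["0,0,0,1,0", "20,0,0,1,0"])
        rec = read_recording(path, METASENSOR)
        assert (rec.subject_id, rec.wrist, rec.activity, rec.trial) == ("s03", "right", "waving", 2)


class TestWriteRecording:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.normal(0, 1, (50, 3)), labels=(rng.random(50) < 0.3).astype(int),
                             profile=METASENSOR)
        back = read_recording(write_recording(rec, tmp_path / "r.csv"), METASENSOR)
        np.testing.assert_array_equal(back.t_ms, rec.t_ms)
        np.testing.assert_array_equal(back.labels, rec.labels)
        np.testing.assert_allclose(back.xyz, rec.xyz, atol=1e-6)

    def test_empty_recording_rejected(self, tmp_path):
        rec = make_recording(np.zeros((1, 3)))
        rec.t_ms = rec.t_ms[:0]
        rec.xyz = rec.xyz[:0]
        rec.labels = rec.labels[:0]
        with pytest.raises(FormatError):
            write_recording(rec, tmp_path / "r.csv")

    def test_labels_preserved_exactly(self, tmp_path):
        labels = np.array([0, 1, 1, 0, 1], dtype=np.int8)
        rec = make_recording(np.ones((5, 3)), labels=labels)
        back = read_recording(write_recording(rec, tmp_path / "r.csv"), MSBAND)
        np.testing.assert_array_equal(back.labels, labels)


class TestDatasetIO:
    def test_directory_round_trip(self, tmp_path, toy_dataset, toy_profile):
        root = write_dataset(toy_dataset, tmp_path / "ds")
        back = read_dataset(root, toy_profile)
        assert len(back) == len(toy_dataset)
        assert back.subjects == toy_dataset.subjects
        orig = {rec.key + (rec.wrist,): rec for rec in toy_dataset}
        for rec in back:
            ref = orig[rec.key + (rec.wrist,)]
            np.testing.assert_allclose(rec.xyz, ref.xyz, atol=1e-6)
            np.testing.assert_array_equal(rec.labels, ref.labels)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            Dataset([])

    def test_mixed_devices_rejected(self):
        a = make_recording(np.ones((5, 3)), profile=MSBAND)
        b = make_recording(np.ones((5, 3)), profile=METASENSOR)
        with pytest.raises(ValueError, match="mixed"):
            Dataset([a, b])


class TestResample:
    def test_identity_at_native_rate(self):
        rng = np.random.default_rng(3)
        rec = make_recording(rng.normal(0, 1, (64, 3)), profile=MSBAND)
        out = resample(rec, 32.0)
        assert len(out) == len(rec)
        np.testing.assert_allclose(out.xyz, rec.xyz, atol=1e-9)
        np.testing.assert_array_equal(out.labels, rec.labels)

    def test_linear_interpolation_example(self):
        rec = make_recording([[0, 0, 0], [1, 1, 1]], t_ms=[0.0, 1000.0])
        out = resample(rec, 4.0)
        assert len(out) == 5
        np.testing.assert_allclose(out.xyz[:, 0], [0, 0.25, 0.5, 0.75, 1.0])

    def test_output_count_formula(self):
        # 101 samples over 2000 ms -> floor(2.0 * 32) + 1 = 65
        rec = make_recording(np.ones((101, 3)), t_ms=np.linspace(0, 2000, 101))
        assert len(resample(rec, 32.0)) == 65

    def test_nearest_label(self):
        rec = make_recording(np.ones((3, 3)), labels=[0, 1, 0], t_ms=[0.0, 100.0, 200.0])
        out = resample(rec, 20.0)  # 50 ms grid
        assert out.labels.tolist() == [0, 0, 1, 1, 0]

    def test_invalid_rate(self):
        rec = make_recording(np.ones((4, 3)))
        with pytest.raises(ValueError):
            resample(rec, 0.0)

    def test_too_short(self):
        rec = make_recording(np.ones((1, 3)))
        with pytest.raises(ValueError):
            resample(rec, 10.0)
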