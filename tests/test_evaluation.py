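import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristfall.device_io import Dataset
from wristfall.evaluation import (
    confusion_counts,
    detect_events,
    evaluate_stream,
    f1_score,
    lopo_folds,
    pr_curve,
    split_per_person,
)
from wristfall.windowing import Hyperparameters, make_block_arrays

from .conftest import make_recording


def brute_force_f1(pred, truth):
    tp = sum(1 for p, t in zip(pred, truth) if p and t)
    fp = sum(1 for p, t in zip(pred, truth) if p and not t)
    fn = sum(1 for p, t in zip(pred, truth) if not p and t)
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


class TestSplitPerPerson:
    def dataset(self, toy_profile, n_subjects=3, recs_per_subject=10, n=30):
        recs = []
        for s in range(n_subjects):
            for t in range(recs_per_subject):
                recs.append(
                    make_recording(
                        np.ones((n, 3)),
                        profile=toy_profile,
                        subject=f"s{s:02d}",
                        trial=t,
                    )
                )
        return Dataset(recs)

    def test_seventy_thirty_on_equal_recordings(self, toy_profile):
        ds = self.dataset(toy_profile)
        train, test = split_per_person(ds, 0.7, seed=0)
        for s in ds.subjects:
            n_train = sum(1 for r in train if r.subject_id == s)
            n_test = sum(1 for r in test if r.subject_id == s)
            assert (n_train, n_test) == (7, 3)

    def test_every_subject_in_both_splits(self, toy_profile):
        ds = self.dataset(toy_profile, recs_per_subject=4)
        train, test = split_per_person(ds, 0.7, seed=1)
        assert {r.subject_id for r in train} == set(ds.subjects)
        assert {r.subject_id for r in test} == set(ds.subjects)

    def test_reproducible(self, toy_profile):
        ds = self.dataset(toy_profile)
        a = split_per_person(ds, 0.7, seed=5)
        b = split_per_person(ds, 0.7, seed=5)
        assert [r.key for r in a[0]] == [r.key for r in b[0]]
        assert [r.key for r in a[1]] == [r.key for r in b[1]]

    def test_single_recording_subject_goes_to_train(self, toy_profile):
        ds = Dataset(
            [make_recording(np.ones((20, 3)), profile=toy_profile, subject="solo")]
        )
        with pytest.warns(UserWarning, match="single trial"):
            train, test = split_per_person(ds, 0.7, seed=0)
        assert len(train) == 1 and len(test) == 0

    def test_invalid_fraction(self, toy_profile):
        ds = self.dataset(toy_profile)
        with pytest.raises(ValueError):
            split_per_person(ds, 1.0)


class TestLopoFolds:
    def dataset(self, toy_profile, n_subjects):
        return Dataset(
            [
                make_recording(
                    np.ones((20, 3)), profile=toy_profile, subject=f"s{s}", trial=t
                )
                for s in range(n_subjects)
                for t in range(2)
            ]
        )

    def test_one_fold_per_subject(self, toy_profile):
        ds = self.dataset(toy_profile, 8)
        assert len(lopo_folds(ds)) == 8

    def test_union_of_test_sets_is_dataset(self, toy_profile):
        ds = self.dataset(toy_profile, 4)
        folds = lopo_folds(ds)
        test_keys = [r.key for _, test in folds for r in test]
        assert sorted(test_keys) == sorted(r.key for r in ds)
        for train, test in folds:
            assert {r.subject_id for r in test}.isdisjoint(
                {r.subject_id for r in train}
            )

    def test_two_subjects_complementary(self, toy_profile):
        ds = self.dataset(toy_profile, 2)
        (tr0, te0), (tr1, te1) = lopo_folds(ds)
        assert [r.key for r in tr0] == [r.key for r in te1]
        assert [r.key for r in te0] == [r.key for r in tr1]

    def test_fewer_than_two_subjects(self, toy_profile):
        ds = self.dataset(toy_profile, 1)
        with pytest.raises(ValueError):
            lopo_folds(ds)


class TestF1:
    def test_perfect(self):
        assert f1_score([1, 0, 1], [1, 0, 1]) == 1.0

    def test_half(self):
        # TP=1, FP=1, FN=1 -> 2/(2+1+1) = 0.5
        assert f1_score([1, 1, 0], [1, 0, 1]) == 0.5

    def test_all_negative_predictions(self):
        assert f1_score([0, 0, 0], [1, 0, 1]) == 0.0

    def test_degenerate_zero_denominator(self):
        assert f1_score([0, 0], [0, 0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            f1_score([1], [1, 0])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, pairs):
        pred = [p for p, _ in pairs]
        truth = [t for _, t in pairs]
        assert f1_score(pred, truth) == pytest.approx(brute_force_f1(pred, truth))
        c = confusion_counts(pred, truth)
        denom = 2 * c["tp"] + c["fp"] + c["fn"]
        recomputed = 2 * c["tp"] / denom if denom else 0.0
        assert f1_score(pred, truth) == pytest.approx(recomputed)


class TestPRCurve:
    def test_perfect_separation(self):
        probs = [0.9, 0.8, 0.2, 0.1]
        truth = [1, 1, 0, 0]
        points, auc = pr_curve(probs, truth)
        assert auc == pytest.approx(1.0)
        assert points[-1] == (1.0, pytest.approx(0.5))

    def test_random_probs_auc_near_prevalence(self):
        rng = np.random.default_rng(0)
        n = 4000
        truth = rng.random(n) < 0.5
        probs = rng.random(n)
        _, auc = pr_curve(probs, truth)
        assert auc == pytest.approx(truth.mean(), abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        probs = rng.random(200)
        truth = rng.random(200) < 0.3
        _, auc = pr_curve(probs, truth)
        _, auc2 = pr_curve(probs**3, truth)  # strictly monotone on [0,1]
        assert auc2 == pytest.approx(auc)

    def test_reversed_probs_are_worse(self):
        probs = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        truth = np.array([1, 1, 1, 0, 0, 0])
        _, good = pr_curve(probs, truth)
        _, bad = pr_curve(1 - probs, truth)
        assert good > bad

    def test_no_positives_warns(self):
        with pytest.warns(UserWarning, match="no positives"):
            points, auc = pr_curve([0.1, 0.2], [0, 0])
        assert points == [] and auc == 0.0

    def test_points_sorted_by_recall(self):
        rng = np.random.default_rng(2)
        probs = rng.random(100)
        truth = rng.random(100) < 0.4
        points, _ = pr_curve(probs, truth)
        recalls = [r for r, _ in points]
        assert recalls == sorted(recalls)


class TestEvaluateStream:
    def test_trace_length_equals_block_count(self, toy_model, toy_dataset, toy_profile):
        hp = toy_profile.default_hparams
        recs = toy_dataset.recordings[:4]
        expected = sum(
            make_block_arrays(r, hp)[0].shape[0] for r in recs
        )
        report = evaluate_stream(toy_model, recs, hp)
        assert report.n_blocks == expected
        assert len(report.trace_prob) == expected

    def test_deterministic(self, toy_model, toy_dataset, toy_profile):
        hp = toy_profile.default_hparams
        recs = toy_dataset.recordings[:3]
        a = evaluate_stream(toy_model, recs, hp)
        b = evaluate_stream(toy_model, recs, hp)
        assert a.f1 == b.f1
        np.testing.assert_array_equal(a.trace_prob, b.trace_prob)

    def test_quiet_recording_yields_no_positives(self, toy_model, toy_profile):
        hp = toy_profile.default_hparams
        rng = np.random.default_rng(0)
        xyz = np.zeros((300, 3))
        xyz[:, 2] = 1.0
        xyz += rng.normal(0, 0.03, xyz.shape)
        rec = make_recording(xyz, profile=toy_profile)
        report = evaluate_stream(toy_model, [rec], hp)
        assert report.confusion["tp"] + report.confusion["fp"] == 0

    def test_f1_consistent_with_confusion(self, toy_model, toy_dataset, toy_profile):
        report = evaluate_stream(
            toy_model, toy_dataset.recordings[:6], toy_profile.default_hparams
        )
        c = report.confusion
        denom = 2 * c["tp"] + c["fp"] + c["fn"]
        assert report.f1 == pytest.approx(2 * c["tp"] / denom if denom else 0.0)

    def test_mixed_devices_rejected(self, toy_model, toy_profile):
        from wristfall.device_io import MSBAND

        recs = [
            make_recording(np.ones((40, 3)), profile=toy_profile),
            make_recording(np.ones((40, 3)), profile=MSBAND),
        ]
        with pytest.raises(ValueError, match="mix"):
            evaluate_stream(toy_model, recs, toy_profile.default_hparams)

    def test_report_json_round_trip(self, tmp_path, toy_model, toy_dataset, toy_profile):
        import json

        report = evaluate_stream(
            toy_model, toy_dataset.recordings[:3], toy_profile.default_hparams
        )
        path = report.to_json(tmp_path / "report.json")
        payload = json.loads(path.read_text())
        assert payload["f1"] == pytest.approx(report.f1)
        assert len(payload["trace"]["prob"]) == report.n_blocks


class TestDetectEvents:
    @pytest.mark.parametrize(
        "pred,expected",
        [
            ([0, 1, 1, 0, 1], 2),
            ([0, 0, 0], 0),
            ([1, 1, 1], 1),
            ([], 0),
            ([1, 0, 1, 0, 1], 3),
        ],
    )
    def test_examples(self, pred, expected):
        assert detect_events(pred) == expected
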