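import numpy as np
import pytest

from eegensemble.detector import (
    FIG_ARCHITECTURE,
    ArchitectureConfig,
    LocalModel,
    TrainConfig,
    balance_training_set,
    build_nsda,
    count_parameters,
    load_model,
    predict_segments,
    save_model,
    train_nsda,
)
from eegensemble.evaluation import auc_score
from eegensemble.preprocess import SegmentSet

from conftest import make_rhythm_task


class TestArchitecture:
    def test_reference_parameter_count(self):
        """The reference configuration has exactly 29 352 learnable weights."""
        assert count_parameters(FIG_ARCHITECTURE) == 29352

    def test_parameter_count_independent_of_channels(self):
        m = build_nsda(FIG_ARCHITECTURE, seed=0)
        n_before = m.count_parameters()
        for c in (3, 18):
            m.predict_proba(np.zeros((2, c, 512)))
        assert m.count_parameters() == n_before

    def test_channel_permutation_invariance(self, toy_arch):
        m = build_nsda(toy_arch, seed=3)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 5, toy_arch.input_samples))
        p1 = m.predict_proba(x)
        p2 = m.predict_proba(x[:, rng.permutation(5), :])
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_one_model_accepts_3_and_18_channels(self):
        m = build_nsda(FIG_ARCHITECTURE, seed=0)
        for c in (3, 18):
            p = m.predict_proba(np.random.default_rng(c).normal(size=(2, c, 512)))
            assert p.shape == (2,)
            assert ((p >= 0) & (p <= 1)).all()

    def test_wrong_segment_length_rejected(self):
        m = build_nsda(FIG_ARCHITECTURE, seed=0)
        with pytest.raises(ValueError):
            m.predict_proba(np.zeros((1, 3, 400)))

    def test_probabilities_sum_to_one(self, toy_arch):
        from eegensemble import nn

        m = build_nsda(toy_arch, seed=1)
        logits = m.forward(np.random.default_rng(1).normal(size=(5, 2, 128)))
        probs = nn.softmax(logits)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)


class TestBalancing:
    def _labels(self, n_pos, n_neg):
        return np.array([1] * n_pos + [0] * n_neg)

    def test_majority_subsampled(self):
        idx = balance_training_set(self._labels(10, 100), np.random.default_rng(0))
        lab = self._labels(10, 100)[idx]
        assert (lab == 1).sum() == 10 and (lab == 0).sum() == 10

    def test_already_balanced_unchanged(self):
        idx = balance_training_set(self._labels(10, 10), np.random.default_rng(0))
        assert len(idx) == 20

    def test_balancing_is_symmetric(self):
        idx = balance_training_set(self._labels(10, 5), np.random.default_rng(0))
        lab = self._labels(10, 5)[idx]
        assert (lab == 1).sum() == 5 and (lab == 0).sum() == 5

    def test_no_seizure_segments_errors(self):
        with pytest.raises(ValueError):
            balance_training_set(self._labels(0, 10), np.random.default_rng(0))


class TestTraining:
    def test_loss_decreases_and_heldout_auc_beats_chance(self, toy_arch, rhythm_task):
        x, y = rhythm_task
        m = build_nsda(toy_arch, seed=7)
        hist = train_nsda(m, x[:160], y[:160], TrainConfig(epochs=8, rng_seed=7))
        assert hist["loss"][-1] < hist["loss"][0]
        auc = auc_score(y[160:], m.predict_proba(x[160:]))
        assert auc > 0.8

    def test_same_seed_identical_weights(self, toy_arch):
        x, y = make_rhythm_task(n=64, seed=5)
        states = []
        for _ in range(2):
            m = build_nsda(toy_arch, seed=11)
            train_nsda(m, x, y, TrainConfig(epochs=2, rng_seed=11))
            states.append(m.state_dict())
        for k in states[0]:
            np.testing.assert_array_equal(states[0][k], states[1][k])

    def test_learning_rate_schedule_halves_every_10_epochs(self):
        cfg = TrainConfig()
        assert cfg.lr_at(0) == 1e-3
        assert cfg.lr_at(9) == 1e-3
        assert cfg.lr_at(10) == 5e-4
        assert cfg.lr_at(20) == 2.5e-4
        assert cfg.lr_at(29) == 2.5e-4

    def test_more_patients_generalize_better(self, toy_arch):
        """Detectors trained on more cohorts transfer better to unseen ones.

        Each synthetic 'patient' has its own discharge frequency band; a
        model trained on six patients is compared with one trained on a
        single patient, on test patients with unseen frequencies.
        Checked in expectation over 5 seeds.
        """
        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            def patient(f0, n, s):
                return make_rhythm_task(
                    n=n, f0_range=(f0 - 0.2, f0 + 0.2), amp=1.2, seed=s
                )
            train_f0s = rng.uniform(2, 6, size=6)
            xs, ys = zip(*[patient(f, 40, 100 + seed * 10 + i)
                           for i, f in enumerate(train_f0s)])
            x_many, y_many = np.concatenate(xs), np.concatenate(ys)
            x_one, y_one = patient(train_f0s[0], 240, 200 + seed)
            x_te, y_te = make_rhythm_task(n=160, amp=1.2, seed=300 + seed)
            aucs = []
            for xtr, ytr in ((x_many, y_many), (x_one, y_one)):
                m = build_nsda(toy_arch, seed=seed)
                train_nsda(m, xtr, ytr, TrainConfig(epochs=6, rng_seed=seed))
                aucs.append(auc_score(y_te, m.predict_proba(x_te)))
            deltas.append(aucs[0] - aucs[1])
        assert np.mean(deltas) > 0

    def test_label_rule_threshold_at_half(self):
        from eegensemble.ensemble import threshold_labels

        assert threshold_labels(np.array([0.5]))[0] == 1
        assert threshold_labels(np.array([0.49]))[0] == 0


class TestSerialization:
    def test_save_load_roundtrip(self, toy_arch, tmp_path):
        x, y = make_rhythm_task(n=48, seed=9)
        m = build_nsda(toy_arch, seed=2)
        train_nsda(m, x, y, TrainConfig(epochs=1, rng_seed=2))
        local = LocalModel("instA", m, patient_ids=("p1", "p2"))
        path = tmp_path / "model.npz"
        save_model(local, path)
        loaded = load_model(path)
        assert loaded.institution_id == "instA"
        assert loaded.patient_ids == ("p1", "p2")
        np.testing.assert_array_equal(
            m.predict_proba(x), loaded.model.predict_proba(x)
        )

    def test_predict_segments_uses_valid_only(self, toy_arch):
        m = build_nsda(toy_arch, seed=0)
        data = np.random.default_rng(0).normal(size=(5, 2, 128))
        seg = SegmentSet(
            patient_id="p",
            start_s=np.arange(5) * 4.0,
            data=data,
            valid=np.array([True, False, True, True, False]),
        )
        probs, idx = predict_segments(m, seg)
        assert idx.tolist() == [0, 2, 3]
        assert len(probs) == 3
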