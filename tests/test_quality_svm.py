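import numpy as np
import pytest

from ecgdenoise.core_io import TimedSignal
from ecgdenoise.errors import ContractError, DegenerateSignalError, TrainingError
from ecgdenoise.preprocess import zscore
from ecgdenoise.quality_svm import (
    ConfusionCounts,
    QualityFeatures,
    confusion_metrics,
    extract_features,
    label_segment_by_qrs,
    power_frequency_90,
    svm_predict,
    svm_train,
)
from ecgdenoise.synthetic import SynthSpec, _contact_loss_pattern, gen_ecg

FS = 250.0


class TestPowerFrequency90:
    def test_pure_sine(self):
        t = np.arange(2500) / FS
        f = power_frequency_90(TimedSignal(np.sin(2 * np.pi * 10 * t), FS))
        assert abs(f - 10.0) <= 0.1

    def test_white_noise_near_90pct_of_nyquist(self):
        rng = np.random.default_rng(11)
        f = power_frequency_90(TimedSignal(rng.standard_normal(2500), FS))
        assert abs(f - 112.5) < 5.0

    def test_zero_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            power_frequency_90(TimedSignal(np.zeros(100), FS))


class TestExtractFeatures:
    def test_clean_ecg_features_in_cardiac_band(self, default_ecg_10s):
        ecg, _ = default_ecg_10s
        seg, _ = zscore(ecg)
        fv = extract_features(seg).as_array()
        assert fv.shape == (8,)
        assert np.all(fv >= 1.0) and np.all(fv <= 45.0)

    def test_contact_loss_f0_separates(self):
        rng = np.random.default_rng(0)
        seg, _ = zscore(TimedSignal(_contact_loss_pattern(rng, 2500, FS), FS))
        fv = extract_features(seg)
        assert fv.f0 > 50.0

    def test_deterministic(self, clean_ecg_10s):
        ecg, _ = clean_ecg_10s
        seg, _ = zscore(ecg)
        a = extract_features(seg).as_array()
        b = extract_features(seg).as_array()
        np.testing.assert_array_equal(a, b)


class TestQrsLabelRule:
    def test_rule_arithmetic(self, reference_segment):
        ecg, _ = reference_segment  # 12 detectable beats
        assert label_segment_by_qrs(ecg, 72.0)

    def test_flat_signal_unusable(self):
        assert not label_segment_by_qrs(TimedSignal(np.zeros(2500), FS), 72.0)

    def test_sparse_beats_unusable(self, reference_segment):
        ecg, _ = reference_segment
        # keep only the first 3 s of beats, flatten the rest: 4 < 0.6*12
        sparse = ecg.samples.copy()
        sparse[int(3 * FS) :] = 0.0
        assert not label_segment_by_qrs(TimedSignal(sparse, FS), 72.0)


def _toy_features(n, seed, center):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        base = rng.normal(center, 1.0, size=8)
        out.append(QualityFeatures(*np.abs(base) + 1))
    return out


class TestSvm:
    def test_separable_toy_set_memorized(self):
        feats = _toy_features(5, 0, 5.0) + _toy_features(5, 1, 40.0)
        labels = [True] * 5 + [False] * 5
        model = svm_train(feats, labels, C=1.0)
        assert [svm_predict(model, f) for f in feats] == labels

    def test_single_class_rejected(self):
        feats = _toy_features(6, 0, 5.0)
        with pytest.raises(TrainingError):
            svm_train(feats, [True] * 6)

    def test_decision_matches_sklearn_oracle(self):
        """The stored support-vector decision function reproduces the library
        decision values it was extracted from."""
        from sklearn.svm import SVC

        feats = _toy_features(20, 2, 5.0) + _toy_features(20, 3, 15.0)
        labels = [True] * 20 + [False] * 20
        model = svm_train(feats, labels, C=1.0)
        X = np.vstack([f.as_array() for f in feats])
        Z = (X - model.feature_mean) / model.feature_sd
        clf = SVC(C=1.0, kernel="rbf", gamma=1.0).fit(Z, np.asarray(labels, dtype=int))
        ours = np.array([model.decision(f) for f in feats])
        np.testing.assert_allclose(ours, clf.decision_function(Z), atol=1e-10)

    def test_permuted_labels_chance_accuracy(self):
        rng = np.random.default_rng(9)
        feats = _toy_features(40, 4, 5.0) + _toy_features(40, 5, 40.0)
        labels = list(rng.permutation([True] * 40 + [False] * 40))
        model = svm_train(feats[::2], labels[::2], C=1.0)
        held = np.mean(
            [svm_predict(model, f) == y for f, y in zip(feats[1::2], labels[1::2])]
        )
        assert 0.2 <= held <= 0.8

    def test_json_round_trip(self, tmp_path):
        feats = _toy_features(5, 0, 5.0) + _toy_features(5, 1, 40.0)
        model = svm_train(feats, [True] * 5 + [False] * 5)
        model.to_json(tmp_path / "m.json")
        from ecgdenoise.quality_svm import SvmModel

        back = SvmModel.from_json(tmp_path / "m.json")
        for f in feats:
            assert back.decision(f) == pytest.approx(model.decision(f))

    def test_wrong_feature_length_rejected(self):
        feats = _toy_features(5, 0, 5.0) + _toy_features(5, 1, 40.0)
        model = svm_train(feats, [True] * 5 + [False] * 5)

        class Fake:
            def as_array(self):
                return np.zeros(5)

        with pytest.raises(ContractError):
            model.decision(Fake())


class TestConfusionMetrics:
    def test_printed_confusion_table(self):
        """SEN/SPC/ACC from the published gate confusion counts."""
        sen, spc, acc = confusion_metrics(ConfusionCounts(tp=99, fp=2, tn=48, fn=1))
        assert sen == pytest.approx(99.0)
        assert spc == pytest.approx(96.0)
        assert acc == pytest.approx(98.0)

    def test_perfect_classifier(self):
        sen, spc, acc = confusion_metrics(ConfusionCounts(10, 0, 10, 0))
        assert (sen, spc, acc) == (100.0, 100.0, 100.0)

    def test_all_wrong(self):
        sen, spc, acc = confusion_metrics(ConfusionCounts(0, 5, 0, 5))
        assert (sen, spc, acc) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("k", [2, 7])
    def test_scale_invariance(self, k):
        base = confusion_metrics(ConfusionCounts(99, 2, 48, 1))
        scaled = confusion_metrics(ConfusionCounts(99 * k, 2 * k, 48 * k, 1 * k))
        assert base == scaled
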