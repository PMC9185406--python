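"""Identification protocols, quantization, the four classifiers, evaluation."""

from dataclasses import replace

import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler

from seatecg import (
    ClassifierSpec,
    ProtocolSpec,
    TemplateSet,
    evaluate,
    make_population,
    quantize_templates,
    split_templates,
    synth_session,
    train_classifier,
)
from seatecg.bcnn import BinarizedConvNet
from seatecg.synth import clean_degradation
from tests.conftest import build_template_sets


def numbered_set(n_templates, length=151, fs=250.0, offset=0.0):
    """Templates whose first sample encodes their temporal order."""
    rng = np.random.default_rng(int(offset))
    t = rng.normal(size=(n_templates, length)) + offset
    t[:, 0] = np.arange(n_templates)
    return TemplateSet(templates=t, fs=fs, window=(0.2, 0.4))


class TestQuantization:
    def test_unit_span_maps_to_full_scale(self):
        t = np.linspace(0.0, 1.0, 151)[None, :]
        q = quantize_templates(t)
        assert q.dtype == np.uint8
        assert q.min() == 0 and q.max() == 255

    def test_constant_template_convention(self):
        q = quantize_templates(np.full((1, 151), 2.5))
        assert np.all(q == 128)

    def test_round_trip_error_bounded(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(20, 151))
        q = quantize_templates(t).astype(float)
        lo = t.min(axis=1, keepdims=True)
        span = t.max(axis=1, keepdims=True) - lo
        back = lo + q / 255.0 * span
        assert np.max(np.abs(back - t)) <= np.max(span) / 255.0 + 1e-12

    def test_train_fitted_standardization(self):
        rng = np.random.default_rng(1)
        train = rng.normal(3.0, 2.0, size=(200, 10))
        z = StandardScaler().fit_transform(train)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-9)


class TestSplits:
    def test_static_30_30_takes_first_and_last(self):
        sets = {"A": numbered_set(90)}
        proto = ProtocolSpec(mode="static", n_train=30, n_test=30)
        xtr, ytr, xte, yte = split_templates(sets, proto)
        assert list(xtr[:, 0]) == list(range(30))
        assert list(xte[:, 0]) == list(range(60, 90))

    def test_static_30_15_takes_last_fifteen(self):
        sets = {"A": numbered_set(90)}
        proto = ProtocolSpec(mode="static", n_train=30, n_test=15)
        _, _, xte, _ = split_templates(sets, proto)
        assert list(xte[:, 0]) == list(range(75, 90))

    def test_static_invariant_across_repetitions(self):
        sets = {"A": numbered_set(90), "B": numbered_set(80, offset=5)}
        proto = ProtocolSpec(mode="static", n_train=30, n_test=20)
        a = split_templates(sets, proto, rep=0)
        b = split_templates(sets, proto, rep=17)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_random_split_seed_reproducible_and_disjoint(self):
        sets = {"A": numbered_set(60), "B": numbered_set(60, offset=4)}
        proto = ProtocolSpec(mode="random", seed=3)
        a = split_templates(sets, proto, rep=2)
        b = split_templates(sets, proto, rep=2)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[2], b[2])
        c = split_templates(sets, proto, rep=3)
        assert not np.array_equal(a[2], c[2])
        # train/test disjoint: order codes never shared within a subject
        tr_a = set(a[0][a[1] == "A"][:, 0])
        te_a = set(a[2][a[3] == "A"][:, 0])
        assert not tr_a & te_a

    def test_insufficient_templates_names_subject(self):
        sets = {"POOR": numbered_set(40)}
        proto = ProtocolSpec(mode="static", n_train=30, n_test=30)
        with pytest.raises(ValueError, match="POOR"):
            split_templates(sets, proto)


class TestClassifiers:
    @staticmethod
    def separable_data(seed=0, n=60, gap=10.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=(n, 151))
        b = rng.normal(gap, 1.0, size=(n, 151))
        X = np.vstack([a, b])
        y = np.array(["A"] * n + ["B"] * n)
        return X, y

    def test_svm_separates_disjoint_classes(self):
        X, y = self.separable_data()
        model = train_classifier(ClassifierSpec("SVM"), X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_gaussian_nb_with_tiny_variance(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.01, (50, 20)), rng.normal(1, 0.01, (50, 20))]
        )
        y = np.array(["A"] * 50 + ["B"] * 50)
        model = train_classifier(ClassifierSpec("GaussianNB"), X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_knn_agrees_with_exhaustive_distance_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 25))
        y = np.array(["A", "B", "C", "D"] * 10)
        probes = rng.normal(size=(15, 25))
        model = train_classifier(ClassifierSpec("KNN3"), X, y)
        pred = model.predict(probes)
        # oracle: standardize identically, rank all Euclidean distances
        scaler = StandardScaler().fit(X)
        Xs, Ps = scaler.transform(X), scaler.transform(probes)
        for i, p in enumerate(Ps):
            d = np.linalg.norm(Xs - p, axis=1)
            top3 = y[np.argsort(d)[:3]]
            labels, counts = np.unique(top3, return_counts=True)
            if counts.max() > 1:  # unambiguous majority only
                assert pred[i] == labels[np.argmax(counts)]

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 10))
        with pytest.raises(ValueError):
            train_classifier(ClassifierSpec("SVM"), X, np.array(["A"] * 20))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("RandomForest")


class TestBCNN:
    def test_learns_separable_classes(self):
        X, y = TestClassifiers.separable_data(seed=3, n=40, gap=3.0)
        model = train_classifier(
            ClassifierSpec("BCNN", {"n_epochs": 10}), X, y, seed=0
        )
        assert np.mean(model.predict(X) == y) >= 0.95

    def test_training_deterministic_given_seed(self):
        X, y = TestClassifiers.separable_data(seed=4, n=20, gap=2.0)
        net1 = BinarizedConvNet(n_epochs=3, random_state=7).fit(X, y)
        net2 = BinarizedConvNet(n_epochs=3, random_state=7).fit(X, y)
        for k in net1.params_:
            np.testing.assert_array_equal(net1.params_[k], net2.params_[k])

    def test_interior_weights_binarized_in_forward(self):
        from seatecg.bcnn import _binarize

        w = np.random.default_rng(0).normal(size=(8, 4, 5))
        wb = _binarize(w)
        alpha = np.mean(np.abs(w), axis=(1, 2))
        assert set(np.unique(np.round(np.abs(wb / alpha[:, None, None]), 12))) == {1.0}


class TestEvaluate:
    def test_population_larger_than_cohort_rejected(self, clean_sets4):
        proto = ProtocolSpec(mode="random", n_repetitions=1, population_sizes=(5,))
        with pytest.raises(ValueError):
            evaluate(clean_sets4, [ClassifierSpec("KNN3")], proto)

    def test_degenerate_twin_subjects_at_chance(self):
        """Two subjects rendered from the same morphology are
        indistinguishable: accuracy sits at chance level."""
        prof = make_population(2, seed=13)[0]
        sets = {}
        for tag, seed in (("A", 1), ("B", 2)):
            ref, _ = synth_session(prof, clean_degradation(), 120.0, 250.0, seed=seed)
            from seatecg import bandpass_fir, detect_r_peaks, extract_templates

            filt = bandpass_fir(ref)
            tset = extract_templates(filt, detect_r_peaks(filt))
            sets[tag] = replace(tset, subject_id=tag)
        proto = ProtocolSpec(mode="random", n_repetitions=10, population_sizes=(2,))
        res = evaluate(sets, [ClassifierSpec("KNN3")], proto)[0]
        assert 25.0 <= res.accuracy <= 75.0

    def test_distinct_clean_cohort_near_perfect(self, clean_sets4):
        proto = ProtocolSpec(mode="random", n_repetitions=2, population_sizes=(4,))
        for kind in ("SVM", "GaussianNB", "KNN3"):
            res = evaluate(clean_sets4, [ClassifierSpec(kind)], proto)[0]
            assert res.accuracy >= 99.0

    def test_static_protocol_no_easier_than_random(self, degraded_sets17):
        """Training on only the first 30 cycles and testing on the last 30
        (temporal gap) is at most as accurate as random template selection."""
        static = ProtocolSpec(mode="static", n_train=30, n_test=30,
                              n_repetitions=10, population_sizes=(6,), seed=4)
        rand = ProtocolSpec(mode="random", n_repetitions=10,
                            population_sizes=(6,), seed=4)
        for kind in ("KNN3", "GaussianNB"):
            acc_static = evaluate(degraded_sets17, [ClassifierSpec(kind)],
                                  static)[0].accuracy
            acc_random = evaluate(degraded_sets17, [ClassifierSpec(kind)],
                                  rand)[0].accuracy
            assert acc_static <= acc_random + 1e-9, kind

    def test_results_ordered_and_bounded(self, clean_sets4):
        proto = ProtocolSpec(
            mode="random", n_repetitions=2, population_sizes=(2, 3, 4)
        )
        res = evaluate(clean_sets4, [ClassifierSpec("KNN3")], proto)
        assert [r.population_size for r in res] == [2, 3, 4]
        for r in res:
            accs = r.per_repetition["accuracy"]
            assert min(accs) - 1e-9 <= r.accuracy <= max(accs) + 1e-9
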