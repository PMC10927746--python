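"""Feature extraction, window annotation and the extra-trees classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graspfuse.emg_preproc import EmgWindow
from graspfuse.gesture_classify import (
    WindowLabel,
    annotate_windows,
    build_training_set,
    extract_features,
    predict_proba,
    restrict_to_grasp_classes,
    train_classifier,
)
from graspfuse.ggs_segmentation import assign_phases, segmentation_from_breakpoints


def _window(x, start=0, rate=1562.5):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return EmgWindow(X=x, t_end_s=(start + x.shape[1] - 1) / rate, start=start)


class TestFeatures:
    def test_constant_window(self):
        z = extract_features(_window(np.full(100, 0.5))).Z
        np.testing.assert_allclose(z, [0.5, 0.5, 0.0], atol=1e-12)

    def test_alternating_window(self):
        z = extract_features(_window([1.0, -1.0, 1.0, -1.0])).Z
        np.testing.assert_allclose(z, [1.0, 1.0, 1.0], atol=1e-12)

    def test_twelve_channels_give_36_features(self, rng):
        z = extract_features(_window(rng.standard_normal((12, 500)))).Z
        assert z.shape == (36,)

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValueError):
            extract_features(_window([1.0, np.nan, 0.0]))

    def test_channel_shuffle_permutes_features_consistently(self, rng):
        x = rng.standard_normal((4, 200))
        perm = np.array([2, 0, 3, 1])
        z = extract_features(_window(x)).Z.reshape(3, 4)
        zp = extract_features(_window(x[perm])).Z.reshape(3, 4)
        np.testing.assert_allclose(zp, z[:, perm], atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_var_identity(self, seed):
        x = np.random.default_rng(seed).standard_normal((2, 300))
        z = extract_features(_window(x)).Z.reshape(3, 2)
        rms, _, var = z
        mean = x.mean(axis=1)
        np.testing.assert_allclose(var, rms**2 - mean**2, atol=1e-9)


class TestAnnotation:
    @pytest.fixture()
    def tagged_seg(self, rng):
        data = rng.standard_normal((2, 2000))
        return assign_phases(
            segmentation_from_breakpoints(data, [500, 1000, 1500], lam=0.1)
        )

    def test_center_in_reach_gets_gesture(self, tagged_seg, rng):
        w = _window(rng.standard_normal((2, 400)), start=100)  # center 300 -> reach
        (lab,) = annotate_windows([w], tagged_seg, gesture_id=5)
        assert lab == WindowLabel(gesture=5, phase="reach")

    def test_center_in_rest_gets_open_palm(self, tagged_seg, rng):
        w = _window(rng.standard_normal((2, 400)), start=1550)  # center 1750 -> rest
        (lab,) = annotate_windows([w], tagged_seg, gesture_id=5)
        assert lab == WindowLabel(gesture=0, phase="rest")

    def test_straddling_window_uses_center_phase(self, tagged_seg, rng):
        # spans the reach/grasp boundary at 500; center 550 -> grasp
        w = _window(rng.standard_normal((2, 400)), start=350)
        (lab,) = annotate_windows([w], tagged_seg, gesture_id=5)
        assert lab.phase == "grasp"

    def test_rest_iff_label_zero_invariant(self):
        with pytest.raises(ValueError):
            WindowLabel(gesture=0, phase="reach")
        with pytest.raises(ValueError):
            WindowLabel(gesture=4, phase="rest")


class TestTrainingSet:
    @pytest.fixture()
    def feats_labels(self, rng):
        feats, labels = [], []
        for phase in ("reach", "grasp", "return", "rest"):
            for _ in range(10):
                w = _window(rng.standard_normal((2, 50)))
                feats.append(extract_features(w))
                labels.append(
                    WindowLabel(gesture=0 if phase == "rest" else 7, phase=phase)
                )
        return feats, labels

    def test_return_phase_excluded_from_gesture_training(self, feats_labels):
        X, y = build_training_set(*feats_labels, task="gesture", exclude_return=True)
        assert len(X) == 30

    def test_no_exclusion_keeps_all_windows(self, feats_labels):
        X, _ = build_training_set(*feats_labels, task="gesture", exclude_return=False)
        assert len(X) == 40

    def test_phase_task_keeps_all_four_phases(self, feats_labels):
        X, y = build_training_set(*feats_labels, task="phase")
        assert len(X) == 40
        assert set(y) == {"reach", "grasp", "return", "rest"}


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (100, 36)), rng.normal(8, 1, (100, 36))])
    y = np.array([0] * 100 + [1] * 100)
    return X, y


class TestClassifier:
    def test_separable_classes_fit_perfectly(self, separable):
        X, y = separable
        clf = train_classifier(X, y, seed=0)
        assert clf.model.n_estimators == 50
        assert (clf.model.predict(X) == y).all()

    def test_deterministic_under_seed(self, separable):
        X, y = separable
        p1 = predict_proba(train_classifier(X, y, seed=3), X)
        p2 = predict_proba(train_classifier(X, y, seed=3), X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        with pytest.raises(ValueError):
            train_classifier(X, np.zeros(20))

    def test_probabilities_on_simplex(self, separable, rng):
        X, y = separable
        clf = train_classifier(X, y, seed=1)
        p = predict_proba(clf, rng.standard_normal((50, 36)) * 4)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_14_label_output_dimension(self, rng):
        X = rng.standard_normal((14 * 20, 6)) + np.repeat(
            np.arange(14)[:, None] * 5, 20, axis=0
        )
        y = np.repeat(np.arange(14), 20)
        clf = train_classifier(X, y, seed=0)
        assert predict_proba(clf, X[:3]).shape == (3, 14)

    def test_dimension_mismatch_rejected(self, separable):
        X, y = separable
        clf = train_classifier(X, y, seed=0)
        with pytest.raises(ValueError):
            predict_proba(clf, np.zeros((2, 5)))


class TestGraspRestriction:
    def test_rest_mass_removed_and_renormalized(self):
        proba = np.array([[0.5] + [0.5 / 13] * 13])  # classes 0..13
        out = restrict_to_grasp_classes(proba, classes=np.arange(14))
        np.testing.assert_allclose(out, 1.0 / 13, atol=1e-12)
        np.testing.assert_allclose(out.sum(), 1.0, atol=1e-12)

    def test_all_mass_on_rest_gives_uniform(self):
        proba = np.array([[1.0] + [0.0] * 13])
        out = restrict_to_grasp_classes(proba, classes=np.arange(14))
        np.testing.assert_allclose(out, 1.0 / 13, atol=1e-12)

    def test_missing_training_classes_get_zero(self):
        proba = np.array([[0.25, 0.75]])
        out = restrict_to_grasp_classes(proba, classes=np.array([3, 7]))
        assert out[0, 2] == pytest.approx(0.25)
        assert out[0, 6] == pytest.approx(0.75)
        assert out.sum() == pytest.approx(1.0)
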