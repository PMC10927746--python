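"""Generator invariants: determinism, phase contrast, simplex structure."""

import numpy as np
import pytest

from graspfuse import (
    Occlusion,
    TrialSpec,
    make_templates,
    synth_emg_trial,
    synth_mvc,
    synth_session,
    synth_trial,
    synth_vision_stream,
)
from graspfuse.emg_preproc import bandpass_filter, mvc_normalize, rms_envelope
from graspfuse.io import read_manifest


class TestTemplates:
    def test_shapes_and_invariants(self):
        tpls = make_templates(13, 12, seed=7)
        assert len(tpls) == 13
        for t in tpls:
            assert t.activation.shape == (3, 12)
            assert np.all(t.activation >= 0)
            assert np.all(t.activation.max(axis=1) > 0)

    def test_deterministic_under_seed(self):
        a = make_templates(13, 12, seed=7)
        b = make_templates(13, 12, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.activation, y.activation)

    def test_templates_pairwise_distinct(self):
        tpls = make_templates(2, 3, seed=1)
        d = np.linalg.norm(tpls[0].activation - tpls[1].activation)
        assert d > 0

    @pytest.mark.parametrize("bad", [(0, 12), (13, 0)])
    def test_nonpositive_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            make_templates(*bad, seed=0)


class TestEmgTrial:
    def test_four_second_trial_shape(self, emg_trial):
        assert emg_trial.emg.samples.shape == (12, 6250)

    def test_breakpoints_strictly_increasing_inside(self, emg_trial):
        bp = emg_trial.true_breakpoints
        assert bp.shape == (3,)
        assert 0 < bp[0] < bp[1] < bp[2] < emg_trial.emg.n_samples

    def test_rest_variance_below_grasp_variance(self, emg_trial, template):
        bp = emg_trial.true_breakpoints
        x = emg_trial.emg.samples
        grasp = x[:, bp[0] + 100 : bp[1] - 100]
        rest = x[:, bp[2] + 100 :]
        active = template.activation[1] > 0
        assert np.all(grasp[active].var(axis=1) > rest[active].var(axis=1))

    def test_phase_power_contrast_exceeds_four(self, emg_trial, template):
        bp = emg_trial.true_breakpoints
        x = emg_trial.emg.samples
        grasp_p = x[:, bp[0] + 100 : bp[1] - 100].var(axis=1)
        rest_p = x[:, bp[2] + 100 :].var(axis=1)
        active = template.activation[1] > 0
        assert np.all(grasp_p[active] / rest_p[active] > 4)

    def test_bit_identical_on_repeat(self, template):
        spec = TrialSpec(gesture_id=5, seed=42)
        a = synth_emg_trial(spec, template)
        b = synth_emg_trial(spec, template)
        np.testing.assert_array_equal(a.emg.samples, b.emg.samples)

    def test_short_phase_rejected(self, template):
        spec = TrialSpec(gesture_id=5, phase_durations_ms=(60.0, 800.0, 704.0, 1376.0), seed=0)
        with pytest.raises(ValueError):
            synth_emg_trial(spec, template, crossfade_ms=50.0)


class TestMvc:
    def test_envelope_positive_everywhere(self, mvc_trial):
        assert mvc_trial.samples.shape[0] == 12
        env = rms_envelope(bandpass_filter(mvc_trial))
        assert np.all(env.values.max(axis=1) > 0)

    def test_reproducible(self, template):
        a = synth_mvc(template, seed=9)
        b = synth_mvc(template, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_normalized_task_envelope_bounded(self, template, mvc_trial):
        # MVC headroom should keep normalized task envelopes ~<= 1.
        spec = TrialSpec(gesture_id=5, seed=21)
        trial = synth_emg_trial(spec, template)
        env = rms_envelope(bandpass_filter(trial.emg))
        mvc_env = rms_envelope(bandpass_filter(mvc_trial))
        norm = mvc_normalize(env, mvc_env)
        assert np.percentile(norm.values, 99) <= 1.5


class TestVisionStream:
    def test_frame_count_and_simplex(self):
        spec = TrialSpec(gesture_id=3, seed=0)
        vs = synth_vision_stream(spec, frame_rate_hz=60.0, seed=0)
        assert len(vs) == 240  # 4 s at 60 Hz
        np.testing.assert_allclose(vs.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(vs.probs >= 0)

    def test_zero_depth_keeps_true_class_flat(self):
        spec = TrialSpec(gesture_id=3, seed=0)
        ptrue = []
        for seed in range(10):
            vs = synth_vision_stream(spec, occlusion=Occlusion(depth=0.0), seed=seed)
            ptrue.append(vs.probs[:, 2])
        ptrue = np.array(ptrue)
        grasp = (vs.t_s >= 1.12) & (vs.t_s <= 1.92)
        assert abs(ptrue[:, grasp].mean() - ptrue[:, ~grasp].mean()) < 0.05

    def test_full_depth_zero_temperature_limits(self):
        spec = TrialSpec(gesture_id=3, seed=0)
        vs = synth_vision_stream(
            spec, occlusion=Occlusion(depth=1.0, margin_ms=0.0),
            temperature=1e-9, logit_noise_sd=0.0, seed=0,
        )
        grasp = (vs.t_s >= 1.12) & (vs.t_s <= 1.92)
        # one-hot on the true class outside occlusion
        assert np.all(vs.probs[~grasp, 2] > 0.999)
        # near-uniform inside (all logits equal)
        np.testing.assert_allclose(vs.probs[grasp], 1.0 / 13, atol=1e-6)

    def test_occlusion_reduces_true_class_probability(self):
        spec = TrialSpec(gesture_id=3, seed=0)
        vs = synth_vision_stream(spec, occlusion=Occlusion(depth=0.8), seed=0)
        grasp = (vs.t_s >= 1.12) & (vs.t_s <= 1.92)
        assert vs.probs[grasp, 2].mean() < vs.probs[~grasp, 2].mean() - 0.1

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            Occlusion(depth=1.5)


class TestSession:
    def test_session_files_and_manifest(self, tmp_path):
        manifest = synth_session(tmp_path, n_objects=2, trials_per_object=3, seed=5)
        assert len(manifest["trials"]) == 6
        assert len(list(tmp_path.glob("trial_*.csv"))) == 6
        assert len(list(tmp_path.glob("vision_*.csv"))) == 6
        assert (tmp_path / "mvc.csv").exists()
        assert all(1 <= t["gesture_id"] <= 13 for t in manifest["trials"])

    def test_manifest_deterministic(self, tmp_path):
        m1 = synth_session(tmp_path / "a", n_objects=2, trials_per_object=2, seed=5)
        m2 = synth_session(tmp_path / "b", n_objects=2, trials_per_object=2, seed=5)
        assert m1["trials"] == m2["trials"]
        assert read_manifest(tmp_path / "a")["trials"] == m1["trials"]

    def test_boxes_and_gaze_cover_frames(self, multimodal_trial):
        assert len(multimodal_trial.boxes) == len(multimodal_trial.vision)
        assert multimodal_trial.vision.t_s[0] >= 0
        assert multimodal_trial.vision.t_s[-1] <= multimodal_trial.emg.duration_s
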