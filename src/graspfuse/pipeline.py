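"""End-to-end orchestration: simulate -> preprocess -> segment -> train -> fuse -> evaluate.

This ties the individual modules into the full grasp-intent inference
experiment on a synthetic session: per-object 4/2 train/validation
split, unsupervised phase segmentation and window annotation, the two
extra-trees classifiers, gaze-contingent visual evidence, Bayesian
product fusion, and the per-phase / over-time accuracy summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, evidence_fusion, gesture_classify, synthgen
from .emg_preproc import (
    EmgTrial,
    WindowConfig,
    bandpass_filter,
    make_windows,
    mvc_normalize,
    rms_envelope,
)
from .evidence_fusion import EvidenceStream, N_GRASP_CLASSES
from .ggs_segmentation import (
    GgsConfig,
    Segmentation,
    assign_phases,
    ggs_fit,
    segmentation_from_breakpoints,
)
from .synthgen import MUSCLES, Occlusion, SyntheticTrial, _child_seed

__all__ = ["SessionData", "PipelineResult", "simulate_session", "run_pipeline"]

SOURCES = ("emg", "vision", "fused", "smoothed")


@dataclass
class SessionData:
    """An in-memory synthetic session: trials, MVC reference, ground truth."""

    trials: dict[tuple[int, int], SyntheticTrial]
    mvc: EmgTrial
    n_objects: int
    trials_per_object: int
    seed: int

    def gesture_of(self, obj: int) -> int:
        return self.trials[(obj, 0)].spec.gesture_id


def simulate_session(
    n_objects: int,
    trials_per_object: int = 6,
    seed: int = 0,
    occlusion: Occlusion | None = None,
    phase_durations_ms=synthgen.DEFAULT_PHASE_DURATIONS_MS,
    rate_hz: float = synthgen.DEFAULT_RATE_HZ,
    **emg_kwargs,
) -> SessionData:
    """In-memory equivalent of ``synthgen.synth_session`` (no files written)."""
    templates = synthgen.make_templates(
        N_GRASP_CLASSES, len(MUSCLES), seed=_child_seed(seed, 0)
    )
    max_act = np.max(
        [t.activation * t.covariance_scale[:, None] for t in templates], axis=0
    )
    mvc_template = synthgen.GestureTemplate(
        gesture_id=1, activation=max_act, covariance_scale=np.ones(3)
    )
    mvc = synthgen.synth_mvc(mvc_template, rate_hz=rate_hz, seed=_child_seed(seed, 10**6))
    trials = {}
    for obj in range(n_objects):
        gesture = obj % N_GRASP_CLASSES + 1
        for k in range(trials_per_object):
            spec = synthgen.TrialSpec(
                gesture_id=gesture,
                phase_durations_ms=tuple(phase_durations_ms),
                rate_hz=rate_hz,
                seed=_child_seed(seed, obj, k),
            )
            trials[(obj, k)] = synthgen.synth_trial(
                spec, templates[gesture - 1], occlusion=occlusion, **emg_kwargs
            )
    return SessionData(
        trials=trials, mvc=mvc, n_objects=n_objects,
        trials_per_object=trials_per_object, seed=seed,
    )


@dataclass
class PipelineResult:
    aligned: pd.DataFrame
    phase_table: pd.DataFrame
    curves: pd.DataFrame
    split: evaluation.SplitPlan
    phase_accuracy_pct: float
    segmentations: dict[tuple[int, int], Segmentation] = field(repr=False, default_factory=dict)

    def source_total(self, source: str) -> float:
        return float(self.phase_table.loc[source, "total"])

    def source_accuracy(self, source: str, phase: str) -> float:
        return float(self.phase_table.loc[source, phase])


def _segment_trial(trial: SyntheticTrial, use_ggs: bool, cfg: GgsConfig) -> Segmentation:
    if use_ggs:
        seg = ggs_fit(trial.emg.samples, cfg)
    else:
        seg = segmentation_from_breakpoints(trial.emg.samples, trial.true_breakpoints)
    return assign_phases(seg)


def _vision_evidence(trial: SyntheticTrial) -> EvidenceStream:
    """Per-frame posterior of the gaze-selected detection box."""
    probs = []
    for frame_boxes, gaze in zip(trial.boxes, trial.vision.gaze):
        idx = evidence_fusion.select_box_by_gaze(frame_boxes, tuple(gaze))
        probs.append(frame_boxes[idx].probs if idx is not None
                     else np.full(N_GRASP_CLASSES, 1.0 / N_GRASP_CLASSES))
    return EvidenceStream(modality="V", t_s=trial.vision.t_s, probs=np.array(probs))


def run_pipeline(
    session: SessionData,
    use_ggs: bool = True,
    ggs_cfg: GgsConfig | None = None,
    split_seed: int | None = None,
    clf_seed: int | None = None,
    window_cfg: WindowConfig | None = None,
    tolerance_s: float = 0.05,
    eps: float = 1e-6,
    smooth_w: int = 5,
    bin_ms: float = 288.0,
) -> PipelineResult:
    """Run the full experiment on a session and summarize accuracy.

    Per validation window the expected answer is the trial's grasp label,
    for every source; the EMG source is the 14-class gesture classifier's
    argmax (so its rest-phase accuracy is near chance, as EMG carries no
    grasp information at rest), the vision source is the gaze-selected
    box posterior, and fusion combines the 13-class restriction of the
    EMG posterior with the vision posterior by the product rule.
    """
    if ggs_cfg is None:
        ggs_cfg = GgsConfig()
    split_seed = session.seed if split_seed is None else split_seed
    clf_seed = session.seed if clf_seed is None else clf_seed
    rate = session.mvc.rate_hz
    if window_cfg is None:
        window_cfg = WindowConfig(rate_hz=rate)

    mvc_env = rms_envelope(bandpass_filter(session.mvc))
    split = evaluation.split_trials(
        session.n_objects, session.trials_per_object,
        n_train=max(1, session.trials_per_object - 2), seed=split_seed,
    )

    # Preprocess, segment and annotate every trial once.
    windows_by_trial, features_by_trial, labels_by_trial, seg_by_trial = {}, {}, {}, {}
    for key, trial in session.trials.items():
        env = rms_envelope(bandpass_filter(trial.emg))
        norm = mvc_normalize(env, mvc_env)
        windows = make_windows(norm, window_cfg)
        seg = _segment_trial(trial, use_ggs, ggs_cfg)
        windows_by_trial[key] = windows
        features_by_trial[key] = [gesture_classify.extract_features(w) for w in windows]
        labels_by_trial[key] = gesture_classify.annotate_windows(
            windows, seg, trial.spec.gesture_id
        )
        seg_by_trial[key] = seg

    train_keys = split.trials("train")
    train_feats = [f for k in train_keys for f in features_by_trial[k]]
    train_labels = [lab for k in train_keys for lab in labels_by_trial[k]]
    Xg, yg = gesture_classify.build_training_set(
        train_feats, train_labels, task="gesture", exclude_return=True
    )
    gesture_clf = gesture_classify.train_classifier(Xg, yg, task="gesture", seed=clf_seed)
    Xp, yp = gesture_classify.build_training_set(train_feats, train_labels, task="phase")
    phase_clf = gesture_classify.train_classifier(Xp, yp, task="phase", seed=clf_seed + 1)

    records = []
    phase_correct, phase_total = 0, 0
    for key in split.trials("validation"):
        trial = session.trials[key]
        windows = windows_by_trial[key]
        feats = np.array([f.Z for f in features_by_trial[key]])
        seg = seg_by_trial[key]
        true_label = trial.spec.gesture_id
        t_windows = np.array([w.t_end_s for w in windows])
        # Cross-modal pairing uses the window-center time: the EMG features
        # summarize the whole window, so the co-temporal (and already past)
        # vision frame is the one at its midpoint, not at its last sample.
        t_centers = np.array([w.center_sample() / rate for w in windows])
        phases = [seg.phase_of_sample(w.center_sample()) for w in windows]

        proba14 = gesture_classify.predict_proba(gesture_clf, feats)
        emg_pred = gesture_clf.classes_[np.argmax(proba14, axis=1)].astype(int)
        emg13 = gesture_classify.restrict_to_grasp_classes(proba14, gesture_clf.classes_)
        emg_stream = EvidenceStream(modality="M", t_s=t_centers, probs=emg13)

        vis_stream = _vision_evidence(trial)
        fused = evidence_fusion.fuse_streams(
            emg_stream, vis_stream, tolerance_s=tolerance_s, eps=eps, smooth_w=smooth_w
        )
        pairs = evidence_fusion.align_streams(emg_stream, vis_stream, tolerance_s)
        vis_pred = np.array(
            [evidence_fusion.decide(pv) if pv is not None else -1 for _, _, pv in pairs]
        )

        phase_pred = phase_clf.model.predict(feats)
        phase_correct += int(np.sum(phase_pred == np.array(phases)))
        phase_total += len(phases)

        preds = {
            "emg": emg_pred,
            "vision": vis_pred,
            "fused": fused.decisions,
            "smoothed": fused.smoothed,
        }
        frames = []
        for source, pred in preds.items():
            frames.append(
                pd.DataFrame(
                    {
                        "t_s": t_windows,
                        "source": source,
                        "pred_label": pred,
                        "true_label": true_label,
                        "phase": phases,
                        "object": key[0],
                        "trial": key[1],
                    }
                )
            )
        trial_df = pd.concat(frames, ignore_index=True)
        onset_s = seg.grasp_onset_sample() / rate
        records.append(evaluation.align_to_grasp(trial_df, onset_s))

    aligned = pd.concat(records, ignore_index=True)
    table = evaluation.per_phase_accuracy(aligned)
    curves = evaluation.accuracy_over_time(aligned, bin_ms=bin_ms)
    return PipelineResult(
        aligned=aligned,
        phase_table=table,
        curves=curves,
        split=split,
        phase_accuracy_pct=100.0 * phase_correct / max(phase_total, 1),
        segmentations=seg_by_trial,
    )
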