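"""Seeded synthetic multimodal reach-to-grasp sessions.

Real recordings for this task are 4-second pick-and-place trials: the
subject rests, reaches for an object, grasps and transports it, returns
the hand and rests again, while 12 surface-EMG channels (1,562.5 Hz) and
a head-mounted camera with gaze tracking (60 Hz) record.  This module
emulates that structure with known ground truth at every stage:

* EMG: within each movement phase the signal is a zero-mean, band-limited
  (40--500 Hz) Gaussian process whose per-channel standard deviation is a
  noise floor plus a gesture- and phase-specific activation; phases blend
  through short raised-cosine cross-fades, and the true phase boundaries
  (cross-fade midpoints) are recorded.
* MVC: a per-muscle maximal-contraction burst whose processed envelope
  exceeds any task-trial envelope, so MVC-normalized task data stays
  roughly within [0, 1].
* Vision: per-frame grasp-class probability vectors peaked on the true
  gesture, degraded during a grasp-phase occlusion interval by scaling
  the true-class logit down; plus gaze points and detection boxes.

Everything is a pure function of its arguments and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .emg_preproc import DEFAULT_RATE_HZ, MUSCLES, EmgTrial
from .evidence_fusion import N_GRASP_CLASSES, DetectionBox

__all__ = [
    "PHASES",
    "ACTIVE_PHASES",
    "DEFAULT_PHASE_DURATIONS_MS",
    "GestureTemplate",
    "TrialSpec",
    "VisionStream",
    "Occlusion",
    "SyntheticTrial",
    "make_templates",
    "synth_mvc",
    "synth_emg_trial",
    "synth_vision_stream",
    "synth_trial",
    "synth_session",
]

PHASES = ("reach", "grasp", "return", "rest")
ACTIVE_PHASES = ("reach", "grasp", "return")

#: Default phase durations (ms), summing to the 4 s trial length with a
#: ~1.4 s rest (half a rest is the usual 700 ms display shift).  Each
#: duration is an exact multiple of the 0.64 ms sample period, so a
#: 4 s trial is exactly 6250 samples.
DEFAULT_PHASE_DURATIONS_MS = (1120.0, 800.0, 704.0, 1376.0)

#: Baseline (resting) EMG standard deviation, arbitrary amplifier units.
DEFAULT_BASE_NOISE = 0.05

#: Trial-to-trial per-channel lognormal gain jitter (sigma of log).
#: Surface-EMG amplitudes commonly vary by ~20-30% between repetitions.
DEFAULT_TRIAL_JITTER_SD = 0.2

_IMAGE_W, _IMAGE_H = 1280.0, 720.0


def _child_seed(*parts: int) -> int:
    """Deterministic 31-bit child seed from a tuple of integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class GestureTemplate:
    """Gesture- and phase-dependent muscle activation pattern.

    ``activation`` is a 3 x C matrix of non-negative weights (rows: reach,
    grasp, return); ``covariance_scale`` is a positive per-phase scalar
    multiplying the weights.  The rest phase always has zero activation.
    """

    gesture_id: int
    activation: np.ndarray
    covariance_scale: np.ndarray

    def __post_init__(self) -> None:
        act = np.asarray(self.activation, dtype=float)
        cov = np.asarray(self.covariance_scale, dtype=float)
        object.__setattr__(self, "activation", act)
        object.__setattr__(self, "covariance_scale", cov)
        if act.ndim != 2 or act.shape[0] != len(ACTIVE_PHASES):
            raise ValueError("activation must be 3 x C (reach, grasp, return)")
        if not np.all(np.isfinite(act)) or np.any(act < 0):
            raise ValueError("activation weights must be finite and >= 0")
        if np.any(act.max(axis=1) <= 0):
            raise ValueError("each non-rest phase needs at least one active channel")
        if cov.shape != (len(ACTIVE_PHASES),) or np.any(cov <= 0):
            raise ValueError("covariance_scale must be 3 positive scalars")

    @property
    def n_channels(self) -> int:
        return self.activation.shape[1]

    def phase_std(self, base_noise: float = DEFAULT_BASE_NOISE) -> np.ndarray:
        """4 x C per-phase, per-channel standard deviation (rest last)."""
        active = base_noise + self.activation * self.covariance_scale[:, None]
        rest = np.full((1, self.n_channels), base_noise)
        return np.vstack([active, rest])


@dataclass(frozen=True)
class TrialSpec:
    """Parameters of one synthetic trial."""

    gesture_id: int
    phase_durations_ms: tuple[float, ...] = DEFAULT_PHASE_DURATIONS_MS
    rate_hz: float = DEFAULT_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.gesture_id <= N_GRASP_CLASSES:
            raise ValueError("gesture_id must be in 1..13")
        if len(self.phase_durations_ms) != 4 or any(
            d <= 0 for d in self.phase_durations_ms
        ):
            raise ValueError("need 4 positive phase durations")
        if self.rate_hz <= 2 * 500.0:
            raise ValueError("sampling rate must exceed 1 kHz for the 40-500 Hz band")

    @property
    def duration_ms(self) -> float:
        return float(sum(self.phase_durations_ms))

    def phase_samples(self) -> np.ndarray:
        return np.array(
            [int(round(d * self.rate_hz / 1000.0)) for d in self.phase_durations_ms]
        )


@dataclass
class Occlusion:
    """Grasp-phase occlusion of the visual evidence.

    ``depth`` in [0, 1] scales the true-class logit down inside the
    grasp phase; the degradation ramps linearly over ``margin_ms`` into
    the neighbouring phases.
    """

    depth: float = 0.8
    margin_ms: float = 150.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("occlusion depth must lie in [0, 1]")
        if self.margin_ms < 0:
            raise ValueError("occlusion margin must be >= 0")


@dataclass
class VisionStream:
    """Per-frame grasp-class probabilities with gaze points."""

    t_s: np.ndarray
    probs: np.ndarray
    gaze: np.ndarray  # (F, 2) pixels

    def __post_init__(self) -> None:
        if len(self.t_s) != len(self.probs) or len(self.t_s) != len(self.gaze):
            raise ValueError("frame count mismatch")

    def __len__(self) -> int:
        return len(self.t_s)


@dataclass
class SyntheticTrial:
    """One fully ground-truthed multimodal trial."""

    emg: EmgTrial
    true_breakpoints: np.ndarray
    spec: TrialSpec
    vision: VisionStream | None = None
    boxes: list[list[DetectionBox]] | None = None  # per frame

    def __post_init__(self) -> None:
        bp = np.asarray(self.true_breakpoints, dtype=int)
        n = self.emg.n_samples
        if bp.shape != (3,) or np.any(np.diff(bp) <= 0) or bp[0] <= 0 or bp[-1] >= n:
            raise ValueError("need 3 strictly increasing breakpoints inside (0, N)")
        self.true_breakpoints = bp


def make_templates(
    n_gestures: int, n_channels: int, seed: int,
    weight_range: tuple[float, float] = (0.3, 1.0),
    scale_range: tuple[float, float] = (0.5, 0.8),
) -> list[GestureTemplate]:
    """Draw ``n_gestures`` distinct activation templates.

    Weights are uniform on ``weight_range`` per channel and phase, so all
    channels are active during movement but with gesture-specific
    patterns; distinct templates differ almost surely, and a degenerate
    draw is re-sampled.
    """
    if n_gestures < 1 or n_channels < 1:
        raise ValueError("n_gestures and n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    templates: list[GestureTemplate] = []
    seen: list[np.ndarray] = []
    gid = 1
    while len(templates) < n_gestures:
        act = rng.uniform(*weight_range, size=(len(ACTIVE_PHASES), n_channels))
        if any(np.linalg.norm(act - prev) == 0.0 for prev in seen):
            continue
        scale = rng.uniform(*scale_range, size=len(ACTIVE_PHASES))
        templates.append(
            GestureTemplate(gesture_id=gid, activation=act, covariance_scale=scale)
        )
        seen.append(act)
        gid += 1
    return templates


def _bandlimited_noise(
    rng: np.random.Generator, shape: tuple[int, int], rate_hz: float,
    low_hz: float = 40.0, high_hz: float = 500.0,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the EMG band."""
    white = rng.standard_normal(shape)
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos")
    carrier = signal.sosfiltfilt(sos, white, axis=1)
    std = carrier.std(axis=1, keepdims=True)
    return carrier / np.where(std > 0, std, 1.0)


def synth_mvc(
    template: GestureTemplate,
    rate_hz: float = DEFAULT_RATE_HZ,
    seed: int = 0,
    duration_s: float = 3.0,
    base_noise: float = DEFAULT_BASE_NOISE,
    headroom: float = 1.2,
) -> EmgTrial:
    """Per-muscle maximal-contraction burst.

    Each channel is band-limited noise whose plateau standard deviation is
    ``headroom`` times the largest per-phase task standard deviation for
    that channel, so task envelopes normalized by this MVC stay ~<= 1.
    The burst ramps up, holds, and ramps down (raised cosine).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    c = template.n_channels
    carrier = _bandlimited_noise(rng, (c, n), rate_hz)
    target = headroom * template.phase_std(base_noise).max(axis=0)  # per channel
    ramp = int(round(0.5 * rate_hz))
    envelope = np.ones(n)
    t = np.arange(ramp)
    envelope[:ramp] = 0.5 * (1 - np.cos(np.pi * t / ramp))
    envelope[-ramp:] = 0.5 * (1 + np.cos(np.pi * t / ramp))
    envelope = base_noise / target[:, None] + (1 - base_noise / target[:, None]) * envelope
    samples = carrier * envelope * target[:, None]
    return EmgTrial(
        samples=samples,
        rate_hz=rate_hz,
        channel_names=MUSCLES[:c] if c <= len(MUSCLES) else tuple(f"ch{i}" for i in range(c)),
        gesture_id=0,
        trial_id="mvc",
    )


def synth_emg_trial(
    spec: TrialSpec,
    template: GestureTemplate,
    base_noise: float = DEFAULT_BASE_NOISE,
    crossfade_ms: float = 50.0,
    trial_jitter_sd: float = DEFAULT_TRIAL_JITTER_SD,
) -> SyntheticTrial:
    """Generate the EMG part of a trial with ground-truth breakpoints.

    The per-channel standard-deviation profile is piecewise constant over
    the four phases (rest has zero activation) with raised-cosine
    cross-fades of ``crossfade_ms`` at the three phase boundaries; the
    true breakpoints sit at the cross-fade midpoints.  A per-trial,
    per-channel lognormal gain jitter models electrode/posture
    variability between repetitions of the same gesture.
    """
    if template.gesture_id != spec.gesture_id:
        raise ValueError("template / spec gesture mismatch")
    rng = np.random.default_rng(spec.seed)
    fade = int(round(crossfade_ms * spec.rate_hz / 1000.0))
    phase_n = spec.phase_samples()
    if np.any(phase_n < 2 * fade):
        raise ValueError("each phase must be at least twice the cross-fade length")
    n = int(phase_n.sum())
    c = template.n_channels

    jitter = rng.lognormal(mean=0.0, sigma=trial_jitter_sd, size=c) if trial_jitter_sd > 0 else np.ones(c)
    stds = template.phase_std(base_noise).copy()
    stds[:3] = base_noise + (stds[:3] - base_noise) * jitter  # rest keeps the floor

    bounds = np.cumsum(phase_n)[:-1]  # 3 true breakpoints
    profile = np.empty((c, n))
    edges = np.concatenate([[0], bounds, [n]])
    for p in range(4):
        profile[:, edges[p] : edges[p + 1]] = stds[p][:, None]
    if fade > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(fade) + 0.5) / fade))
        for i, b in enumerate(bounds):
            lo, hi = b - fade // 2, b - fade // 2 + fade
            left, right = stds[i][:, None], stds[i + 1][:, None]
            profile[:, lo:hi] = left + (right - left) * ramp[None, :]

    carrier = _bandlimited_noise(rng, (c, n), spec.rate_hz)
    samples = carrier * profile
    emg = EmgTrial(
        samples=samples,
        rate_hz=spec.rate_hz,
        channel_names=MUSCLES[:c] if c <= len(MUSCLES) else tuple(f"ch{i}" for i in range(c)),
        gesture_id=spec.gesture_id,
    )
    return SyntheticTrial(emg=emg, true_breakpoints=bounds, spec=spec)


def synth_vision_stream(
    spec: TrialSpec,
    frame_rate_hz: float = 60.0,
    occlusion: Occlusion | None = None,
    temperature: float = 1.5,
    seed: int = 0,
    peak_logit: float = 3.0,
    logit_noise_sd: float = 1.1,
    n_classes: int = N_GRASP_CLASSES,
) -> VisionStream:
    """Per-frame grasp-class probability stream with gaze points.

    Outside occlusion the true gesture's logit is ``peak_logit`` and all
    other logits are 0; per-frame Gaussian logit noise produces a
    realistic (imperfect) frame-level accuracy.  Inside the occlusion
    interval (grasp phase, ramping over the margin into neighbouring
    phases) the true-class logit is scaled by ``1 - depth``.
    Probabilities are ``softmax(logits / temperature)``.
    """
    if occlusion is None:
        occlusion = Occlusion()
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(spec.duration_ms / 1000.0 * frame_rate_hz))
    t_s = (np.arange(n_frames) + 0.5) / frame_rate_hz

    cum_ms = np.cumsum(spec.phase_durations_ms)
    grasp_start_s, grasp_end_s = cum_ms[0] / 1000.0, cum_ms[1] / 1000.0
    margin_s = occlusion.margin_ms / 1000.0
    w = np.zeros(n_frames)
    inside = (t_s >= grasp_start_s) & (t_s <= grasp_end_s)
    w[inside] = 1.0
    if margin_s > 0:
        before = (t_s >= grasp_start_s - margin_s) & (t_s < grasp_start_s)
        w[before] = (t_s[before] - (grasp_start_s - margin_s)) / margin_s
        after = (t_s > grasp_end_s) & (t_s <= grasp_end_s + margin_s)
        w[after] = ((grasp_end_s + margin_s) - t_s[after]) / margin_s

    logits = rng.normal(0.0, logit_noise_sd, size=(n_frames, n_classes))
    logits[:, spec.gesture_id - 1] += peak_logit * (1.0 - occlusion.depth * w)
    z = logits / temperature
    z -= z.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)

    center = np.array([_IMAGE_W * 0.5, _IMAGE_H * 0.55])
    gaze = center[None, :] + rng.normal(0.0, 15.0, size=(n_frames, 2))
    return VisionStream(t_s=t_s, probs=probs, gaze=gaze)


def _make_boxes(
    vision: VisionStream, gesture_id: int, rng: np.random.Generator,
    n_classes: int = N_GRASP_CLASSES,
) -> list[list[DetectionBox]]:
    """Per-frame detections: the gazed true object plus one distractor."""
    true_center = np.array([_IMAGE_W * 0.5, _IMAGE_H * 0.55])
    distract_center = true_center + np.array([320.0, -40.0])
    wrong = gesture_id % n_classes + 1
    distract_probs = np.full(n_classes, 0.1 / (n_classes - 1))
    distract_probs[wrong - 1] = 0.9
    boxes: list[list[DetectionBox]] = []
    for probs in vision.probs:
        jit = rng.normal(0.0, 3.0, size=4)
        boxes.append(
            [
                DetectionBox(
                    x_min=true_center[0] - 70 + jit[0], y_min=true_center[1] - 55 + jit[1],
                    x_max=true_center[0] + 70 + jit[2], y_max=true_center[1] + 55 + jit[3],
                    probs=probs, is_true_object=True,
                ),
                DetectionBox(
                    x_min=distract_center[0] - 60, y_min=distract_center[1] - 45,
                    x_max=distract_center[0] + 60, y_max=distract_center[1] + 45,
                    probs=distract_probs.copy(), is_true_object=False,
                ),
            ]
        )
    return boxes


def synth_trial(
    spec: TrialSpec,
    template: GestureTemplate,
    occlusion: Occlusion | None = None,
    frame_rate_hz: float = 60.0,
    **emg_kwargs,
) -> SyntheticTrial:
    """Full multimodal trial: EMG, vision stream, gaze and detection boxes."""
    trial = synth_emg_trial(spec, template, **emg_kwargs)
    vision = synth_vision_stream(
        spec, frame_rate_hz=frame_rate_hz, occlusion=occlusion,
        seed=_child_seed(spec.seed, 1),
    )
    rng = np.random.default_rng(_child_seed(spec.seed, 2))
    trial.vision = vision
    trial.boxes = _make_boxes(vision, spec.gesture_id, rng)
    return trial


def synth_session(
    out_dir: str | Path,
    n_objects: int,
    trials_per_object: int = 6,
    seed: int = 0,
    phase_durations_ms: tuple[float, ...] = DEFAULT_PHASE_DURATIONS_MS,
    rate_hz: float = DEFAULT_RATE_HZ,
    occlusion: Occlusion | None = None,
    **emg_kwargs,
) -> dict:
    """Generate and write a full session to ``out_dir``; returns the manifest.

    Each object is assigned a grasp gesture (cycling through the 13-class
    taxonomy) and performed for ``trials_per_object`` trials.  Files per
    trial: ``trial_<object>_<k>.csv`` (+ JSON sidecar) and
    ``vision_<object>_<k>.csv``; one session-wide ``mvc.csv`` and a
    ``manifest.json`` listing every trial with its ground truth.
    """
    from . import io as gio  # local import to avoid cycle at module load

    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    templates = make_templates(N_GRASP_CLASSES, len(MUSCLES), seed=_child_seed(seed, 0))
    # MVC must dominate every gesture: build it from the channel-wise max template.
    max_act = np.max([t.activation * t.covariance_scale[:, None] for t in templates], axis=0)
    mvc_template = GestureTemplate(
        gesture_id=1, activation=max_act, covariance_scale=np.ones(len(ACTIVE_PHASES))
    )
    mvc = synth_mvc(mvc_template, rate_hz=rate_hz, seed=_child_seed(seed, 10**6))
    gio.write_trial(out / "mvc.csv", mvc, meta={"kind": "mvc", "seed": seed})

    manifest: dict = {
        "n_objects": n_objects,
        "trials_per_object": trials_per_object,
        "seed": seed,
        "rate_hz": rate_hz,
        "phase_durations_ms": list(phase_durations_ms),
        "mvc_csv": "mvc.csv",
        "trials": [],
    }
    for obj in range(n_objects):
        gesture = obj % N_GRASP_CLASSES + 1
        template = templates[gesture - 1]
        for k in range(trials_per_object):
            spec = TrialSpec(
                gesture_id=gesture,
                phase_durations_ms=phase_durations_ms,
                rate_hz=rate_hz,
                seed=_child_seed(seed, obj, k),
            )
            trial = synth_trial(spec, template, occlusion=occlusion, **emg_kwargs)
            stem = f"trial_{obj}_{k}"
            gio.write_trial(
                out / f"{stem}.csv",
                trial.emg,
                meta={
                    "rate_hz": rate_hz,
                    "gesture_id": gesture,
                    "true_breakpoints": [int(b) for b in trial.true_breakpoints],
                    "phase_durations_ms": list(phase_durations_ms),
                    "seed": spec.seed,
                },
            )
            gio.write_vision(out / f"vision_{obj}_{k}.csv", trial.vision)
            manifest["trials"].append(
                {
                    "object": obj,
                    "trial": k,
                    "gesture_id": gesture,
                    "emg_csv": f"{stem}.csv",
                    "emg_json": f"{stem}.json",
                    "vision_csv": f"vision_{obj}_{k}.csv",
                    "true_breakpoints": [int(b) for b in trial.true_breakpoints],
                }
            )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
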