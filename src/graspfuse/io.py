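"""CSV + JSON on-disk formats for trials, vision streams and sessions.

* Trial: ``trial_<object>_<k>.csv`` -- header row of channel names, then
  N rows x C columns of float samples; sidecar ``trial_<object>_<k>.json``
  with rate, gesture, ground-truth breakpoints and seed.
* Vision: ``vision_<object>_<k>.csv`` with columns t_s, p1..p13, gaze_x,
  gaze_y.
* Session: a directory of the above plus ``manifest.json`` and a
  session-wide ``mvc.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg_preproc import DEFAULT_RATE_HZ, EmgTrial
from .evidence_fusion import N_GRASP_CLASSES

__all__ = [
    "write_trial",
    "read_trial",
    "write_vision",
    "read_vision",
    "read_manifest",
]


def write_trial(csv_path: str | Path, trial: EmgTrial, meta: dict | None = None) -> None:
    csv_path = Path(csv_path)
    df = pd.DataFrame(trial.samples.T, columns=list(trial.channel_names))
    df.to_csv(csv_path, index=False, float_format="%.6g")
    sidecar = dict(meta or {})
    sidecar.setdefault("rate_hz", trial.rate_hz)
    sidecar.setdefault("gesture_id", trial.gesture_id)
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_trial(csv_path: str | Path) -> tuple[EmgTrial, dict]:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    meta: dict = {}
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    trial = EmgTrial(
        samples=df.to_numpy().T,
        rate_hz=float(meta.get("rate_hz", DEFAULT_RATE_HZ)),
        channel_names=tuple(df.columns),
        gesture_id=int(meta.get("gesture_id", 0)),
        trial_id=csv_path.stem,
    )
    return trial, meta


def write_vision(csv_path: str | Path, vision) -> None:
    cols = {"t_s": vision.t_s}
    for j in range(vision.probs.shape[1]):
        cols[f"p{j + 1}"] = vision.probs[:, j]
    cols["gaze_x"] = vision.gaze[:, 0]
    cols["gaze_y"] = vision.gaze[:, 1]
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.8g")


def read_vision(csv_path: str | Path):
    from .synthgen import VisionStream

    df = pd.read_csv(csv_path)
    pcols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    pcols = sorted(pcols, key=lambda c: int(c[1:]))
    probs = df[pcols].to_numpy()
    probs = probs / probs.sum(axis=1, keepdims=True)  # undo rounding drift
    gaze = df[["gaze_x", "gaze_y"]].to_numpy() if "gaze_x" in df.columns else np.zeros((len(df), 2))
    return VisionStream(t_s=df["t_s"].to_numpy(), probs=probs, gaze=gaze)


def read_manifest(session_dir: str | Path) -> dict:
    with open(Path(session_dir) / "manifest.json") as fh:
        return json.load(fh)
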