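"""Trial splitting, grasp-onset alignment and accuracy summaries.

Validation follows the protocol of the grasp experiments: of the 6
trials per object, 4 are randomly assigned to training and 2 to
validation (216/108 for the full 54-object session).  For time-resolved
accuracy, every validation trial is re-timed so the onset of its grasp
phase is 0 ms; an additional 700 ms backward shift is applied only to
the exported display timeline (it presents the previous trial's rest
before the reach) and never affects accuracy computation.  Top-1
accuracy is the frequency with which the label of maximum probability
matches the expected grasp label, reported per time bin and per phase,
the latter in the five-column layout rest / reach / grasp / return /
rest plus a window-count-weighted total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PHASE_COLUMNS",
    "SplitPlan",
    "split_trials",
    "align_to_grasp",
    "accuracy_over_time",
    "per_phase_accuracy",
    "random_baseline",
]

#: Table layout: initial rest, the three movement phases, final rest, total.
PHASE_COLUMNS = ("rest_pre", "reach", "grasp", "return", "rest_post", "total")

DISPLAY_SHIFT_MS = 700.0


@dataclass
class SplitPlan:
    """Per-(object, trial) train/validation assignment."""

    assignments: dict[tuple[int, int], str]
    seed: int

    def role(self, obj: int, trial: int) -> str:
        return self.assignments[(obj, trial)]

    @property
    def n_train(self) -> int:
        return sum(r == "train" for r in self.assignments.values())

    @property
    def n_validation(self) -> int:
        return sum(r == "validation" for r in self.assignments.values())

    def trials(self, role: str) -> list[tuple[int, int]]:
        return sorted(k for k, r in self.assignments.items() if r == role)


def split_trials(
    n_objects: int = 54,
    trials_per_object: int = 6,
    n_train: int = 4,
    seed: int = 0,
) -> SplitPlan:
    """Uniform per-object random split into ``n_train`` train and the rest validation."""
    if n_objects < 1 or trials_per_object < 1:
        raise ValueError("counts must be >= 1")
    if not 0 < n_train < trials_per_object:
        raise ValueError("n_train must be in 1..trials_per_object-1")
    rng = np.random.default_rng(seed)
    assignments: dict[tuple[int, int], str] = {}
    for obj in range(n_objects):
        train_idx = set(rng.choice(trials_per_object, size=n_train, replace=False).tolist())
        for k in range(trials_per_object):
            assignments[(obj, k)] = "train" if k in train_idx else "validation"
    return SplitPlan(assignments=assignments, seed=seed)


def align_to_grasp(
    predictions: pd.DataFrame,
    grasp_onset_s: float,
    display_shift_ms: float = DISPLAY_SHIFT_MS,
) -> pd.DataFrame:
    """Re-time one trial's predictions relative to grasp onset.

    ``predictions`` needs columns ``t_s``, ``source``, ``pred_label``,
    ``true_label`` and ``phase``.  Adds ``time_rel_ms`` (0 at grasp
    onset) and ``display_time_ms`` (shifted backward by
    ``display_shift_ms``); predictions and labels are untouched.
    """
    required = {"t_s", "source", "pred_label", "true_label", "phase"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions frame lacks columns: {sorted(missing)}")
    out = predictions.copy()
    out["time_rel_ms"] = (out["t_s"] - grasp_onset_s) * 1000.0
    out["display_time_ms"] = out["time_rel_ms"] - display_shift_ms
    return out


def accuracy_over_time(aligned: pd.DataFrame, bin_ms: float = 288.0) -> pd.DataFrame:
    """Top-1 accuracy per aligned time bin and source; empty bins are omitted.

    Returns columns ``time_rel_ms`` (bin center), ``source``,
    ``accuracy`` (fraction in [0, 1]) and ``n``.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    df = aligned.copy()
    df["_bin"] = np.floor(df["time_rel_ms"] / bin_ms).astype(int)
    df["_correct"] = (df["pred_label"] == df["true_label"]).astype(float)
    grouped = (
        df.groupby(["source", "_bin"])
        .agg(accuracy=("_correct", "mean"), n=("_correct", "size"))
        .reset_index()
    )
    grouped["time_rel_ms"] = (grouped["_bin"] + 0.5) * bin_ms
    return grouped[["time_rel_ms", "source", "accuracy", "n"]].sort_values(
        ["source", "time_rel_ms"], ignore_index=True
    )


def _phase_column(row) -> str:
    if row["phase"] != "rest":
        return row["phase"]
    return "rest_pre" if row["time_rel_ms"] < 0 else "rest_post"


def per_phase_accuracy(aligned: pd.DataFrame) -> pd.DataFrame:
    """Top-1 accuracy (percent) per source and phase column, plus weighted total.

    Rest windows are split into the pre-reach and post-return columns by
    their aligned time (before/after grasp onset).  A phase column with
    no windows is NaN and excluded from the total, which therefore
    equals the overall window accuracy.
    """
    df = aligned.copy()
    df["_col"] = df.apply(_phase_column, axis=1)
    df["_correct"] = (df["pred_label"] == df["true_label"]).astype(float)
    sources = sorted(df["source"].unique())
    table = pd.DataFrame(index=sources, columns=list(PHASE_COLUMNS), dtype=float)
    for src in sources:
        sub = df[df["source"] == src]
        for col in PHASE_COLUMNS[:-1]:
            vals = sub.loc[sub["_col"] == col, "_correct"]
            table.loc[src, col] = 100.0 * vals.mean() if len(vals) else np.nan
        table.loc[src, "total"] = 100.0 * sub["_correct"].mean()
    table.index.name = "source"
    return table


def random_baseline(n_classes: int) -> float:
    """Chance-level top-1 accuracy in percent: 100 / n_classes."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 100.0 / n_classes
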