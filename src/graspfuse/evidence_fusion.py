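"""Bayesian product fusion of EMG and visual grasp evidence.

Each modality supplies a stream of posterior probability vectors over the
13 grasp classes: ``P(L|M)`` from the EMG gesture classifier and
``P(L|V)`` from the visual detector's gaze-selected bounding box.  Under
a uniform class prior and conditionally independent evidence, the
maximum-a-posteriori grasp type maximizes the elementwise product
``P(L=l|M) P(L=l|V)``; this module implements that product rule, the
gaze-based box selection, stream alignment across the two sampling rates
(EMG windows at roughly 3.5 Hz, vision frames at 60 Hz), the argmax
decision, and a causal majority-vote smoother over recent decisions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_GRASP_CLASSES",
    "EvidenceStream",
    "GazeSample",
    "DetectionBox",
    "FusedDecisionSeries",
    "select_box_by_gaze",
    "align_streams",
    "fuse_evidence",
    "decide",
    "smooth_decisions",
    "fuse_streams",
]

#: Number of non-rest grasp classes in the taxonomy (labels 1..13).
N_GRASP_CLASSES = 13

_SIMPLEX_TOL = 1e-6


def _check_simplex(p: np.ndarray, tol: float = _SIMPLEX_TOL) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("probability vector must be 1-D")
    if np.any(p < -tol) or abs(p.sum() - 1.0) > max(tol, 1e-9 * p.size):
        raise ValueError("probabilities must be non-negative and sum to 1")
    return np.clip(p, 0.0, None)


@dataclass
class EvidenceStream:
    """Time-stamped posterior vectors over grasp classes from one modality.

    ``modality`` is ``"M"`` (muscle/EMG) or ``"V"`` (vision); ``t_s`` is
    strictly increasing; each row of ``probs`` lies on the simplex.
    """

    modality: str
    t_s: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.modality not in ("M", "V"):
            raise ValueError("modality must be 'M' or 'V'")
        if self.t_s.ndim != 1 or self.probs.ndim != 2:
            raise ValueError("t_s must be 1-D and probs 2-D")
        if len(self.t_s) != len(self.probs):
            raise ValueError("timestamp / probability length mismatch")
        if len(self.t_s) and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        sums = self.probs.sum(axis=1)
        if np.any(self.probs < -_SIMPLEX_TOL) or np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each probability vector must lie on the simplex")

    def __len__(self) -> int:
        return len(self.t_s)


@dataclass(frozen=True)
class GazeSample:
    t_s: float
    x: float
    y: float


@dataclass
class DetectionBox:
    """One detected object: pixel bounding box + grasp-class probabilities."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    probs: np.ndarray
    is_true_object: bool = False

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("box must have positive extent")
        self.probs = _check_simplex(self.probs)

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass
class FusedDecisionSeries:
    """Per-timestamp fused vectors, argmax decisions and smoothed decisions."""

    t_s: np.ndarray
    fused: np.ndarray
    decisions: np.ndarray
    smoothed: np.ndarray


def select_box_by_gaze(boxes: list[DetectionBox], gaze_xy: tuple[float, float]) -> int | None:
    """Index of the box the user is looking at, or ``None`` if no boxes.

    If the gaze point falls inside exactly one box that box wins;
    otherwise the box whose center is nearest the gaze point wins, ties
    going to the smallest index.
    """
    if not boxes:
        return None
    x, y = float(gaze_xy[0]), float(gaze_xy[1])
    inside = [i for i, b in enumerate(boxes) if b.contains(x, y)]
    if len(inside) == 1:
        return inside[0]
    centers = np.array([b.center() for b in boxes])
    d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
    return int(np.argmin(d2))  # argmin takes the first (smallest index) on ties


def align_streams(
    emg: EvidenceStream, vis: EvidenceStream, tolerance_s: float = 0.05
) -> list[tuple[float, np.ndarray, np.ndarray | None]]:
    """Pair each EMG timestamp with the nearest vision entry.

    A vision entry further than ``tolerance_s`` away is treated as
    missing (``None`` in the vision slot); missing is a value, not an
    error.  On an exact distance tie the earlier frame wins.
    """
    if len(emg) == 0 or len(vis) == 0:
        raise ValueError("both evidence streams must be non-empty")
    pairs: list[tuple[float, np.ndarray, np.ndarray | None]] = []
    vt = vis.t_s
    for t, pm in zip(emg.t_s, emg.probs):
        j = int(np.searchsorted(vt, t))
        best, best_d = None, np.inf
        for k in (j - 1, j):  # earlier candidate first so ties keep it
            if 0 <= k < len(vt):
                d = abs(vt[k] - t)
                if d < best_d:
                    best, best_d = k, d
        pv = vis.probs[best] if best is not None and best_d <= tolerance_s else None
        pairs.append((float(t), pm, pv))
    return pairs


def fuse_evidence(
    pM: np.ndarray | None, pV: np.ndarray | None, eps: float = 1e-6
) -> np.ndarray | None:
    """Normalized elementwise product of the two posteriors.

    Inputs are floored at ``eps`` and renormalized before the product so
    a hard zero in one modality cannot permanently veto a class.  A
    missing modality is replaced by the uniform vector, which is the
    multiplicative identity after renormalization, so fusion degrades
    gracefully to the available modality.  Returns ``None`` when both
    modalities are missing.
    """
    if pM is None and pV is None:
        return None
    vecs = []
    size = len(pM) if pM is not None else len(pV)  # type: ignore[arg-type]
    for p in (pM, pV):
        if p is None:
            vecs.append(np.full(size, 1.0 / size))
        else:
            p = np.clip(np.asarray(p, dtype=float), eps, None)
            vecs.append(p / p.sum())
    prod = vecs[0] * vecs[1]
    return prod / prod.sum()


def decide(fused: np.ndarray) -> int:
    """Top-1 grasp label (1-based over the 13 classes); ties -> smallest label."""
    fused = np.asarray(fused, dtype=float)
    return int(np.argmax(fused)) + 1


def smooth_decisions(labels, w: int = 5) -> np.ndarray:
    """Causal sliding-window majority vote over the last ``w`` decisions.

    Ties go to the most recently emitted label among the tied ones.
    Length is preserved; the first few outputs use the shorter available
    history.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    labels = np.asarray(labels)
    out = np.empty_like(labels)
    for i in range(len(labels)):
        window = labels[max(0, i - w + 1) : i + 1]
        counts = Counter(window.tolist())
        top = max(counts.values())
        tied = {lab for lab, c in counts.items() if c == top}
        # most recent among tied labels
        for lab in reversed(window.tolist()):
            if lab in tied:
                out[i] = lab
                break
    return out


def fuse_streams(
    emg: EvidenceStream,
    vis: EvidenceStream,
    tolerance_s: float = 0.05,
    eps: float = 1e-6,
    smooth_w: int = 5,
) -> FusedDecisionSeries:
    """Align, fuse, decide and smooth two full evidence streams."""
    pairs = align_streams(emg, vis, tolerance_s)
    t_s = np.array([t for t, _, _ in pairs])
    fused = np.array([fuse_evidence(pm, pv, eps) for _, pm, pv in pairs])
    decisions = np.array([decide(f) for f in fused])
    smoothed = smooth_decisions(decisions, smooth_w)
    return FusedDecisionSeries(t_s=t_s, fused=fused, decisions=decisions, smoothed=smoothed)
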