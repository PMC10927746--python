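"""Greedy Gaussian Segmentation (GGS) of multichannel EMG trials.

A trial is modeled as a sequence of segments, each an independent
multivariate Gaussian with its own mean and covariance.  Segmenting with
K breakpoints is a maximum-likelihood problem over breakpoint positions;
up to partition-independent constants the per-segment contribution is

    psi(start, end) = -(T/2) * log det(S + (lambda/T) * I)

where ``T = end - start``, ``S`` is the empirical covariance of the
segment (about the estimated mean, or about zero when ``zero_mean``),
and ``lambda >= 0`` regularizes the covariance of short segments.

``ggs_fit`` maximizes the total score greedily: breakpoints are inserted
one at a time (each insertion is the best single split of any current
segment, found by exhaustive scan), then all breakpoints are re-adjusted
between their neighbours until none moves.  ``exhaustive_segment`` is a
small-instance brute-force oracle over all admissible breakpoint tuples,
used to validate the greedy search.

Segmentation runs on raw (unfiltered, unnormalized) trials; a
reach-to-grasp trial with K=3 yields four segments tagged positionally
as reach, grasp, return, rest.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PHASES",
    "GgsConfig",
    "SegmentStats",
    "Segmentation",
    "segment_score",
    "ggs_fit",
    "exhaustive_segment",
    "assign_phases",
]

PHASES = ("reach", "grasp", "return", "rest")

NEG_INF = float("-inf")


@dataclass
class GgsConfig:
    """Segmentation hyper-parameters.

    ``lambda_reg=None`` resolves at fit time to 0.1 times the mean
    per-channel variance of the whole series, keeping the regularizer
    unit-free.  ``min_segment_samples`` must be at least C+1 when
    ``lambda_reg`` is exactly 0 (else covariances are always singular).
    ``split_stride > 1`` scans every stride-th candidate position and
    then refines around the best coarse hit at stride 1.
    """

    n_breakpoints: int = 3
    lambda_reg: float | None = None
    min_segment_samples: int = 50
    max_adjust_sweeps: int = 20
    zero_mean: bool = False
    split_stride: int = 1

    def __post_init__(self) -> None:
        if self.n_breakpoints < 0:
            raise ValueError("n_breakpoints must be >= 0")
        if self.lambda_reg is not None and self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.min_segment_samples < 1:
            raise ValueError("min_segment_samples must be >= 1")
        if self.split_stride < 1:
            raise ValueError("split_stride must be >= 1")


@dataclass
class SegmentStats:
    """Fitted Gaussian statistics of one segment [start, end)."""

    start: int
    end: int
    mean: np.ndarray
    cov: np.ndarray
    score: float

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class Segmentation:
    """Ordered breakpoints, per-segment stats, and the total objective."""

    breakpoints: tuple[int, ...]
    segments: list[SegmentStats]
    objective: float
    phase_tags: tuple[str, ...] | None = None

    def phase_of_sample(self, i: int) -> str:
        if self.phase_tags is None:
            raise ValueError("segmentation has no phase tags; call assign_phases")
        for seg, tag in zip(self.segments, self.phase_tags):
            if seg.start <= i < seg.end:
                return tag
        raise IndexError(f"sample {i} outside the segmented span")

    def grasp_onset_sample(self) -> int:
        if self.phase_tags is None:
            raise ValueError("segmentation has no phase tags; call assign_phases")
        return self.segments[self.phase_tags.index("grasp")].start


class _Prefix:
    """Cumulative first and second moments for O(1) segment statistics."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a C x N matrix")
        self.c, self.n = data.shape
        x = data.T  # N x C
        self.s1 = np.concatenate([np.zeros((1, self.c)), np.cumsum(x, axis=0)])
        outer = np.einsum("nc,nd->ncd", x, x)
        self.s2 = np.concatenate([np.zeros((1, self.c, self.c)), np.cumsum(outer, axis=0)])

    def scores(
        self, starts: np.ndarray, ends: np.ndarray, lam: float, zero_mean: bool
    ) -> np.ndarray:
        """Vectorized psi for an array of (start, end) segments."""
        starts = np.asarray(starts, dtype=int)
        ends = np.asarray(ends, dtype=int)
        t = (ends - starts).astype(float)
        s = (self.s2[ends] - self.s2[starts]) / t[:, None, None]
        if not zero_mean:
            mu = (self.s1[ends] - self.s1[starts]) / t[:, None]
            s = s - mu[:, :, None] * mu[:, None, :]
        s = 0.5 * (s + np.transpose(s, (0, 2, 1)))  # symmetrize
        s = s + (lam / t)[:, None, None] * np.eye(self.c)
        sign, logdet = np.linalg.slogdet(s)
        psi = -0.5 * t * logdet
        psi[sign <= 0] = NEG_INF
        return psi

    def score(self, start: int, end: int, lam: float, zero_mean: bool) -> float:
        return float(self.scores(np.array([start]), np.array([end]), lam, zero_mean)[0])


def segment_score(
    data: np.ndarray, start: int, end: int, lam: float = 0.0, zero_mean: bool = False
) -> float:
    """psi(start, end) for one segment; larger is better.

    Returns ``-inf`` (never raises) when ``lam == 0`` and the empirical
    covariance is singular, e.g. on a constant segment.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if end - start < 1:
        raise ValueError("segment must contain at least one sample")
    seg = data[:, start:end]
    t = seg.shape[1]
    if zero_mean:
        s = seg @ seg.T / t
    else:
        mu = seg.mean(axis=1, keepdims=True)
        s = (seg - mu) @ (seg - mu).T / t
    s = 0.5 * (s + s.T) + (lam / t) * np.eye(data.shape[0])
    sign, logdet = np.linalg.slogdet(s)
    if sign <= 0:
        return NEG_INF
    return -0.5 * t * logdet


def _resolve_lambda(data: np.ndarray, cfg: GgsConfig) -> float:
    if cfg.lambda_reg is not None:
        return float(cfg.lambda_reg)
    return 0.1 * float(np.var(data, axis=1).mean())


def _validate(data: np.ndarray, cfg: GgsConfig, lam: float, k: int) -> None:
    c, n = data.shape
    if lam == 0.0 and cfg.min_segment_samples < c + 1:
        raise ValueError(
            "min_segment_samples must be >= C+1 when lambda_reg == 0"
        )
    if n < (k + 1) * cfg.min_segment_samples:
        raise ValueError(
            f"series of {n} samples cannot hold {k + 1} segments of >= "
            f"{cfg.min_segment_samples} samples"
        )


def _candidate_splits(start: int, end: int, min_len: int, stride: int) -> np.ndarray:
    lo, hi = start + min_len, end - min_len
    if hi < lo:
        return np.empty(0, dtype=int)
    ts = np.arange(lo, hi + 1, stride)
    if ts[-1] != hi:
        ts = np.append(ts, hi)
    return ts


def _best_split(
    prefix: _Prefix, start: int, end: int, lam: float, zero_mean: bool,
    min_len: int, stride: int,
) -> tuple[int, float] | None:
    """Best position to split [start, end); returns (t, combined score)."""
    ts = _candidate_splits(start, end, min_len, stride)
    if ts.size == 0:
        return None
    total = prefix.scores(np.full_like(ts, start), ts, lam, zero_mean) + prefix.scores(
        ts, np.full_like(ts, end), lam, zero_mean
    )
    j = int(np.argmax(total))  # first max -> smallest index on ties
    best_t, best_v = int(ts[j]), float(total[j])
    if stride > 1:  # refine around the coarse optimum
        lo = max(start + min_len, best_t - stride + 1)
        hi = min(end - min_len, best_t + stride - 1)
        fine = np.arange(lo, hi + 1)
        tot = prefix.scores(np.full_like(fine, start), fine, lam, zero_mean) + prefix.scores(
            fine, np.full_like(fine, end), lam, zero_mean
        )
        j = int(np.argmax(tot))
        best_t, best_v = int(fine[j]), float(tot[j])
    return best_t, best_v


def _build_segmentation(
    data: np.ndarray, prefix: _Prefix, bkps: list[int], lam: float, zero_mean: bool
) -> Segmentation:
    edges = [0, *sorted(bkps), data.shape[1]]
    segments = []
    total = 0.0
    for s, e in itertools.pairwise(edges):
        seg = data[:, s:e]
        t = e - s
        mu = np.zeros(data.shape[0]) if zero_mean else seg.mean(axis=1)
        dev = seg - mu[:, None]
        cov = dev @ dev.T / t
        score = prefix.score(s, e, lam, zero_mean)
        segments.append(SegmentStats(start=s, end=e, mean=mu, cov=cov, score=score))
        total += score
    return Segmentation(
        breakpoints=tuple(sorted(bkps)), segments=segments, objective=total
    )


def ggs_fit(data: np.ndarray, cfg: GgsConfig | None = None) -> Segmentation:
    """Greedy insertion plus adjustment sweeps.

    Each insertion exhaustively scans every admissible split of every
    current segment and takes the largest total-score gain (ties toward
    the smallest index).  Adjustment then re-optimizes each breakpoint
    between its neighbours, sweeping until no breakpoint moves or
    ``max_adjust_sweeps`` is reached; the objective never decreases
    during adjustment by construction.
    """
    if cfg is None:
        cfg = GgsConfig()
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    lam = _resolve_lambda(data, cfg)
    _validate(data, cfg, lam, cfg.n_breakpoints)
    n = data.shape[1]
    prefix = _Prefix(data)
    zm, ml, stride = cfg.zero_mean, cfg.min_segment_samples, cfg.split_stride

    bkps: list[int] = []
    for _ in range(cfg.n_breakpoints):
        edges = [0, *bkps, n]
        best = None  # (gain, t)
        for s, e in itertools.pairwise(edges):
            found = _best_split(prefix, s, e, lam, zm, ml, stride)
            if found is None:
                continue
            t, combined = found
            gain = combined - prefix.score(s, e, lam, zm)
            if best is None or gain > best[0]:
                best = (gain, t)
        if best is None:
            raise ValueError("no admissible split; relax min_segment_samples")
        bkps = sorted([*bkps, best[1]])

    for _ in range(cfg.max_adjust_sweeps):
        moved = False
        for i in range(len(bkps)):
            left = bkps[i - 1] if i > 0 else 0
            right = bkps[i + 1] if i + 1 < len(bkps) else n
            found = _best_split(prefix, left, right, lam, zm, ml, stride=1)
            if found is not None and found[0] != bkps[i]:
                cur = prefix.score(left, bkps[i], lam, zm) + prefix.score(
                    bkps[i], right, lam, zm
                )
                if found[1] > cur:
                    bkps[i] = found[0]
                    moved = True
        if not moved:
            break

    return _build_segmentation(data, prefix, bkps, lam, zm)


def exhaustive_segment(
    data: np.ndarray, cfg: GgsConfig | None = None, max_tuples: int = 2_000_000
) -> Segmentation:
    """Brute-force global optimum over all admissible breakpoint tuples.

    Only feasible on small instances; refuses (``ValueError``) when the
    number of tuples exceeds ``max_tuples``.
    """
    if cfg is None:
        cfg = GgsConfig()
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    lam = _resolve_lambda(data, cfg)
    _validate(data, cfg, lam, cfg.n_breakpoints)
    n = data.shape[1]
    k, ml = cfg.n_breakpoints, cfg.min_segment_samples
    prefix = _Prefix(data)

    if k == 0:
        return _build_segmentation(data, prefix, [], lam, cfg.zero_mean)

    positions = list(range(ml, n - ml + 1))
    n_tuples = math.comb(len(positions), k)
    if n_tuples > max_tuples:
        raise ValueError(
            f"{n_tuples} breakpoint tuples exceed the cap of {max_tuples}"
        )

    # Pairwise segment scores between admissible boundaries (incl. 0 and N).
    bounds = [0, *positions, n]
    idx = {b: i for i, b in enumerate(bounds)}
    pair_scores = np.full((len(bounds), len(bounds)), np.nan)
    starts, ends = [], []
    for i, s in enumerate(bounds):
        for j, e in enumerate(bounds):
            if e - s >= ml:
                starts.append(s)
                ends.append(e)
    vals = prefix.scores(np.array(starts), np.array(ends), lam, cfg.zero_mean)
    for s, e, v in zip(starts, ends, vals):
        pair_scores[idx[s], idx[e]] = v

    best_phi, best_bkps = NEG_INF, None
    for combo in itertools.combinations(positions, k):
        edges = [0, *combo, n]
        if any(e - s < ml for s, e in itertools.pairwise(edges)):
            continue
        phi = sum(pair_scores[idx[s], idx[e]] for s, e in itertools.pairwise(edges))
        if phi > best_phi:
            best_phi, best_bkps = phi, list(combo)
    if best_bkps is None:
        raise ValueError("no admissible breakpoint tuple")
    return _build_segmentation(data, prefix, best_bkps, lam, cfg.zero_mean)


def segmentation_from_breakpoints(
    data: np.ndarray,
    breakpoints,
    lam: float = 0.0,
    zero_mean: bool = False,
) -> Segmentation:
    """Segmentation with fixed (e.g. ground-truth) breakpoints.

    Scores and per-segment Gaussian statistics are computed exactly as in
    ``ggs_fit``; no search is performed.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    bkps = sorted(int(b) for b in breakpoints)
    n = data.shape[1]
    if any(not 0 < b < n for b in bkps) or len(set(bkps)) != len(bkps):
        raise ValueError("breakpoints must be distinct and inside (0, N)")
    return _build_segmentation(data, _Prefix(data), bkps, lam, zero_mean)


def assign_phases(seg: Segmentation) -> Segmentation:
    """Tag the four segments positionally as reach, grasp, return, rest."""
    if len(seg.segments) != len(PHASES):
        raise ValueError(
            f"phase tagging needs exactly {len(PHASES)} segments, got {len(seg.segments)}"
        )
    return replace(seg, phase_tags=PHASES)
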