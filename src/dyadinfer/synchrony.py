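"""Gaze-synchrony pipeline: paired pupil-position streams to per-trial
synchrony indices and the gamma weight.

The pipeline mirrors how paired headset recordings are processed: drop
missing samples, resample both streams onto a shared 0.02 s grid over their
temporal overlap, differentiate into per-axis velocities, then compare the
two velocity series with (a) dynamic time warping — temporally elastic shape
similarity — and (b) zero-lag Pearson correlation — instantaneous alignment.
Raw DTW distances are negated and min-max normalized across a session's
trials so the most synchronous trial scores 1; the per-trial model weight is
gamma_t = gamma0 * normalized index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GazeSeries",
    "VelocitySeries",
    "SynchronyIndex",
    "clean_and_align",
    "compute_velocity",
    "dtw_distance",
    "normalize_sync",
    "gamma_weight",
    "cross_correlation",
    "trial_synchrony",
    "session_synchrony",
]

#: resampling interval for temporally linking paired streams (seconds)
GRID_INTERVAL = 0.02


@dataclass
class GazeSeries:
    """Timestamped 3-D pupil-position samples for one participant/trial."""

    participant_id: str
    trial_id: int
    t: np.ndarray            # seconds, strictly increasing
    xyz: np.ndarray          # shape (n, 3), device units
    phase: str = "object_presentation"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if len(self.t) != len(self.xyz):
            raise ValueError("t and xyz must have the same length")

    def __len__(self) -> int:
        return len(self.t)

    def dropna(self) -> "GazeSeries":
        """Remove samples with any missing coordinate or timestamp."""
        keep = np.isfinite(self.t) & np.all(np.isfinite(self.xyz), axis=1)
        return GazeSeries(self.participant_id, self.trial_id,
                          self.t[keep], self.xyz[keep], self.phase)


@dataclass
class VelocitySeries:
    """Per-axis instantaneous velocities from successive-sample differences."""

    t: np.ndarray            # midpoint convention: timestamp of the later sample
    v: np.ndarray            # shape (n - 1, 3)


@dataclass
class SynchronyIndex:
    """Per-trial synchrony summary."""

    trial_id: int
    dtw_raw: float           # negated DTW distance (higher = more similar)
    dtw_norm: float          # min-max normalized to [0, 1] within the session
    xcorr: float             # zero-lag correlation, NaN when undefined
    gamma_t: float           # gamma0 * dtw_norm


def clean_and_align(
    a: GazeSeries,
    b: GazeSeries,
    grid_interval: float = GRID_INTERVAL,
) -> tuple[GazeSeries, GazeSeries]:
    """Drop missing samples and linearly resample both streams onto a shared
    grid spanning their temporal overlap.

    Raises ``ValueError`` when either stream is empty after cleaning or the
    two streams do not overlap in time.
    """
    a = a.dropna()
    b = b.dropna()
    for s in (a, b):
        if len(s) < 2:
            raise ValueError(f"series {s.participant_id!r} has <2 valid samples")
        if np.any(np.diff(s.t) <= 0):
            raise ValueError(f"series {s.participant_id!r} has non-increasing timestamps")
    start = max(a.t[0], b.t[0])
    stop = min(a.t[-1], b.t[-1])
    if stop <= start:
        raise ValueError("gaze series have no temporal overlap")
    grid = np.arange(start, stop + 0.5 * grid_interval, grid_interval)
    grid = grid[grid <= stop]

    def resample(s: GazeSeries) -> GazeSeries:
        xyz = np.column_stack([np.interp(grid, s.t, s.xyz[:, k]) for k in range(3)])
        return GazeSeries(s.participant_id, s.trial_id, grid.copy(), xyz, s.phase)

    return resample(a), resample(b)


def compute_velocity(s: GazeSeries) -> VelocitySeries:
    """First differences of position over time: v_k = (x_{k+1}-x_k)/(t_{k+1}-t_k)."""
    if len(s) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    dt = np.diff(s.t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    v = np.diff(s.xyz, axis=0) / dt[:, None]
    return VelocitySeries(t=s.t[1:].copy(), v=v)


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Dynamic-time-warping distance between two 1-D series.

    Absolute-difference local cost, steps (i-1,j), (i,j-1), (i-1,j-1),
    boundary-anchored path, no warping-window constraint.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("dtw_distance requires non-empty inputs")
    n, m = len(x), len(y)
    cost = np.abs(x[:, None] - y[None, :])
    # row-by-row accumulation keeps memory at O(m)
    prev = np.empty(m)
    prev[0] = cost[0, 0]
    for j in range(1, m):
        prev[j] = prev[j - 1] + cost[0, j]
    cur = np.empty(m)
    for i in range(1, n):
        cur[0] = prev[0] + cost[i, 0]
        row = cost[i]
        for j in range(1, m):
            cur[j] = row[j] + min(prev[j], cur[j - 1], prev[j - 1])
        prev, cur = cur, prev
    return float(prev[m - 1])


def normalize_sync(distances) -> np.ndarray:
    """Map per-trial DTW distances to the [0, 1] synchrony scale.

    Distances are negated (smaller distance = more synchronous) then min-max
    scaled across the trial set, so the smallest distance maps to 1 and the
    largest to 0.  A degenerate range (all distances equal, or a single
    trial) yields 0.5 everywhere, asserting neither extreme.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("normalize_sync requires at least one distance")
    raw = -d
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full(d.shape, 0.5)
    return (raw - lo) / (hi - lo)


def gamma_weight(dtw_norm: float, gamma0: float) -> float:
    """Per-trial synchrony weight: gamma_t = gamma0 * dtw_norm, in [0, gamma0]."""
    if not 0.0 <= gamma0 <= 1.0:
        raise ValueError("gamma0 must lie in [0, 1]")
    if not 0.0 <= dtw_norm <= 1.0:
        raise ValueError("dtw_norm must lie in [0, 1]")
    return gamma0 * dtw_norm


def cross_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag Pearson correlation of two equal-length series.

    Returns NaN when either series is constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def trial_synchrony(
    a: GazeSeries,
    b: GazeSeries,
    grid_interval: float = GRID_INTERVAL,
) -> tuple[float, float]:
    """One trial's (mean per-axis DTW distance, mean per-axis zero-lag r).

    The two streams are cleaned, aligned, differentiated, and compared per
    velocity axis; axis values are averaged into single per-trial numbers.
    Axes with undefined correlation are skipped in the correlation mean
    (NaN if all three are undefined).
    """
    aa, bb = clean_and_align(a, b, grid_interval)
    va, vb = compute_velocity(aa), compute_velocity(bb)
    dists = [dtw_distance(va.v[:, k], vb.v[:, k]) for k in range(3)]
    rs = [cross_correlation(va.v[:, k], vb.v[:, k]) for k in range(3)]
    rs = [r for r in rs if np.isfinite(r)]
    xcorr = float(np.mean(rs)) if rs else float("nan")
    return float(np.mean(dists)), xcorr


def session_synchrony(
    pairs: dict[int, tuple[GazeSeries, GazeSeries]],
    gamma0: float,
    grid_interval: float = GRID_INTERVAL,
) -> list[SynchronyIndex]:
    """Full per-session pipeline: per-trial DTW + correlation, session-wide
    min-max normalization, and gamma weights.

    ``pairs`` maps trial_id to that trial's two gaze streams.  Normalization
    is over all trials of this session so dtw_norm is comparable within it.
    """
    trial_ids = sorted(pairs)
    dists, xcorrs = [], []
    for tid in trial_ids:
        a, b = pairs[tid]
        d, r = trial_synchrony(a, b, grid_interval)
        dists.append(d)
        xcorrs.append(r)
    norms = normalize_sync(dists)
    return [
        SynchronyIndex(
            trial_id=tid,
            dtw_raw=-d,
            dtw_norm=float(nn),
            xcorr=r,
            gamma_t=gamma_weight(float(nn), gamma0),
        )
        for tid, d, nn, r in zip(trial_ids, dists, norms, xcorrs)
    ]
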