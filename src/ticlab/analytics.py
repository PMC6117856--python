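"""Per-session summary metrics and point-process timing analyses.

Three layers:

* :func:`compute_metrics` — descriptive per-session statistics (tic counts
  and rates, longest tic-free interval, disjoint tic-free window counts,
  reward counts, inter-tic intervals).
* :func:`fano_curve` — variance-to-mean (Fano factor) scaling of tic counts
  across window sizes, with a log-log slope, a renewal-bootstrap confidence
  interval, and an inter-interval-shuffle surrogate p-value.  A slope near
  zero is Poisson-like; a positive slope indicates fractal (long-range
  dependent) clustering.
* :func:`reward_timing_test` — conditional tic rate as a function of lag
  since the most recent reward, tested against a circular-shift null that
  preserves the internal structure of the tic stream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .session import SessionRecord

__all__ = [
    "SessionMetrics",
    "FanoResult",
    "RewardTimingResult",
    "event_times_s",
    "compute_metrics",
    "fano_curve",
    "reward_timing_test",
    "reward_timing_test_arrays",
    "benjamini_hochberg",
]

MIN_FANO_EVENTS = 30
MIN_FANO_WINDOW_SIZES = 4


@dataclass(frozen=True)
class SessionMetrics:
    duration_s: float
    tic_count: int
    mean_tic_frequency: float  # tics per minute
    longest_tic_free_s: float
    n_tic_free_windows: int
    window_s: float
    reward_count: int
    personal_record_s: float
    iti_list: tuple[float, ...]

    def to_kv(self) -> str:
        parts = [
            f"duration_s={self.duration_s:g}",
            f"tic_count={self.tic_count}",
            f"mean_tic_frequency={self.mean_tic_frequency:g}",
            f"longest_tic_free_s={self.longest_tic_free_s:g}",
            f"n_tic_free_windows={self.n_tic_free_windows}",
            f"window_s={self.window_s:g}",
            f"reward_count={self.reward_count}",
            f"personal_record_s={self.personal_record_s:g}",
        ]
        return ";".join(parts)

    def to_json(self) -> str:
        doc = asdict(self)
        doc["iti_list"] = list(self.iti_list)
        doc["schema_version"] = 1
        return json.dumps(doc, indent=2, sort_keys=True)


def event_times_s(record: SessionRecord, kind: str) -> np.ndarray:
    """Times (seconds since session start) of all events of one kind."""
    return np.array(
        [(ev.timestamp_ms - record.start_ms) / 1000.0 for ev in record.events if ev.kind == kind],
        dtype=float,
    )


def _gaps(tics: np.ndarray, duration: float) -> np.ndarray:
    """Tic-free segment lengths: start->first tic, between tics, last tic->end."""
    bounds = np.concatenate(([0.0], tics, [duration]))
    return np.diff(bounds)


def compute_metrics(record: SessionRecord, window_s: float = 10.0) -> SessionMetrics:
    """Summarize a closed session.

    Tic-free windows are disjoint, left-aligned within each tic-free
    segment, and restart after every tic: a segment of length ``g``
    contributes ``floor(g / window_s)`` windows.
    """
    if record.end_ms is None:
        raise ValueError("metrics require a closed session record")
    duration = (record.end_ms - record.start_ms) / 1000.0
    if duration <= 0:
        raise ValueError("zero-duration session")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    tics = event_times_s(record, "tic")
    gaps = _gaps(tics, duration)
    longest = float(gaps.max())
    # tolerance absorbs float noise from ms quantization at exact multiples
    n_windows = int(np.floor(gaps / window_s + 1e-9).sum())
    itis = np.diff(tics)
    return SessionMetrics(
        duration_s=duration,
        tic_count=int(tics.size),
        mean_tic_frequency=60.0 * tics.size / duration,
        longest_tic_free_s=longest,
        n_tic_free_windows=n_windows,
        window_s=window_s,
        reward_count=int(sum(1 for ev in record.events if ev.kind == "reward")),
        personal_record_s=longest,
        iti_list=tuple(float(x) for x in itis),
    )


# ---------------------------------------------------------------------------
# Fano-factor scaling


@dataclass(frozen=True)
class FanoResult:
    ok: bool
    reason: str
    window_sizes_s: tuple[float, ...] = ()
    fano_factors: tuple[float, ...] = ()
    loglog_slope: float = math.nan
    slope_ci: tuple[float, float] = (math.nan, math.nan)
    surrogate_p: float = math.nan
    n_events: int = 0

    def to_json(self) -> str:
        doc = asdict(self)
        doc["schema_version"] = 1
        return json.dumps(doc, indent=2, sort_keys=True)


def _fano_factors(times: np.ndarray, duration: float, window_sizes: np.ndarray) -> np.ndarray:
    out = np.empty(window_sizes.size)
    for i, T in enumerate(window_sizes):
        n_bins = int(duration // T)
        counts = np.histogram(times, bins=n_bins, range=(0.0, n_bins * T))[0]
        mean = counts.mean()
        out[i] = counts.var(ddof=1) / mean if mean > 0 else math.nan
    return out


def _loglog_slope(window_sizes: np.ndarray, fano: np.ndarray) -> float:
    mask = np.isfinite(fano) & (fano > 0)
    if mask.sum() < 2:
        return math.nan
    return float(np.polyfit(np.log(window_sizes[mask]), np.log(fano[mask]), 1)[0])


def fano_curve(
    event_times,
    duration_s: float,
    window_sizes=(5.0, 10.0, 20.0, 40.0, 80.0),
    n_surrogates: int = 999,
    n_bootstrap: int = 200,
    rng: np.random.Generator | None = None,
) -> FanoResult:
    """Fano factor (count variance / count mean) across window sizes.

    The log-log slope is estimated by least squares; its confidence interval
    comes from resampling inter-event intervals with replacement (renewal
    bootstrap).  ``surrogate_p`` is the fraction of interval-shuffled
    surrogates with a slope at least as large as observed, which probes
    temporal ordering of the intervals rather than their marginal
    distribution.  Returns an explicit not-ok result when fewer than
    ``MIN_FANO_EVENTS`` events are available.
    """
    rng = rng or np.random.default_rng()
    times = np.sort(np.asarray(event_times, dtype=float))
    window_sizes = np.sort(np.asarray(window_sizes, dtype=float))
    if times.size < MIN_FANO_EVENTS:
        return FanoResult(False, f"insufficient events ({times.size} < {MIN_FANO_EVENTS})",
                          n_events=int(times.size))
    if window_sizes.size < MIN_FANO_WINDOW_SIZES:
        return FanoResult(False, f"need >= {MIN_FANO_WINDOW_SIZES} window sizes",
                          n_events=int(times.size))
    if window_sizes.max() > duration_s / 2:
        return FanoResult(False, "largest window exceeds half the session duration",
                          n_events=int(times.size))

    fano = _fano_factors(times, duration_s, window_sizes)
    slope = _loglog_slope(window_sizes, fano)

    intervals = np.diff(np.concatenate(([0.0], times)))

    def rebuild(iv: np.ndarray) -> np.ndarray:
        return np.cumsum(iv)

    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        iv = rng.choice(intervals, size=intervals.size, replace=True)
        t = rebuild(iv)
        boot[b] = _loglog_slope(window_sizes, _fano_factors(t, duration_s, window_sizes))
    boot = boot[np.isfinite(boot)]
    if boot.size:
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    else:
        ci = (math.nan, math.nan)

    exceed = 0
    for _ in range(n_surrogates):
        iv = rng.permutation(intervals)
        s = _loglog_slope(window_sizes, _fano_factors(rebuild(iv), duration_s, window_sizes))
        if np.isfinite(s) and s >= slope:
            exceed += 1
    p = (1 + exceed) / (n_surrogates + 1)

    return FanoResult(
        ok=True,
        reason="",
        window_sizes_s=tuple(float(x) for x in window_sizes),
        fano_factors=tuple(float(x) for x in fano),
        loglog_slope=slope,
        slope_ci=ci,
        surrogate_p=float(p),
        n_events=int(times.size),
    )


# ---------------------------------------------------------------------------
# Reward-timing dependence


@dataclass(frozen=True)
class RewardTimingResult:
    lag_bins_s: tuple[float, ...]  # edges, length n_bins + 1
    tic_counts: tuple[int, ...]
    occupancy_s: tuple[float, ...]
    conditional_tic_rate: tuple[float, ...]  # tics/minute in each lag bin
    session_mean_rate: float  # tics/minute
    permutation_p: tuple[float, ...]
    bh_reject: tuple[bool, ...]
    n_permutations: int

    def to_json(self) -> str:
        doc = asdict(self)
        doc["schema_version"] = 1
        return json.dumps(doc, indent=2, sort_keys=True)


def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure; returns a boolean reject mask."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject


def _lag_since_reward(tics: np.ndarray, rewards: np.ndarray) -> np.ndarray:
    """Lag of each tic since the most recent reward; NaN before any reward."""
    idx = np.searchsorted(rewards, tics, side="right") - 1
    lags = np.full(tics.shape, np.nan)
    valid = idx >= 0
    lags[valid] = tics[valid] - rewards[idx[valid]]
    return lags


def _bin_occupancy(rewards: np.ndarray, duration: float, edges: np.ndarray) -> np.ndarray:
    """Total session time spent at each lag-since-last-reward bin."""
    # time after reward r at lag l exists while l < (next reward or end) - r
    next_bound = np.append(rewards[1:], duration)
    horizon = np.clip(next_bound - rewards, 0.0, None)
    occ = np.zeros(edges.size - 1)
    for j in range(edges.size - 1):
        lo, hi = edges[j], edges[j + 1]
        occ[j] = np.clip(np.minimum(horizon, hi) - lo, 0.0, None).sum()
    return occ


def reward_timing_test_arrays(
    tic_times,
    reward_times,
    duration_s: float,
    lag_bins=(0.0, 5.0, 10.0, 20.0),
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> RewardTimingResult:
    """Test whether tic timing depends on reward timing.

    For each post-reward lag bin the conditional tic rate is the number of
    tics at that lag divided by the total session time spent at that lag.
    The null distribution comes from circularly shifting the tic stream by
    uniform random offsets, which preserves inter-tic structure while
    breaking any alignment with rewards.  Per-bin one-sided p-values (rate
    elevated above null) use exchangeable random tie-breaking so they are
    exactly uniform under the null; a Benjamini-Hochberg mask across bins is
    reported alongside the raw p-values.
    """
    rng = rng or np.random.default_rng()
    tics = np.sort(np.asarray(tic_times, dtype=float))
    rewards = np.sort(np.asarray(reward_times, dtype=float))
    edges = np.asarray(lag_bins, dtype=float)
    if tics.size == 0:
        raise ValueError("no tic events: reward-timing test undefined")
    if rewards.size == 0:
        raise ValueError("no reward events: reward-timing test undefined")
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("lag_bins must be increasing edges with at least one bin")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")

    occ = _bin_occupancy(rewards, duration_s, edges)

    def bin_counts(t: np.ndarray) -> np.ndarray:
        lags = _lag_since_reward(t, rewards)
        lags = lags[np.isfinite(lags)]
        return np.histogram(lags, bins=edges)[0]

    obs_counts = bin_counts(tics)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(occ > 0, 60.0 * obs_counts / occ, np.nan)

    shifts = rng.uniform(0.0, duration_s, size=n_permutations)
    perm_counts = np.empty((n_permutations, edges.size - 1), dtype=int)
    for i, s in enumerate(shifts):
        perm_counts[i] = bin_counts(np.sort((tics + s) % duration_s))

    # random lexicographic tie-break keeps the permutation p-value exactly
    # uniform despite the discreteness of the counts
    tie = rng.random(n_permutations + 1)
    p = np.empty(edges.size - 1)
    for j in range(edges.size - 1):
        greater = (perm_counts[:, j] > obs_counts[j]) | (
            (perm_counts[:, j] == obs_counts[j]) & (tie[1:] > tie[0])
        )
        p[j] = (1 + int(greater.sum())) / (n_permutations + 1)

    reject = benjamini_hochberg(p, alpha=alpha)
    return RewardTimingResult(
        lag_bins_s=tuple(float(x) for x in edges),
        tic_counts=tuple(int(x) for x in obs_counts),
        occupancy_s=tuple(float(x) for x in occ),
        conditional_tic_rate=tuple(float(x) for x in rates),
        session_mean_rate=60.0 * tics.size / duration_s,
        permutation_p=tuple(float(x) for x in p),
        bh_reject=tuple(bool(x) for x in reject),
        n_permutations=n_permutations,
    )


def reward_timing_test(
    record: SessionRecord,
    lag_bins=(0.0, 5.0, 10.0, 20.0),
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> RewardTimingResult:
    """Record-level wrapper around :func:`reward_timing_test_arrays`."""
    if record.end_ms is None:
        raise ValueError("reward-timing test requires a closed session record")
    duration = (record.end_ms - record.start_ms) / 1000.0
    return reward_timing_test_arrays(
        event_times_s(record, "tic"),
        event_times_s(record, "reward"),
        duration,
        lag_bins=lag_bins,
        n_permutations=n_permutations,
        rng=rng,
        alpha=alpha,
    )
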