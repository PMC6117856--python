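"""Synthetic tic streams and fully simulated training sessions.

Tic generation supports three renewal processes: homogeneous Poisson,
suppressed Poisson (the hazard is multiplied by a suppression factor while
contingent reinforcement is active, i.e. in the DRO condition), and a
heavy-tailed Pareto renewal process that serves as a fractal positive
control for the analytics.  ``simulate_session`` drives the full session
engine — trainer tics, 30-second keep-alive heartbeats, and (in NCR) the
level-scaled reward schedule — and returns a closed, archivable record.
Everything is seeded: identical parameters and seed give a byte-identical
archived log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ncr import NcrConfig, next_reward_delay
from .reward_core import DroConfig
from .session import (
    SessionRecord,
    check_timeout,
    ncr_reward,
    start_session,
    trainer_event,
)

__all__ = [
    "PROCESS_KINDS",
    "TicProcessParams",
    "SuppressionEstimate",
    "simulate_tic_stream",
    "simulate_session",
    "recover_suppression",
]

PROCESS_KINDS = ("poisson", "suppressed_poisson", "pareto_renewal")


@dataclass(frozen=True)
class TicProcessParams:
    """Generative model for a synthetic tic stream.

    ``baseline_rate`` is in tics/minute.  ``suppression_factor`` multiplies
    the hazard while contingent reinforcement is active (DRO condition) and
    is ignored unless ``process_kind == "suppressed_poisson"``.
    ``pareto_alpha`` is the tail index of the fractal positive control
    (inter-tic intervals are classical Pareto, rescaled to the target mean
    rate).  The seed fully determines the stream.
    """

    baseline_rate: float = 6.0
    suppression_factor: float = 1.0
    process_kind: str = "poisson"
    pareto_alpha: float = 1.5
    duration_s: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_rate > 0:
            raise ValueError("baseline_rate must be positive")
        if not 0 < self.suppression_factor <= 1:
            raise ValueError("suppression_factor must be in (0, 1]")
        if self.process_kind not in PROCESS_KINDS:
            raise ValueError(f"process_kind must be one of {PROCESS_KINDS}")
        if not self.pareto_alpha > 1:
            raise ValueError("pareto_alpha must exceed 1 (finite mean)")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")


def simulate_tic_stream(params: TicProcessParams, condition: str = "DRO") -> np.ndarray:
    """Generate sorted tic times in seconds over ``[0, duration_s)``."""
    rng = np.random.default_rng(params.seed)
    rate_per_s = params.baseline_rate / 60.0
    if params.process_kind == "suppressed_poisson" and condition == "DRO":
        rate_per_s *= params.suppression_factor

    mean_iti = 1.0 / rate_per_s
    times: list[float] = []
    t = 0.0
    if params.process_kind in ("poisson", "suppressed_poisson"):
        draw = lambda: float(rng.exponential(mean_iti))
    else:
        # classical Pareto with scale x_m chosen so E[ITI] = mean_iti
        x_m = mean_iti * (params.pareto_alpha - 1.0) / params.pareto_alpha
        draw = lambda: float(x_m * (1.0 + rng.pareto(params.pareto_alpha)))
    while True:
        t += draw()
        if t >= params.duration_s:
            break
        times.append(t)
    return np.array(times, dtype=float)


def simulate_session(
    condition: str,
    dro_config: DroConfig | None,
    ncr_config: NcrConfig | None,
    tic_params: TicProcessParams,
    *,
    user_id: str = "user0",
    trainer_id: str = "trainer0",
    start_ms: int = 0,
    heartbeat_s: float | None = 30.0,
    masked: bool = False,
) -> SessionRecord:
    """Run one full simulated session and return the closed record.

    Heartbeats are injected every ``heartbeat_s`` seconds so the 60-second
    inactivity timeout is exercised but never tripped; pass
    ``heartbeat_s=None`` to withhold them and let the timeout close the
    session instead.  In the NCR condition rewards follow the exponential
    schedule, redrawn at the level in force when each delay is scheduled.
    """
    dro_config = dro_config or DroConfig()
    duration_ms = int(round(tic_params.duration_s * 1000))
    end_ms = start_ms + duration_ms

    record = start_session(
        user_id,
        trainer_id,
        condition,
        {(trainer_id, user_id)},
        dro_config,
        ncr_config,
        start_ms=start_ms,
        masked=masked,
        session_id=f"{user_id}-{tic_params.seed}-{start_ms}",
    )

    tic_ms = [start_ms + int(round(t * 1000)) for t in simulate_tic_stream(tic_params, condition)]
    hb_ms: list[int] = []
    if heartbeat_s is not None:
        step = int(round(heartbeat_s * 1000))
        hb_ms = list(range(start_ms + step, end_ms, step))

    ncr_rng = np.random.default_rng(ncr_config.rng_seed) if condition == "NCR" else None
    next_reward = None
    if ncr_rng is not None:
        next_reward = start_ms + int(
            round(next_reward_delay(ncr_config, record.state.level, ncr_rng) * 1000)
        )

    i_tic = i_hb = 0
    while True:
        candidates: list[tuple[int, int]] = []  # (timestamp, priority)
        if i_tic < len(tic_ms):
            candidates.append((tic_ms[i_tic], 0))
        if next_reward is not None and next_reward < end_ms:
            candidates.append((next_reward, 1))
        if i_hb < len(hb_ms):
            candidates.append((hb_ms[i_hb], 2))
        if not candidates:
            break
        ts, kind = min(candidates)
        if ts >= end_ms:
            break
        if heartbeat_s is None and ts - record.last_activity_ms >= 60_000:
            break  # the inactivity timeout fires before this event
        if kind == 0:
            trainer_event(record, "tic", ts)
            i_tic += 1
        elif kind == 1:
            ncr_reward(record, ts)
            next_reward = ts + int(
                round(next_reward_delay(ncr_config, record.state.level, ncr_rng) * 1000)
            )
        else:
            trainer_event(record, "heartbeat", ts)
            i_hb += 1

    if heartbeat_s is None:
        check_timeout(record, end_ms + 120_000)
        if record.is_open:  # trainer activity ran right up to the end
            trainer_event(record, "end", end_ms)
    else:
        trainer_event(record, "end", end_ms)
    return record


@dataclass(frozen=True)
class SuppressionEstimate:
    s_hat: float
    ci_low: float
    ci_high: float
    rate_contingent: float  # pooled tics/minute, DRO group
    rate_noncontingent: float  # pooled tics/minute, NCR group
    n_contingent: int
    n_noncontingent: int


def _pooled_rate(records: list[SessionRecord]) -> float:
    tics = sum(sum(1 for ev in r.events if ev.kind == "tic") for r in records)
    total_s = sum((r.end_ms - r.start_ms) / 1000.0 for r in records)
    return 60.0 * tics / total_s


def recover_suppression(
    records: list[SessionRecord],
    labels: list[str] | None = None,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
    ci: float = 0.95,
) -> SuppressionEstimate:
    """Estimate the suppression factor from labeled session records.

    The estimate is the ratio of pooled tic rates, contingent (DRO) over
    noncontingent (NCR); the confidence interval is a session-level
    percentile bootstrap.
    """
    rng = rng or np.random.default_rng()
    if labels is None:
        labels = [r.condition for r in records]
    if len(labels) != len(records):
        raise ValueError("labels must match records one-to-one")
    dro = [r for r, lab in zip(records, labels) if lab == "DRO"]
    ncr = [r for r, lab in zip(records, labels) if lab == "NCR"]
    if not dro or not ncr:
        raise ValueError("need at least one record in each condition group")

    r_dro = _pooled_rate(dro)
    r_ncr = _pooled_rate(ncr)
    s_hat = r_dro / r_ncr

    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        d = [dro[i] for i in rng.integers(0, len(dro), len(dro))]
        n = [ncr[i] for i in rng.integers(0, len(ncr), len(ncr))]
        denom = _pooled_rate(n)
        boot[b] = _pooled_rate(d) / denom if denom > 0 else np.nan
    boot = boot[np.isfinite(boot)]
    tail = 100 * (1 - ci) / 2
    lo, hi = np.percentile(boot, [tail, 100 - tail]) if boot.size else (np.nan, np.nan)

    return SuppressionEstimate(
        s_hat=float(s_hat),
        ci_low=float(lo),
        ci_high=float(hi),
        rate_contingent=float(r_dro),
        rate_noncontingent=float(r_ncr),
        n_contingent=len(dro),
        n_noncontingent=len(ncr),
    )
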