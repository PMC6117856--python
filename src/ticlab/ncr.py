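"""Noncontingent-reward (NCR) control scheduler.

In the masked control condition rewards arrive on a time-based schedule that
ignores tics entirely.  Inter-reward delays are exponential (memoryless, so
reward timing carries no information about tic timing) with mean
``initial_mean_interval * level``: the mean delay grows linearly with level,
mirroring the contingent engine's one-reward-per-``level``-seconds cadence.
Each reward pays ``points_per_reward_multiplier * level ** 2`` points and
runs the same level-up/coin processing as the contingent engine, so the
user-facing event stream is indistinguishable between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reward_core import DroState, EngineEvent, DroConfig, process_level_ups

__all__ = ["NcrConfig", "next_reward_delay", "apply_ncr_reward"]

# exponential draws can round to 0.0; clamp so inter-reward delays stay positive
_MIN_DELAY_S = 1e-9


@dataclass(frozen=True)
class NcrConfig:
    """Control-condition parameters.

    ``initial_mean_interval`` is the admin-set mean seconds between rewards
    at level 1 (typically chosen from the participant's previously recorded
    tic frequency).  ``points_per_reward_multiplier`` scales the per-reward
    point payload by ``level ** 2``.
    """

    initial_mean_interval: float = 1.0
    points_per_reward_multiplier: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.initial_mean_interval > 0:
            raise ValueError("initial_mean_interval must be positive")
        if self.points_per_reward_multiplier < 1:
            raise ValueError("points_per_reward_multiplier must be a positive integer")


def next_reward_delay(config: NcrConfig, level: int, rng: np.random.Generator) -> float:
    """Draw the delay in seconds until the next noncontingent reward.

    Exponential with mean ``initial_mean_interval * level``.  Successive
    draws are independent given the generator state; a fixed seed replays
    the identical delay sequence.
    """
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    delay = float(rng.exponential(config.initial_mean_interval * level))
    return max(delay, _MIN_DELAY_S)


def apply_ncr_reward(
    state: DroState, config: NcrConfig, dro_config: DroConfig
) -> tuple[DroState, list[EngineEvent]]:
    """Deliver one noncontingent reward.

    Points grow by ``points_per_reward_multiplier * level ** 2`` regardless of
    tic history; level-up and coin processing are identical to the contingent
    engine.
    """
    from dataclasses import replace

    delta = config.points_per_reward_multiplier * state.level**2
    points = state.points + delta
    events = [
        EngineEvent(
            "reward",
            {"points_delta": str(delta), "points": str(points), "rate": str(state.rate)},
        )
    ]
    new = replace(state, points=points)
    new, lvl_events = process_level_ups(new, dro_config)
    events.extend(lvl_events)
    return new, events
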