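"""Differential-reinforcement-of-other-behavior (DRO) reward engine.

The engine runs on a discrete one-second clock.  Every completed tic-free
interval of ``level * interval_seconds_per_level`` seconds pays the current
accrual rate into the point total, *then* raises the rate by ``level ** 2``
(capped at ``cap_multiplier * level ** 2``).  A tic resets the rate and the
streak clock to zero; cumulative totals (points, level, coins, medals)
persist across tics.  A level-up fires whenever the point total strictly
exceeds ``levelup_multiplier * level ** 2`` and pays a coin bonus equal to
the square of the previous level.

All operations are pure: they return a new :class:`DroState` plus the list
of :class:`EngineEvent` records they emitted, leaving the input untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "DroConfig",
    "DroState",
    "EngineEvent",
    "InsufficientCoinsError",
    "new_dro_state",
    "interval_length",
    "advance_second",
    "register_tic",
    "process_level_ups",
    "redeem_coins",
    "state_to_kv",
    "state_from_kv",
]


class InsufficientCoinsError(ValueError):
    """Raised when a medal redemption asks for more coins than are held."""


@dataclass(frozen=True)
class DroConfig:
    """Tunable constants of the reward algebra.

    Parameters
    ----------
    levelup_multiplier:
        A level-up fires when points strictly exceed
        ``levelup_multiplier * level ** 2``.
    cap_multiplier:
        The accrual rate saturates at ``cap_multiplier * level ** 2``.
    interval_seconds_per_level:
        One reward interval lasts ``level * interval_seconds_per_level``
        seconds.
    medal_cost_coins:
        Store price of one medal, in coins.
    """

    levelup_multiplier: int = 1000
    cap_multiplier: int = 10
    interval_seconds_per_level: int = 1
    medal_cost_coins: int = 1

    def __post_init__(self) -> None:
        for name in (
            "levelup_multiplier",
            "cap_multiplier",
            "interval_seconds_per_level",
            "medal_cost_coins",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 1:
                raise ValueError(f"{name} must be a strictly positive integer, got {value!r}")


@dataclass(frozen=True)
class DroState:
    """Live engine state.  ``streak_seconds`` counts whole seconds since the
    most recent tic (or session start); ``session_clock`` counts processed
    engine seconds since session start."""

    level: int = 1
    points: int = 0
    rate: int = 0
    coins: int = 0
    medals: int = 0
    streak_seconds: int = 0
    session_clock: int = 0

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        for name in ("points", "rate", "coins", "medals", "streak_seconds", "session_clock"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EngineEvent:
    """A reward-algebra event: ``kind`` is one of ``reward``, ``level_up``,
    ``coin_award`` or ``tic``; ``payload`` maps short ASCII keys to string
    values."""

    kind: str
    payload: dict[str, str]


def new_dro_state(config: DroConfig) -> DroState:
    """Fresh session state: level 1, zero points, rate starts at zero."""
    if not isinstance(config, DroConfig):
        raise TypeError("config must be a DroConfig")
    return DroState()


def interval_length(state: DroState, config: DroConfig) -> int:
    """Length in seconds of one reward interval at the state's level."""
    return state.level * config.interval_seconds_per_level


def rate_cap(state: DroState, config: DroConfig) -> int:
    """Accrual-rate ceiling at the state's level."""
    return config.cap_multiplier * state.level**2


def advance_second(state: DroState, config: DroConfig) -> tuple[DroState, list[EngineEvent]]:
    """Advance the engine by one tic-free second.

    If the new streak length completes a reward interval, points grow by the
    current rate first, and the rate then grows by ``level ** 2`` (capped).
    Any pending level-ups are resolved before returning.
    """
    events: list[EngineEvent] = []
    streak = state.streak_seconds + 1
    clock = state.session_clock + 1
    points = state.points
    rate = state.rate
    if streak % interval_length(state, config) == 0:
        points += rate
        rate = min(rate + state.level**2, rate_cap(state, config))
        events.append(
            EngineEvent(
                "reward",
                {"points_delta": str(state.rate), "points": str(points), "rate": str(rate)},
            )
        )
    new = replace(
        state, points=points, rate=rate, streak_seconds=streak, session_clock=clock
    )
    new, lvl_events = process_level_ups(new, config)
    events.extend(lvl_events)
    return new, events


def register_tic(state: DroState) -> tuple[DroState, EngineEvent]:
    """A tic: rate and streak reset to zero; all totals persist."""
    new = replace(state, rate=0, streak_seconds=0)
    return new, EngineEvent("tic", {})


def process_level_ups(state: DroState, config: DroConfig) -> tuple[DroState, list[EngineEvent]]:
    """Resolve pending level-ups.

    While points strictly exceed ``levelup_multiplier * level ** 2`` the level
    increments and a coin bonus of (previous level) squared is paid.  Points
    are never reset; the rate persists, re-capped at the new (higher) cap.
    """
    events: list[EngineEvent] = []
    level = state.level
    coins = state.coins
    while state.points > config.levelup_multiplier * level**2:
        bonus = level**2
        level += 1
        coins += bonus
        events.append(EngineEvent("level_up", {"level": str(level)}))
        events.append(EngineEvent("coin_award", {"coins_delta": str(bonus), "coins": str(coins)}))
    if level == state.level:
        return state, events
    rate = min(state.rate, config.cap_multiplier * level**2)
    return replace(state, level=level, coins=coins, rate=rate), events


def redeem_coins(state: DroState, n_medals: int, config: DroConfig) -> DroState:
    """Trade coins for ``n_medals`` medals at the store price.

    Raises :class:`InsufficientCoinsError` if the balance cannot cover the
    purchase; the state is unchanged on error.
    """
    if not isinstance(n_medals, int) or isinstance(n_medals, bool) or n_medals < 1:
        raise ValueError(f"n_medals must be a positive integer, got {n_medals!r}")
    cost = n_medals * config.medal_cost_coins
    if state.coins < cost:
        raise InsufficientCoinsError(
            f"need {cost} coins for {n_medals} medal(s), have {state.coins}"
        )
    return replace(state, coins=state.coins - cost, medals=state.medals + n_medals)


_STATE_FIELDS = ("level", "points", "rate", "coins", "medals", "streak_seconds", "session_clock")


def state_to_kv(state: DroState) -> str:
    """Serialize to a flat ``key=value`` block joined by commas (comma, not
    semicolon, so a state block can live inside a log-event payload)."""
    return ",".join(f"{k}={getattr(state, k)}" for k in _STATE_FIELDS)


def state_from_kv(text: str) -> DroState:
    """Inverse of :func:`state_to_kv`."""
    values: dict[str, int] = {}
    for part in text.strip().split(","):
        if not part:
            continue
        key, sep, raw = part.partition("=")
        if not sep:
            raise ValueError(f"malformed state item {part!r}")
        if key in _STATE_FIELDS:
            values[key] = int(raw)
    missing = [k for k in _STATE_FIELDS if k not in values]
    if missing:
        raise ValueError(f"state block missing fields: {', '.join(missing)}")
    return DroState(**values)
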