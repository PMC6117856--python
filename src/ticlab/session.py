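"""Session lifecycle state machine.

Mediates the trainer's event stream (tic / heartbeat / end presses) and the
reward engine.  Timestamps are epoch milliseconds UTC; the reward engine is
quantized to whole seconds measured from session start.  A second that
contains a tic never counts toward a reward interval (tic-first resolution),
and only fully elapsed seconds are processed, so replaying a closed record's
trainer events reproduces the final engine state exactly.

The trainer keeps the session alive: any trainer event restarts a one-minute
inactivity timer, and :func:`check_timeout` closes the session once the
timer has fully elapsed (inclusive boundary).

Also houses the account anonymizer: the stored birthdate is drawn uniformly
within +/-45 calendar days of the 15th of the supplied birth month, so the
true day of birth is never recorded.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np

from .ncr import NcrConfig, apply_ncr_reward
from .reward_core import (
    DroConfig,
    DroState,
    new_dro_state,
    advance_second,
    register_tic,
    state_to_kv,
)

__all__ = [
    "EVENT_KINDS",
    "ACTORS",
    "END_REASONS",
    "DEFAULT_TIMEOUT_S",
    "SessionEvent",
    "SessionRecord",
    "SessionError",
    "UnlinkedPairError",
    "SessionClosedError",
    "EventOrderError",
    "load_link_table",
    "start_session",
    "trainer_event",
    "ncr_reward",
    "check_timeout",
    "close_session",
    "replay_record",
    "anonymize_birthdate",
]

EVENT_KINDS = frozenset(
    {"session_start", "tic", "reward", "level_up", "coin_award", "heartbeat", "session_end"}
)
ACTORS = frozenset({"user", "trainer", "system"})
END_REASONS = frozenset({"trainer_end", "timeout"})
DEFAULT_TIMEOUT_S = 60

BIRTHDATE_JITTER_DAYS = 45


class SessionError(RuntimeError):
    pass


class UnlinkedPairError(SessionError):
    pass


class SessionClosedError(SessionError):
    pass


class EventOrderError(SessionError):
    pass


@dataclass(frozen=True)
class SessionEvent:
    timestamp_ms: int
    kind: str
    actor: str
    payload: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timestamp_ms < 0:
            raise ValueError("timestamp_ms must be non-negative")
        if self.actor not in ACTORS:
            raise ValueError(f"unknown actor {self.actor!r}")
        for key, value in self.payload.items():
            for text in (key, value):
                if not text.isascii() or "\t" in text or "\n" in text:
                    raise ValueError(f"payload entries must be ASCII without tabs/newlines: {text!r}")
            if "=" in key or ";" in key or ";" in value:
                raise ValueError(f"payload entries may not contain '=' keys or ';': {key}={value}")


@dataclass
class SessionRecord:
    """One training session: metadata, ordered events, live engine state."""

    session_id: str
    user_id: str
    trainer_id: str
    condition: str  # "DRO" | "NCR"
    masked: bool
    start_ms: int
    dro_config: DroConfig
    ncr_config: NcrConfig | None
    events: list[SessionEvent] = field(default_factory=list)
    end_ms: int | None = None
    state: DroState = field(default_factory=DroState)
    # bookkeeping, excluded from equality: next engine second to process and
    # the timestamp of the most recent trainer activity (timer anchor)
    processed_s: int = field(default=0, compare=False)
    last_activity_ms: int = field(default=0, compare=False)

    @property
    def is_open(self) -> bool:
        return self.end_ms is None

    @property
    def end_reason(self) -> str | None:
        if self.is_open:
            return None
        return self.events[-1].payload.get("reason")


def load_link_table(path) -> set[tuple[str, str]]:
    """Read a two-column (trainer_id, user_id) whitespace-separated text file."""
    links: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'trainer_id user_id', got {line!r}")
            links.add((parts[0], parts[1]))
    return links


def start_session(
    user_id: str,
    trainer_id: str,
    condition: str,
    links: set[tuple[str, str]],
    dro_config: DroConfig | None = None,
    ncr_config: NcrConfig | None = None,
    *,
    start_ms: int = 0,
    masked: bool = False,
    session_id: str | None = None,
    restored_state: DroState | None = None,
) -> SessionRecord:
    """Open a session for a mutually linked (trainer, user) pair.

    ``restored_state`` carries cumulative account totals (points, level,
    coins, medals) into the new session; its per-session clocks are reset and
    the rate starts at zero.
    """
    if condition not in ("DRO", "NCR"):
        raise ValueError(f"condition must be 'DRO' or 'NCR', got {condition!r}")
    if (trainer_id, user_id) not in links:
        raise UnlinkedPairError(f"trainer {trainer_id!r} and user {user_id!r} are not linked")
    dro_config = dro_config or DroConfig()
    if condition == "NCR" and ncr_config is None:
        raise ValueError("NCR sessions require an NcrConfig")
    if restored_state is None:
        state = new_dro_state(dro_config)
    else:
        state = replace(restored_state, rate=0, streak_seconds=0, session_clock=0)
    record = SessionRecord(
        session_id=session_id or f"{user_id}-{start_ms}",
        user_id=user_id,
        trainer_id=trainer_id,
        condition=condition,
        masked=masked,
        start_ms=start_ms,
        dro_config=dro_config,
        ncr_config=ncr_config,
        state=state,
        last_activity_ms=start_ms,
    )
    record.events.append(
        SessionEvent(start_ms, "session_start", "trainer", {"condition_engine": "v1"})
    )
    return record


def _elapsed_seconds(record: SessionRecord, timestamp_ms: int) -> int:
    return (timestamp_ms - record.start_ms) // 1000


def _second_end_ms(record: SessionRecord, second: int) -> int:
    return record.start_ms + (second + 1) * 1000


def _advance_engine(record: SessionRecord, upto_ms: int) -> None:
    """Process all fully elapsed tic-free seconds before ``upto_ms``."""
    target = _elapsed_seconds(record, upto_ms)
    while record.processed_s < target:
        second = record.processed_s
        if record.condition == "DRO":
            record.state, engine_events = advance_second(record.state, record.dro_config)
            stamp = _second_end_ms(record, second)
            for ev in engine_events:
                record.events.append(SessionEvent(stamp, ev.kind, "system", dict(ev.payload)))
        else:
            # noncontingent condition: the clock advances but no interval
            # rewards accrue; the streak still tracks tic-free time
            record.state = replace(
                record.state,
                streak_seconds=record.state.streak_seconds + 1,
                session_clock=record.state.session_clock + 1,
            )
        record.processed_s = second + 1


def _require_open_ordered(record: SessionRecord, timestamp_ms: int) -> None:
    if not record.is_open:
        raise SessionClosedError(f"session {record.session_id} is closed")
    if record.events and timestamp_ms < record.events[-1].timestamp_ms:
        raise EventOrderError(
            f"timestamp {timestamp_ms} precedes last event at {record.events[-1].timestamp_ms}"
        )


def trainer_event(record: SessionRecord, kind: str, timestamp_ms: int) -> SessionRecord:
    """Apply a trainer button press: ``tic``, ``heartbeat`` or ``end``.

    Every trainer event restarts the inactivity timer.  A tic resets the
    engine rate and consumes its containing second (no reward can complete
    in a second that holds a tic).
    """
    if kind not in ("tic", "heartbeat", "end"):
        raise ValueError(f"trainer event kind must be tic/heartbeat/end, got {kind!r}")
    _require_open_ordered(record, timestamp_ms)
    if kind == "end":
        close_session(record, timestamp_ms, "trainer_end")
        return record
    _advance_engine(record, timestamp_ms)
    record.last_activity_ms = timestamp_ms
    if kind == "heartbeat":
        record.events.append(SessionEvent(timestamp_ms, "heartbeat", "trainer"))
        return record
    # tic
    record.state, _ = register_tic(record.state)
    record.events.append(SessionEvent(timestamp_ms, "tic", "trainer"))
    tic_second = _elapsed_seconds(record, timestamp_ms)
    if record.processed_s <= tic_second:
        # mark the tic's second as consumed: it elapses on the session clock
        # but can never complete a reward interval
        record.state = replace(
            record.state, session_clock=record.state.session_clock + (tic_second + 1 - record.processed_s)
        )
        record.processed_s = tic_second + 1
    return record


def ncr_reward(record: SessionRecord, timestamp_ms: int) -> SessionRecord:
    """Deliver one scheduled noncontingent reward (NCR sessions only)."""
    if record.condition != "NCR":
        raise SessionError("scheduled rewards are only valid in the NCR condition")
    _require_open_ordered(record, timestamp_ms)
    _advance_engine(record, timestamp_ms)
    record.state, events = apply_ncr_reward(record.state, record.ncr_config, record.dro_config)
    for ev in events:
        record.events.append(SessionEvent(timestamp_ms, ev.kind, "system", dict(ev.payload)))
    return record


def check_timeout(
    record: SessionRecord, now_ms: int, timeout_seconds: int = DEFAULT_TIMEOUT_S
) -> SessionRecord:
    """Close the session if trainer inactivity has reached the timeout.

    The boundary is inclusive: exactly ``timeout_seconds`` of silence ends
    the session, timestamped at the instant the timer elapsed.
    """
    if not record.is_open:
        return record
    if now_ms - record.last_activity_ms >= timeout_seconds * 1000:
        close_session(record, record.last_activity_ms + timeout_seconds * 1000, "timeout")
    return record


def close_session(record: SessionRecord, timestamp_ms: int, reason: str) -> SessionRecord:
    if reason not in END_REASONS:
        raise ValueError(f"end reason must be one of {sorted(END_REASONS)}, got {reason!r}")
    _require_open_ordered(record, timestamp_ms)
    _advance_engine(record, timestamp_ms)
    payload = {"reason": reason, "final_state": state_to_kv(record.state)}
    actor = "trainer" if reason == "trainer_end" else "system"
    record.events.append(SessionEvent(timestamp_ms, "session_end", actor, payload))
    record.end_ms = timestamp_ms
    return record


def replay_record(record: SessionRecord) -> SessionRecord:
    """Re-run a closed record's input events through a fresh engine.

    Trainer tics/heartbeats (and, in NCR, the scheduled reward stream) are
    the inputs; interval rewards, level-ups and coins are regenerated.  On a
    well-formed record the replayed final state matches the original.
    """
    if record.is_open:
        raise SessionError("cannot replay an open session")
    fresh = start_session(
        record.user_id,
        record.trainer_id,
        record.condition,
        {(record.trainer_id, record.user_id)},
        record.dro_config,
        record.ncr_config,
        start_ms=record.start_ms,
        masked=record.masked,
        session_id=record.session_id,
    )
    for ev in record.events:
        if ev.kind in ("tic", "heartbeat") and ev.actor == "trainer":
            trainer_event(fresh, ev.kind, ev.timestamp_ms)
        elif ev.kind == "reward" and ev.actor == "system" and record.condition == "NCR":
            ncr_reward(fresh, ev.timestamp_ms)
        elif ev.kind == "session_end":
            close_session(fresh, ev.timestamp_ms, ev.payload.get("reason", "trainer_end"))
    return fresh


def anonymize_birthdate(
    birth_month: int,
    birth_year: int,
    rng: np.random.Generator,
    *,
    min_year: int = 1900,
    max_year: int = 2100,
) -> datetime.date:
    """Jitter a birth month/year into a stored date.

    Returns a date uniform over the 91 calendar days centred on the 15th of
    the supplied month (offset in [-45, +45], endpoints included).  The true
    day of month is never an input, so it can never be stored.
    """
    if not 1 <= int(birth_month) <= 12:
        raise ValueError(f"birth_month must be in 1..12, got {birth_month!r}")
    if not min_year <= int(birth_year) <= max_year:
        raise ValueError(f"birth_year {birth_year!r} outside plausible range {min_year}..{max_year}")
    anchor = datetime.date(int(birth_year), int(birth_month), 15)
    offset = int(rng.integers(-BIRTHDATE_JITTER_DAYS, BIRTHDATE_JITTER_DAYS + 1))
    return anchor + datetime.timedelta(days=offset)
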