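import numpy as np
import pytest

from ticlab.ncr import NcrConfig
from ticlab.reward_core import DroConfig, DroState, state_to_kv
from ticlab.session import SessionEvent, SessionRecord


@pytest.fixture
def config():
    return DroConfig()


@pytest.fixture
def ncr_config():
    return NcrConfig(initial_mean_interval=1.0, rng_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_record(
    tic_times_s=(),
    reward_times_s=(),
    duration_s=60.0,
    condition="DRO",
    start_ms=0,
    state=None,
    user_id="u1",
    trainer_id="t1",
):
    """Assemble a closed SessionRecord directly from event-time arrays,
    bypassing the engine. Used to feed analytics/log tests known streams."""
    state = state or DroState()
    end_ms = start_ms + int(round(duration_s * 1000))
    stamped = [(start_ms, "session_start", "trainer", {"condition_engine": "v1"})]
    for t in tic_times_s:
        stamped.append((start_ms + int(round(t * 1000)), "tic", "trainer", {}))
    for t in reward_times_s:
        stamped.append((start_ms + int(round(t * 1000)), "reward", "system", {"points_delta": "1"}))
    stamped.sort(key=lambda x: x[0])
    stamped.append(
        (end_ms, "session_end", "trainer", {"reason": "trainer_end", "final_state": state_to_kv(state)})
    )
    events = [SessionEvent(*s) for s in stamped]
    return SessionRecord(
        session_id=f"{user_id}-{start_ms}",
        user_id=user_id,
        trainer_id=trainer_id,
        condition=condition,
        masked=False,
        start_ms=start_ms,
        dro_config=DroConfig(),
        ncr_config=NcrConfig() if condition == "NCR" else None,
        events=events,
        end_ms=end_ms,
        state=state,
    )


def random_record(rng, max_duration_s=120):
    """Random but structurally valid closed record, for round-trip tests."""
    duration = float(rng.uniform(5, max_duration_s))
    n_tics = int(rng.integers(0, 20))
    tics = np.sort(rng.uniform(0, duration, n_tics))
    n_rewards = int(rng.integers(0, 20))
    rewards = np.sort(rng.uniform(0, duration, n_rewards))
    condition = "DRO" if rng.random() < 0.5 else "NCR"
    state = DroState(
        level=int(rng.integers(1, 5)),
        points=int(rng.integers(0, 5000)),
        rate=int(rng.integers(0, 10)),
        coins=int(rng.integers(0, 10)),
        medals=int(rng.integers(0, 3)),
        streak_seconds=int(rng.integers(0, 100)),
        session_clock=int(rng.integers(0, 1000)),
    )
    return build_record(
        tic_times_s=tics,
        reward_times_s=rewards,
        duration_s=duration,
        condition=condition,
        start_ms=int(rng.integers(0, 10**9)),
        state=state,
        user_id=f"u{int(rng.integers(0, 100))}",
        trainer_id=f"t{int(rng.integers(0, 100))}",
    )
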