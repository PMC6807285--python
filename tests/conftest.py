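import numpy as np
import pandas as pd
import pytest

from aacsim.config import ApproachPolicy, TaskConfig
from aacsim.events import Event, EventLog
from aacsim.extract import reconstruct_decisions
from aacsim.simulate import simulate_task1_block


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def control_policy() -> ApproachPolicy:
    return ApproachPolicy()


@pytest.fixture(scope="session")
def task1_block(config, control_policy) -> EventLog:
    """One default Task-1 block, reused across read-only tests."""
    return simulate_task1_block(config, control_policy, 12345)


@pytest.fixture(scope="session")
def cohort_decisions(config) -> pd.DataFrame:
    """Decision tables for a small cohort of distinct control agents."""
    frames = []
    for i in range(8):
        rng = np.random.default_rng(1000 + i)
        pol = ApproachPolicy(
            approach_intercept=2.0 + 0.35 * rng.normal(),
            approach_coef_loss=-0.45 + 0.1 * rng.normal(), seed=i)
        log = simulate_task1_block(config, pol, 2000 + i,
                                   subject_id=f"ctrl{i:02d}")
        frames.append(reconstruct_decisions(log))
    return pd.concat(frames, ignore_index=True)


def make_epoch_events(epoch_id: int, threat: str, *, n_collected: int = 0,
                      caught: bool = False, closed: bool = True,
                      t0: float = 0.0) -> list[Event]:
    """Hand-built minimal Task-1 epoch for extraction tests."""
    events = [Event(t0, "epoch_start", epoch_id, threat)]
    t = t0
    for i in range(1, 7):
        t += 1000.0
        events.append(Event(t, "token_on", epoch_id, threat,
                            {"token_index": i, "side": "left",
                             "availability": 1500.0,
                             "loss_at_onset": min(i - 1, n_collected)}))
        if i <= n_collected:
            events.append(Event(t + 500.0, "leave_safe", epoch_id, threat,
                                {"token_index": i}))
            events.append(Event(t + 500.0, "token_collected", epoch_id,
                                threat, {"token_index": i,
                                         "loss_before": i - 1}))
            events.append(Event(t + 800.0, "enter_safe", epoch_id, threat,
                                {"token_index": i, "n_checks": 3}))
            t += 800.0
        else:
            events.append(Event(t + 1500.0, "token_off", epoch_id, threat,
                                {"token_index": i}))
            t += 1500.0
    if caught:
        events.append(Event(t + 50.0, "caught", epoch_id, threat,
                            {"n_checks": 1, "tokens_lost": n_collected}))
    if closed:
        events.append(Event(t + 100.0, "epoch_end", epoch_id, threat,
                            {"collected": n_collected, "caught": caught,
                             "retained": 0 if caught else n_collected}))
    return events


def make_task1_log(epoch_specs, subject_id: str = "sX") -> EventLog:
    """Assemble a Task-1 log from (n_collected, caught) epoch specs."""
    log = EventLog(subject_id=subject_id, block_id=0, task="task1",
                   config_hash="manual")
    t0 = 0.0
    for epoch_id, spec in enumerate(epoch_specs):
        events = make_epoch_events(epoch_id, spec.get("threat", "med"),
                                   n_collected=spec.get("n_collected", 0),
                                   caught=spec.get("caught", False),
                                   closed=spec.get("closed", True), t0=t0)
        log.events.extend(events)
        t0 = events[-1].t + 500.0
    return log
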