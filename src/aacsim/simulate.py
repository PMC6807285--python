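"""Generative simulator for the two behavioural tasks.

Task 1 (approach-avoidance conflict game): on each epoch, up to six reward
tokens appear one after another; the player may leave a safe place to
collect a token and return.  While outside the safe place, a sleeping
predator wakes with a constant per-100-ms hazard that depends on the
epoch's threat level; on waking it catches the player and all tokens
collected in the epoch are lost.  Token availability is exponential (mean
1.25 s); the wait before the next token is the same exponential plus
500 ms.

Task 2 (safe predator exposure): the player stays in the safe place and
has six attempts per epoch to "expose" the predator with the up key; each
attempt succeeds with the threat level's wake-up probability, and a success
ends the epoch.  Simulated press times mix a token-unrelated uniform
process (weight ``w``) with an exGauss-delayed simple response to the most
recent token onset.

Space is abstracted to three positions (safe, left, right): a single key
press moves the player out to a token's side — collecting it on arrival —
and a single press returns it.  Approach latency is therefore the time
from token onset to the outward key press, return latency the time from
collection to the homeward press, and hazard exposure accrues during the
return interval in discrete 100-ms steps.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .config import (
    THREAT_CODES,
    THREAT_LEVELS,
    ApproachPolicy,
    CohortSpec,
    ConfigurationError,
    ExposurePolicy,
    TaskConfig,
    derive_seed,
)
from .events import Event, EventLog

#: per-subject variability of control agents' policy parameters
DEFAULT_CONTROL_SD = {
    "approach_intercept": 0.35,
    "approach_coef_threat": 0.12,
    "approach_coef_loss": 0.10,
    "al_base": 60.0,
    "al_coef_threat": 12.0,
    "al_coef_loss": 8.0,
    "rl_base": 40.0,
    "rl_coef_threat": 8.0,
    "rl_coef_loss": 4.0,
}

DEFAULT_EXPOSURE_SD = {"w": 0.06, "mu": 40.0, "sigma": 15.0,
                       "presses_per_epoch_mean": 0.5}


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _linear_latency(base: float, b_threat: float, b_loss: float,
                    threat: str, loss: int, sd: float,
                    rng: np.random.Generator) -> float:
    """Gaussian latency around a linear predictor, truncated at 1 ms."""
    lat = base + b_threat * THREAT_CODES[threat] + b_loss * loss
    if sd > 0:
        lat += rng.normal(0.0, sd)
    return max(lat, 1.0)


def sample_exgauss(mu: float, sigma: float, lam: float,
                   rng: np.random.Generator, size=None):
    """Draw exGauss variates: Normal(mu, sigma) + Exponential(rate lam)."""
    return rng.normal(mu, sigma, size=size) + rng.exponential(1.0 / lam, size=size)


# ---------------------------------------------------------------------------
# Task 1
# ---------------------------------------------------------------------------

def simulate_task1_epoch(config: TaskConfig, policy: ApproachPolicy,
                         threat: str, rng_state, *, epoch_id: int = 0,
                         t_start: float = 0.0) -> list[Event]:
    """Simulate one Task-1 epoch; returns its time-ordered event list.

    Exactly ``config.tokens_per_epoch`` token cycles are scheduled.  After
    a catch, remaining tokens still appear but cannot be collected and no
    further excursions occur.
    """
    if threat not in THREAT_LEVELS:
        raise ConfigurationError(f"unknown threat level {threat!r}")
    rng = _as_rng(rng_state)
    hazard = config.hazard(threat)
    step = config.step_ms

    events: list[Event] = [Event(t_start, "epoch_start", epoch_id, threat)]
    t = t_start
    loss = 0          # tokens currently held
    collected = 0
    caught = False
    t_player_home = t_start   # time the player is back in the safe place

    for token_index in range(1, config.tokens_per_epoch + 1):
        wait = rng.exponential(config.availability_mean) + config.wait_offset
        avail = rng.exponential(config.availability_mean)
        t_on = max(t + wait, t_player_home)
        side = "left" if rng.random() < 0.5 else "right"
        events.append(Event(t_on, "token_on", epoch_id, threat,
                            {"token_index": token_index, "side": side,
                             "availability": avail, "loss_at_onset": loss}))

        approached = False
        if not caught and rng.random() < policy.approach_probability(threat, loss):
            # a committed approach reaches the token: the availability
            # window governs only the on-screen cycle of unapproached tokens
            approached = True
            al = _linear_latency(policy.al_base, policy.al_coef_threat,
                                 policy.al_coef_loss, threat, loss,
                                 policy.latency_noise_sd, rng)
            t_leave = t_on + al
            key = "key_left" if side == "left" else "key_right"
            events.append(Event(t_leave, key, epoch_id, threat,
                                {"token_index": token_index}))
            events.append(Event(t_leave, "leave_safe", epoch_id, threat,
                                {"token_index": token_index}))
            collected += 1
            loss += 1
            events.append(Event(t_leave, "token_collected", epoch_id,
                                threat, {"token_index": token_index,
                                         "loss_before": loss - 1}))
            rl = _linear_latency(policy.rl_base, policy.rl_coef_threat,
                                 policy.rl_coef_loss, threat, loss,
                                 policy.latency_noise_sd, rng)
            t_enter = t_leave + rl
            # discrete per-step hazard while outside the safe place
            n_checks = int(np.floor(rl / step))
            t_caught = None
            for k in range(1, n_checks + 1):
                if rng.random() < hazard:
                    t_caught = t_leave + k * step
                    events.append(Event(t_caught, "predator_wake",
                                        epoch_id, threat))
                    events.append(Event(
                        t_caught, "caught", epoch_id, threat,
                        {"n_checks": k, "tokens_lost": loss}))
                    caught = True
                    loss = 0
                    break
            if t_caught is None:
                key = "key_right" if side == "left" else "key_left"
                events.append(Event(t_enter, key, epoch_id, threat,
                                    {"token_index": token_index}))
                events.append(Event(t_enter, "enter_safe", epoch_id,
                                    threat, {"token_index": token_index,
                                             "n_checks": n_checks}))
                t_player_home = t_enter
            else:
                t_player_home = t_caught
            t_off = t_leave
        else:
            t_off = t_on + avail
            events.append(Event(t_off, "token_off", epoch_id, threat,
                                {"token_index": token_index}))
        t = max(t_off, t_player_home)

    t_end = max(t, t_player_home)
    events.append(Event(t_end, "epoch_end", epoch_id, threat,
                        {"collected": collected, "caught": caught,
                         "retained": 0 if caught else collected}))
    events.sort(key=lambda ev: (ev.t, _KIND_ORDER.get(ev.kind, 5)))
    return events


# stable secondary sort so simultaneous events keep a canonical order
_KIND_ORDER = {"epoch_start": 0, "token_on": 1, "key_left": 2, "key_right": 2,
               "key_up": 2, "leave_safe": 3, "token_collected": 4,
               "predator_wake": 6, "caught": 7, "enter_safe": 8,
               "token_off": 9, "expose_fail": 6, "expose_success": 7,
               "epoch_end": 10}


def balanced_threat_sequence(n_epochs: int, rng: np.random.Generator) -> list[str]:
    """Shuffled threat labels, balanced across the three levels.

    Emits a warning and a near-balanced assignment when ``n_epochs`` is not
    divisible by 3.
    """
    base, rem = divmod(n_epochs, 3)
    if rem:
        warnings.warn(f"{n_epochs} epochs not divisible by 3; "
                      "using near-balanced threat assignment", stacklevel=2)
    counts = [base + (1 if i < rem else 0) for i in range(3)]
    seq = [lv for lv, c in zip(THREAT_LEVELS, counts) for _ in range(c)]
    perm = rng.permutation(len(seq))
    return [seq[i] for i in perm]


def simulate_task1_block(config: TaskConfig, policy: ApproachPolicy,
                         rng_state, *, subject_id: str = "s0",
                         block_id: int = 0) -> EventLog:
    """Simulate one Task-1 block of ``epochs_per_block`` epochs.

    Threat levels are balanced within the block (15/15/15 by default) and
    shuffled.  Deterministic for a fixed (config, policy, seed).
    """
    rng = _as_rng(rng_state)
    threats = balanced_threat_sequence(config.epochs_per_block, rng)
    log = EventLog(subject_id=subject_id, block_id=block_id, task="task1",
                   config_hash=config.config_hash())
    t = 0.0
    for epoch_id, threat in enumerate(threats):
        epoch_events = simulate_task1_epoch(config, policy, threat, rng,
                                            epoch_id=epoch_id, t_start=t)
        log.events.extend(epoch_events)
        t = epoch_events[-1].t + 500.0   # inter-epoch gap
    return log


# ---------------------------------------------------------------------------
# Task 2
# ---------------------------------------------------------------------------

def _task2_token_schedule(config: TaskConfig, rng: np.random.Generator):
    """Scheduled token onsets/offsets and epoch duration for one epoch."""
    t = 0.0
    onsets, offsets = [], []
    for _ in range(config.tokens_per_epoch):
        wait = rng.exponential(config.availability_mean) + config.wait_offset
        avail = rng.exponential(config.availability_mean)
        t_on = t + wait
        onsets.append(t_on)
        offsets.append(t_on + avail)
        t = t_on + avail
    return np.asarray(onsets), np.asarray(offsets), t


def simulate_task2_epoch(config: TaskConfig, epolicy: ExposurePolicy,
                         threat: str, rng_state, *, epoch_id: int = 0,
                         t_start: float = 0.0) -> list[Event]:
    """Simulate one safe-predator-exposure epoch.

    Press times follow the ``w``-weighted uniform + exGauss mixture; each
    press is an exposure attempt succeeding with the threat level's wake-up
    probability; a success ends the epoch, and attempts beyond
    ``exposure_attempts_max`` are ignored (key disabled).
    """
    if threat not in THREAT_LEVELS:
        raise ConfigurationError(f"unknown threat level {threat!r}")
    rng = _as_rng(rng_state)
    p_wake = config.hazard(threat)
    onsets, offsets, duration = _task2_token_schedule(config, rng)

    n_press = rng.poisson(epolicy.presses_per_epoch_mean)
    press_times = []
    for _ in range(n_press):
        if rng.random() < epolicy.w:
            tp = rng.uniform(0.0, duration)
        else:
            j = rng.integers(0, len(onsets))
            tp = onsets[j] + sample_exgauss(epolicy.mu, epolicy.sigma,
                                            epolicy.lam, rng)
        if 0.0 <= tp <= duration:
            press_times.append(float(tp))
    press_times.sort()

    events: list[Event] = [Event(t_start, "epoch_start", epoch_id, threat)]
    t_end = t_start + duration
    exposed_at = None
    n_attempts = 0
    for tp in press_times:
        if n_attempts >= config.exposure_attempts_max:
            break   # key disabled: press emits no event
        n_attempts += 1
        t_abs = t_start + tp
        events.append(Event(t_abs, "key_up", epoch_id, threat,
                            {"attempt": n_attempts}))
        if rng.random() < p_wake:
            events.append(Event(t_abs, "expose_success", epoch_id, threat,
                                {"attempt": n_attempts}))
            exposed_at = t_abs
            t_end = t_abs
            break
        events.append(Event(t_abs, "expose_fail", epoch_id, threat,
                            {"attempt": n_attempts}))

    for i, (t_on, t_off) in enumerate(zip(onsets, offsets), start=1):
        if exposed_at is not None and t_start + t_on > exposed_at:
            continue
        events.append(Event(t_start + t_on, "token_on", epoch_id, threat,
                            {"token_index": i}))
        if exposed_at is None or t_start + t_off <= exposed_at:
            events.append(Event(t_start + t_off, "token_off", epoch_id,
                                threat, {"token_index": i}))
    events.append(Event(t_end, "epoch_end", epoch_id, threat,
                        {"exposed": exposed_at is not None,
                         "duration": t_end - t_start}))
    events.sort(key=lambda ev: (ev.t, _KIND_ORDER.get(ev.kind, 5)))
    return events


def simulate_task2_block(config: TaskConfig, epolicy: ExposurePolicy,
                         rng_state, *, subject_id: str = "s0",
                         block_id: int = 0) -> EventLog:
    """Simulate one Task-2 block of ``exposure_epochs_per_block`` epochs."""
    rng = _as_rng(rng_state)
    threats = balanced_threat_sequence(config.exposure_epochs_per_block, rng)
    log = EventLog(subject_id=subject_id, block_id=block_id, task="task2",
                   config_hash=config.config_hash())
    t = 0.0
    for epoch_id, threat in enumerate(threats):
        epoch_events = simulate_task2_epoch(config, epolicy, threat, rng,
                                            epoch_id=epoch_id, t_start=t)
        log.events.extend(epoch_events)
        t = epoch_events[-1].t + 500.0
    return log


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _draw_policy(mean_overrides, sds, rng, cls, *, seed: int):
    base = cls() if cls is ExposurePolicy else cls(seed=seed)
    params = dataclasses.asdict(base)
    params.update(mean_overrides)
    defaults = DEFAULT_CONTROL_SD if cls is ApproachPolicy else DEFAULT_EXPOSURE_SD
    sds = {**defaults, **sds}
    for name, sd in sds.items():
        if name in params and sd > 0:
            params[name] = params[name] + rng.normal(0.0, sd)
    if cls is ApproachPolicy:
        params["latency_noise_sd"] = max(params["latency_noise_sd"], 0.0)
        params["seed"] = seed
    else:
        params["w"] = float(np.clip(params["w"], 0.0, 1.0))
        params["sigma"] = max(params["sigma"], 1.0)
        params["lam"] = max(params["lam"], 1e-6)
        params["presses_per_epoch_mean"] = max(params["presses_per_epoch_mean"], 0.5)
    return cls(**params)


def simulate_cohort(spec: CohortSpec, config: TaskConfig,
                    *, tasks=("task1", "task2")):
    """Simulate a full cohort of control and lesion agents.

    Returns ``(logs, manifest)``: all event logs plus a DataFrame mapping
    subject -> group -> seed (and the realized policy parameters).  Every
    subject receives a distinct seed derived from ``spec.master_seed``, so
    an identical spec reproduces identical logs.
    """
    logs: list[EventLog] = []
    manifest_rows = []

    subjects: list[tuple[str, str, dict, dict]] = []
    for i in range(spec.n_controls):
        subjects.append((f"ctrl{i:02d}", "control", {}, {}))
    for p in spec.patients:
        subjects.append((p.label, p.group, dict(p.approach_overrides),
                         dict(p.exposure_overrides)))

    for subj_id, group, a_over, e_over in subjects:
        seed = derive_seed(spec.master_seed, "subject", subj_id)
        rng = np.random.default_rng(seed)
        if group == "control":
            apolicy = _draw_policy(spec.control_policy_mean,
                                   spec.control_policy_sd, rng,
                                   ApproachPolicy, seed=seed)
            epolicy = _draw_policy(spec.control_exposure_mean,
                                   spec.control_exposure_sd, rng,
                                   ExposurePolicy, seed=seed)
        else:
            # lesion agent: cohort-mean policy with explicit perturbations
            apolicy = ApproachPolicy(**{**dataclasses.asdict(ApproachPolicy()),
                                        **spec.control_policy_mean,
                                        **a_over, "seed": seed})
            epolicy = ExposurePolicy(**{**dataclasses.asdict(ExposurePolicy()),
                                        **spec.control_exposure_mean,
                                        **e_over})
        row = {"subject_id": subj_id, "group": group, "seed": seed}
        row.update({f"a_{k}": v for k, v in dataclasses.asdict(apolicy).items()
                    if k != "seed"})
        row.update({f"e_{k}": v for k, v in dataclasses.asdict(epolicy).items()})
        manifest_rows.append(row)

        if "task1" in tasks:
            for b in range(config.n_blocks_task1):
                bseed = derive_seed(spec.master_seed, "task1", subj_id, b)
                logs.append(simulate_task1_block(
                    config, apolicy, bseed, subject_id=subj_id, block_id=b))
        if "task2" in tasks:
            for b in range(config.n_blocks_task2):
                bseed = derive_seed(spec.master_seed, "task2", subj_id, b)
                logs.append(simulate_task2_block(
                    config, epolicy, bseed, subject_id=subj_id,
                    block_id=config.n_blocks_task1 + b))

    manifest = pd.DataFrame(manifest_rows)
    return logs, manifest


def simulate_memory_ratings(true_rates: dict[str, float], spec: CohortSpec,
                            rng_state=None) -> dict[str, float]:
    """Simulate end-of-experiment catch-rate ratings on a 0-100 scale.

    ``rating = clip(slope * true_rate + bias + noise, 0, 100)``; the default
    slope (0.99) and bias (+36.3) emulate healthy players' near-unit but
    upward-shifted estimation of their actual catch rates.
    """
    rng = _as_rng(rng_state if rng_state is not None else spec.master_seed)
    out = {}
    for level, rate in true_rates.items():
        if not 0.0 <= rate <= 100.0:
            raise ValueError(f"true rate must be in [0, 100], got {rate}")
        noise = rng.normal(0.0, spec.rating_noise_sd) if spec.rating_noise_sd > 0 else 0.0
        out[level] = float(np.clip(spec.rating_slope * rate
                                   + spec.rating_bias + noise, 0.0, 100.0))
    return out
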