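"""Readout extraction: event logs -> analysis tables.

Converts raw event streams into the tables the statistics operate on:
reconstructed approach decisions (six per uncaught epoch), windowed
approach/return latencies, per-threat true catch rates, per-subject
condition means, and cohort-level performance quality control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import THREAT_LEVELS, TaskConfig
from .events import EventLog

logger = logging.getLogger(__name__)

DECISION_COLUMNS = ["subject_id", "epoch_id", "threat_level", "token_index",
                    "potential_loss", "approached"]
LATENCY_COLUMNS = ["subject_id", "epoch_id", "threat_level", "token_index",
                   "potential_loss", "approach_latency_ms",
                   "return_latency_ms", "caught",
                   "approach_excluded", "return_excluded"]


class OrphanEventError(ValueError):
    """A movement event with no preceding token onset."""


def _epoch_summaries(log: EventLog):
    """Per-epoch (threat, collected count, caught flag, well-formed flag)."""
    out = {}
    for epoch_id, events in log.epochs().items():
        threat = events[0].threat_level
        collected = sum(1 for ev in events if ev.kind == "token_collected")
        caught = any(ev.kind == "caught" for ev in events)
        closed = any(ev.kind == "epoch_end" for ev in events)
        out[epoch_id] = (threat, collected, caught, closed)
    return out


def reconstruct_decisions(log: EventLog) -> pd.DataFrame:
    """Reconstruct approach decisions from collection counts.

    For each uncaught epoch, six records are created — one per possible
    token — scored 1 if the player collected at least that many tokens and
    0 otherwise.  Caught epochs yield no records, because choices after the
    catch cannot be reconstructed.  Malformed epochs (no ``epoch_end``) are
    skipped with a warning.
    """
    if log.task != "task1":
        raise ValueError("decision reconstruction requires a Task-1 log")
    rows = []
    for epoch_id, (threat, collected, caught, closed) in sorted(
            _epoch_summaries(log).items()):
        if not closed:
            logger.warning("skipping malformed epoch %s of %s/%s "
                           "(missing epoch_end)", epoch_id, log.subject_id,
                           log.block_id)
            continue
        if caught:
            continue
        for token_index in range(1, 7):
            rows.append({"subject_id": log.subject_id, "epoch_id": epoch_id,
                         "threat_level": threat, "token_index": token_index,
                         "potential_loss": token_index - 1,
                         "approached": int(collected >= token_index)})
    return pd.DataFrame(rows, columns=DECISION_COLUMNS)


def extract_latencies(log: EventLog, config: TaskConfig) -> pd.DataFrame:
    """Extract windowed approach and return latencies.

    One record per approached token with index <= 5 (the sixth token is
    excluded from all latency analysis).  Latencies outside the open
    acceptance windows are set to NaN but the record is retained with an
    exclusion flag for auditability.  Return latency is absent when the
    excursion ended in a catch.
    """
    if log.task != "task1":
        raise ValueError("latency extraction requires a Task-1 log")
    a_lo, a_hi = config.approach_window
    r_lo, r_hi = config.return_window
    rows = []
    for epoch_id, events in sorted(log.epochs().items()):
        threat = events[0].threat_level
        token_on_t: dict[int, float] = {}
        loss_at: dict[int, int] = {}
        for ev in events:
            if ev.kind == "token_on":
                idx = ev.payload["token_index"]
                token_on_t[idx] = ev.t
                loss_at[idx] = ev.payload.get("loss_at_onset", idx - 1)
        collected_t: dict[int, float] = {}
        leave_t: dict[int, float] = {}
        enter_t: dict[int, float] = {}
        caught_after: dict[int, bool] = {}
        current_idx = None
        for ev in events:
            if ev.kind == "leave_safe":
                idx = ev.payload.get("token_index") if ev.payload else None
                if idx is None or idx not in token_on_t:
                    raise OrphanEventError(
                        f"leave_safe at t={ev.t} without preceding token_on "
                        f"(epoch {epoch_id})")
                current_idx = idx
                leave_t[idx] = ev.t
                caught_after[idx] = False
            elif ev.kind == "token_collected":
                collected_t[ev.payload["token_index"]] = ev.t
            elif ev.kind == "enter_safe" and current_idx is not None:
                enter_t[current_idx] = ev.t
                current_idx = None
            elif ev.kind == "caught" and current_idx is not None:
                caught_after[current_idx] = True
                current_idx = None

        for idx in sorted(leave_t):
            if idx > 5:
                continue   # sixth token excluded from latency analysis
            al = leave_t[idx] - token_on_t[idx]
            caught = caught_after.get(idx, False)
            rl = math.nan
            if not caught and idx in enter_t and idx in collected_t:
                rl = enter_t[idx] - collected_t[idx]
            a_ok = a_lo < al < a_hi
            r_ok = (not math.isnan(rl)) and (r_lo < rl < r_hi)
            rows.append({
                "subject_id": log.subject_id, "epoch_id": epoch_id,
                "threat_level": threat, "token_index": idx,
                "potential_loss": loss_at.get(idx, idx - 1),
                "approach_latency_ms": al if a_ok else math.nan,
                "return_latency_ms": rl if r_ok else math.nan,
                "caught": caught,
                "approach_excluded": not a_ok,
                "return_excluded": math.isnan(rl) or not r_ok,
            })
    return pd.DataFrame(rows, columns=LATENCY_COLUMNS)


def true_catch_rates(log: EventLog) -> pd.DataFrame:
    """Per-threat excursion counts, catches, and true catch rate (%).

    An excursion spans leave_safe to enter_safe or to the catch.  Levels
    with no excursions get a NaN rate.
    """
    if log.task != "task1":
        raise ValueError("catch rates require a Task-1 log")
    counts = {lv: [0, 0] for lv in THREAT_LEVELS}   # [excursions, catches]
    for events in log.epochs().values():
        threat = events[0].threat_level
        for ev in events:
            if ev.kind == "leave_safe":
                counts[threat][0] += 1
            elif ev.kind == "caught":
                counts[threat][1] += 1
    rows = []
    for lv in THREAT_LEVELS:
        exc, cat = counts[lv]
        rows.append({"subject_id": log.subject_id, "threat_level": lv,
                     "excursions": exc, "catches": cat,
                     "rate_pct": 100.0 * cat / exc if exc else math.nan})
    return pd.DataFrame(rows)


def cohort_catch_rates(logs: Iterable[EventLog]) -> pd.DataFrame:
    """Aggregate true catch rates per subject across Task-1 blocks."""
    parts = [true_catch_rates(lg) for lg in logs if lg.task == "task1"]
    df = pd.concat(parts, ignore_index=True)
    agg = (df.groupby(["subject_id", "threat_level"], sort=False)
             [["excursions", "catches"]].sum().reset_index())
    agg["rate_pct"] = np.where(agg["excursions"] > 0,
                               100.0 * agg["catches"] / agg["excursions"],
                               np.nan)
    return agg


def empirical_hazard(logs: Iterable[EventLog], config: TaskConfig) -> pd.DataFrame:
    """Estimate the per-step predator-activation hazard from event logs.

    Every completed 100-ms step outside the safe place is one Bernoulli
    trial; a catch at step k contributes k trials and one activation.
    Returns activations/steps per threat level with a binomial SE.
    """
    steps = {lv: 0 for lv in THREAT_LEVELS}
    acts = {lv: 0 for lv in THREAT_LEVELS}
    for log in logs:
        if log.task != "task1":
            continue
        for ev in log.events:
            if ev.kind == "caught":
                steps[ev.threat_level] += ev.payload["n_checks"]
                acts[ev.threat_level] += 1
            elif ev.kind == "enter_safe":
                steps[ev.threat_level] += ev.payload.get("n_checks", 0)
    rows = []
    for lv in THREAT_LEVELS:
        n, k = steps[lv], acts[lv]
        p = k / n if n else math.nan
        se = math.sqrt(p * (1 - p) / n) if n else math.nan
        rows.append({"threat_level": lv, "steps": n, "activations": k,
                     "hazard_hat": p, "se": se})
    return pd.DataFrame(rows)


def token_availability_durations(logs: Iterable[EventLog]) -> np.ndarray:
    """Realized token availability durations (ms) from token_on payloads."""
    out = []
    for log in logs:
        for ev in log.events:
            if ev.kind == "token_on" and ev.payload and "availability" in ev.payload:
                out.append(ev.payload["availability"])
    return np.asarray(out, dtype=float)


def condition_means(decisions: pd.DataFrame) -> pd.DataFrame:
    """Per-subject 3 (threat) x 6 (loss) table of approach proportions.

    Returns one row per subject x threat x potential-loss cell with the
    mean of ``approached`` and the contributing epoch count; cells with no
    data are present with NaN and flagged ``is_empty``.
    """
    full = pd.MultiIndex.from_product(
        [decisions["subject_id"].unique(), THREAT_LEVELS, range(6)],
        names=["subject_id", "threat_level", "potential_loss"])
    g = (decisions.groupby(["subject_id", "threat_level", "potential_loss"],
                           sort=False)["approached"]
         .agg(approach_proportion="mean", n_epochs="size"))
    out = g.reindex(full).reset_index()
    out["n_epochs"] = out["n_epochs"].fillna(0).astype(int)
    out["is_empty"] = out["n_epochs"] == 0
    return out


@dataclass(frozen=True)
class QCResult:
    kept: tuple[str, ...]
    excluded: tuple[str, ...]
    performance: dict[str, int]


def uncaught_approach_counts(decisions: pd.DataFrame) -> pd.Series:
    """Performance score per subject: approached-and-survived trials.

    Decision records exist only for uncaught epochs, so the per-subject sum
    of ``approached`` counts trials on which the player approached the
    token and survived the epoch.
    """
    return decisions.groupby("subject_id")["approached"].sum()


def performance_qc(performance: pd.Series | dict, sd_threshold: float = 4.0) -> QCResult:
    """Exclude low-performing controls by a leave-one-out SD rule.

    A control is excluded when its performance score falls more than
    ``sd_threshold`` SDs below the mean of the *remaining* controls;
    exclusion is iterated to a fixed point.  A zero leave-one-out SD never
    excludes.  Raises if fewer than 3 controls are given or all would be
    excluded.
    """
    perf = dict(performance)
    if len(perf) < 3:
        raise ValueError("performance QC requires at least 3 controls")
    kept = set(perf)
    changed = True
    while changed:
        changed = False
        for subj in sorted(kept):
            others = [perf[s] for s in kept if s != subj]
            if len(others) < 2:
                break
            mu = float(np.mean(others))
            sd = float(np.std(others, ddof=1))
            if sd > 0 and perf[subj] < mu - sd_threshold * sd:
                kept.discard(subj)
                changed = True
                break
    if not kept:
        raise ValueError("performance QC excluded every control")
    excluded = tuple(sorted(set(perf) - kept))
    return QCResult(kept=tuple(sorted(kept)), excluded=excluded,
                    performance={k: int(v) for k, v in perf.items()})
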