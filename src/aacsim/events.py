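"""Timestamped behavioural event streams.

An :class:`EventLog` is the only raw-data format of the package: one
time-ordered stream of events per subject per block, serialized as JSONL
(one event per line) with the subject/block/task metadata in a sidecar
manifest or a header line.  A flat CSV export is provided for inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

EVENT_KINDS = frozenset({
    "epoch_start", "epoch_end",
    "token_on", "token_off", "token_collected",
    "key_left", "key_right", "key_up",
    "leave_safe", "enter_safe",
    "predator_wake", "caught",
    "expose_success", "expose_fail",
})


@dataclass(frozen=True)
class Event:
    """One timestamped event within a block.

    ``t`` is milliseconds from block start; ``epoch_id`` numbers epochs
    consecutively within the block; ``threat_level`` labels the epoch's
    predator.  ``payload`` carries event-specific detail such as the token
    index or the number of elapsed hazard steps at a catch.
    """

    t: float
    kind: str
    epoch_id: int
    threat_level: str
    payload: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")

    def to_json(self) -> str:
        d = {"t": self.t, "kind": self.kind, "epoch_id": self.epoch_id,
             "threat_level": self.threat_level}
        if self.payload:
            d["payload"] = self.payload
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "Event":
        d = json.loads(line)
        return cls(t=d["t"], kind=d["kind"], epoch_id=d["epoch_id"],
                   threat_level=d["threat_level"], payload=d.get("payload"))


@dataclass
class EventLog:
    """Event stream for one subject and one block of one task."""

    subject_id: str
    block_id: int
    task: str  # "task1" | "task2"
    config_hash: str
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.task not in ("task1", "task2"):
            raise ValueError(f"task must be 'task1' or 'task2', got {self.task!r}")

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def epoch_ids(self) -> list[int]:
        seen: list[int] = []
        for ev in self.events:
            if ev.kind == "epoch_start":
                seen.append(ev.epoch_id)
        return seen

    def epochs(self) -> dict[int, list[Event]]:
        """Group events by epoch, preserving order."""
        out: dict[int, list[Event]] = {}
        for ev in self.events:
            out.setdefault(ev.epoch_id, []).append(ev)
        return out

    # --- serialization ---------------------------------------------------

    def header(self) -> dict:
        return {"subject_id": self.subject_id, "block_id": self.block_id,
                "task": self.task, "config_hash": self.config_hash}

    def to_jsonl(self, path) -> None:
        """Write header line plus one event per line."""
        with open(path, "w") as fh:
            fh.write(json.dumps({"_header": self.header()}, sort_keys=True) + "\n")
            for ev in self.events:
                fh.write(ev.to_json() + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "EventLog":
        with open(path) as fh:
            first = json.loads(fh.readline())
            if "_header" not in first:
                raise ValueError(f"{path}: missing header line")
            log = cls(events=[], **first["_header"])
            for line in fh:
                line = line.strip()
                if line:
                    log.events.append(Event.from_json(line))
        return log

    def to_frame(self) -> pd.DataFrame:
        """Flat tabular view (payload flattened into extra columns)."""
        rows = []
        for ev in self.events:
            row = {"subject_id": self.subject_id, "block_id": self.block_id,
                   "task": self.task, "t": ev.t, "kind": ev.kind,
                   "epoch_id": ev.epoch_id, "threat_level": ev.threat_level}
            if ev.payload:
                row.update(ev.payload)
            rows.append(row)
        return pd.DataFrame(rows)


def write_cohort_jsonl(logs: Iterable[EventLog], path) -> None:
    """Concatenate many logs into one JSONL file (header line per block)."""
    with open(path, "w") as fh:
        for log in logs:
            fh.write(json.dumps({"_header": log.header()}, sort_keys=True) + "\n")
            for ev in log.events:
                fh.write(ev.to_json() + "\n")


def read_cohort_jsonl(path) -> list[EventLog]:
    logs: list[EventLog] = []
    with open(path) as fh:
        current: Optional[EventLog] = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            if "_header" in d:
                current = EventLog(events=[], **d["_header"])
                logs.append(current)
            else:
                if current is None:
                    raise ValueError(f"{path}: event before any header")
                current.events.append(Event(
                    t=d["t"], kind=d["kind"], epoch_id=d["epoch_id"],
                    threat_level=d["threat_level"], payload=d.get("payload")))
    return logs
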