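"""Model clock and event log.

All scientific timestamps are *model time* in milliseconds, advanced by
configurable per-stage costs, never wall-clock time. The defaults follow the
timing conventions of the attention literature the model emulates: a priming
signal is effective when it leads stimulus onset by 80-300 ms, a full
feedforward sweep of the visual hierarchy takes about 150 ms, and a full
top-down (recurrent) pass takes 100-150 ms. Decision and saccade costs are
free parameters of the artifact.

The event log is the single source of truth for what the executive did: every
stage, selection, memory access, and decision is recorded with its model-time
stamp, and several sequencing contracts (priming precedes onset, a saccade is
preceded by a disengage in the same cycle) are asserted against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterator


class SequencingError(RuntimeError):
    """A stage or action was invoked out of its contractual order."""


@dataclass(frozen=True)
class StageCosts:
    """Per-stage model-time costs in milliseconds."""

    priming_lead_ms: float = 150.0  # must lie in [80, 300]
    feedforward_ms: float = 150.0
    top_down_ms: float = 125.0  # must lie in [100, 150]
    decision_ms: float = 25.0
    saccade_ms: float = 30.0

    def __post_init__(self) -> None:
        if not (80.0 <= self.priming_lead_ms <= 300.0):
            raise ValueError("priming lead must lie in [80, 300] ms")
        if not (100.0 <= self.top_down_ms <= 150.0):
            raise ValueError("top-down pass cost must lie in [100, 150] ms")
        for name in ("feedforward_ms", "decision_ms", "saccade_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class ModelClock:
    """Monotone model-time counter with named stage costs."""

    def __init__(self, costs: StageCosts | None = None, start_ms: float = 0.0):
        self.costs = costs or StageCosts()
        self.now_ms = float(start_ms)

    def advance(self, cost_ms: float) -> float:
        if cost_ms < 0:
            raise ValueError("clock only advances")
        self.now_ms += cost_ms
        return self.now_ms


@dataclass(frozen=True)
class Event:
    t_ms: float
    component: str
    event: str
    payload: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"t_ms": self.t_ms, "component": self.component, "event": self.event,
             "payload": self.payload},
            sort_keys=True,
        )


class EventLog:
    """Append-only ordered record with non-decreasing model-time stamps."""

    def __init__(self) -> None:
        self.events: list[Event] = []

    def record(self, t_ms: float, component: str, event: str, **payload: Any) -> Event:
        if self.events and t_ms < self.events[-1].t_ms - 1e-9:
            raise SequencingError(
                f"event {event!r} at {t_ms} ms precedes last stamp {self.events[-1].t_ms} ms"
            )
        ev = Event(float(t_ms), component, event, payload)
        self.events.append(ev)
        return ev

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def filter(self, component: str | None = None, event: str | None = None) -> list[Event]:
        return [
            ev
            for ev in self.events
            if (component is None or ev.component == component)
            and (event is None or ev.event == event)
        ]

    def stages(self) -> list[str]:
        """The sequence of attentive-cycle stage labels (B, C, D, E) logged."""
        return [ev.payload["stage"] for ev in self.filter(event="stage")]

    def last_index(self, event: str) -> int:
        for i in range(len(self.events) - 1, -1, -1):
            if self.events[i].event == event:
                return i
        return -1

    def to_jsonl(self) -> str:
        return "\n".join(ev.to_json() for ev in self.events) + ("\n" if self.events else "")

    def total_stage_cost(self, costs: StageCosts) -> float:
        """Recompute total model time from the logged stages and actions.

        The clock contract is linear: the final timestamp equals the sum of
        the costs of the logged stage/action events (priming contributes its
        lead time, since the clock starts at the beginning of the priming
        window).
        """
        cost_of = {
            "B": costs.priming_lead_ms,
            "C": costs.feedforward_ms,
            "E": costs.feedforward_ms,
        }
        total = 0.0
        for ev in self.events:
            if ev.event == "stage":
                stage = ev.payload["stage"]
                if stage == "D":
                    total += ev.payload.get("cost_ms", costs.top_down_ms)
                else:
                    total += cost_of[stage]
            elif ev.event == "decision":
                total += costs.decision_ms
            elif ev.event == "saccade":
                total += costs.saccade_ms
        return total
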