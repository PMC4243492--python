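"""Memories: method long-term memory, visual working memory, task working memory.

* **mLTM** -- an associative store of cognitive-program methods indexed by
  task-descriptor terms. Retrieval is exact-term overlap scoring (deterministic
  and auditable, no embeddings): a query descriptor ranks stored methods by
  the fraction of their index keys it covers.
* **vWM Blackboard** -- holds the current attentional sample so every other
  component can read it, plus a bounded history of recent samples.
* **tWM Active Script NotePad** -- append-only trace of attentional samples,
  fixations and checkpoint outcomes as a task unfolds, the active scripts with
  their progress pointers, and a key-value store of task-relevant knowledge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Any, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .methods import CPMethod
    from .wta import AttentionalSample


# ---------------------------------------------------------------------------
# mLTM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodRecord:
    method: "CPMethod"
    index_keys: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "index_keys", frozenset(self.index_keys))
        if not self.index_keys:
            raise ValueError("index_keys must be non-empty")


class MethodLibrary:
    """Associative long-term memory for cognitive-program methods."""

    def __init__(self) -> None:
        self._records: list[MethodRecord] = []

    def __len__(self) -> int:
        return len(self._records)

    def store(self, record: MethodRecord) -> None:
        from .methods import validate_method

        report = validate_method(record.method)
        if not report.ok:
            raise ValueError(f"invalid method {record.method.name!r}: {report.violations}")
        self._records.append(record)

    def fetch(self, descriptor: Iterable[str]) -> list[MethodRecord]:
        """Rank by descending |descriptor ∩ keys| / |keys|, ties by insertion order."""
        descriptor = frozenset(descriptor)
        if not descriptor:
            raise ValueError("descriptor must be non-empty")
        scored = []
        for i, rec in enumerate(self._records):
            overlap = len(descriptor & rec.index_keys)
            if overlap:
                scored.append((-overlap / len(rec.index_keys), i, rec))
        scored.sort(key=lambda t: (t[0], t[1]))
        return [rec for _, _, rec in scored]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rec in self._records:
            payload = json.loads(rec.method.to_json())
            payload["index_keys"] = sorted(rec.index_keys)
            (directory / f"{rec.method.name}.json").write_text(
                json.dumps(payload, sort_keys=True, indent=1) + "\n"
            )

    @classmethod
    def load(cls, directory: str | Path) -> "MethodLibrary":
        from .methods import CPMethod

        lib = cls()
        for path in sorted(Path(directory).glob("*.json")):
            payload = json.loads(path.read_text())
            keys = frozenset(payload.pop("index_keys"))
            lib.store(MethodRecord(CPMethod.from_dict(payload), keys))
        return lib


# ---------------------------------------------------------------------------
# vWM Blackboard
# ---------------------------------------------------------------------------

class EmptyBlackboard(LookupError):
    """Read attempted on a blackboard holding no sample."""


class Blackboard:
    """Current attentional sample plus a bounded history of predecessors."""

    def __init__(self, capacity: int = 10):
        if capacity < 0:
            raise ValueError("capacity must be >= 0")
        self.capacity = capacity
        self.current: "AttentionalSample | None" = None
        self.current_cycle: int | None = None
        self.history: list[tuple[int, "AttentionalSample"]] = []

    def write_sample(self, sample: "AttentionalSample", cycle: int = 0) -> "Blackboard":
        if self.current is not None:
            self.history.append((self.current_cycle or 0, self.current))
            if len(self.history) > self.capacity:
                self.history = self.history[-self.capacity :]
        self.current = sample
        self.current_cycle = cycle
        return self

    def read_sample(self) -> "AttentionalSample":
        if self.current is None:
            raise EmptyBlackboard("no attentional sample on the blackboard")
        return self.current

    @property
    def empty(self) -> bool:
        return self.current is None

    def clear_current(self) -> None:
        self.current = None
        self.current_cycle = None


# ---------------------------------------------------------------------------
# tWM Active Script NotePad
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NotePadRecord:
    kind: str  # e.g. "sample", "fixation", "checkpoint", "transfer"
    cycle: int
    payload: dict[str, Any] = field(default_factory=dict)


class NotePad:
    """Append-only task-execution trace plus script progress and knowledge."""

    def __init__(self) -> None:
        self.trace: list[NotePadRecord] = []
        self.active_scripts: list[tuple[Any, int]] = []  # (script, progress pointer)
        self.knowledge: dict[str, Any] = {}

    def append(self, kind: str, cycle: int = 0, **payload: Any) -> NotePadRecord:
        if self.trace and cycle < self.trace[-1].cycle:
            raise ValueError("trace cycle stamps must be non-decreasing")
        rec = NotePadRecord(kind, cycle, payload)
        self.trace.append(rec)
        return rec

    def query(
        self,
        kind: str | None = None,
        cycle_range: tuple[int, int] | None = None,
    ) -> list[NotePadRecord]:
        out = []
        for rec in self.trace:
            if kind is not None and rec.kind != kind:
                continue
            if cycle_range is not None and not (cycle_range[0] <= rec.cycle <= cycle_range[1]):
                continue
            out.append(rec)
        return out

    def to_jsonl(self) -> str:
        lines = [
            json.dumps(
                {"kind": r.kind, "cycle": r.cycle, "payload": r.payload}, sort_keys=True
            )
            for r in self.trace
        ]
        return "\n".join(lines) + ("\n" if lines else "")
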