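"""Cognitive-program methods and scripts.

A *method* is a directed control-flow graph over four node kinds -- moving
information between components (``transfer``), executing a process
(``process``), making a selection (``select``), and setting control
parameters (``set_parameters``). Edges may carry an outcome condition
(``when``), a parallel-group annotation (branches of one group run before
their barrier join, serialized deterministically), or a ``repeat`` flag
marking the one legal kind of cycle: re-entry into the attentive loop.

Methods carry open parameter slots written as ``"$name"``; a *script* is a
method with every slot bound from a task specification, a program pointer,
and a completion status. Only scripts are runnable.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any

import networkx as nx

NODE_KINDS = ("transfer", "process", "select", "set_parameters")


@dataclass
class CPNode:
    id: str
    kind: str
    op: str
    params: dict[str, Any] = field(default_factory=dict)
    checkpoint: str | None = None  # monitored predicate name, if any

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")

    def open_slots(self) -> list[str]:
        return [
            v[1:]
            for v in self.params.values()
            if isinstance(v, str) and v.startswith("$")
        ]


@dataclass
class CPEdge:
    src: str
    dst: str
    when: str | None = None
    repeat: bool = False
    group: str | None = None


@dataclass
class CPMethod:
    name: str
    nodes: dict[str, CPNode]
    edges: list[CPEdge]

    def out_edges(self, node_id: str) -> list[CPEdge]:
        return [e for e in self.edges if e.src == node_id]

    def in_edges(self, node_id: str) -> list[CPEdge]:
        return [e for e in self.edges if e.dst == node_id]

    @property
    def start(self) -> str:
        starts = [n for n in self.nodes if not any(not e.repeat for e in self.in_edges(n))]
        if len(starts) != 1:
            raise ValueError(f"method {self.name!r} has {len(starts)} start nodes")
        return starts[0]

    @property
    def end(self) -> str:
        ends = [n for n in self.nodes if not self.out_edges(n)]
        if len(ends) != 1:
            raise ValueError(f"method {self.name!r} has {len(ends)} end nodes")
        return ends[0]

    def kind_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in NODE_KINDS}
        for node in self.nodes.values():
            counts[node.kind] += 1
        return counts

    def open_slots(self) -> set[str]:
        slots: set[str] = set()
        for node in self.nodes.values():
            slots.update(node.open_slots())
        return slots

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "nodes": [
                {
                    "id": n.id,
                    "kind": n.kind,
                    "op": n.op,
                    "params": n.params,
                    "checkpoint": n.checkpoint,
                }
                for n in self.nodes.values()
            ],
            "edges": [
                {
                    "src": e.src,
                    "dst": e.dst,
                    "when": e.when,
                    "repeat": e.repeat,
                    "group": e.group,
                }
                for e in self.edges
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CPMethod":
        nodes = {
            n["id"]: CPNode(
                n["id"], n["kind"], n["op"], dict(n.get("params", {})), n.get("checkpoint")
            )
            for n in d["nodes"]
        }
        edges = [
            CPEdge(
                e["src"], e["dst"], e.get("when"), bool(e.get("repeat", False)), e.get("group")
            )
            for e in d["edges"]
        ]
        return cls(d["name"], nodes, edges)

    @classmethod
    def from_json(cls, text: str) -> "CPMethod":
        return cls.from_dict(json.loads(text))


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_method(m: CPMethod) -> ValidationReport:
    """Structural checks: single start/end, reachability, acyclicity, slots.

    Cycles are allowed only through edges explicitly marked ``repeat``; every
    open parameter slot must carry a name (``"$"`` alone is a violation).
    """
    report = ValidationReport()
    for edge in m.edges:
        for endpoint in (edge.src, edge.dst):
            if endpoint not in m.nodes:
                report.violations.append(f"edge references unknown node {endpoint!r}")
    if report.violations:
        return report

    starts = [n for n in m.nodes if not any(not e.repeat for e in m.in_edges(n))]
    if len(starts) != 1:
        report.violations.append(f"expected exactly one start node, found {sorted(starts)}")
    ends = [n for n in m.nodes if not m.out_edges(n)]
    if len(ends) != 1:
        report.violations.append(f"expected exactly one end node, found {sorted(ends)}")

    g = nx.DiGraph()
    g.add_nodes_from(m.nodes)
    g.add_edges_from((e.src, e.dst) for e in m.edges if not e.repeat)
    if len(starts) == 1:
        reachable = nx.descendants(g, starts[0]) | {starts[0]}
        unreachable = sorted(set(m.nodes) - reachable)
        if unreachable:
            report.violations.append(f"unreachable nodes: {unreachable}")
    if not nx.is_directed_acyclic_graph(g):
        report.violations.append("cycle outside marked repeat edges")

    for node in m.nodes.values():
        for value in node.params.values():
            if isinstance(value, str) and value == "$":
                report.violations.append(f"node {node.id!r} has an unnamed open slot")
    return report


@dataclass
class CPScript:
    """An executable, fully bound method instance with a progress pointer."""

    method: CPMethod
    bindings: dict[str, Any]
    pointer: str | None = None
    status: str = "running"  # {running, done_positive, done_negative, failed}
    state: dict[str, Any] = field(default_factory=dict)
    cycles_done: int = 0

    @property
    def runnable(self) -> bool:
        return not self.method.open_slots()


class ScriptConstructionError(ValueError):
    """A method slot could not be bound from the task specification."""


def bind_method(method: CPMethod, bindings: dict[str, Any]) -> CPMethod:
    """Substitute every ``"$slot"`` parameter; error names any unbound slot."""
    bound = copy.deepcopy(method)
    missing: set[str] = set()
    for node in bound.nodes.values():
        for key, value in list(node.params.items()):
            if isinstance(value, str) and value.startswith("$"):
                slot = value[1:]
                if slot in bindings:
                    node.params[key] = bindings[slot]
                else:
                    missing.add(slot)
    if missing:
        raise ScriptConstructionError(
            f"cannot bind method {method.name!r}: unbound slots {sorted(missing)}"
        )
    return bound
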