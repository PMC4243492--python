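"""The shipped cognitive-program library: five linked method graphs.

Discrimination is the base method; covert search wraps it in a repeat cycle
with object-based inhibition of return at each disengage; overt search
extends covert search with the fixation-control chain (peripheral priority,
history bias, saccade); localize/reinterpret runs the full recurrent
localization and re-analysis and reports the attentional sample; curve
tracing composes overt search with the tracing loop.

Methods are plain data (JSON graphs); the builders here are the source of
truth and the package also ships the serialized files under
``methods_data/`` so the long-term memory can be loaded from disk.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .memory import MethodLibrary, MethodRecord
from .methods import CPEdge, CPMethod, CPNode


def _preamble(nodes: dict, edges: list) -> None:
    """Shared entry: receive task, fetch + tune method, start the cycle,
    then prime / disengage / set-parameters in parallel before the barrier."""
    for nid, kind, op, params in [
        ("receive_task", "transfer", "receive_task", {}),
        ("fetch_method", "transfer", "fetch_method", {}),
        ("tune_method", "process", "tune_method", {}),
        ("init_cycle", "process", "init_cycle", {}),
        ("prime_vh", "process", "prime_vh", {"gain": "$priming_gain"}),
        ("disengage_prev", "process", "disengage", {}),
        ("set_competition", "set_parameters", "set_parameters",
         {"theta": "$theta", "suppression_factor": "$suppression_factor"}),
        ("await_stimulus", "transfer", "await_stimulus", {}),
    ]:
        nodes[nid] = CPNode(nid, kind, op, params)
    edges += [
        CPEdge("receive_task", "fetch_method"),
        CPEdge("fetch_method", "tune_method"),
        CPEdge("tune_method", "init_cycle"),
        CPEdge("init_cycle", "prime_vh", group="pre"),
        CPEdge("init_cycle", "disengage_prev", group="pre"),
        CPEdge("init_cycle", "set_competition", group="pre"),
        CPEdge("prime_vh", "await_stimulus"),
        CPEdge("disengage_prev", "await_stimulus"),
        CPEdge("set_competition", "await_stimulus"),
    ]


def _reports(nodes: dict, edges: list) -> None:
    nodes["report_positive"] = CPNode("report_positive", "process", "report_positive")
    nodes["report_negative"] = CPNode("report_negative", "process", "report_negative")
    nodes["end"] = CPNode("end", "transfer", "end")
    edges += [CPEdge("report_positive", "end"), CPEdge("report_negative", "end")]


def method_discrimination() -> CPMethod:
    """Yes/no discrimination: one primed feedforward pass and a goal match."""
    nodes: dict[str, CPNode] = {}
    edges: list[CPEdge] = []
    _preamble(nodes, edges)
    nodes["feedforward"] = CPNode("feedforward", "process", "feedforward")
    nodes["select_cfoa"] = CPNode("select_cfoa", "select", "select_cfoa")
    nodes["transfer_cfoa"] = CPNode("transfer_cfoa", "transfer", "transfer_cfoa")
    nodes["match_goals"] = CPNode(
        "match_goals", "select", "match_goals",
        {"target_channel": "$target_channel"}, checkpoint="selection_valid",
    )
    _reports(nodes, edges)
    edges += [
        CPEdge("await_stimulus", "feedforward"),
        CPEdge("feedforward", "select_cfoa"),
        CPEdge("select_cfoa", "transfer_cfoa", when="cfoa"),
        CPEdge("select_cfoa", "report_negative", when="none"),
        CPEdge("transfer_cfoa", "match_goals"),
        CPEdge("match_goals", "report_positive", when="match"),
        CPEdge("match_goals", "report_negative", when="no_match"),
    ]
    return CPMethod("discrimination", nodes, edges)


def method_covert_search() -> CPMethod:
    """Discrimination wrapped in a repeat cycle: localize, re-analyse, match;
    on a non-match, disengage (object IOR) and re-select -- no saccades."""
    nodes: dict[str, CPNode] = {}
    edges: list[CPEdge] = []
    _preamble(nodes, edges)
    for nid, kind, op, params in [
        ("feedforward", "process", "feedforward", {}),
        ("localize", "process", "localize", {}),
        ("repass", "process", "repass", {}),
        ("transfer_cfoa", "transfer", "transfer_cfoa", {}),
        ("disengage_ior", "process", "disengage", {}),
        ("next_cycle", "process", "next_cycle", {"max_cycles": "$max_cycles"}),
    ]:
        nodes[nid] = CPNode(nid, kind, op, params)
    nodes["select_cfoa"] = CPNode(
        "select_cfoa", "select", "select_cfoa", {}, checkpoint="selection_valid"
    )
    nodes["match_goals"] = CPNode(
        "match_goals", "select", "match_goals",
        {"target_channel": "$target_channel"}, checkpoint="selection_valid",
    )
    _reports(nodes, edges)
    edges += [
        CPEdge("await_stimulus", "feedforward"),
        CPEdge("feedforward", "select_cfoa"),
        CPEdge("select_cfoa", "localize", when="cfoa"),
        CPEdge("select_cfoa", "report_negative", when="none"),
        CPEdge("localize", "repass"),
        CPEdge("repass", "transfer_cfoa"),
        CPEdge("transfer_cfoa", "match_goals"),
        CPEdge("match_goals", "report_positive", when="match"),
        CPEdge("match_goals", "disengage_ior", when="no_match"),
        CPEdge("disengage_ior", "next_cycle"),
        CPEdge("next_cycle", "feedforward", when="continue", repeat=True),
        CPEdge("next_cycle", "report_negative", when="exhausted"),
    ]
    return CPMethod("covert_search", nodes, edges)


def method_overt_search() -> CPMethod:
    """Covert search extended with fixation control: when the central field
    yields no match, compute the peripheral priority map, bias it by the
    fixation history, pick the next fixation, disengage and saccade."""
    nodes: dict[str, CPNode] = {}
    edges: list[CPEdge] = []
    _preamble(nodes, edges)
    for nid, kind, op, params in [
        ("feedforward", "process", "feedforward", {}),
        ("localize", "process", "localize", {}),
        ("repass", "process", "repass", {}),
        ("transfer_cfoa", "transfer", "transfer_cfoa", {}),
        ("disengage_ior", "process", "disengage", {}),
        ("compute_ppm", "process", "compute_ppm", {}),
        ("select_pfoa", "process", "select_pfoa", {}),
        ("compose_hbpm", "process", "compose_hbpm", {}),
        ("select_next_fixation", "select", "select_next_fixation", {}),
        ("saccade", "process", "saccade", {}),
        ("next_cycle", "process", "next_cycle", {"max_cycles": "$max_cycles"}),
    ]:
        nodes[nid] = CPNode(nid, kind, op, params)
    nodes["select_cfoa"] = CPNode(
        "select_cfoa", "select", "select_cfoa", {}, checkpoint="selection_valid"
    )
    nodes["match_goals"] = CPNode(
        "match_goals", "select", "match_goals",
        {"target_channel": "$target_channel"}, checkpoint="selection_valid",
    )
    _reports(nodes, edges)
    edges += [
        CPEdge("await_stimulus", "feedforward"),
        CPEdge("feedforward", "select_cfoa"),
        CPEdge("select_cfoa", "localize", when="cfoa"),
        CPEdge("select_cfoa", "disengage_ior", when="none"),
        CPEdge("localize", "repass"),
        CPEdge("repass", "transfer_cfoa"),
        CPEdge("transfer_cfoa", "match_goals"),
        CPEdge("match_goals", "report_positive", when="match"),
        CPEdge("match_goals", "disengage_ior", when="no_match"),
        CPEdge("disengage_ior", "compute_ppm"),
        CPEdge("compute_ppm", "select_pfoa"),
        CPEdge("select_pfoa", "compose_hbpm"),
        CPEdge("compose_hbpm", "select_next_fixation"),
        CPEdge("select_next_fixation", "saccade", when="fix"),
        CPEdge("select_next_fixation", "report_negative", when="none"),
        CPEdge("saccade", "next_cycle"),
        CPEdge("next_cycle", "feedforward", when="continue", repeat=True),
        CPEdge("next_cycle", "report_negative", when="exhausted"),
    ]
    return CPMethod("overt_search", nodes, edges)


def method_localize_reinterpret() -> CPMethod:
    """Full recurrent localization: stages B, C, a complete top-down pass (D)
    and re-analysis (E); the attentional sample goes to the blackboard and its
    input-level support is the localization answer."""
    nodes: dict[str, CPNode] = {}
    edges: list[CPEdge] = []
    _preamble(nodes, edges)
    for nid, kind, op in [
        ("feedforward", "process", "feedforward"),
        ("select_cfoa", "select", "select_cfoa"),
        ("localize", "process", "localize"),
        ("repass", "process", "repass"),
        ("transfer_sample", "transfer", "transfer_cfoa"),
    ]:
        nodes[nid] = CPNode(nid, kind, op)
    _reports(nodes, edges)
    edges += [
        CPEdge("await_stimulus", "feedforward"),
        CPEdge("feedforward", "select_cfoa"),
        CPEdge("select_cfoa", "localize", when="cfoa"),
        CPEdge("select_cfoa", "report_negative", when="none"),
        CPEdge("localize", "repass"),
        CPEdge("repass", "transfer_sample"),
        CPEdge("transfer_sample", "report_positive"),
    ]
    return CPMethod("localize_reinterpret", nodes, edges)


def method_curve_trace() -> CPMethod:
    """Curve tracing: overt search specialized with the tracing loop -- each
    cycle localizes the curve at fixation, extends the traced set, and picks
    the next fixation along the uninhibited connected curve portion."""
    nodes: dict[str, CPNode] = {}
    edges: list[CPEdge] = []
    _preamble(nodes, edges)
    nodes["trace_loop"] = CPNode(
        "trace_loop", "process", "run_trace", {"max_cycles": "$max_cycles"}
    )
    _reports(nodes, edges)
    edges += [
        CPEdge("await_stimulus", "trace_loop"),
        CPEdge("trace_loop", "report_positive", when="same"),
        CPEdge("trace_loop", "report_negative", when="different"),
    ]
    return CPMethod("curve_trace", nodes, edges)


INDEX_KEYS: dict[str, frozenset[str]] = {
    "discrimination": frozenset({"discriminate", "categorize", "identify", "central", "covert"}),
    "covert_search": frozenset({"search", "covert", "target"}),
    "overt_search": frozenset({"search", "overt", "target", "saccade"}),
    "localize_reinterpret": frozenset({"localize", "covert", "sample"}),
    "curve_trace": frozenset({"trace", "curve", "overt"}),
}

BUILDERS = {
    "discrimination": method_discrimination,
    "covert_search": method_covert_search,
    "overt_search": method_overt_search,
    "localize_reinterpret": method_localize_reinterpret,
    "curve_trace": method_curve_trace,
}


def build_library() -> MethodLibrary:
    """The five-method library, constructed in memory."""
    lib = MethodLibrary()
    for name, build in BUILDERS.items():
        lib.store(MethodRecord(build(), INDEX_KEYS[name]))
    return lib


def default_library() -> MethodLibrary:
    """Load the shipped method JSON files; fall back to the builders."""
    try:
        data_dir = resources.files("stcp").joinpath("methods_data")
        if data_dir.is_dir():
            return MethodLibrary.load(Path(str(data_dir)))
    except (FileNotFoundError, ModuleNotFoundError):
        pass
    return build_library()


def write_method_files(directory: str | Path) -> None:
    """Serialize the builder output as the on-disk method library."""
    build_library().save(directory)
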