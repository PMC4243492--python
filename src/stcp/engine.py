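"""The visual attention executive (vAE) and visual task executive (vTE).

The vAE owns the attentive cycle: it translates a task specification into
control signals (theta, priming bias, suppression parameters, localization
depth, cycle budget), initiates and terminates the stages of the selective
tuning process -- priming (B), feedforward (C) with central-focus selection,
recurrent localization (D), and re-analysis (E) -- and implements *disengage*:
lifting all surround suppression while inhibiting the pathways of the
previously attended sample (object-based inhibition of return).

The task-to-stage policy: discrimination-class tasks (discriminate,
categorize, identify) are satisfied by the first feedforward pass, so
localization depth is none and one cycle suffices; within-category
identification needs a partial recurrent pass; full localization tasks need a
complete top-down pass; search and tracing need the full cycle with
repetitions.

The vTE fetches the appropriate method from long-term memory, tunes it into a
script by binding every open slot from the task, executes it node by node
(parallel groups are serialized deterministically before their barrier), and
monitors declared checkpoints. On a checkpoint mismatch a three-step
remediation ladder applies: (1) re-select excluding the failed winner, (2)
replace the script with the next-ranked method, (3) abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Callable

import numpy as np

from .events import EventLog, ModelClock, SequencingError, StageCosts
from .fixation import (
    FHM,
    Fixation,
    Gaze,
    compose_hbpm,
    compute_ppm,
    execute_saccade,
    select_next_fixation,
    select_pfoa,
)
from .hierarchy import Activations, BiasSpec, HierarchyConfig, VisualHierarchy, build_hierarchy
from .image import ChannelImage
from .memory import Blackboard, MethodLibrary, NotePad
from .methods import CPMethod, CPScript, ScriptConstructionError, bind_method, validate_method
from .wta import AttentionalSample, ThetaWTAParams, WTAResult, recurrent_localize, select_cfoa

TASK_TYPES = (
    "discriminate",
    "categorize",
    "identify",
    "within_category_identify",
    "localize",
    "search_covert",
    "search_overt",
    "trace",
)

_DESCRIPTORS: dict[str, frozenset[str]] = {
    "discriminate": frozenset({"discriminate", "central", "covert"}),
    "categorize": frozenset({"categorize", "central", "covert"}),
    "identify": frozenset({"identify", "central", "covert"}),
    "within_category_identify": frozenset({"identify", "within_category", "covert"}),
    "localize": frozenset({"localize", "covert", "sample"}),
    "search_covert": frozenset({"search", "covert", "target"}),
    "search_overt": frozenset({"search", "overt", "target", "saccade"}),
    "trace": frozenset({"trace", "curve", "overt"}),
}


@dataclass
class TaskSpecification:
    """What the executive receives from outside: the task encoding."""

    task_type: str
    target: dict[str, Any] | None = None
    display: dict[str, Any] | None = None
    response_map: dict[str, str] = field(default_factory=dict)
    overrides: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task_type {self.task_type!r}")
        if self.task_type in ("search_covert", "search_overt", "trace") and not self.target:
            raise ValueError(f"task_type {self.task_type!r} requires a target descriptor")

    def descriptor(self) -> frozenset[str]:
        return _DESCRIPTORS[self.task_type]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TaskSpecification":
        return cls(
            task_type=d["task_type"],
            target=d.get("target"),
            display=d.get("display"),
            response_map=d.get("response_map", {}),
            overrides=d.get("overrides", {}),
        )

    @classmethod
    def from_file(cls, path: str) -> "TaskSpecification":
        import json

        import yaml

        text = open(path).read()
        data = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class ControlSignals:
    """The vAE's translation of a task into concrete attentive parameters.

    The default selection threshold is generous (theta = 0.8, i.e. the region
    admits units down to 20% of the peak) so that a compact item's full
    top-level support -- including units whose pooling window only partially
    overlaps the item -- enters one winning region and is inhibited as one
    object.
    """

    theta: float = 0.8
    bias: BiasSpec = field(default_factory=BiasSpec)
    suppression_factor: float = 0.1
    suppression_extent: int = 2
    feature_surround: tuple[str, ...] = ()
    max_cycles: int = 1
    depth: str = "none"  # {"none", "partial", "full"}
    partial_depth: int = 1
    repass: bool = False
    overt: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("theta must lie in [0, 1)")
        if self.depth not in ("none", "partial", "full"):
            raise ValueError("depth must be none, partial or full")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")

    @property
    def wta_params(self) -> ThetaWTAParams:
        return ThetaWTAParams(theta=self.theta)


@dataclass(frozen=True)
class FixationParams:
    """Fixation-control knobs (peripheral selection and history bias)."""

    pfoa_k: int = 5
    nms_radius: int = 6
    inhibit_radius_px: float = 10.0
    floor_frac: float = 0.05
    surround_px: int = 5
    lam: float = 0.85
    eps: float = 0.01
    override_ior: bool = False


def vae_translate_parameters(
    task: TaskSpecification, default_max_cycles: int = 10
) -> ControlSignals:
    """Deterministic task -> control-signal mapping (the stage policy)."""
    t = task.task_type
    if t in ("discriminate", "categorize", "identify"):
        depth, repass, max_cycles, overt = "none", False, 1, False
    elif t == "within_category_identify":
        depth, repass, max_cycles, overt = "partial", False, 1, False
    elif t == "localize":
        depth, repass, max_cycles, overt = "full", True, 1, False
    elif t == "search_covert":
        depth, repass, max_cycles, overt = "full", True, default_max_cycles, False
    elif t == "search_overt":
        depth, repass, max_cycles, overt = "full", True, default_max_cycles, True
    elif t == "trace":
        # tracing repeats one bounded-extent step per cycle, so its budget
        # scales with curve length rather than item count
        depth, repass, max_cycles, overt = "full", True, 6 * default_max_cycles, True
    else:  # pragma: no cover - guarded by TaskSpecification
        raise ValueError(f"unknown task_type {t!r}")

    gains: dict[str, float] = {}
    if task.target and task.target.get("channel"):
        gain = float(task.overrides.get("priming_gain", 2.0))
        if gain != 1.0:
            gains[task.target["channel"]] = gain
    signals = ControlSignals(
        theta=float(task.overrides.get("theta", 0.8)),
        bias=BiasSpec(channel_gains=gains),
        suppression_factor=float(task.overrides.get("suppression_factor", 0.1)),
        suppression_extent=int(task.overrides.get("suppression_extent", 2)),
        feature_surround=tuple(task.overrides.get("feature_surround", ())),
        max_cycles=int(task.overrides.get("max_cycles", max_cycles)),
        depth=task.overrides.get("depth", depth),
        partial_depth=int(task.overrides.get("partial_depth", 1)),
        repass=bool(task.overrides.get("repass", repass)),
        overt=overt,
    )
    return signals


# ---------------------------------------------------------------------------
# runtime
# ---------------------------------------------------------------------------

class Runtime:
    """Everything one task execution touches: VH, gaze, memories, clock, log."""

    def __init__(
        self,
        vh: VisualHierarchy,
        image: ChannelImage | None = None,
        world: ChannelImage | None = None,
        gaze: Gaze | None = None,
        library: MethodLibrary | None = None,
        costs: StageCosts | None = None,
        fc: FixationParams | None = None,
        seed: int = 0,
        hooks: dict[str, Callable] | None = None,
    ):
        if image is None and world is None:
            raise ValueError("a static image or a world image is required")
        self.vh = vh
        self.static_image = image
        self.world = world
        self.fc = fc or FixationParams()
        if world is not None and gaze is None:
            gaze = Gaze(world.shape, vh.config.input_shape)
        self.gaze = gaze
        self.library = library if library is not None else MethodLibrary()
        self.clock = ModelClock(costs)
        self.log = EventLog()
        self.blackboard = Blackboard()
        self.notepad = NotePad()
        self.fhm = FHM(lam=self.fc.lam, eps=self.fc.eps)
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.hooks = hooks or {}
        self.cycle = 0
        self.primed = False
        self.onset_logged = False
        self.fixations: list[Fixation] = []
        if self.gaze is not None:
            self.fixations.append(
                Fixation(self.gaze.fixation[0], self.gaze.fixation[1], "overt", 0)
            )
        self.remediation = 0
        self.log.record(self.clock.now_ms, "run", "header", seed=seed)

    def current_image(self) -> ChannelImage:
        if self.world is not None and self.gaze is not None:
            return self.gaze.view(self.world)
        assert self.static_image is not None
        return self.static_image

    @property
    def central_radius_px(self) -> float:
        return self.vh.config.central_radius_px


# ---------------------------------------------------------------------------
# vAE stage operations
# ---------------------------------------------------------------------------

def stage_prime(runtime: Runtime, signals: ControlSignals) -> None:
    """Stage B: install the priming bias during the pre-onset window."""
    runtime.vh.apply_priming(signals.bias, clock=runtime.clock, log=runtime.log)
    runtime.primed = True


def log_stimulus_onset(runtime: Runtime) -> None:
    runtime.log.record(runtime.clock.now_ms, "VH", "stimulus_onset")
    runtime.onset_logged = True


def stage_feedforward(
    runtime: Runtime, signals: ControlSignals, stage: str = "C"
) -> Activations:
    if stage == "C" and not runtime.onset_logged:
        log_stimulus_onset(runtime)
    acts = runtime.vh.feedforward(
        runtime.current_image(), clock=runtime.clock, log=runtime.log, stage=stage
    )
    return acts


def stage_select(
    runtime: Runtime,
    signals: ControlSignals,
    acts: Activations,
    exclude: set[tuple[int, int]] | None = None,
    use_hook: bool = True,
    silent: bool = False,
    within: WTAResult | None = None,
) -> WTAResult:
    extra_mask = None
    if within is not None and not within.empty:
        # stage-E re-analysis: competition restricted to the attended region
        extra_mask = np.zeros(runtime.vh.level_shape(runtime.vh.top_level), dtype=bool)
        for loc in within.region:
            extra_mask[loc] = True
    result = select_cfoa(
        runtime.vh,
        acts,
        params=signals.wta_params,
        exclude=exclude,
        extra_mask=extra_mask,
        clock=None if silent else runtime.clock,
        log=None if silent else runtime.log,
    )
    hook = runtime.hooks.get("force_cfoa") if use_hook else None
    if hook is not None:
        forced = hook(runtime, result)
        if forced is not None and (exclude is None or tuple(forced) not in exclude):
            result = WTAResult(frozenset({tuple(forced)}), tuple(forced))
    return result


def stage_localize(
    runtime: Runtime, signals: ControlSignals, acts: Activations, root: WTAResult
) -> AttentionalSample:
    depth = "full" if signals.depth == "full" else signals.partial_depth
    sample = recurrent_localize(
        runtime.vh,
        acts,
        root,
        params=signals.wta_params,
        depth=depth,
        suppress=True,
        feature_channels=signals.feature_surround,
        clock=runtime.clock,
        log=runtime.log,
    )
    runtime.blackboard.write_sample(sample, cycle=runtime.cycle)
    runtime.log.record(
        runtime.clock.now_ms, "vWM", "bb_write", cycle=runtime.cycle,
        units=sum(len(u) for u in sample.levels.values()),
    )
    runtime.notepad.append(
        "sample", cycle=runtime.cycle, root=list(sample.root),
        level0=len(sample.levels.get(0, frozenset())),
    )
    return sample


def vae_disengage(runtime: Runtime) -> None:
    """Lift all surround suppression and inhibit the attended pathways.

    Both effects are one "disengage" act; it is a no-op when nothing has been
    attended (empty blackboard).
    """
    runtime.vh.lift_surround_suppression()
    inhibited = 0
    if not runtime.blackboard.empty:
        sample = runtime.blackboard.read_sample()
        runtime.vh.inhibit_pathways(sample)
        inhibited = sum(len(u) for u in sample.levels.values())
    runtime.log.record(
        runtime.clock.now_ms, "vAE", "disengage", inhibited_units=inhibited
    )


@dataclass
class CycleResult:
    cfoa: WTAResult
    sample: AttentionalSample | None
    acts: Activations


def vae_run_cycle(
    runtime: Runtime, signals: ControlSignals, image: ChannelImage | None = None
) -> CycleResult:
    """One attentive cycle under the cycle controller's stage policy.

    Stage B runs only before stimulus onset (first cycle); stage C is the
    feedforward pass plus central-focus selection; stages D (localization at
    the signalled depth) and E (re-analysis with suppression in place, then
    re-selection) run only when the task demands them.
    """
    if image is not None:
        runtime.static_image = image
    runtime.log.record(runtime.clock.now_ms, "vAE", "cycle_start", cycle=runtime.cycle)
    if not runtime.primed:
        if runtime.onset_logged:
            raise SequencingError("priming must precede stimulus onset")
        stage_prime(runtime, signals)
    acts = stage_feedforward(runtime, signals, stage="C")
    cfoa = stage_select(runtime, signals, acts)
    sample = None
    if signals.depth != "none" and not cfoa.empty:
        sample = stage_localize(runtime, signals, acts, cfoa)
        if signals.repass:
            acts = stage_feedforward(runtime, signals, stage="E")
            reselected = stage_select(runtime, signals, acts, within=cfoa)
            if not reselected.empty:
                cfoa = reselected
    return CycleResult(cfoa, sample, acts)


# ---------------------------------------------------------------------------
# vTE: script construction, execution, monitoring
# ---------------------------------------------------------------------------

class ReplaceScript(Exception):
    """Remediation step 2: swap in the next-ranked method."""


class AbortScript(Exception):
    """Remediation step 3: give up on the task."""


def task_bindings(task: TaskSpecification, signals: ControlSignals) -> dict[str, Any]:
    bindings: dict[str, Any] = {
        "theta": signals.theta,
        "max_cycles": signals.max_cycles,
        "priming_gain": float(task.overrides.get("priming_gain", 2.0)),
        "suppression_factor": signals.suppression_factor,
    }
    if task.target and task.target.get("channel"):
        bindings["target_channel"] = task.target["channel"]
    return bindings


def vte_construct_script(
    method: CPMethod, task: TaskSpecification, signals: ControlSignals | None = None
) -> CPScript:
    """Tune a method into an executable script; errors name unbound slots."""
    report = validate_method(method)
    if not report.ok:
        raise ScriptConstructionError(f"method invalid: {report.violations}")
    signals = signals or vae_translate_parameters(task)
    bindings = task_bindings(task, signals)
    bound = bind_method(method, bindings)
    return CPScript(method=bound, bindings=bindings)


def _cfoa_features(
    runtime: Runtime, acts: Activations, cfoa: WTAResult
) -> dict[str, float]:
    assert cfoa.peak is not None
    return {
        ch: float(acts.top[ch][cfoa.peak]) for ch in runtime.vh.config.channels
    }


def _match_target(
    runtime: Runtime, script: CPScript, node_params: dict[str, Any]
) -> str:
    cfoa: WTAResult = script.state.get("cfoa")
    acts: Activations = script.state.get("acts")
    if cfoa is None or cfoa.empty:
        return "no_match"
    target_channel = node_params.get("target_channel")
    feats = _cfoa_features(runtime, acts, cfoa)
    dominant = max(sorted(feats), key=lambda ch: feats[ch])
    matched = (
        target_channel is not None
        and dominant == target_channel
        and feats[dominant] > float(node_params.get("min_response", 1e-9))
    )
    return "match" if matched else "no_match"


# -- node handlers ---------------------------------------------------------

def _h_log_transfer(rt: Runtime, script: CPScript, node, signals) -> None:
    rt.log.record(rt.clock.now_ms, "vTE", "transfer", op=node.op, node=node.id)
    rt.notepad.append("transfer", cycle=rt.cycle, op=node.op)


def _h_init_cycle(rt: Runtime, script: CPScript, node, signals) -> None:
    script.cycles_done = 1
    rt.log.record(rt.clock.now_ms, "vAE", "cycle_start", cycle=rt.cycle)


def _h_prime(rt: Runtime, script: CPScript, node, signals) -> None:
    if rt.primed:
        return  # the bias is already installed for this trial
    if rt.onset_logged:
        raise SequencingError("priming must precede stimulus onset")
    stage_prime(rt, signals)


def _h_disengage(rt: Runtime, script: CPScript, node, signals) -> None:
    vae_disengage(rt)


def _h_set_parameters(rt: Runtime, script: CPScript, node, signals) -> None:
    script.state["params"] = dict(node.params)
    rt.log.record(
        rt.clock.now_ms, "vAE", "set_parameters",
        params={k: v for k, v in sorted(node.params.items()) if not callable(v)},
    )


def _h_await_stimulus(rt: Runtime, script: CPScript, node, signals) -> None:
    if not rt.onset_logged:  # a replacement script joins the trial in flight
        log_stimulus_onset(rt)


def _h_feedforward(rt: Runtime, script: CPScript, node, signals) -> None:
    script.state["acts"] = stage_feedforward(rt, signals, stage="C")


def _h_select_cfoa(rt: Runtime, script: CPScript, node, signals) -> str:
    cfoa = stage_select(
        rt, signals, script.state["acts"], exclude=script.state.get("exclude")
    )
    script.state["cfoa"] = cfoa
    script.state["cfoa_within"] = None
    return "none" if cfoa.empty else "cfoa"


def _h_localize(rt: Runtime, script: CPScript, node, signals) -> None:
    sample = stage_localize(rt, signals, script.state["acts"], script.state["cfoa"])
    script.state["sample"] = sample


def _h_repass(rt: Runtime, script: CPScript, node, signals) -> None:
    acts = stage_feedforward(rt, signals, stage="E")
    script.state["acts"] = acts
    within = script.state.get("cfoa")
    reselected = stage_select(
        rt, signals, acts, exclude=script.state.get("exclude"), within=within,
    )
    if not reselected.empty:
        script.state["cfoa"] = reselected
        script.state["cfoa_within"] = within


def _h_match_goals(rt: Runtime, script: CPScript, node, signals) -> str:
    outcome = _match_target(rt, script, node.params)
    rt.notepad.append("checkpoint", cycle=rt.cycle, node=node.id, outcome=outcome)
    rt.log.record(rt.clock.now_ms, "vTE", "checkpoint", node=node.id, outcome=outcome)
    return outcome


def _h_report(status: str):
    def handler(rt: Runtime, script: CPScript, node, signals) -> None:
        script.status = status
        if status == "done_positive" and script.state.get("sample") is not None:
            script.state["answer"] = script.state["sample"].levels.get(0)
        rt.log.record(rt.clock.now_ms, "vTE", "report", status=status)

    return handler


def _h_next_cycle(rt: Runtime, script: CPScript, node, signals) -> str:
    if script.cycles_done >= signals.max_cycles:
        return "exhausted"
    script.cycles_done += 1
    rt.cycle += 1
    rt.vh.advance_cycle()
    rt.log.record(rt.clock.now_ms, "vAE", "cycle_start", cycle=rt.cycle)
    return "continue"


def _h_compute_ppm(rt: Runtime, script: CPScript, node, signals) -> None:
    script.state["ppm"] = compute_ppm(
        rt.current_image(), signals.bias, rt.central_radius_px, rt.fc.surround_px
    )
    rt.log.record(rt.clock.now_ms, "FC", "ppm", max=float(script.state["ppm"].grid.max()))


def _h_select_pfoa(rt: Runtime, script: CPScript, node, signals) -> None:
    script.state["pfoa"] = select_pfoa(
        script.state["ppm"], rt.fc.pfoa_k, rt.fc.nms_radius
    )


def _h_compose_hbpm(rt: Runtime, script: CPScript, node, signals) -> None:
    cfoa = script.state.get("cfoa")
    mark = None
    if cfoa is not None and not cfoa.empty:
        top = rt.vh.top_level
        center = rt.vh.unit_center_px(top, cfoa.peak)
        mark = (int(round(center[0])), int(round(center[1])))
    if mark is None and not script.state.get("pfoa"):
        # nothing to attend centrally or peripherally: empty priority map
        script.state["hbpm"] = None
        return
    script.state["hbpm"] = compose_hbpm(
        script.state["ppm"],
        mark,
        script.state.get("pfoa", []),
        rt.fhm,
        rt.gaze,
        rt.fc.inhibit_radius_px,
        rt.fc.override_ior,
    )


def _h_select_next_fixation(rt: Runtime, script: CPScript, node, signals) -> str:
    if script.state.get("hbpm") is None:
        rt.log.record(rt.clock.now_ms, "FC", "decision", kind="next_fixation", pos=None)
        script.state["next_fix"] = None
        return "none"
    fix = select_next_fixation(
        script.state["hbpm"],
        rt.gaze,
        constraint=script.state.get("constraint"),
        floor_frac=rt.fc.floor_frac,
        cycle=rt.cycle,
    )
    script.state["next_fix"] = fix
    rt.log.record(
        rt.clock.now_ms, "FC", "decision", kind="next_fixation",
        pos=list(fix.pos) if fix else None,
    )
    return "none" if fix is None else "fix"


def _h_saccade(rt: Runtime, script: CPScript, node, signals) -> None:
    rt.fhm.update(rt.gaze.fixation)
    fix: Fixation = script.state["next_fix"]
    execute_saccade(rt.gaze, fix, rt.world, log=rt.log, clock=rt.clock)
    rt.fixations.append(fix)
    rt.notepad.append("fixation", cycle=rt.cycle, pos=list(fix.pos), fix_kind=fix.kind)


def _h_run_trace(rt: Runtime, script: CPScript, node, signals) -> str:
    from .tracing import trace_loop

    outcome, state = trace_loop(rt, signals)
    script.state["trace_state"] = state
    return outcome


HANDLERS: dict[str, Callable] = {
    "receive_task": _h_log_transfer,
    "fetch_method": _h_log_transfer,
    "tune_method": _h_log_transfer,
    "transfer_cfoa": _h_log_transfer,
    "end": _h_log_transfer,
    "init_cycle": _h_init_cycle,
    "prime_vh": _h_prime,
    "disengage": _h_disengage,
    "set_parameters": _h_set_parameters,
    "await_stimulus": _h_await_stimulus,
    "feedforward": _h_feedforward,
    "select_cfoa": _h_select_cfoa,
    "localize": _h_localize,
    "repass": _h_repass,
    "match_goals": _h_match_goals,
    "report_positive": _h_report("done_positive"),
    "report_negative": _h_report("done_negative"),
    "next_cycle": _h_next_cycle,
    "compute_ppm": _h_compute_ppm,
    "select_pfoa": _h_select_pfoa,
    "compose_hbpm": _h_compose_hbpm,
    "select_next_fixation": _h_select_next_fixation,
    "saccade": _h_saccade,
    "run_trace": _h_run_trace,
}


# -- monitoring ------------------------------------------------------------

def _checkpoint_ok(rt: Runtime, script: CPScript, predicate: str) -> bool:
    """Evaluate a declared checkpoint predicate against the runtime state."""
    if predicate == "selection_valid":
        cfoa: WTAResult = script.state.get("cfoa")
        if cfoa is None or cfoa.empty:
            return True  # "no winner" is a valid (negative) observation
        signals: ControlSignals = script.state["signals"]
        reference = stage_select(
            rt, signals, script.state["acts"],
            exclude=script.state.get("exclude"), use_hook=False, silent=True,
            within=script.state.get("cfoa_within"),
        )
        return reference.peak == cfoa.peak
    if predicate == "sample_rooted":
        from .wta import sample_is_valid

        sample = script.state.get("sample")
        return sample is None or sample_is_valid(rt.vh, sample)
    raise ValueError(f"unknown checkpoint predicate {predicate!r}")


def vte_monitor(rt: Runtime, script: CPScript, node, outcome: str | None) -> str | None:
    """Check a monitored node; on mismatch walk the remediation ladder.

    Returns the (possibly revised) outcome; raises ReplaceScript / AbortScript
    for ladder steps 2 and 3.
    """
    if node.checkpoint is None:
        return outcome
    while not _checkpoint_ok(rt, script, node.checkpoint):
        rt.remediation += 1
        step = rt.remediation
        if step == 1:
            failed = script.state["cfoa"].peak
            rt.log.record(
                rt.clock.now_ms, "vTE", "remediate", step=1, action="re-select",
                excluded=list(failed) if failed else None,
            )
            exclude = script.state.setdefault("exclude", set())
            if failed is not None:
                exclude.add(failed)
            signals: ControlSignals = script.state["signals"]
            script.state["cfoa"] = stage_select(
                rt, signals, script.state["acts"], exclude=exclude
            )
            script.state["cfoa_within"] = None
            if node.op == "match_goals":
                outcome = _match_target(rt, script, node.params)
            elif node.op == "select_cfoa":
                outcome = "none" if script.state["cfoa"].empty else "cfoa"
        elif step == 2:
            rt.log.record(
                rt.clock.now_ms, "vTE", "remediate", step=2, action="replace-script"
            )
            raise ReplaceScript()
        else:
            rt.log.record(rt.clock.now_ms, "vTE", "remediate", step=3, action="abort")
            raise AbortScript("checkpoint mismatch persisted through the ladder")
    return outcome


# -- executor --------------------------------------------------------------

def _pick_edge(edges, outcome: str | None):
    for e in edges:
        if e.when is not None and e.when == outcome:
            return e
    for e in edges:
        if e.when is None:
            return e
    raise SequencingError(
        f"no out-edge matches outcome {outcome!r} from {edges[0].src!r}"
    )


def _run_branch(rt: Runtime, script: CPScript, signals, start_id: str) -> str:
    """Execute a parallel branch up to (not including) its join node."""
    method = script.method
    node_id = start_id
    while True:
        if len([e for e in method.in_edges(node_id) if not e.repeat]) > 1:
            return node_id  # join / barrier
        node = method.nodes[node_id]
        script.pointer = node_id
        outcome = HANDLERS[node.op](rt, script, node, signals)
        outcome = vte_monitor(rt, script, node, outcome)
        out = method.out_edges(node_id)
        if not out:
            return node_id
        node_id = _pick_edge(out, outcome).dst


def execute_script(
    rt: Runtime, script: CPScript, signals: ControlSignals
) -> str:
    """Walk the script graph to completion; returns the final status."""
    if not script.runnable:
        raise ScriptConstructionError(
            f"script has open slots {sorted(script.method.open_slots())}"
        )
    script.state["signals"] = signals
    rt.notepad.active_scripts.append((script, 0))
    method = script.method
    node_id = method.start
    budget = (signals.max_cycles + 2) * (len(method.nodes) + 4) * 4
    steps = 0
    while True:
        steps += 1
        if steps > budget:
            raise AbortScript("script step budget exceeded")
        node = method.nodes[node_id]
        script.pointer = node_id
        outcome = HANDLERS[node.op](rt, script, node, signals)
        outcome = vte_monitor(rt, script, node, outcome)
        if script.status != "running":
            return script.status
        out = method.out_edges(node_id)
        if not out:
            return script.status
        groups = {e.group for e in out}
        if len(out) > 1 and None not in groups:
            # parallel fork: serialize branches deterministically, then join
            joins = set()
            for e in sorted(out, key=lambda e: (e.group or "", e.dst)):
                joins.add(_run_branch(rt, script, signals, e.dst))
            if len(joins) != 1:
                raise SequencingError(f"parallel branches do not share a barrier: {joins}")
            node_id = joins.pop()
            continue
        node_id = _pick_edge(out, outcome).dst


@dataclass
class RunResult:
    outcome: str  # {"done_positive", "done_negative", "failed"}
    reason: str | None
    log: EventLog
    notepad: NotePad
    runtime: Runtime
    script: CPScript | None = None

    @property
    def answer(self):
        return self.script.state.get("answer") if self.script else None


def vte_run(
    task: TaskSpecification,
    image: ChannelImage | None = None,
    world: ChannelImage | None = None,
    library: MethodLibrary | None = None,
    hierarchy_config: HierarchyConfig | None = None,
    runtime: Runtime | None = None,
    costs: StageCosts | None = None,
    fc: FixationParams | None = None,
    seed: int = 0,
    hooks: dict[str, Callable] | None = None,
) -> RunResult:
    """Full task execution: fetch, tune, execute, monitor.

    Provide either a retina-sized ``image`` (covert tasks) or a larger
    ``world`` (overt tasks). A prepared ``runtime`` overrides both.
    """
    if runtime is None:
        src = world if world is not None else image
        if src is None:
            raise ValueError("an image or world is required")
        if hierarchy_config is None:
            hierarchy_config = HierarchyConfig(
                input_shape=(64, 64) if world is not None else src.shape,
                channels=src.channels,
            )
        vh = build_hierarchy(hierarchy_config)
        if library is None:
            from .library import default_library

            library = default_library()
        runtime = Runtime(
            vh, image=image, world=world, library=library, costs=costs, fc=fc,
            seed=seed, hooks=hooks,
        )
    rt = runtime
    rt.log.record(rt.clock.now_ms, "vTE", "task_received", task_type=task.task_type)
    records = rt.library.fetch(task.descriptor()) if len(rt.library) else []
    if not records:
        rt.log.record(rt.clock.now_ms, "vTE", "report", status="failed", reason="no method")
        return RunResult("failed", "no method", rt.log, rt.notepad, rt)
    signals = vae_translate_parameters(task)
    method_idx = 0
    script: CPScript | None = None
    while method_idx < len(records):
        record = records[method_idx]
        rt.log.record(
            rt.clock.now_ms, "mLTM", "fetched", method=record.method.name, rank=method_idx
        )
        try:
            script = vte_construct_script(record.method, task, signals)
        except ScriptConstructionError as exc:
            rt.log.record(rt.clock.now_ms, "vTE", "report", status="failed", reason=str(exc))
            return RunResult("failed", str(exc), rt.log, rt.notepad, rt, script=None)
        try:
            status = execute_script(rt, script, signals)
            return RunResult(status, None, rt.log, rt.notepad, rt, script=script)
        except ReplaceScript:
            method_idx += 1
            continue
        except AbortScript as exc:
            rt.log.record(rt.clock.now_ms, "vTE", "report", status="failed", reason=str(exc))
            return RunResult("failed", str(exc), rt.log, rt.notepad, rt, script=script)
    rt.log.record(
        rt.clock.now_ms, "vTE", "report", status="failed", reason="methods exhausted"
    )
    return RunResult("failed", "methods exhausted", rt.log, rt.notepad, rt, script=script)
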