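"""Executive: parameter translation, the attentive cycle, monitoring."""

import numpy as np
import pytest

from stcp.engine import (
    ControlSignals,
    FixationParams,
    Runtime,
    TaskSpecification,
    vae_disengage,
    vae_run_cycle,
    vae_translate_parameters,
    vte_run,
)
from stcp.events import SequencingError, StageCosts
from stcp.hierarchy import HierarchyConfig, build_hierarchy
from stcp.library import default_library
from stcp.memory import MethodLibrary
from stcp.stimuli import (
    DisplaySpec,
    make_cluttered_display,
    make_discrimination_display,
    make_ring_display,
)


@pytest.mark.parametrize(
    "task_type,depth,repass,multi_cycle",
    [
        ("discriminate", "none", False, False),
        ("categorize", "none", False, False),
        ("identify", "none", False, False),
        ("within_category_identify", "partial", False, False),
        ("localize", "full", True, False),
        ("search_covert", "full", True, True),
        ("search_overt", "full", True, True),
        ("trace", "full", True, True),
    ],
)
def test_stage_policy_translation(task_type, depth, repass, multi_cycle):
    target = {"channel": "x"} if task_type in ("search_covert", "search_overt", "trace") else None
    signals = vae_translate_parameters(TaskSpecification(task_type=task_type, target=target))
    assert signals.depth == depth
    assert signals.repass == repass
    assert (signals.max_cycles > 1) == multi_cycle


def test_unknown_task_type_rejected():
    with pytest.raises(ValueError):
        TaskSpecification(task_type="observe")


def test_search_without_target_rejected():
    with pytest.raises(ValueError):
        TaskSpecification(task_type="search_covert")


def _disc_runtime(seed=0, class_id="A"):
    spec = DisplaySpec(channels=("featA", "featB"), seed=seed)
    image, _ = make_discrimination_display(spec, class_id)
    vh = build_hierarchy(HierarchyConfig(input_shape=image.shape, channels=image.channels))
    return Runtime(vh, image=image, library=default_library(), seed=seed)


class TestRunCycle:
    def test_depth_none_logs_only_b_and_c(self):
        rt = _disc_runtime()
        task = TaskSpecification(task_type="discriminate", target={"channel": "featA"})
        vae_run_cycle(rt, vae_translate_parameters(task))
        assert rt.log.stages() == ["B", "C"]

    def test_depth_partial_adds_partial_d(self):
        rt = _disc_runtime()
        signals = vae_translate_parameters(
            TaskSpecification(task_type="within_category_identify")
        )
        vae_run_cycle(rt, signals)
        assert rt.log.stages() == ["B", "C", "D"]
        d_event = rt.log.filter(event="stage")[-1]
        assert d_event.payload["depth"] == 1

    def test_depth_full_runs_b_c_d_e_in_order(self):
        rt = _disc_runtime()
        signals = vae_translate_parameters(
            TaskSpecification(task_type="localize", target={"channel": "featA"})
        )
        vae_run_cycle(rt, signals)
        assert rt.log.stages() == ["B", "C", "D", "E"]

    def test_clock_arithmetic_for_one_bc_cycle(self):
        rt = _disc_runtime()
        task = TaskSpecification(task_type="discriminate", target={"channel": "featA"})
        vae_run_cycle(rt, vae_translate_parameters(task))
        onset = rt.log.filter(event="stimulus_onset")[0]
        assert onset.t_ms == 150.0  # one priming lead after t=0
        stage_c = [e for e in rt.log.filter(event="stage") if e.payload["stage"] == "C"][0]
        assert stage_c.t_ms == 300.0  # decision starts at onset + feedforward
        decision = rt.log.filter(event="decision")[0]
        assert decision.t_ms == 325.0

    def test_priming_after_onset_is_a_sequencing_error(self):
        rt = _disc_runtime()
        task = TaskSpecification(task_type="discriminate", target={"channel": "featA"})
        signals = vae_translate_parameters(task)
        vae_run_cycle(rt, signals)
        rt.primed = False  # force a second priming attempt post-onset
        with pytest.raises(SequencingError):
            vae_run_cycle(rt, signals)


class TestDisengage:
    def test_noop_on_fresh_system(self):
        rt = _disc_runtime()
        vae_disengage(rt)
        ev = rt.log.filter(event="disengage")[0]
        assert ev.payload["inhibited_units"] == 0

    def test_lifts_suppression_and_inhibits_sample(self):
        rt = _disc_runtime()
        signals = vae_translate_parameters(
            TaskSpecification(task_type="localize", target={"channel": "featA"})
        )
        result = vae_run_cycle(rt, signals)
        assert result.sample is not None
        suppressed_before = any(
            (arr < 1.0).any() for lvl in rt.vh.suppression for arr in lvl.values()
        )
        assert suppressed_before
        vae_disengage(rt)
        assert all(
            (arr == 1.0).all() for lvl in rt.vh.suppression for arr in lvl.values()
        )
        lvl, r, c = result.sample.root
        ch = next(ch for ch, rr, cc in result.sample.levels[lvl] if (rr, cc) == (r, c))
        assert rt.vh.inhibited(lvl, ch)[r, c]

    def test_two_identical_items_attended_in_turn(self):
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=21)
        image, gt = make_cluttered_display(
            spec, n_clutter=1, target_features={"colorB": 1.0},
            clutter_features={"colorB": 1.0}, min_separation=24, align=8, jitter=0.0,
        )
        vh = build_hierarchy(
            HierarchyConfig(input_shape=image.shape, channels=image.channels,
                            central_radius_deg=23.0)
        )
        rt = Runtime(vh, image=image, library=default_library(), seed=21)
        signals = vae_translate_parameters(
            TaskSpecification(task_type="localize", target={"channel": "colorA"})
        )
        first = vae_run_cycle(rt, signals)
        vae_disengage(rt)
        rt.cycle += 1
        rt.vh.advance_cycle()
        second = vae_run_cycle(rt, signals)
        assert not first.cfoa.empty and not second.cfoa.empty
        assert first.cfoa.peak != second.cfoa.peak


class TestVteRun:
    def test_empty_method_memory_fails_cleanly(self):
        spec = DisplaySpec(channels=("featA", "featB"), seed=0)
        image, _ = make_discrimination_display(spec, "A")
        task = TaskSpecification(task_type="discriminate", target={"channel": "featA"})
        result = vte_run(task, image=image, library=MethodLibrary(), seed=0)
        assert result.outcome == "failed"
        assert result.reason == "no method"

    def test_clock_linearity_total_time_recomputable_from_log(self):
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=31)
        image, _ = make_ring_display(spec, n_items=4, target_index=2, ring_radius=7.0,
                                     jitter=0.2)
        task = TaskSpecification(task_type="search_covert", target={"channel": "colorA"},
                                 overrides={"max_cycles": 6})
        result = vte_run(task, image=image, seed=31)
        costs = StageCosts()
        assert result.log.events[-1].t_ms == pytest.approx(
            result.log.total_stage_cost(costs)
        )

    def test_reproducible_event_logs_byte_identical(self):
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=41)
        image, _ = make_ring_display(spec, n_items=4, target_index=1, ring_radius=7.0,
                                     jitter=0.2)
        task = TaskSpecification(task_type="search_covert", target={"channel": "colorA"},
                                 overrides={"max_cycles": 6})
        log1 = vte_run(task, image=image, seed=7).log.to_jsonl()
        log2 = vte_run(task, image=image, seed=7).log.to_jsonl()
        assert log1 == log2
        log3 = vte_run(task, image=image, seed=8).log.to_jsonl()
        assert log3 != log1  # the seed is part of the logged header

    def test_termination_within_cycle_budget(self):
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=51)
        image, _ = make_ring_display(spec, n_items=6, target_index=None, ring_radius=7.0)
        task = TaskSpecification(task_type="search_covert", target={"channel": "colorA"},
                                 overrides={"max_cycles": 3})
        result = vte_run(task, image=image, seed=51)
        assert result.outcome == "done_negative"
        assert result.script.cycles_done <= 3


def _search_setup(seed=61):
    spec = DisplaySpec(channels=("colorA", "colorB"), seed=seed)
    image, gt = make_ring_display(spec, n_items=4, target_index=2, ring_radius=7.0,
                                  jitter=0.2)
    task = TaskSpecification(task_type="search_covert", target={"channel": "colorA"},
                             overrides={"max_cycles": 8})
    return image, gt, task


class TestMonitorRemediation:
    def test_clean_run_has_no_remediation(self):
        image, gt, task = _search_setup()
        result = vte_run(task, image=image, seed=61)
        assert result.outcome == "done_positive"
        assert result.log.filter(event="remediate") == []

    def test_injected_wrong_selection_is_remediated_and_run_succeeds(self):
        image, gt, task = _search_setup()
        fired = {"n": 0}

        def force_wrong(rt, result):
            # misreport the winner once: point the selection at a distractor
            if fired["n"] or result.empty:
                return None
            fired["n"] += 1
            distractor = gt.item_positions[0]  # not the target (index 2)
            return (distractor[0] // 8, distractor[1] // 8)

        result = vte_run(task, image=image, seed=61, hooks={"force_cfoa": force_wrong})
        assert result.outcome == "done_positive"
        steps = [e.payload["step"] for e in result.log.filter(event="remediate")]
        assert steps == [1]

    def test_persistent_mismatch_walks_the_full_ladder_and_aborts(self):
        image, gt, task = _search_setup()
        calls = {"n": 0}

        def always_wrong(rt, result):
            # persistently misreport the winner, rotating over the distractors
            # so the exclusion from ladder step 1 never cures it
            if result.empty:
                return None
            distractors = [p for i, p in enumerate(gt.item_positions) if i != 2]
            d = distractors[calls["n"] % len(distractors)]
            calls["n"] += 1
            return (d[0] // 8, d[1] // 8)

        result = vte_run(task, image=image, seed=61, hooks={"force_cfoa": always_wrong})
        assert result.outcome == "failed"
        steps = [e.payload["step"] for e in result.log.filter(event="remediate")]
        assert steps == [1, 2, 3]
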