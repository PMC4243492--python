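"""End-to-end behavior of the five shipped cognitive programs."""

import numpy as np
import pytest

from stcp.engine import FixationParams, TaskSpecification, vte_run
from stcp.experiments import (
    covert_ior_sequence,
    overt_ring_scan,
    priming_benefit,
    reanalysis_comparison,
    trace_one,
    tracing_accuracy,
)
from stcp.hierarchy import HierarchyConfig
from stcp.stimuli import DisplaySpec, make_discrimination_display, make_ring_display


class TestDiscriminationCP:
    def _run(self, class_id, seed=0):
        spec = DisplaySpec(channels=("featA", "featB"), seed=seed)
        image, _ = make_discrimination_display(spec, class_id)
        task = TaskSpecification(task_type="discriminate", target={"channel": "featA"})
        return vte_run(task, image=image, seed=seed)

    def test_class_a_display_matches_positively(self):
        assert self._run("A").outcome == "done_positive"

    def test_class_b_display_completes_negatively(self):
        assert self._run("B").outcome == "done_negative"

    def test_step_order_follows_the_flowchart(self):
        result = self._run("A")
        events = [(e.component, e.event, e.payload.get("stage") or e.payload.get("op"))
                  for e in result.log.events]
        # task reception and method fetch precede priming; priming precedes
        # onset; onset precedes the feedforward stage; selection precedes the
        # goal match; the run ends with a report
        def index_of(pred):
            return next(i for i, e in enumerate(events) if pred(e))

        i_task = index_of(lambda e: e[1] == "task_received")
        i_fetch = index_of(lambda e: e[1] == "fetched")
        i_prime = index_of(lambda e: e[2] == "B")
        i_onset = index_of(lambda e: e[1] == "stimulus_onset")
        i_ff = index_of(lambda e: e[2] == "C")
        i_dec = index_of(lambda e: e[1] == "decision")
        i_match = index_of(lambda e: e[1] == "checkpoint")
        i_report = index_of(lambda e: e[1] == "report")
        assert i_task < i_fetch < i_prime < i_onset < i_ff < i_dec < i_match < i_report


class TestCovertSearchCP:
    def test_target_found_within_item_budget_with_zero_saccades(self):
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=71)
        image, _ = make_ring_display(spec, n_items=4, target_index=3, ring_radius=7.0,
                                     jitter=0.2)
        task = TaskSpecification(task_type="search_covert", target={"channel": "colorA"},
                                 overrides={"max_cycles": 8})
        result = vte_run(task, image=image, seed=71)
        assert result.outcome == "done_positive"
        assert result.script.cycles_done <= 4
        assert result.log.filter(event="saccade") == []

    def test_target_absent_exhausts_negatively(self):
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=72)
        image, _ = make_ring_display(spec, n_items=4, target_index=None, ring_radius=7.0)
        task = TaskSpecification(task_type="search_covert", target={"channel": "colorA"},
                                 overrides={"max_cycles": 6})
        result = vte_run(task, image=image, seed=72)
        assert result.outcome == "done_negative"
        assert result.script.cycles_done <= 6

    def test_each_repeat_preceded_by_a_disengage(self):
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=73)
        image, _ = make_ring_display(spec, n_items=4, target_index=None, ring_radius=7.0)
        task = TaskSpecification(task_type="search_covert", target={"channel": "colorA"},
                                 overrides={"max_cycles": 4})
        result = vte_run(task, image=image, seed=73)
        events = result.log.events
        starts = [i for i, e in enumerate(events)
                  if e.event == "cycle_start" and e.payload["cycle"] > 0]
        for i in starts:
            preceding = [e.event for e in events[:i]]
            assert "disengage" in preceding

    def test_object_ior_scan_visits_distinct_items(self):
        out = covert_ior_sequence(n_items=3, seed=9)
        assert out["repeats"] == 0
        assert out["items_seen"] == 3
        assert out["outcome"] == "done_negative"


class TestOvertSearchCP:
    def _world_task(self, seed, target_index):
        spec = DisplaySpec(width=160, height=160, channels=("colorA", "colorB"),
                           seed=seed)
        world, gt = make_ring_display(spec, n_items=6, target_index=target_index,
                                      ring_radius=7.0)
        hc = HierarchyConfig(input_shape=(64, 64), channels=world.channels,
                             central_radius_deg=5.0)
        task = TaskSpecification(task_type="search_overt", target={"channel": "colorA"},
                                 overrides={"max_cycles": 14})
        return world, gt, hc, task

    def test_peripheral_target_needs_at_least_one_saccade(self):
        world, gt, hc, task = self._world_task(81, target_index=2)
        result = vte_run(task, world=world, seed=81, hierarchy_config=hc,
                         fc=FixationParams(lam=1.0, eps=0.0, inhibit_radius_px=6.0))
        assert result.outcome == "done_positive"
        assert len(result.log.filter(event="saccade")) >= 1

    def test_central_target_needs_no_saccade(self):
        spec = DisplaySpec(width=160, height=160, channels=("colorA", "colorB"),
                           seed=82)
        world, _ = make_ring_display(spec, n_items=1, target_index=0, ring_radius=0.5,
                                     item_half=1)
        hc = HierarchyConfig(input_shape=(64, 64), channels=world.channels,
                             central_radius_deg=5.0)
        task = TaskSpecification(task_type="search_overt", target={"channel": "colorA"},
                                 overrides={"max_cycles": 4})
        result = vte_run(task, world=world, seed=82, hierarchy_config=hc)
        assert result.outcome == "done_positive"
        assert result.log.filter(event="saccade") == []

    def test_exhaustive_ring_scan_no_repeats(self):
        for n in (4, 6):
            out = overt_ring_scan(n, seed=83)
            assert out["outcome"] == "done_negative"
            assert out["unique"] == n
            assert out["repeats"] == 0
            assert out["off_item_fixations"] == 0


class TestLocalizeReinterpretCP:
    def test_sample_written_once_and_answer_is_item_support(self):
        from stcp.stimuli import make_cluttered_display

        spec = DisplaySpec(channels=("colorA", "colorB"), seed=91)
        image, gt = make_cluttered_display(spec, n_clutter=0, align=8, jitter=0.0)
        hc = HierarchyConfig(input_shape=image.shape, channels=image.channels,
                             central_radius_deg=23.0)
        task = TaskSpecification(task_type="localize", target={"channel": "colorA"})
        result = vte_run(task, image=image, seed=91, hierarchy_config=hc)
        assert result.outcome == "done_positive"
        assert len(result.log.filter(event="bb_write")) == 1
        answer_locs = {(r, c) for _, r, c in result.answer}
        pos = gt.item_positions[0]
        expected = {(pos[0] - 4 + r, pos[1] - 4 + c) for r in range(8) for c in range(8)}
        assert answer_locs == expected

    def test_reanalysis_never_degrades_attended_response(self):
        out = reanalysis_comparison(n_displays=25, seed=13)
        assert out["not_worse"] == 25


class TestCurveTraceCP:
    def test_same_and_different_judgments_with_subset_soundness(self):
        out = tracing_accuracy(n_displays=10, seed=14)
        assert out["correct"] == 10
        assert out["subset_ok"] == 10

    def test_rt_grows_with_along_curve_distance(self):
        rts = {}
        for d in (2.2, 4.4):
            vals = []
            for i in range(5):
                _w, _gt, _res, state = trace_one(
                    800 + i, same_curve=True, distance_deg=d, n_curves=1
                )
                assert state.outcome == "same"
                vals.append(state.rt_ms)
            rts[d] = np.mean(vals)
        assert rts[4.4] > rts[2.2]

    def test_whole_curve_in_central_field_needs_no_saccade(self):
        from stcp.hierarchy import HierarchyConfig as HC
        from stcp.stimuli import make_curve_display
        from stcp.tracing import run_curve_trace

        spec = DisplaySpec(width=256, height=256, deg_per_pixel=0.1,
                           channels=("curve", "marker"), seed=15)
        world, gt = make_curve_display(spec, n_curves=1, curve_length=1.5,
                                       n_markers=2, same_curve=True,
                                       marker_arc_sep=1.0)
        hc = HC(input_shape=(64, 64), channels=world.channels,
                central_radius_deg=2.0, deg_per_pixel=0.1)
        task = TaskSpecification(task_type="trace", target={"channel": "curve"})
        result, state = run_curve_trace(task, world, seed=15, hierarchy_config=hc)
        assert state.outcome == "same"
        assert result.log.filter(event="saccade") == []


class TestPrimingBenefit:
    def test_primed_search_is_never_slower_on_paired_displays(self):
        out = priming_benefit(n_pairs=25, seed=16)
        assert out["primed_not_worse"] >= 24
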