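"""Canonical simulation experiments at desk scale.

Each function sets up one of the study conditions the model is meant to
reproduce -- the display geometry, the task, and the parameters -- runs the
executive, and returns summary quantities. Tests and the acceptance script
share these so the conditions are defined exactly once.

Geometry conventions used throughout (all configurable per call):

* covert displays: a 64 x 64 retina at 0.5 deg/px with a 10 deg central
  attentional field; search rings of radius 7 deg lie inside it;
* overt search: a 160 x 160 world viewed through the 64 x 64 retina with a
  5 deg central field, ring radius 7 deg, so every ring item stays on the
  retina from any ring fixation while remaining peripheral;
* curve tracing: a 256 x 256 world at 0.1 deg/px with a 1 deg central field,
  marker separations spanning 2.2-8.8 deg of arc along the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import FixationParams, TaskSpecification, vte_run
from .hierarchy import HierarchyConfig
from .stimuli import (
    DisplaySpec,
    PlacementError,
    make_cluttered_display,
    make_curve_display,
    make_ring_display,
)
from .tracing import run_curve_trace

TRACE_DISTANCES_DEG = (2.2, 3.85, 5.5, 7.15, 8.8)


def covert_search_cycles(
    seed: int,
    n_items: int = 6,
    primed: bool = True,
    target_index: int | None = None,
    max_cycles: int = 12,
) -> tuple[str, int]:
    """Run covert search on a jittered ring; return (outcome, cycles used)."""
    rng = np.random.default_rng(seed)
    spec = DisplaySpec(channels=("colorA", "colorB"), seed=seed)
    if target_index is None:
        target_index = int(rng.integers(n_items))
    image, _gt = make_ring_display(
        spec, n_items=n_items, target_index=target_index, ring_radius=7.0, jitter=0.2
    )
    overrides = {"max_cycles": max_cycles}
    if not primed:
        overrides["priming_gain"] = 1.0
    task = TaskSpecification(
        task_type="search_covert", target={"channel": "colorA"}, overrides=overrides
    )
    result = vte_run(task, image=image, seed=seed)
    return result.outcome, result.script.cycles_done


def priming_benefit(n_pairs: int = 100, seed: int = 0) -> dict:
    """Paired primed-vs-unprimed covert search over matched displays."""
    wins = 0
    for i in range(n_pairs):
        s = seed * 10_000 + i
        _, primed_cycles = covert_search_cycles(s, primed=True)
        _, unprimed_cycles = covert_search_cycles(s, primed=False)
        wins += primed_cycles <= unprimed_cycles
    return {"n": n_pairs, "primed_not_worse": wins, "fraction": wins / n_pairs}


def overt_ring_scan(
    n_items: int,
    seed: int = 0,
    max_cycles: int | None = None,
) -> dict:
    """Exhaustive overt scan of an all-identical ring under undecayed IOR.

    Returns the outcome, the item index sequence visited, and repeat count.
    """
    spec = DisplaySpec(width=160, height=160, channels=("colorA", "colorB"), seed=seed)
    world, gt = make_ring_display(
        spec, n_items=n_items, target_index=None, ring_radius=7.0, item_half=1
    )
    hc = HierarchyConfig(
        input_shape=(64, 64), channels=world.channels, central_radius_deg=5.0
    )
    task = TaskSpecification(
        task_type="search_overt",
        target={"channel": "colorA"},
        overrides={"max_cycles": max_cycles or (2 * n_items)},
    )
    result = vte_run(
        task, world=world, seed=seed, hierarchy_config=hc,
        fc=FixationParams(lam=1.0, eps=0.0, inhibit_radius_px=6.0),
    )
    items = gt.item_positions
    visited = []
    for fix in result.runtime.fixations[1:]:
        d, idx = min(
            (max(abs(items[i][0] - fix.row), abs(items[i][1] - fix.col)), i)
            for i in range(len(items))
        )
        visited.append(idx if d <= 2 else None)
    return {
        "outcome": result.outcome,
        "visited": visited,
        "n_items": n_items,
        "unique": len({v for v in visited if v is not None}),
        "repeats": len(visited) - len(set(visited)),
        "off_item_fixations": sum(v is None for v in visited),
    }


def _trace_spec(seed: int) -> DisplaySpec:
    return DisplaySpec(
        width=256, height=256, deg_per_pixel=0.1, channels=("curve", "marker"), seed=seed
    )


def trace_one(
    seed: int,
    same_curve: bool,
    distance_deg: float = 4.4,
    n_curves: int = 2,
    margin_deg: float = 0.5,
):
    """Generate one tracing display and run the tracer on it.

    The curve length is the marker separation plus a small margin on each
    side, so the work the tracer must do scales with the separation (a large
    margin would add variable exploration of the stub beyond the markers).
    """
    spec = _trace_spec(seed)
    world, gt = make_curve_display(
        spec,
        n_curves=n_curves,
        curve_length=distance_deg + 2 * margin_deg,
        n_markers=2,
        same_curve=same_curve,
        marker_arc_sep=distance_deg,
    )
    task = TaskSpecification(task_type="trace", target={"channel": "curve"})
    result, state = run_curve_trace(task, world, seed=seed)
    return world, gt, result, state


def tracing_accuracy(n_displays: int = 50, seed: int = 0) -> dict:
    """Same/different accuracy and traced-subset soundness on random displays."""
    correct = 0
    subset_ok = 0
    n_done = 0
    i = 0
    while n_done < n_displays:
        s = seed * 100_000 + i
        i += 1
        same = n_done % 2 == 0
        try:
            _world, gt, _res, state = trace_one(s, same_curve=same)
        except PlacementError:
            continue
        n_done += 1
        correct += state.outcome == gt.label
        start = state.fixations[0].pos
        cid = next(
            (k for k, pix in enumerate(gt.curve_pixel_sets) if start in pix), None
        )
        subset_ok += cid is not None and state.traced <= set(gt.curve_pixel_sets[cid])
    return {
        "n": n_displays,
        "correct": correct,
        "accuracy": correct / n_displays,
        "subset_ok": subset_ok,
        "subset_fraction": subset_ok / n_displays,
    }


def rt_by_distance(
    distances_deg: tuple[float, ...] = TRACE_DISTANCES_DEG,
    n_per_level: int = 20,
    seed: int = 0,
) -> dict:
    """Mean model RT of correct "same" traces per along-curve distance level."""
    from scipy.stats import spearmanr

    means = []
    all_rts = []
    for li, d in enumerate(distances_deg):
        rts = []
        i = 0
        while len(rts) < n_per_level:
            s = seed * 1_000_000 + li * 10_000 + i
            i += 1
            try:
                _w, gt, _res, state = trace_one(s, same_curve=True, distance_deg=d,
                                                n_curves=1)
            except PlacementError:
                continue
            if state.outcome == "same":
                rts.append(state.rt_ms)
        means.append(float(np.mean(rts)))
        all_rts.append(rts)
    rho = float(spearmanr(range(len(distances_deg)), means).statistic)
    return {
        "distances_deg": list(distances_deg),
        "mean_rt_ms": means,
        "n_per_level": n_per_level,
        "spearman_rho": rho,
        "strictly_increasing": all(b > a for a, b in zip(means, means[1:])),
    }


def reanalysis_comparison(n_displays: int = 100, seed: int = 0) -> dict:
    """Attended top-level response, stage E (after suppression + repass) vs C.

    Cluttered displays: one target plus distractor clutter, all well
    separated. The attended unit's response must not fall once the clutter's
    surround is suppressed.
    """
    from .engine import Runtime, vae_run_cycle, vae_translate_parameters
    from .hierarchy import build_hierarchy
    from .library import default_library

    improved = 0
    deltas = []
    n_done = 0
    i = 0
    lib = default_library()
    while n_done < n_displays:
        s = seed * 50_000 + i
        i += 1
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=s)
        try:
            # lattice-aligned items: the attended support tiles the pooling
            # windows, so re-analysis preserves the attended response exactly
            # while the clutter's surround is suppressed
            image, _gt = make_cluttered_display(
                spec, n_clutter=3, min_separation=24, align=8
            )
        except PlacementError:
            continue
        n_done += 1
        task = TaskSpecification(
            task_type="localize", target={"channel": "colorA"}
        )
        signals = vae_translate_parameters(task)
        vh = build_hierarchy(
            HierarchyConfig(input_shape=image.shape, channels=image.channels)
        )
        rt = Runtime(vh, image=image, library=lib, seed=s)
        from .engine import stage_feedforward, stage_localize, stage_prime, stage_select

        stage_prime(rt, signals)
        acts_c = stage_feedforward(rt, signals, stage="C")
        cfoa = stage_select(rt, signals, acts_c)
        if cfoa.empty:
            n_done -= 1
            continue
        before = sum(acts_c.top[ch][cfoa.peak] for ch in image.channels)
        stage_localize(rt, signals, acts_c, cfoa)
        acts_e = stage_feedforward(rt, signals, stage="E")
        after = sum(acts_e.top[ch][cfoa.peak] for ch in image.channels)
        improved += after >= before - 1e-12
        deltas.append(float(after - before))
    return {
        "n": n_displays,
        "not_worse": improved,
        "fraction": improved / n_displays,
        "mean_delta": float(np.mean(deltas)),
    }


def attentional_sample_study(n_displays: int = 100, seed: int = 0) -> dict:
    """Structural soundness of attentional samples on random displays.

    Alternates single-item and two-item (feature-distinguishable) displays;
    checks that every sample is rooted, top-to-bottom connected and per-level
    spatially connected, and that on two-item displays the sample never
    includes the unattended item's support.
    """
    from .engine import Runtime, vae_translate_parameters
    from .hierarchy import build_hierarchy
    from .wta import recurrent_localize, sample_is_valid, select_cfoa

    valid = 0
    excluded = 0
    n_two = 0
    n_done = 0
    i = 0
    while n_done < n_displays:
        s = seed * 70_000 + i
        i += 1
        two_items = n_done % 2 == 1
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=s)
        try:
            image, gt = make_cluttered_display(
                spec, n_clutter=1 if two_items else 0, min_separation=28, align=8,
                jitter=0.0,
            )
        except PlacementError:
            continue
        task = TaskSpecification(task_type="localize", target={"channel": "colorA"})
        signals = vae_translate_parameters(task)
        vh = build_hierarchy(
            HierarchyConfig(
                input_shape=image.shape, channels=image.channels,
                central_radius_deg=23.0,
            )
        )
        vh.apply_priming(signals.bias)
        acts = vh.feedforward(image)
        root = select_cfoa(vh, acts, params=signals.wta_params)
        if root.empty:
            continue
        n_done += 1
        sample = recurrent_localize(vh, acts, root, params=signals.wta_params)
        valid += sample_is_valid(vh, sample)
        if two_items:
            n_two += 1
            # which item was attended? the root's receptive-field center
            center = vh.unit_center_px(vh.top_level, (sample.root[1], sample.root[2]))
            d0 = abs(center[0] - gt.item_positions[0][0]) + abs(center[1] - gt.item_positions[0][1])
            d1 = abs(center[0] - gt.item_positions[1][0]) + abs(center[1] - gt.item_positions[1][1])
            other = gt.item_positions[1] if d0 <= d1 else gt.item_positions[0]
            half = 4  # aligned 8x8 items
            other_support = {
                (other[0] - half + r, other[1] - half + c)
                for r in range(8)
                for c in range(8)
            }
            excluded += not (sample.locations(0) & other_support)
    return {
        "n": n_displays,
        "valid": valid,
        "valid_fraction": valid / n_displays,
        "two_item_displays": n_two,
        "excluded": excluded,
        "excluded_fraction": excluded / n_two if n_two else 1.0,
    }


def _upward_closure(vh) -> list[dict[str, np.ndarray]]:
    """Units at or above a pathway-inhibited unit, per level and channel."""
    from numpy.lib.stride_tricks import sliding_window_view

    affected = [
        {ch: vh.inhibited(l, ch).copy() for ch in vh.config.channels}
        for l in range(vh.n_levels)
    ]
    for l, pool in enumerate(vh.config.pools):
        for ch in vh.config.channels:
            win = sliding_window_view(affected[l][ch], (pool.rf, pool.rf))
            up = win[:: pool.stride, :: pool.stride].any(axis=(-2, -1))
            affected[l + 1][ch] |= up
    return affected


def disengage_equality(n_displays: int = 10, seed: int = 0) -> dict:
    """After disengage, a sweep equals a never-attended hierarchy's sweep
    everywhere except at (and above) pathway-inhibited units -- exactly."""
    from .engine import Runtime, vae_disengage, vae_run_cycle, vae_translate_parameters
    from .hierarchy import build_hierarchy
    from .library import default_library

    exact = 0
    n_done = 0
    i = 0
    lib = default_library()
    while n_done < n_displays:
        s = seed * 30_000 + i
        i += 1
        spec = DisplaySpec(channels=("colorA", "colorB"), seed=s)
        try:
            image, _gt = make_cluttered_display(spec, n_clutter=2, min_separation=24, align=8)
        except PlacementError:
            continue
        n_done += 1
        task = TaskSpecification(task_type="localize", target={"channel": "colorA"})
        signals = vae_translate_parameters(task)
        cfg = HierarchyConfig(input_shape=image.shape, channels=image.channels)
        vh = build_hierarchy(cfg)
        rt = Runtime(vh, image=image, library=lib, seed=s)
        vae_run_cycle(rt, signals)  # one attended cycle leaves suppression in place
        vae_disengage(rt)
        acts_after = vh.feedforward(image)
        fresh = build_hierarchy(cfg)
        fresh.apply_priming(signals.bias)
        acts_fresh = fresh.feedforward(image)
        affected = _upward_closure(vh)
        ok = True
        for l in range(vh.n_levels):
            for ch in cfg.channels:
                free = ~affected[l][ch]
                if not np.array_equal(
                    acts_after.levels[l][ch][free], acts_fresh.levels[l][ch][free]
                ):
                    ok = False
        exact += ok
    return {"n": n_displays, "exact": exact, "fraction": exact / n_displays}


def covert_ior_sequence(n_items: int = 4, seed: int = 0) -> dict:
    """Covert search over identical well-separated items: the object IOR must
    never re-select an inhibited item within its horizon, so the scan visits
    distinct items until none remains."""
    spec = DisplaySpec(channels=("colorA", "colorB"), seed=seed)
    image, gt = make_cluttered_display(
        spec, n_clutter=n_items - 1,
        target_features={"colorB": 1.0},  # identical to the clutter
        clutter_features={"colorB": 1.0},
        min_separation=24, align=8, jitter=0.0,
    )
    hc = HierarchyConfig(
        input_shape=image.shape, channels=image.channels,
        ior_horizon_cycles=2 * n_items,
        central_radius_deg=23.0,  # the whole display subtends the central field
    )
    task = TaskSpecification(
        task_type="search_covert", target={"channel": "colorA"},
        overrides={"max_cycles": n_items + 2},
    )
    result = vte_run(task, image=image, seed=seed, hierarchy_config=hc)
    roots = [tuple(rec.payload["root"][1:]) for rec in result.notepad.query("sample")]
    items_seen = set()
    for r, c in roots:
        center = result.runtime.vh.unit_center_px(result.runtime.vh.top_level, (r, c))
        d, idx = min(
            (abs(center[0] - p[0]) + abs(center[1] - p[1]), k)
            for k, p in enumerate(gt.item_positions)
        )
        items_seen.add(idx if d <= 8 else None)
    return {
        "outcome": result.outcome,
        "n_items": n_items,
        "selections": roots,
        "distinct": len(set(roots)),
        "items_seen": len({i for i in items_seen if i is not None}),
        "repeats": len(roots) - len(set(roots)),
    }


def stage_policies() -> dict[str, list[str]]:
    """Logged stage sequences for each shipped cognitive program."""
    from .stimuli import make_discrimination_display

    out: dict[str, list[str]] = {}

    # discrimination: one pass, no localization
    spec = DisplaySpec(channels=("featA", "featB"), seed=11)
    image, _ = make_discrimination_display(spec, "A")
    task = TaskSpecification(task_type="discriminate", target={"channel": "featA"})
    out["discrimination"] = vte_run(task, image=image, seed=11).log.stages()

    # within-category identification: partial recurrent pass (direct cycle)
    from .engine import Runtime, vae_run_cycle, vae_translate_parameters
    from .hierarchy import build_hierarchy

    task_w = TaskSpecification(task_type="within_category_identify")
    signals = vae_translate_parameters(task_w)
    vh = build_hierarchy(HierarchyConfig(input_shape=image.shape, channels=image.channels))
    rt = Runtime(vh, image=image, seed=11)
    vae_run_cycle(rt, signals)
    out["within_category_identify"] = rt.log.stages()

    # localize/reinterpret: full D plus re-analysis
    task_l = TaskSpecification(task_type="localize", target={"channel": "featA"})
    out["localize_reinterpret"] = vte_run(task_l, image=image, seed=11).log.stages()

    # covert search: repeated full cycles
    spec_r = DisplaySpec(channels=("colorA", "colorB"), seed=11)
    image_r, _ = make_ring_display(spec_r, n_items=4, target_index=None, ring_radius=7.0)
    task_c = TaskSpecification(
        task_type="search_covert", target={"channel": "colorA"},
        overrides={"max_cycles": 3},
    )
    out["covert_search"] = vte_run(task_c, image=image_r, seed=11).log.stages()

    # overt search: repeated full cycles with saccades
    out["overt_search"] = _overt_stages()

    # curve tracing: repeated full cycles
    _w, _gt, res_t, _state = trace_one(17, same_curve=True, distance_deg=3.0)
    out["curve_trace"] = res_t.log.stages()
    return out


def _overt_stages() -> list[str]:
    scan = None
    spec = DisplaySpec(width=160, height=160, channels=("colorA", "colorB"), seed=13)
    world, _gt = make_ring_display(spec, n_items=4, target_index=1, ring_radius=7.0)
    hc = HierarchyConfig(input_shape=(64, 64), channels=world.channels, central_radius_deg=5.0)
    task = TaskSpecification(
        task_type="search_overt", target={"channel": "colorA"},
        overrides={"max_cycles": 8},
    )
    res = vte_run(task, world=world, seed=13, hierarchy_config=hc,
                  fc=FixationParams(lam=1.0, eps=0.0, inhibit_radius_px=6.0))
    return res.log.stages()
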