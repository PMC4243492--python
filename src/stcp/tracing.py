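"""Curve tracing: same/different judgment on two X markers.

The task: decide whether two X markers lie on the same curve. The tracer
fixates the first marker, localizes the curve at fixation, and extends a
traced set along the curve -- within a fixation the trace spreads over the
connected curve pixels of the central attentional field, and between
fixations the gaze saccades to the farthest point of the uninhibited curve
portion connected to what has already been traced (the connectivity
constraint of the history-biased priority map). Traced pixels and past
fixations enter the fixation history map in world coordinates and provide
the inhibition-of-return bias, so tracing never doubles back. The trace ends
positively when the second marker joins the traced set, negatively when the
connected curve is exhausted without reaching it.

When the remaining curve lies inside the central field (where peripheral
priority is zero by construction) the tracer advances covertly, without a
saccade -- small displays are traced with covert shifts alone.

Model response time is the final model-clock reading; because the traced
extent per cycle is bounded by the central attentional field, the cycle count
-- and hence RT -- grows with the along-curve distance between the markers.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .engine import (
    ControlSignals,
    Runtime,
    stage_feedforward,
    stage_localize,
    stage_prime,
    stage_select,
    vae_disengage,
)
from .fixation import (
    PPM,
    Fixation,
    compose_hbpm,
    compute_ppm,
    execute_saccade,
    select_next_fixation,
    select_pfoa,
)

CURVE_THRESHOLD = 0.5


@dataclass
class TraceState:
    """World-frame tracing progress."""

    traced: set[tuple[int, int]] = field(default_factory=set)
    loose_ends: set[tuple[int, int]] = field(default_factory=set)
    markers: list[tuple[int, int]] = field(default_factory=list)
    target_marker: tuple[int, int] | None = None
    fixations: list[Fixation] = field(default_factory=list)
    steps: int = 0
    outcome: str | None = None
    rt_ms: float | None = None


def detect_markers(world, k: int = 2, exclusion_radius: int = 4) -> list[tuple[int, int]]:
    """Find X-marker centers as non-maximum-suppressed peaks of the marker
    channel (the center pixel of an X is its brightest point)."""
    grid = world["marker"].copy()
    ppm = PPM(grid, central_radius_px=0.0)
    return [pos for _, pos in select_pfoa(ppm, k=k, exclusion_radius=exclusion_radius)]


def _curve_mask(image) -> np.ndarray:
    return image["curve"] > CURVE_THRESHOLD


def _snap_to_curve(mask: np.ndarray, pos: tuple[int, int], radius: int = 3):
    """Nearest curve pixel within a small neighborhood, or None."""
    H, W = mask.shape
    best = None
    best_d = None
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            r, c = pos[0] + dr, pos[1] + dc
            if 0 <= r < H and 0 <= c < W and mask[r, c]:
                d = (dr * dr + dc * dc, r, c)
                if best_d is None or d < best_d:
                    best_d = d
                    best = (r, c)
    return best


_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def _bfs_arc(
    mask: np.ndarray,
    seeds: list[tuple[int, int]],
    max_arc: int,
    blocked: set[tuple[int, int]] | None = None,
    with_parents: bool = False,
):
    """8-connected BFS over curve pixels; arc distance from the seed set.

    With ``with_parents`` also returns the BFS tree (pixel -> predecessor),
    from which the connecting chain to any reached pixel can be read off.
    """
    H, W = mask.shape
    dist: dict[tuple[int, int], int] = {}
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    queue: deque[tuple[int, int]] = deque()
    for s in seeds:
        if 0 <= s[0] < H and 0 <= s[1] < W and mask[s]:
            dist[s] = 0
            parent[s] = None
            queue.append(s)
    while queue:
        r, c = queue.popleft()
        d = dist[(r, c)]
        if d >= max_arc:
            continue
        for dr, dc in _OFFSETS:
            q = (r + dr, c + dc)
            if 0 <= q[0] < H and 0 <= q[1] < W and mask[q] and q not in dist:
                if blocked is not None and q in blocked:
                    continue
                dist[q] = d + 1
                parent[q] = (r, c)
                queue.append(q)
    if with_parents:
        return dist, parent
    return dist


def _chain(
    parent: dict[tuple[int, int], tuple[int, int] | None], pixel: tuple[int, int]
) -> set[tuple[int, int]]:
    """The BFS chain from a reached pixel back to the seed set."""
    out: set[tuple[int, int]] = set()
    node: tuple[int, int] | None = pixel
    while node is not None:
        out.add(node)
        node = parent.get(node)
    return out


def trace_loop(rt: Runtime, signals: ControlSignals) -> tuple[str, TraceState]:
    """Run the tracing cycle to completion; returns ("same"/"different", state).

    Requires an overt runtime (world + gaze) whose world image carries
    ``curve`` and ``marker`` channels with exactly two X markers.
    """
    if rt.world is None or rt.gaze is None:
        raise ValueError("curve tracing requires a world image and gaze control")
    markers = detect_markers(rt.world)
    if len(markers) < 2:
        raise ValueError(f"curve tracing requires 2 markers, found {len(markers)}")
    state = TraceState(markers=markers[:2])
    start, target = markers[0], markers[1]
    state.target_marker = target
    rt.gaze.saccade_to(start)  # task setup: the first X is fixated directly
    state.fixations.append(Fixation(start[0], start[1], "overt", rt.cycle))

    extent = int(round(rt.central_radius_px))
    reach_cap = 2 * extent

    def reached(traced: set[tuple[int, int]]) -> bool:
        tr, tc = target
        return any(
            (tr + dr, tc + dc) in traced for dr in (-1, 0, 1) for dc in (-1, 0, 1)
        )

    for _step in range(signals.max_cycles):
        state.steps += 1
        rt.log.record(rt.clock.now_ms, "vAE", "cycle_start", cycle=rt.cycle)
        if not rt.primed:
            stage_prime(rt, signals)
        view = rt.current_image()
        acts = stage_feedforward(rt, signals, stage="C")
        cfoa = stage_select(rt, signals, acts)
        if not cfoa.empty:
            stage_localize(rt, signals, acts, cfoa)
            acts = stage_feedforward(rt, signals, stage="E")

        # spread the trace over the connected curve within the central field
        mask = _curve_mask(view)
        fix_ret = rt.gaze.world_to_retina(rt.gaze.fixation)
        anchor = _snap_to_curve(mask, fix_ret)
        if anchor is not None:
            spread = _bfs_arc(mask, [anchor], extent)
            new_world = {rt.gaze.retina_to_world(p) for p in spread}
            added = new_world - state.traced
            state.traced |= new_world
            if added:
                rt.notepad.append("trace", cycle=rt.cycle, added=len(added),
                                  total=len(state.traced))
        if reached(state.traced):
            state.outcome = "same"
            break

        # frontier: untraced curve pixels connected to the traced set
        state.loose_ends -= state.traced
        traced_ret = {
            rt.gaze.world_to_retina(p)
            for p in state.traced
            if rt.gaze.on_retina(rt.gaze.world_to_retina(p))
        }
        arc, parents = _bfs_arc(mask, sorted(traced_ret), reach_cap, with_parents=True)
        frontier = {p: d for p, d in arc.items() if p not in traced_ret and d > 0}
        if not frontier:
            if state.loose_ends:
                # a previously seen, still-untraced continuation lies beyond
                # the current view: return to it (the history map's
                # extra-retinal extent is what makes this possible)
                back = min(state.loose_ends)
                vae_disengage(rt)
                fix = Fixation(back[0], back[1], "overt", rt.cycle)
                execute_saccade(rt.gaze, fix, rt.world, log=rt.log, clock=rt.clock)
                state.fixations.append(fix)
                rt.notepad.append("fixation", cycle=rt.cycle, pos=list(fix.pos),
                                  fix_kind="overt", return_to_frontier=True)
                rt.cycle += 1
                rt.vh.advance_cycle()
                continue
            state.outcome = "different"
            break
        max_arc = max(frontier.values())
        far = {p for p, d in frontier.items() if d >= max_arc - 1}

        rt.fhm.update(rt.gaze.fixation, traced=frozenset(state.traced))
        ppm = compute_ppm(view, signals.bias, rt.central_radius_px, rt.fc.surround_px)
        pfoa = select_pfoa(ppm, rt.fc.pfoa_k, rt.fc.nms_radius)
        hbpm = compose_hbpm(
            ppm, None, pfoa or [(0.0, fix_ret)], rt.fhm, rt.gaze,
            rt.fc.inhibit_radius_px, rt.fc.override_ior,
        )

        def on_far_frontier(world_pos: tuple[int, int]) -> bool:
            ret = rt.gaze.world_to_retina(world_pos)
            return ret in far

        fix = select_next_fixation(
            hbpm, rt.gaze, constraint=on_far_frontier,
            floor_frac=rt.fc.floor_frac, cycle=rt.cycle,
        )
        if fix is not None:
            chosen_ret = rt.gaze.world_to_retina(fix.pos)
        else:
            # remaining reachable curve lies in the central field (where
            # peripheral priority is zero): advance covertly instead
            chosen_ret = max(
                frontier.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1])
            )[0]
        # absorb the verified chain to the chosen continuation; remember the
        # other, unabsorbed frontier branches as loose ends in world space
        chain = _chain(parents, chosen_ret)
        state.traced |= {rt.gaze.retina_to_world(p) for p in chain}
        for p in frontier:
            if p not in chain:
                wp = rt.gaze.retina_to_world(p)
                if wp not in state.traced:
                    state.loose_ends.add(wp)
        if reached(state.traced):
            state.outcome = "same"
            break
        vae_disengage(rt)
        if fix is not None:
            execute_saccade(rt.gaze, fix, rt.world, log=rt.log, clock=rt.clock)
            state.fixations.append(fix)
            rt.notepad.append("fixation", cycle=rt.cycle, pos=list(fix.pos),
                              fix_kind="overt")
        else:
            world_best = rt.gaze.retina_to_world(chosen_ret)
            state.fixations.append(Fixation(world_best[0], world_best[1], "covert", rt.cycle))
            rt.log.record(rt.clock.now_ms, "FC", "covert_shift", pos=list(world_best))
        rt.cycle += 1
        rt.vh.advance_cycle()
    else:
        state.outcome = "different"  # budget exhausted without reaching the marker

    state.rt_ms = rt.clock.now_ms
    rt.log.record(rt.clock.now_ms, "vTE", "trace_outcome", outcome=state.outcome,
                  steps=state.steps, traced=len(state.traced))
    return state.outcome, state


def run_curve_trace(
    task,
    world,
    seed: int = 0,
    hierarchy_config=None,
    fc=None,
    costs=None,
    library=None,
):
    """Convenience driver: build an overt runtime tuned for tracing and run
    the curve-trace method through the task executive."""
    from .engine import FixationParams, RunResult, vte_run
    from .hierarchy import HierarchyConfig, build_hierarchy

    if hierarchy_config is None:
        # a small attentional field makes the per-cycle traceable extent a
        # fine-grained fraction of the curve, so cycle count tracks arc length
        hierarchy_config = HierarchyConfig(
            input_shape=(64, 64),
            channels=world.channels,
            central_radius_deg=0.6,
            deg_per_pixel=0.1,
        )
    if fc is None:
        # tracing keeps its history bias undecayed and inhibits the traced
        # pixels themselves rather than broad disks around past fixations
        fc = FixationParams(lam=1.0, eps=0.0, inhibit_radius_px=3.0, pfoa_k=8)
    if library is None:
        from .library import default_library

        library = default_library()
    vh = build_hierarchy(hierarchy_config)
    rt = Runtime(vh, world=world, library=library, costs=costs, fc=fc, seed=seed)
    result: RunResult = vte_run(task, runtime=rt)
    script = result.script
    state: TraceState | None = script.state.get("trace_state") if script else None
    return result, state
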