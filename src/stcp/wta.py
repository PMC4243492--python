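"""theta-WTA selection and recurrent localization (the attentional sample).

The winner-take-all used throughout is not a single-unit argmax: given a
response map, ``theta_wta`` returns the spatially contiguous set of
near-maximal values -- all admissible units whose response is at least
``(1 - theta)`` times the admissible maximum, restricted to the connected
component containing the peak. ``theta`` is therefore a dimensionless
selectivity knob: ``theta = 0`` selects the argmax alone, larger values admit
a broader contiguous region. (The threshold is relative to the maximum, not a
histogram bin; this keeps the selection scale-free.)

``recurrent_localize`` deploys this selection top-down through the hierarchy:
starting from the top-level winner, each lower level's admissible units are
exactly those feeding the selected units above, theta-WTA picks the contiguous
near-maximal subset among them, and a suppressive annulus is imposed around
each level's selection as it forms. The union of per-level selections, linked
by the feeding pathways, is the attentional sample: a rooted, top-to-bottom
connected subset of the hierarchy representing the attended stimulus.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .events import EventLog, ModelClock
from .hierarchy import Activations, VisualHierarchy

_EPS = 1e-12


@dataclass(frozen=True)
class ThetaWTAParams:
    theta: float = 0.25
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("theta must lie in [0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class WTAResult:
    """A contiguous winning region and its peak; empty means no winner."""

    region: frozenset[tuple[int, int]]
    peak: tuple[int, int] | None

    @property
    def empty(self) -> bool:
        return self.peak is None


_NO_WINNER = WTAResult(frozenset(), None)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def theta_wta(
    grid: np.ndarray,
    params: ThetaWTAParams = ThetaWTAParams(),
    mask: np.ndarray | None = None,
) -> WTAResult:
    """Contiguous near-maximal selection on a 2-D response map.

    The peak is the admissible argmax (ties broken by smallest (row, col));
    the region is the connected component, under ``params.connectivity``, of
    admissible units with value >= (1 - theta) * max that contains the peak.
    An all-zero (or negative) admissible map yields the no-winner result.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError("mask shape must match grid")
        if not mask.any():
            raise ValueError("admissible mask is empty")
    else:
        mask = np.ones(grid.shape, dtype=bool)
    vals = np.where(mask, grid, -np.inf)
    m = vals.max()
    if m <= 0.0:
        return _NO_WINNER
    peak = tuple(int(x) for x in np.argwhere(vals == m)[0])  # row-major => lexicographic
    candidates = mask & (grid >= (1.0 - params.theta) * m - _EPS)
    labels, _ = ndimage.label(candidates, structure=_structure(params.connectivity))
    region_mask = labels == labels[peak]
    region = frozenset((int(r), int(c)) for r, c in np.argwhere(region_mask))
    return WTAResult(region, peak)


@dataclass
class AttentionalSample:
    """Per-level connected selections plus the pathways rooted at the winner.

    ``levels`` maps level index -> set of (channel, row, col) selected units;
    ``edges`` links each selected unit to the selected units above that it
    feeds through the receptive-field map; ``root`` is the top-level peak.
    """

    root: tuple[int, int, int]  # (level, row, col)
    levels: dict[int, frozenset[tuple[str, int, int]]] = field(default_factory=dict)
    edges: list[tuple[tuple[int, str, int, int], tuple[int, str, int, int]]] = field(
        default_factory=list
    )

    @property
    def empty(self) -> bool:
        return not any(self.levels.values())

    def locations(self, level: int) -> set[tuple[int, int]]:
        return {(r, c) for _, r, c in self.levels.get(level, frozenset())}

    def by_channel(self, level: int) -> dict[str, set[tuple[int, int]]]:
        out: dict[str, set[tuple[int, int]]] = {}
        for ch, r, c in self.levels.get(level, frozenset()):
            out.setdefault(ch, set()).add((r, c))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "root": list(self.root),
                "levels": {
                    str(l): sorted([ch, r, c] for ch, r, c in units)
                    for l, units in self.levels.items()
                },
                "edges": sorted(
                    [list(lo), list(hi)] for lo, hi in self.edges
                ),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "AttentionalSample":
        d = json.loads(text)
        levels = {
            int(l): frozenset((ch, int(r), int(c)) for ch, r, c in units)
            for l, units in d["levels"].items()
        }
        edges = [
            ((int(a[0]), a[1], int(a[2]), int(a[3])), (int(b[0]), b[1], int(b[2]), int(b[3])))
            for a, b in d["edges"]
        ]
        return cls(tuple(d["root"]), levels, edges)


def _summed_map(
    acts: Activations, level: int, channels: tuple[str, ...]
) -> np.ndarray:
    return sum(acts.level(level)[ch] for ch in channels)


def _channels_at(
    acts: Activations,
    level: int,
    loc: tuple[int, int],
    channels: tuple[str, ...],
    theta: float,
) -> list[str]:
    """Channels entering the sample at a selected location.

    Channels compete jointly at a location: all channels whose response is
    within (1 - theta) of the strongest channel there (and positive) enter.
    """
    vals = {ch: acts.level(level)[ch][loc] for ch in channels}
    m = max(vals.values())
    if m <= 0:
        return []
    return [ch for ch, v in vals.items() if v >= (1.0 - theta) * m - _EPS]


def select_cfoa(
    vh: VisualHierarchy,
    acts: Activations,
    params: ThetaWTAParams = ThetaWTAParams(),
    channels: tuple[str, ...] | None = None,
    fixation_px: tuple[float, float] | None = None,
    extra_mask: np.ndarray | None = None,
    exclude: set[tuple[int, int]] | None = None,
    clock: ModelClock | None = None,
    log: EventLog | None = None,
) -> WTAResult:
    """Select the central focus of attention at the top of the hierarchy.

    theta-WTA runs on the task-relevant channels summed at the top level,
    restricted to units whose receptive-field center lies within the central
    attentional field of the current fixation and which are not
    pathway-inhibited. An empty result is the "no cFOA" signal and drives
    target-absent handling.
    """
    channels = channels or vh.config.channels
    top = vh.top_level
    grid = np.zeros(vh.level_shape(top))
    stacked = []
    uninhibited_any = np.zeros(vh.level_shape(top), dtype=bool)
    for ch in channels:
        free = ~vh.inhibited(top, ch)
        plane = np.where(free, acts.top[ch], 0.0)
        grid += plane
        stacked.append(plane)
        uninhibited_any |= free
    mask = vh.central_mask(top, fixation_px) & uninhibited_any
    if extra_mask is not None:
        mask &= extra_mask
    if exclude:
        for loc in exclude:
            mask[loc] = False
    if mask.any() and np.where(mask, grid, -np.inf).max() > 0.0:
        # stimuli distinguishable by their constituent features are not
        # selected together: the winning region only admits units whose
        # dominant channel agrees with the peak's
        vals = np.where(mask, grid, -np.inf)
        peak = tuple(int(x) for x in np.argwhere(vals == vals.max())[0])
        dominant = np.argmax(np.stack(stacked), axis=0)
        coherent = mask & (dominant == dominant[peak])
        coherent[peak] = True
        result = theta_wta(grid, params, coherent)
    else:
        result = _NO_WINNER
    if clock is not None:
        clock.advance(clock.costs.decision_ms)
        if log is not None:
            log.record(
                clock.now_ms,
                "vAE",
                "decision",
                kind="cfoa",
                peak=list(result.peak) if result.peak else None,
                region_size=len(result.region),
            )
    return result


def recurrent_localize(
    vh: VisualHierarchy,
    acts: Activations,
    root: WTAResult,
    params: ThetaWTAParams = ThetaWTAParams(),
    channels: tuple[str, ...] | None = None,
    depth: int | str = "full",
    suppress: bool = True,
    feature_channels: tuple[str, ...] = (),
    clock: ModelClock | None = None,
    log: EventLog | None = None,
) -> AttentionalSample:
    """Top-down traversal producing the attentional sample.

    Descends level by level from the top-level ``root`` selection: the
    admissible set at level ``l`` is the union of receptive-field windows of
    the level ``l+1`` selected units; theta-WTA (on the channel-summed map)
    picks the contiguous winner within that restriction; the suppressive
    surround is imposed around each level's selection as soon as it is formed.
    ``depth`` is the number of levels to descend, or ``"full"`` to reach the
    input level. The model clock advances by the top-down cost, scaled by the
    fraction of the hierarchy traversed.
    """
    if root.empty:
        raise ValueError("recurrent localization requires a non-empty top selection")
    channels = channels or vh.config.channels
    top = vh.top_level
    n_descend = top if depth == "full" else int(depth)
    if not (0 <= n_descend <= top):
        raise ValueError(f"depth must be in [0, {top}] or 'full'")

    theta = params.theta
    top_units: set[tuple[str, int, int]] = set()
    for loc in root.region:
        for ch in _channels_at(acts, top, loc, channels, theta):
            top_units.add((ch, loc[0], loc[1]))
    sample = AttentionalSample(
        root=(top, root.peak[0], root.peak[1]),
        levels={top: frozenset(top_units)},
    )
    if suppress:
        vh.suppress_level(top, sample.by_channel(top), feature_channels=feature_channels)

    selected_locs = set(root.region)
    for step in range(n_descend):
        level = top - step - 1
        parent = level + 1
        admissible = np.zeros(vh.level_shape(level), dtype=bool)
        for loc in selected_locs:
            r0, r1, c0, c1 = vh.children_window(parent, loc)
            admissible[r0:r1, c0:c1] = True
        grid = _summed_map(acts, level, channels)
        result = theta_wta(grid, params, admissible)
        if result.empty:
            break
        units: set[tuple[str, int, int]] = set()
        for loc in result.region:
            for ch in _channels_at(acts, level, loc, channels, theta):
                units.add((ch, loc[0], loc[1]))
        sample.levels[level] = frozenset(units)
        # pathway edges: a selected child feeds every selected parent whose
        # window contains it; channels pair up when both carry the channel.
        parent_units = sample.levels[parent]
        parent_locs_by_ch: dict[str, set[tuple[int, int]]] = {}
        for ch, r, c in parent_units:
            parent_locs_by_ch.setdefault(ch, set()).add((r, c))
        for ch, r, c in units:
            for pr, pc in selected_locs:
                r0, r1, c0, c1 = vh.children_window(parent, (pr, pc))
                if r0 <= r < r1 and c0 <= c < c1:
                    pch = ch if (pr, pc) in parent_locs_by_ch.get(ch, set()) else next(
                        (k for k, locs in sorted(parent_locs_by_ch.items()) if (pr, pc) in locs),
                        ch,
                    )
                    sample.edges.append(((level, ch, r, c), (parent, pch, pr, pc)))
        if suppress:
            vh.suppress_level(level, sample.by_channel(level), feature_channels=feature_channels)
        selected_locs = set(result.region)

    if clock is not None:
        frac = n_descend / top if top else 1.0
        cost = clock.costs.top_down_ms * frac
        clock.advance(cost)
        if log is not None:
            log.record(
                clock.now_ms,
                "vAE",
                "stage",
                stage="D",
                depth="full" if depth == "full" else n_descend,
                cost_ms=cost,
            )
    return sample


def sample_is_valid(
    vh: VisualHierarchy, sample: AttentionalSample, connectivity: int = 8
) -> bool:
    """Graph-traversal check of both attentional-sample invariants.

    (1) every selected non-top unit feeds some selected unit above through
    the receptive-field map; (2) each level's selected locations form one
    spatially connected set under the declared connectivity.
    """
    top = vh.top_level
    for level, units in sample.levels.items():
        locs = {(r, c) for _, r, c in units}
        if not locs:
            return False
        # spatial connectivity by BFS
        seen = {next(iter(sorted(locs)))}
        queue = deque(seen)
        offsets = (
            [(-1, 0), (1, 0), (0, -1), (0, 1)]
            if connectivity == 4
            else [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
        )
        while queue:
            r, c = queue.popleft()
            for dr, dc in offsets:
                q = (r + dr, c + dc)
                if q in locs and q not in seen:
                    seen.add(q)
                    queue.append(q)
        if seen != locs:
            return False
        # rooted feeding: every non-top unit lies in some selected parent window
        if level < top and (level + 1) in sample.levels:
            parent_locs = sample.locations(level + 1)
            for r, c in locs:
                fed = False
                for pr, pc in parent_locs:
                    r0, r1, c0, c1 = vh.children_window(level + 1, (pr, pc))
                    if r0 <= r < r1 and c0 <= c < c1:
                        fed = True
                        break
                if not fed:
                    return False
        elif level < top:
            return False
    # root present at top
    if top not in sample.levels or sample.root[0] != top:
        return False
    if (sample.root[1], sample.root[2]) not in sample.locations(top):
        return False
    return True
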