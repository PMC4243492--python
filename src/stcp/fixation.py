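"""Fixation control: peripheral priority, fixation history, and saccades.

Saliency is computed only in the periphery (the central attentional field is
zeroed by construction): the Peripheral Priority Map (PPM) is a task-biased
center-surround contrast over the early feature channels of the current
retinal view. The Fixation History Map (FHM) stores previous fixations (and,
for tracing tasks, the pixels already traced) in *world* coordinates -- its
extent is the whole world, strictly larger than the retinal field, which
prevents gaze oscillation between just-off-retina targets. FHM entries decay
multiplicatively per fixation and supply the location-based
inhibition-of-return bias. The History-Biased Priority Map (HBPM) combines
the central focus, the peripheral peaks, and the FHM inhibition into one
priority surface from which the next fixation is chosen; an overt fixation
change (a saccade) shifts the retina-to-world offset and requires a disengage
in the same cycle.

The saliency operator here is a documented stand-in (rectified
center-surround contrast, channel-gain weighted, summed); the interface
accepts a drop-in replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .events import EventLog, ModelClock, SequencingError
from .hierarchy import BiasSpec
from .image import ChannelImage


@dataclass(frozen=True)
class Fixation:
    """A fixation in world coordinates; covert shifts do not move the retina."""

    row: int
    col: int
    kind: str = "overt"  # {"covert", "overt"}
    cycle: int = 0

    @property
    def pos(self) -> tuple[int, int]:
        return (self.row, self.col)


class Gaze:
    """Retina-to-world geometry: a retina-sized window centered on fixation."""

    def __init__(
        self,
        world_shape: tuple[int, int],
        retina_shape: tuple[int, int],
        fixation: tuple[int, int] | None = None,
    ):
        self.world_shape = tuple(world_shape)
        self.retina_shape = tuple(retina_shape)
        if fixation is None:
            fixation = (world_shape[0] // 2, world_shape[1] // 2)
        self.fixation = tuple(fixation)

    @property
    def retina_center(self) -> tuple[int, int]:
        return (self.retina_shape[0] // 2, self.retina_shape[1] // 2)

    @property
    def origin(self) -> tuple[int, int]:
        """World position of the retina's (0, 0) pixel."""
        return (
            self.fixation[0] - self.retina_center[0],
            self.fixation[1] - self.retina_center[1],
        )

    def world_to_retina(self, pos: tuple[int, int]) -> tuple[int, int]:
        o = self.origin
        return (pos[0] - o[0], pos[1] - o[1])

    def retina_to_world(self, pos: tuple[int, int]) -> tuple[int, int]:
        o = self.origin
        return (pos[0] + o[0], pos[1] + o[1])

    def on_retina(self, pos_ret: tuple[int, int]) -> bool:
        return 0 <= pos_ret[0] < self.retina_shape[0] and 0 <= pos_ret[1] < self.retina_shape[1]

    def view(self, world: ChannelImage) -> ChannelImage:
        """The current retinal view: a zero-padded crop centered on fixation."""
        o = self.origin
        return world.crop(o[0], o[1], self.retina_shape)

    def saccade_to(self, world_pos: tuple[int, int]) -> None:
        if not (0 <= world_pos[0] < self.world_shape[0] and 0 <= world_pos[1] < self.world_shape[1]):
            raise ValueError(f"fixation {world_pos} outside world bounds {self.world_shape}")
        self.fixation = tuple(world_pos)


@dataclass
class PPM:
    """Peripheral priority: saliency, identically zero in the central field."""

    grid: np.ndarray
    central_radius_px: float


def compute_ppm(
    image: ChannelImage,
    bias: BiasSpec | None = None,
    central_radius_px: float = 20.0,
    surround_px: int = 5,
) -> PPM:
    """Task-biased center-surround saliency of the retinal periphery.

    Per channel: response minus its local (surround) mean, rectified, weighted
    by the task's channel gain, then summed over channels. The disk of
    ``central_radius_px`` around the retina center is zeroed by construction.
    """
    gains = bias.channel_gains if bias is not None else {}
    H, W = image.shape
    sal = np.zeros((H, W))
    size = 2 * surround_px + 1
    for ch, plane in image.items():
        surround = ndimage.uniform_filter(plane, size=size, mode="reflect")
        contrast = np.maximum(plane - surround, 0.0)
        sal += gains.get(ch, 1.0) * contrast
    rr = np.arange(H)[:, None] - (H // 2)
    cc = np.arange(W)[None, :] - (W // 2)
    sal[rr**2 + cc**2 <= central_radius_px**2] = 0.0
    return PPM(sal, central_radius_px)


def select_pfoa(
    ppm: PPM, k: int = 5, exclusion_radius: int = 6
) -> list[tuple[float, tuple[int, int]]]:
    """Greedy non-maximum-suppression peak picking on the PPM.

    Returns up to ``k`` (value, (row, col)) peaks in descending value, ties
    broken by smallest (row, col); each accepted peak excludes a Chebyshev
    square of ``exclusion_radius`` around it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grid = ppm.grid.copy()
    H, W = grid.shape
    peaks: list[tuple[float, tuple[int, int]]] = []
    for _ in range(k):
        m = grid.max()
        if m <= 1e-9:  # guard against filter round-off masquerading as saliency
            break
        r, c = (int(x) for x in np.argwhere(grid == m)[0])
        peaks.append((float(m), (r, c)))
        r0, r1 = max(r - exclusion_radius, 0), min(r + exclusion_radius + 1, H)
        c0, c1 = max(c - exclusion_radius, 0), min(c + exclusion_radius + 1, W)
        grid[r0:r1, c0:c1] = 0.0
    return peaks


@dataclass
class FHMEntry:
    world_pos: tuple[int, int]
    weight: float
    traced: frozenset[tuple[int, int]] | None = None  # world-frame pixels


class FHM:
    """Fixation history in world coordinates with per-update decay.

    Every update decays all stored weights by ``lam`` and appends the new
    fixation at weight 1; entries are dropped once their weight falls below
    ``eps`` (with ``eps = 0`` entries persist indefinitely, and ``lam = 1``
    disables decay entirely -- the no-revisit regime).
    """

    def __init__(self, lam: float = 0.85, eps: float = 0.01):
        if not (0.0 < lam <= 1.0):
            raise ValueError("decay rate lam must lie in (0, 1]")
        if eps < 0:
            raise ValueError("eps must be >= 0")
        self.lam = lam
        self.eps = eps
        self.entries: list[FHMEntry] = []

    def update(
        self,
        fixation: Fixation | tuple[int, int],
        traced: frozenset[tuple[int, int]] | None = None,
    ) -> "FHM":
        pos = fixation.pos if isinstance(fixation, Fixation) else tuple(fixation)
        for e in self.entries:
            e.weight *= self.lam
        self.entries = [e for e in self.entries if e.weight >= self.eps or self.eps == 0.0]
        self.entries.append(FHMEntry(pos, 1.0, traced))
        return self

    def inhibition(
        self, gaze: Gaze, radius_px: float = 10.0
    ) -> np.ndarray:
        """Retinal-frame inhibition in [0, 1]: max covering-entry weight.

        An entry covers the disk of ``radius_px`` around its fixation plus its
        traced pixel set, all stored in world coordinates and projected into
        the current retinal frame.
        """
        H, W = gaze.retina_shape
        inh = np.zeros((H, W))
        rr = np.arange(H)[:, None]
        cc = np.arange(W)[None, :]
        for e in self.entries:
            r, c = gaze.world_to_retina(e.world_pos)
            disk = (rr - r) ** 2 + (cc - c) ** 2 <= radius_px**2
            np.maximum(inh, np.where(disk, e.weight, 0.0), out=inh)
            if e.traced:
                for wp in e.traced:
                    pr, pc = gaze.world_to_retina(wp)
                    if 0 <= pr < H and 0 <= pc < W:
                        inh[pr, pc] = max(inh[pr, pc], e.weight)
        return inh


@dataclass
class HBPM:
    """History-biased priority: saliency discounted by IOR inhibition."""

    grid: np.ndarray
    cfoa_mark: tuple[int, int] | None = None  # retinal frame; exempt from competition
    pfoa_candidates: list[tuple[float, tuple[int, int]]] = field(default_factory=list)


def compose_hbpm(
    ppm: PPM,
    cfoa_mark: tuple[int, int] | None,
    pfoa: list[tuple[float, tuple[int, int]]],
    fhm: FHM | None,
    gaze: Gaze,
    inhibit_radius_px: float = 10.0,
    override_ior: bool = False,
) -> HBPM:
    """priority(x) = saliency(x) * (1 - inhibition(x)).

    The current central focus is marked but exempt from peripheral
    competition (attending it requires no gaze change). With
    ``override_ior`` set, task demands override the history bias and
    priorities equal raw saliency.
    """
    if cfoa_mark is None and not pfoa:
        raise ValueError("at least one of cFOA / pFOA must be present")
    if fhm is None or override_ior or not fhm.entries:
        grid = ppm.grid.copy()
    else:
        grid = ppm.grid * (1.0 - fhm.inhibition(gaze, inhibit_radius_px))
    return HBPM(grid, cfoa_mark, list(pfoa))


def select_next_fixation(
    hbpm: HBPM,
    gaze: Gaze,
    constraint=None,
    floor_frac: float = 0.05,
    cycle: int = 0,
    max_candidates: int = 4096,
) -> Fixation | None:
    """Highest-priority candidate satisfying the task predicate, or None.

    Candidates are retinal pixels scanned in descending priority (ties by
    smallest (row, col)); the predicate receives the candidate's *world*
    position. Candidates below ``floor_frac`` of the map maximum are not
    considered -- when none qualifies the task-level interpretation is
    "nothing left to fixate" and drives termination.
    """
    grid = hbpm.grid
    m = grid.max()
    if m <= 1e-9:  # nothing above numerical round-off
        return None
    floor = max(floor_frac * m, 1e-9)
    flat = grid.ravel()
    order = np.argsort(-flat, kind="stable")[:max_candidates]
    W = grid.shape[1]
    for idx in order:
        value = flat[idx]
        if value < floor or value <= 0.0:
            break
        pos_ret = (int(idx // W), int(idx % W))
        pos_world = gaze.retina_to_world(pos_ret)
        if constraint is None or constraint(pos_world):
            return Fixation(pos_world[0], pos_world[1], kind="overt", cycle=cycle)
    return None


def execute_saccade(
    gaze: Gaze,
    fixation: Fixation,
    world: ChannelImage,
    log: EventLog | None = None,
    clock: ModelClock | None = None,
    require_disengage: bool = True,
) -> ChannelImage:
    """Move the eyes: re-center the retina on ``fixation`` and return the view.

    Attention must have been disengaged earlier in the same cycle (asserted
    against the event log); the model clock advances by the saccade cost.
    """
    if require_disengage and log is not None:
        start = log.last_index("cycle_start")
        events_since = [ev.event for ev in log.events[start + 1 :]] if start >= 0 else [
            ev.event for ev in log.events
        ]
        if "disengage" not in events_since:
            raise SequencingError("saccade attempted without a disengage in this cycle")
    old = gaze.fixation
    gaze.saccade_to(fixation.pos)
    if clock is not None:
        clock.advance(clock.costs.saccade_ms)
        if log is not None:
            log.record(
                clock.now_ms,
                "FC",
                "saccade",
                frm=list(old),
                to=list(fixation.pos),
                cycle=fixation.cycle,
            )
    return gaze.view(world)
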