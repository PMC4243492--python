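"""The visual hierarchy (VH): a tuned, retinotopic feature pyramid.

Level 0 is at input resolution; each higher level pools a half-open window of
the level below with a uniform weighted sum (a mean). There is deliberately no
feedforward maximum anywhere in this module: selection is the job of the
top-down theta-WTA / recurrent localization machinery, so the feedforward
sweep must be non-selecting. With all gains at 1 and no suppression the sweep
is exactly linear in the input.

Three kinds of attentive state live on the hierarchy and are strictly
independent of one another:

* **gains** -- multiplicative priming biases, per channel and per location
  (installed before stimulus onset, 80-300 ms ahead);
* **suppression** -- multiplicative attenuation in [0, 1] on unit outputs,
  imposed around an attended selection (spatial annulus plus sibling feature
  channels) and lifted at disengage;
* **pathway inhibition** -- boolean flags implementing object-based
  inhibition of return: an inhibited unit contributes 0 to all units above it
  for a configurable number of attentive cycles, then auto-releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .events import EventLog, ModelClock
from .image import ChannelImage

if TYPE_CHECKING:  # pragma: no cover
    from .wta import AttentionalSample


@dataclass(frozen=True)
class BiasSpec:
    """Top-down priming: per-channel gain factors and an optional spatial prior."""

    channel_gains: dict[str, float] = field(default_factory=dict)
    spatial_prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        for ch, g in self.channel_gains.items():
            if g <= 0:
                raise ValueError(f"gain for channel {ch!r} must be positive")


@dataclass(frozen=True)
class PoolSpec:
    """One feedforward pooling transition: window ``rf`` stepped by ``stride``."""

    rf: int = 2
    stride: int = 2

    def __post_init__(self) -> None:
        if self.rf < 2:
            raise ValueError("rf must be >= 2")
        if not (1 <= self.stride <= self.rf):
            raise ValueError("stride must satisfy 1 <= stride <= rf (full coverage)")


@dataclass(frozen=True)
class HierarchyConfig:
    input_shape: tuple[int, int] = (64, 64)
    channels: tuple[str, ...] = ("colorA", "colorB")
    pools: tuple[PoolSpec, ...] = (PoolSpec(), PoolSpec(), PoolSpec())
    central_radius_deg: float = 10.0
    deg_per_pixel: float = 0.5
    ior_horizon_cycles: int = 3
    suppression_factor: float = 0.1
    suppression_extent: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_shape", tuple(self.input_shape))
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(
            self, "pools", tuple(p if isinstance(p, PoolSpec) else PoolSpec(*p) for p in self.pools)
        )
        if len(self.pools) < 2:
            raise ValueError("a hierarchy needs at least 3 levels (>= 2 pooling transitions)")
        # validate that every transition tiles its level exactly
        shape = self.input_shape
        for i, pool in enumerate(self.pools):
            for dim in shape:
                if dim < pool.rf or (dim - pool.rf) % pool.stride != 0:
                    raise ValueError(
                        f"pool {i} (rf={pool.rf}, stride={pool.stride}) does not tile "
                        f"a level of shape {shape}"
                    )
            shape = tuple((d - pool.rf) // pool.stride + 1 for d in shape)

    @property
    def n_levels(self) -> int:
        return len(self.pools) + 1

    def level_shape(self, level: int) -> tuple[int, int]:
        shape = self.input_shape
        for pool in self.pools[:level]:
            shape = tuple((d - pool.rf) // pool.stride + 1 for d in shape)
        return shape

    @property
    def central_radius_px(self) -> float:
        return self.central_radius_deg / self.deg_per_pixel

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyConfig":
        if "pools" in d:
            d = dict(d)
            d["pools"] = tuple(PoolSpec(**p) if isinstance(p, dict) else PoolSpec(*p) for p in d["pools"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "HierarchyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Activations:
    """All feature maps filled by one feedforward sweep."""

    levels: list[dict[str, np.ndarray]]

    @property
    def top(self) -> dict[str, np.ndarray]:
        return self.levels[-1]

    def level(self, l: int) -> dict[str, np.ndarray]:
        return self.levels[l]


def _pool_mean(x: np.ndarray, rf: int, stride: int) -> np.ndarray:
    win = sliding_window_view(x, (rf, rf))[::stride, ::stride]
    return win.mean(axis=(-2, -1))


class VisualHierarchy:
    """Mutable hierarchy state plus the feedforward sweep."""

    def __init__(self, config: HierarchyConfig):
        self.config = config
        self.cycle = 0
        n = config.n_levels
        self._shapes = [config.level_shape(l) for l in range(n)]
        self.gains: list[dict[str, np.ndarray]] = [
            {ch: np.ones(self._shapes[l]) for ch in config.channels} for l in range(n)
        ]
        self.spatial_prior: np.ndarray = np.ones(self._shapes[0])
        self.suppression: list[dict[str, np.ndarray]] = [
            {ch: np.ones(self._shapes[l]) for ch in config.channels} for l in range(n)
        ]
        self._inhibit_expiry: list[dict[str, np.ndarray]] = [
            {ch: np.zeros(self._shapes[l], dtype=int) for ch in config.channels}
            for l in range(n)
        ]
        # input-space centers of each unit, per level, for central-field masks
        self._row_centers: list[np.ndarray] = []
        self._col_centers: list[np.ndarray] = []
        rows = np.arange(self._shapes[0][0], dtype=float)
        cols = np.arange(self._shapes[0][1], dtype=float)
        self._row_centers.append(rows)
        self._col_centers.append(cols)
        for pool in config.pools:
            rows = sliding_window_view(rows, pool.rf)[:: pool.stride].mean(axis=-1)
            cols = sliding_window_view(cols, pool.rf)[:: pool.stride].mean(axis=-1)
            self._row_centers.append(rows)
            self._col_centers.append(cols)

    # -- geometry ----------------------------------------------------------

    @property
    def n_levels(self) -> int:
        return self.config.n_levels

    @property
    def top_level(self) -> int:
        return self.config.n_levels - 1

    def level_shape(self, level: int) -> tuple[int, int]:
        return self._shapes[level]

    def unit_center_px(self, level: int, unit: tuple[int, int]) -> tuple[float, float]:
        """Input-space (level-0) center of a unit's receptive field."""
        r, c = unit
        return (float(self._row_centers[level][r]), float(self._col_centers[level][c]))

    def children_window(self, level: int, unit: tuple[int, int]) -> tuple[int, int, int, int]:
        """Half-open window (r0, r1, c0, c1) of level-1 units feeding ``unit``.

        ``level`` is the level of the parent unit (>= 1).
        """
        pool = self.config.pools[level - 1]
        r, c = unit
        return (r * pool.stride, r * pool.stride + pool.rf, c * pool.stride, c * pool.stride + pool.rf)

    def central_mask(self, level: int, fixation_px: tuple[float, float] | None = None) -> np.ndarray:
        """Units whose input-space center lies within the central attentional field."""
        H0, W0 = self._shapes[0]
        if fixation_px is None:
            fixation_px = ((H0 - 1) / 2.0, (W0 - 1) / 2.0)
        rr = self._row_centers[level][:, None] - fixation_px[0]
        cc = self._col_centers[level][None, :] - fixation_px[1]
        return rr**2 + cc**2 <= self.config.central_radius_px**2

    # -- attentive state ---------------------------------------------------

    def inhibited(self, level: int, channel: str) -> np.ndarray:
        return self._inhibit_expiry[level][channel] > self.cycle

    def advance_cycle(self) -> None:
        self.cycle += 1

    def apply_priming(
        self,
        bias: BiasSpec,
        clock: ModelClock | None = None,
        log: EventLog | None = None,
    ) -> "VisualHierarchy":
        """Install top-down gains; responses change only on the next sweep.

        Priming is applied at the input level and, because the sweep is
        linear, multiplies every unprimed-unsuppressed response of that
        channel at every level by the same factor.
        """
        for ch in bias.channel_gains:
            if ch not in self.config.channels:
                raise KeyError(f"unknown channel {ch!r}")
        for ch, g in bias.channel_gains.items():
            self.gains[0][ch] *= g
        if bias.spatial_prior is not None:
            prior = np.asarray(bias.spatial_prior, dtype=float)
            if prior.shape != self._shapes[0]:
                raise ValueError("spatial prior must be at input resolution")
            self.spatial_prior = self.spatial_prior * prior
        if clock is not None:
            # the priming event is stamped at the start of the priming window,
            # one lead time before stimulus onset
            if log is not None:
                log.record(
                    clock.now_ms,
                    "vAE",
                    "stage",
                    stage="B",
                    lead_ms=clock.costs.priming_lead_ms,
                    gains={ch: float(g) for ch, g in sorted(bias.channel_gains.items())},
                )
            clock.advance(clock.costs.priming_lead_ms)
        return self

    def reset_priming(self) -> "VisualHierarchy":
        for ch in self.config.channels:
            for l in range(self.n_levels):
                self.gains[l][ch][...] = 1.0
        self.spatial_prior = np.ones(self._shapes[0])
        return self

    def feedforward(
        self,
        image: ChannelImage,
        clock: ModelClock | None = None,
        log: EventLog | None = None,
        stage: str = "C",
    ) -> Activations:
        """One feedforward sweep of the tuned hierarchy.

        Level-0 responses are the image times gains times the spatial prior;
        each higher unit is the mean over its window of the lower responses,
        attenuated by suppression and zeroed at inhibited units, times its own
        gain.
        """
        if image.shape != self._shapes[0]:
            raise ValueError(
                f"image shape {image.shape} does not match input level {self._shapes[0]}"
            )
        missing = [ch for ch in self.config.channels if ch not in image]
        if missing:
            raise ValueError(f"image lacks channels {missing}")
        levels: list[dict[str, np.ndarray]] = []
        level0 = {
            ch: image[ch] * self.gains[0][ch] * self.spatial_prior
            for ch in self.config.channels
        }
        levels.append(level0)
        for l, pool in enumerate(self.config.pools):
            upper: dict[str, np.ndarray] = {}
            for ch in self.config.channels:
                contrib = levels[l][ch] * self.suppression[l][ch]
                contrib = np.where(self.inhibited(l, ch), 0.0, contrib)
                upper[ch] = _pool_mean(contrib, pool.rf, pool.stride) * self.gains[l + 1][ch]
            levels.append(upper)
        if clock is not None:
            clock.advance(clock.costs.feedforward_ms)
            if log is not None:
                log.record(clock.now_ms, "VH", "stage", stage=stage)
        return Activations(levels)

    # -- surround suppression ---------------------------------------------

    def suppress_level(
        self,
        level: int,
        selected: dict[str, set[tuple[int, int]]],
        extent: int | None = None,
        feature_channels: Iterable[str] = (),
        factor: float | None = None,
    ) -> None:
        """Suppress the Chebyshev annulus around one level's selected set.

        ``selected`` maps channel -> selected (row, col) units at this level.
        Units in the annulus of width ``extent`` around the selected locations
        (any channel), and units of the listed sibling ``feature_channels`` at
        the selected locations, get their suppression multiplied by
        ``factor``. Selected units themselves are never suppressed.
        """
        factor = self.config.suppression_factor if factor is None else factor
        if not (0.0 <= factor < 1.0):
            raise ValueError("suppression factor must lie in [0, 1)")
        extent = self.config.suppression_extent if extent is None else extent
        shape = self._shapes[level]
        loc_mask = np.zeros(shape, dtype=bool)
        sel_masks = {ch: np.zeros(shape, dtype=bool) for ch in selected}
        for ch, units in selected.items():
            for r, c in units:
                sel_masks[ch][r, c] = True
                loc_mask[r, c] = True
        if not loc_mask.any():
            return
        from scipy.ndimage import binary_dilation

        structure = np.ones((2 * extent + 1, 2 * extent + 1), dtype=bool)
        annulus = binary_dilation(loc_mask, structure=structure) & ~loc_mask
        feature_channels = set(feature_channels)
        for ch in self.config.channels:
            mask = annulus.copy()
            if ch in feature_channels:
                mask |= loc_mask & ~sel_masks.get(ch, np.zeros(shape, dtype=bool))
            self.suppression[level][ch][mask] *= factor

    def impose_surround_suppression(
        self,
        sample: "AttentionalSample",
        extent: int | None = None,
        feature_channels: Iterable[str] = (),
        factor: float | None = None,
    ) -> "VisualHierarchy":
        for level, units in sample.levels.items():
            by_channel: dict[str, set[tuple[int, int]]] = {}
            for ch, r, c in units:
                by_channel.setdefault(ch, set()).add((r, c))
            self.suppress_level(level, by_channel, extent, feature_channels, factor)
        return self

    def lift_surround_suppression(self) -> "VisualHierarchy":
        """Reset all suppression to 1; priming and inhibition are untouched."""
        for level in self.suppression:
            for arr in level.values():
                arr[...] = 1.0
        return self

    # -- pathway inhibition (object-based IOR) -----------------------------

    def inhibit_pathways(self, sample: "AttentionalSample") -> "VisualHierarchy":
        """Flag every unit of the sample; flags auto-release after the horizon."""
        expiry = self.cycle + self.config.ior_horizon_cycles
        for level, units in sample.levels.items():
            for ch, r, c in units:
                self._inhibit_expiry[level][ch][r, c] = max(
                    self._inhibit_expiry[level][ch][r, c], expiry
                )
        return self

    def clear_inhibition(self) -> "VisualHierarchy":
        for level in self._inhibit_expiry:
            for arr in level.values():
                arr[...] = 0
        return self


def build_hierarchy(config: HierarchyConfig | dict) -> VisualHierarchy:
    """Fresh hierarchy: all gains 1, no suppression, no inhibition."""
    if isinstance(config, dict):
        config = HierarchyConfig.from_dict(config)
    return VisualHierarchy(config)
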