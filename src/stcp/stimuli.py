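"""Synthetic display generator with ground truth.

Every display the model is tested on is generated here, as a pure function of
a :class:`DisplaySpec` and the operation arguments, together with a ground
truth record that the tests (never the model) may consult. Supported display
families:

* smooth non-crossing curves with optional X markers, for curve tracing;
* rings of items around the display center, for covert/overt search;
* a single central stimulus from one of two feature classes (or noise), for
  discrimination;
* a target among scattered clutter items, for re-analysis experiments.

The visual-angle mapping is linear: ``deg_per_pixel`` is constant across the
field (no cortical magnification).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .image import ChannelImage


class PlacementError(RuntimeError):
    """Geometry could not be placed in the canvas under the constraints."""


@dataclass(frozen=True)
class DisplaySpec:
    """Canvas geometry, visual-angle scale, feature channels, and seed."""

    width: int = 64
    height: int = 64
    deg_per_pixel: float = 0.5
    channels: tuple[str, ...] = ("colorA", "colorB")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.deg_per_pixel <= 0:
            raise ValueError("deg_per_pixel must be positive")
        if not self.channels:
            raise ValueError("at least one feature channel is required")
        object.__setattr__(self, "channels", tuple(self.channels))

    def px(self, degrees: float) -> float:
        return degrees / self.deg_per_pixel

    @property
    def center(self) -> tuple[int, int]:
        return (self.height // 2, self.width // 2)


@dataclass
class GroundTruth:
    """What the generator actually drew; consumed by tests and scoring only."""

    item_positions: list[tuple[int, int]] = field(default_factory=list)
    item_features: list[dict[str, float]] = field(default_factory=list)
    curve_pixel_sets: list[frozenset[tuple[int, int]]] = field(default_factory=list)
    curve_paths: list[list[tuple[int, int]]] = field(default_factory=list)
    marker_positions: list[tuple[int, int]] = field(default_factory=list)
    marker_curve_ids: list[int] = field(default_factory=list)
    label: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "items": [list(p) for p in self.item_positions],
                "item_features": self.item_features,
                "curves": [[list(p) for p in path] for path in self.curve_paths],
                "markers": [list(p) for p in self.marker_positions],
                "marker_curve_ids": list(self.marker_curve_ids),
                "label": self.label,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        paths = [[tuple(p) for p in path] for path in d.get("curves", [])]
        return cls(
            item_positions=[tuple(p) for p in d.get("items", [])],
            item_features=d.get("item_features", []),
            curve_pixel_sets=[frozenset(path) for path in paths],
            curve_paths=paths,
            marker_positions=[tuple(p) for p in d.get("markers", [])],
            marker_curve_ids=list(d.get("marker_curve_ids", [])),
            label=d.get("label"),
        )


def polyline_length(points: Sequence[tuple[float, float]]) -> float:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# curve displays
# ---------------------------------------------------------------------------

def _walk_curve(
    rng: np.random.Generator,
    shape: tuple[int, int],
    target_arc_px: float,
    other_pixels: set[tuple[int, int]],
    min_separation: int,
    max_turn: float,
    margin: int,
    start: tuple[float, float] | None = None,
) -> list[tuple[int, int]] | None:
    """One bounded-curvature chain-code random walk, or None if it gets stuck.

    The walk moves between 8-connected pixels (diagonal steps count sqrt(2)
    of arc) until the cumulative arc length reaches ``target_arc_px``. A
    candidate pixel is rejected when it comes within ``min_separation``
    (Chebyshev) of another curve, or of this curve's own older pixels --
    recent pixels are exempt so the walk can continue smoothly.
    """
    H, W = shape
    recent = 3 * min_separation + 6

    def clear(p: tuple[int, int], own_age: dict[tuple[int, int], int], step: int) -> bool:
        r, c = p
        if not (margin <= r < H - margin and margin <= c < W - margin):
            return False
        for dr in range(-min_separation, min_separation + 1):
            for dc in range(-min_separation, min_separation + 1):
                q = (r + dr, c + dc)
                if q in other_pixels:
                    return False
                age = own_age.get(q)
                if age is not None and step - age > recent:
                    return False
        return True

    if start is None:
        p0 = (
            int(rng.uniform(margin + 2, H - margin - 2)),
            int(rng.uniform(margin + 2, W - margin - 2)),
        )
    else:
        p0 = (int(round(start[0])), int(round(start[1])))
    heading = rng.uniform(0.0, 2 * np.pi)
    own_age: dict[tuple[int, int], int] = {}
    if not clear(p0, own_age, 0):
        return None
    path: list[tuple[int, int]] = [p0]
    own_age[p0] = 0

    arc = 0.0
    step = 0
    while arc < target_arc_px:
        step += 1
        placed = False
        h = heading + rng.uniform(-max_turn, max_turn)
        for attempt in range(9):
            dr = int(np.round(np.sin(h)))
            dc = int(np.round(np.cos(h)))
            if (dr, dc) == (0, 0):  # heading too close to an axis midpoint
                dc = 1 if np.cos(h) >= 0 else -1
            q = (path[-1][0] + dr, path[-1][1] + dc)
            if q not in own_age and clear(q, own_age, step):
                heading = h
                placed = True
                break
            # steer progressively harder away from the obstacle
            h = heading + rng.uniform(-max_turn, max_turn) * (1 + attempt)
        if not placed:
            return None
        path.append(q)
        own_age[q] = step
        arc += float(np.hypot(dr, dc))
    return path


def _cumulative_arc(path: Sequence[tuple[int, int]]) -> list[float]:
    arcs = [0.0]
    for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
        arcs.append(arcs[-1] + float(np.hypot(r1 - r0, c1 - c0)))
    return arcs


def _index_at_arc(arcs: list[float], target: float) -> int:
    for i, a in enumerate(arcs):
        if a >= target:
            return i
    return len(arcs) - 1


def _stamp_marker(plane: np.ndarray, pos: tuple[int, int], arm: int = 2) -> None:
    """Draw an X: dim diagonal arms with a bright center pixel."""
    H, W = plane.shape
    r0, c0 = pos
    for d in range(1, arm + 1):
        for dr, dc in ((d, d), (d, -d), (-d, d), (-d, -d)):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < H and 0 <= c < W:
                plane[r, c] = max(plane[r, c], 0.6)
    plane[r0, c0] = 1.0


def make_curve_display(
    spec: DisplaySpec,
    n_curves: int = 2,
    curve_length: float = 6.6,
    n_markers: int = 2,
    same_curve: bool = True,
    marker_arc_sep: float | None = None,
    min_separation: int = 6,
    max_turn: float = 0.22,
    margin: int = 4,
    max_retries: int = 100,
) -> tuple[ChannelImage, GroundTruth]:
    """Smooth non-crossing curves with optional X markers.

    ``curve_length`` and ``marker_arc_sep`` are in degrees of visual angle;
    the markers are placed symmetrically about the curve midpoint, separated
    by ``marker_arc_sep`` along the curve (default: half the curve). With
    ``same_curve=False`` the two markers go on different curves (requires
    ``n_curves >= 2``).
    """
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    if curve_length <= 0:
        raise ValueError("curve_length must be positive")
    if n_markers not in (0, 1, 2):
        raise ValueError("n_markers must be 0, 1 or 2")
    if not same_curve and n_markers == 2 and n_curves < 2:
        raise ValueError("different-curve markers require n_curves >= 2")
    if "curve" not in spec.channels or (n_markers and "marker" not in spec.channels):
        raise ValueError('spec.channels must include "curve" (and "marker" when used)')

    rng = np.random.default_rng(spec.seed)
    arc_px = spec.px(curve_length)
    shape = (spec.height, spec.width)

    paths: list[list[tuple[int, int]]] = []
    pixel_sets: list[set[tuple[int, int]]] = []
    occupied: set[tuple[int, int]] = set()
    for _ in range(n_curves):
        path = None
        for _attempt in range(max_retries):
            path = _walk_curve(rng, shape, arc_px, occupied, min_separation, max_turn, margin)
            if path is not None:
                break
        if path is None:
            raise PlacementError(
                f"could not place {n_curves} non-crossing curves of {arc_px:.0f} px "
                f"in a {spec.height}x{spec.width} canvas after {max_retries} retries"
            )
        pixels = set(path)
        if pixels & occupied:  # defensive: separation should already forbid this
            raise PlacementError("curve placement produced overlapping pixel sets")
        paths.append(path)
        pixel_sets.append(pixels)
        occupied |= pixels

    image = ChannelImage.blank(spec.channels, shape)
    curve_plane = image["curve"]
    for pixels in pixel_sets:
        for r, c in pixels:
            curve_plane[r, c] = 1.0

    marker_positions: list[tuple[int, int]] = []
    marker_curve_ids: list[int] = []
    if n_markers:
        arcs = _cumulative_arc(paths[0])
        total = arcs[-1]
        sep_px = min(
            spec.px(marker_arc_sep) if marker_arc_sep is not None else total / 2.0,
            total,
        )
        if n_markers == 1:
            marker_positions = [paths[0][_index_at_arc(arcs, total / 2)]]
            marker_curve_ids = [0]
        elif same_curve:
            i1 = _index_at_arc(arcs, (total - sep_px) / 2)
            i2 = _index_at_arc(arcs, (total + sep_px) / 2)
            marker_positions = [paths[0][i1], paths[0][i2]]
            marker_curve_ids = [0, 0]
        else:
            arcs2 = _cumulative_arc(paths[1])
            marker_positions = [
                paths[0][_index_at_arc(arcs, total / 2)],
                paths[1][_index_at_arc(arcs2, arcs2[-1] / 2)],
            ]
            marker_curve_ids = [0, 1]
        marker_plane = image["marker"]
        for pos in marker_positions:
            _stamp_marker(marker_plane, pos)

    label = None
    if n_markers == 2:
        label = "same" if marker_curve_ids[0] == marker_curve_ids[1] else "different"

    gt = GroundTruth(
        curve_pixel_sets=[frozenset(s) for s in pixel_sets],
        curve_paths=paths,
        marker_positions=marker_positions,
        marker_curve_ids=marker_curve_ids,
        label=label,
    )
    return image, gt


# ---------------------------------------------------------------------------
# item displays
# ---------------------------------------------------------------------------

def _stamp_item(
    image: ChannelImage,
    pos: tuple[int, int],
    features: Mapping[str, float],
    half: int,
    scale: float = 1.0,
) -> None:
    r, c = pos
    H, W = image.shape
    r0, r1 = max(r - half, 0), min(r + half + 1, H)
    c0, c1 = max(c - half, 0), min(c + half + 1, W)
    for ch, value in features.items():
        plane = image[ch]
        plane[r0:r1, c0:c1] = np.maximum(plane[r0:r1, c0:c1], value * scale)


def make_ring_display(
    spec: DisplaySpec,
    n_items: int = 8,
    target_index: int | None = None,
    target_features: Mapping[str, float] | None = None,
    distractor_features: Mapping[str, float] | None = None,
    ring_radius: float | None = None,
    item_half: int = 1,
    jitter: float = 0.0,
    center: tuple[int, int] | None = None,
) -> tuple[ChannelImage, GroundTruth]:
    """``n_items`` equally spaced on a circle about the display center.

    Exactly one item carries ``target_features`` when ``target_index`` is
    given; otherwise all items are distractors (target-absent). ``ring_radius``
    is in degrees (default: 40% of the smaller canvas dimension). ``jitter``
    scales each item's features by an independent factor in
    ``[1-jitter, 1+jitter]``.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if target_index is not None and not (0 <= target_index < n_items):
        raise ValueError("target_index out of range")
    if distractor_features is None:
        distractor_features = {spec.channels[-1]: 1.0}
    if target_features is None:
        target_features = {spec.channels[0]: 1.0}

    rng = np.random.default_rng(spec.seed)
    cr, cc = center if center is not None else spec.center
    radius_px = (
        spec.px(ring_radius)
        if ring_radius is not None
        else 0.4 * min(spec.height, spec.width)
    )
    if (
        cr - radius_px - item_half < 0
        or cr + radius_px + item_half >= spec.height
        or cc - radius_px - item_half < 0
        or cc + radius_px + item_half >= spec.width
    ):
        raise PlacementError("ring radius exceeds the canvas")

    image = ChannelImage.blank(spec.channels, (spec.height, spec.width))
    positions: list[tuple[int, int]] = []
    feats: list[dict[str, float]] = []
    for k in range(n_items):
        ang = -np.pi / 2 + 2 * np.pi * k / n_items
        pos = (int(round(cr + radius_px * np.sin(ang))), int(round(cc + radius_px * np.cos(ang))))
        features = dict(target_features) if k == target_index else dict(distractor_features)
        scale = 1.0 + jitter * rng.uniform(-1.0, 1.0) if jitter else 1.0
        _stamp_item(image, pos, features, item_half, scale)
        positions.append(pos)
        feats.append({ch: v * scale for ch, v in features.items()})

    label = "target-present" if target_index is not None else "target-absent"
    gt = GroundTruth(item_positions=positions, item_features=feats, label=label)
    return image, gt


def make_discrimination_display(
    spec: DisplaySpec, class_id: str = "A", item_half: int = 2
) -> tuple[ChannelImage, GroundTruth]:
    """One central stimulus from class A, class B, or channel-uncorrelated noise.

    Class A is strong in the first channel and weak in the others; class B is
    strong in the second channel. ``noise`` renders an independent random
    texture in every channel with no coherent central item.
    """
    if class_id not in ("A", "B", "noise"):
        raise ValueError("class_id must be 'A', 'B' or 'noise'")
    rng = np.random.default_rng(spec.seed)
    image = ChannelImage.blank(spec.channels, (spec.height, spec.width))
    center = spec.center
    if class_id == "noise":
        image.data[...] = rng.uniform(0.0, 0.3, size=image.data.shape)
        gt = GroundTruth(label="noise")
        return image, gt
    strong = spec.channels[0] if class_id == "A" else spec.channels[min(1, len(spec.channels) - 1)]
    features = {ch: (1.0 if ch == strong else 0.1) for ch in spec.channels}
    _stamp_item(image, center, features, item_half)
    gt = GroundTruth(item_positions=[center], item_features=[features], label=class_id)
    return image, gt


def make_cluttered_display(
    spec: DisplaySpec,
    n_clutter: int = 4,
    target_features: Mapping[str, float] | None = None,
    clutter_features: Mapping[str, float] | None = None,
    min_separation: int = 22,
    item_half: int = 1,
    jitter: float = 0.3,
    align: int | None = None,
    max_retries: int = 200,
) -> tuple[ChannelImage, GroundTruth]:
    """A target item plus scattered clutter items, pairwise well separated.

    The first ground-truth item is the target. Clutter items carry the
    distractor feature signature with per-item strength jitter. With
    ``align`` set, items are ``align x align`` squares whose corners sit on
    the ``align`` lattice (so item support tiles pooling windows exactly);
    positions then record item centers rounded down.
    """
    if target_features is None:
        target_features = {spec.channels[0]: 1.0}
    if clutter_features is None:
        clutter_features = {spec.channels[-1]: 1.0}
    rng = np.random.default_rng(spec.seed)
    margin = item_half + 2
    positions: list[tuple[int, int]] = []

    def place() -> tuple[int, int] | None:
        for _ in range(max_retries):
            if align:
                cell = (
                    int(rng.integers(1, spec.height // align - 1)),
                    int(rng.integers(1, spec.width // align - 1)),
                )
                p = (cell[0] * align + align // 2, cell[1] * align + align // 2)
            else:
                p = (
                    int(rng.integers(margin, spec.height - margin)),
                    int(rng.integers(margin, spec.width - margin)),
                )
            if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) >= min_separation for q in positions):
                return p
        return None

    image = ChannelImage.blank(spec.channels, (spec.height, spec.width))
    feats: list[dict[str, float]] = []
    for i in range(1 + n_clutter):
        pos = place()
        if pos is None:
            raise PlacementError(
                f"could not place {1 + n_clutter} items at separation {min_separation}"
            )
        positions.append(pos)
        features = dict(target_features) if i == 0 else dict(clutter_features)
        scale = 1.0 if i == 0 else 1.0 + jitter * rng.uniform(-1.0, 0.0)
        if align:
            r0, c0 = pos[0] - align // 2, pos[1] - align // 2
            for ch, value in features.items():
                plane = image[ch]
                plane[r0 : r0 + align, c0 : c0 + align] = np.maximum(
                    plane[r0 : r0 + align, c0 : c0 + align], value * scale
                )
        else:
            _stamp_item(image, pos, features, item_half, scale)
        feats.append({ch: v * scale for ch, v in features.items()})
    gt = GroundTruth(item_positions=positions, item_features=feats, label="cluttered")
    return image, gt


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_display(directory: str | Path, image: ChannelImage, gt: GroundTruth) -> None:
    """Write one PNG per channel plus a ground-truth JSON sidecar."""
    from PIL import Image as PILImage

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch, plane in image.items():
        arr = np.clip(plane, 0.0, 1.0)
        PILImage.fromarray((arr * 255).astype(np.uint8), mode="L").save(
            directory / f"channel_{ch}.png"
        )
    (directory / "ground_truth.json").write_text(gt.to_json() + "\n")


def load_display(directory: str | Path) -> tuple[ChannelImage, GroundTruth]:
    from PIL import Image as PILImage

    directory = Path(directory)
    planes: dict[str, np.ndarray] = {}
    for path in sorted(directory.glob("channel_*.png")):
        ch = path.stem[len("channel_"):]
        planes[ch] = np.asarray(PILImage.open(path), dtype=float) / 255.0
    if not planes:
        raise FileNotFoundError(f"no channel PNGs under {directory}")
    gt = GroundTruth.from_json((directory / "ground_truth.json").read_text())
    return ChannelImage.from_planes(planes), gt
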