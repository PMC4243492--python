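"""Multi-channel raster images.

Displays are stacks of named feature planes (e.g. ``"curve"``, ``"marker"``,
``"colorA"``) rather than RGB images: the visual hierarchy consumes feature
channels directly, and the encoding of features into screen colors is outside
the model. Coordinates are 0-based ``(row, col)`` with the origin at the
top-left; windows are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np


@dataclass
class ChannelImage:
    """A named stack of equally sized 2-D float planes."""

    channels: tuple[str, ...]
    data: np.ndarray  # (C, H, W)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} does not match channels {self.channels}"
            )

    @classmethod
    def blank(cls, channels: tuple[str, ...], shape: tuple[int, int]) -> "ChannelImage":
        return cls(tuple(channels), np.zeros((len(channels),) + tuple(shape)))

    @classmethod
    def from_planes(cls, planes: Mapping[str, np.ndarray]) -> "ChannelImage":
        channels = tuple(planes)
        return cls(channels, np.stack([np.asarray(planes[c], dtype=float) for c in channels]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[self.channels.index(channel)]

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return zip(self.channels, self.data)

    def copy(self) -> "ChannelImage":
        return ChannelImage(self.channels, self.data.copy())

    def crop(self, row0: int, col0: int, shape: tuple[int, int]) -> "ChannelImage":
        """Window ``[row0:row0+h, col0:col0+w)`` zero-padded outside the image."""
        h, w = shape
        out = np.zeros((len(self.channels), h, w))
        H, W = self.shape
        r0, r1 = max(row0, 0), min(row0 + h, H)
        c0, c1 = max(col0, 0), min(col0 + w, W)
        if r0 < r1 and c0 < c1:
            out[:, r0 - row0 : r1 - row0, c0 - col0 : c1 - col0] = self.data[:, r0:r1, c0:c1]
        return ChannelImage(self.channels, out)
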