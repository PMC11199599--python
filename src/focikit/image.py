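"""In-memory containers for multi-channel images, time-lapse stacks and label maps.

Conventions used throughout focikit:

* images are 2D ``float64`` arrays indexed ``[row, col]``;
* coordinates are 0-based, pixel-center (the center of pixel ``[i, j]`` is the
  point ``(i, j)``);
* all distances are Euclidean in pixels and converted to micrometres only when
  reported;
* ``pixel_scale`` is the projected pixel size in µm/px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Rect:
    """Axis-aligned pixel rectangle: rows ``row0 .. row0+height-1``, likewise cols."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("Rect height and width must be positive")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def within(self, shape: tuple[int, int]) -> bool:
        return (
            self.row0 >= 0
            and self.col0 >= 0
            and self.row0 + self.height <= shape[0]
            and self.col0 + self.width <= shape[1]
        )

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.row0 + self.height <= other.row0
            or other.row0 + other.height <= self.row0
            or self.col0 + self.width <= other.col0
            or other.col0 + other.width <= self.col0
        )

    def to_json(self) -> list[int]:
        return [int(self.row0), int(self.col0), int(self.height), int(self.width)]

    @classmethod
    def from_json(cls, data) -> "Rect":
        return cls(*(int(v) for v in data))


@dataclass
class MultiChannelImage:
    """Named-channel 2D image; the unit of foci analysis.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"hoechst"``, ``"egfp"``, ``"53bp1"``)
        to a 2D intensity array. All channels share one shape.
    pixel_scale
        Projected pixel size in µm/px.
    """

    channels: dict[str, np.ndarray]
    pixel_scale: float

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class TimeLapse:
    """Single-channel time-lapse stack (T, Y, X) with a fixed frame interval."""

    frames: np.ndarray
    frame_interval_s: float
    pixel_scale: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, Y, X) stack")
        if self.frame_interval_s <= 0 or self.pixel_scale <= 0:
            raise ValueError("frame_interval_s and pixel_scale must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame index × interval)."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class LabelMap:
    """Instance segmentation: integer grid where 0 is background and nuclei
    are labelled 1..n_labels with no gaps; each label is one 4-connected
    component."""

    labels: np.ndarray
    pixel_scale: float

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label
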