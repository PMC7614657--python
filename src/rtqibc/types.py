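"""Shared containers for images and label maps.

Conventions used throughout the package: pixel coordinates are 0-based,
(row, col) = (y, x), y increasing downward; centroids are floats; all
times are minutes from the start of the live movie; intensities are
arbitrary units (a.u.) unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image2D", "LabelMap"]


@dataclass
class Image2D:
    """A single-channel intensity frame with a physical pixel size."""

    data: np.ndarray
    pixel_size_um: float = 1.0
    channel: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"Image2D requires a 2D array, got shape {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um


@dataclass
class LabelMap:
    """Integer-labelled nuclear masks: 0 = background, >0 = nucleus id."""

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMap requires a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um
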