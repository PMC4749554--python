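"""In-memory containers for segmented time-lapse movies.

A movie is a stack of 2-D frames in acquisition order.  Label movies hold
integer segmentation masks (0 = background, positive integers = object
labels) for either the cell layer or the CMAC (cell–matrix adhesion complex)
layer.  Intensity movies hold the matching fluorescence channels (paxillin
marking CMACs, LifeAct marking F-actin).

Coordinate convention: pixel indices are 0-based ``(row, col)``; physical
coordinates are ``index * pixel_size_um`` at pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelMovie", "IntensityMovie", "CELL_LAYER", "CMAC_LAYER"]

CELL_LAYER = "cell"
CMAC_LAYER = "cmac"


def _as_stack(frames) -> np.ndarray:
    arr = np.asarray(frames)
    if arr.dtype == object or arr.ndim != 3:
        shapes = {np.asarray(f).shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"all frames must share one shape, got {sorted(shapes)}")
        raise ValueError(f"expected a stack of 2-D frames, got ndim={arr.ndim}")
    return arr


@dataclass
class LabelMovie:
    """Per-frame integer label images with acquisition metadata."""

    frames: np.ndarray
    pixel_size_um: float = 0.21
    frame_interval_min: float = 5.0
    layer: str = CELL_LAYER

    def __post_init__(self) -> None:
        self.frames = _as_stack(self.frames)
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise ValueError(
                f"label frames must have an integer dtype, got {self.frames.dtype}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.layer not in (CELL_LAYER, CMAC_LAYER):
            raise ValueError(f"layer must be 'cell' or 'cmac', got {self.layer!r}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    def object_counts(self) -> list[int]:
        """Number of distinct labeled objects per frame."""
        return [int(np.count_nonzero(np.unique(f))) for f in self.frames]

    def labels_in_frame(self, t: int) -> np.ndarray:
        labs = np.unique(self.frames[t])
        return labs[labs != 0]


@dataclass
class IntensityMovie:
    """Scalar fluorescence frames aligned to a :class:`LabelMovie`."""

    frames: np.ndarray
    channel: str = "other"
    pixel_size_um: float = 0.21
    frame_interval_min: float = 5.0

    def __post_init__(self) -> None:
        self.frames = _as_stack(self.frames)
        self.frames = self.frames.astype(float, copy=False)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def check_aligned(self, movie: LabelMovie) -> None:
        if self.frames.shape != movie.frames.shape:
            raise ValueError(
                f"intensity stack shape {self.frames.shape} does not match "
                f"label movie shape {movie.frames.shape}"
            )
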