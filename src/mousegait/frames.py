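"""In-memory representation of a single RGB video frame."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True, eq=False)
class FrameImage:
    """One RGB frame of a trackway video.

    Parameters
    ----------
    pixels : ndarray of shape (height, width, 3), uint8
        Channel order is (R, G, B); values in [0, 255].
    frame_index : int
        0-based temporal index of the frame within its run.
    """

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must have shape (H, W, 3), got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("frame must be at least 1x1")
        if px.dtype != np.uint8:
            px = np.clip(np.round(px), 0, 255).astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def green(self) -> np.ndarray:
        """The G channel as an (H, W) uint8 view."""
        return self.pixels[:, :, 1]

    def with_pixels(self, pixels: np.ndarray) -> "FrameImage":
        return FrameImage(pixels, self.frame_index)
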