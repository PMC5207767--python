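"""Reading and writing stacks, tables and metadata.

Image stacks are multi-page TIFF (time x height x width, 16-bit grayscale)
via tifffile; tabular outputs are CSV via pandas; acquisition metadata
(pixel size in µm/px, frame interval in s, channel) travels as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageStack:
    """A time series of frames with its acquisition metadata."""

    frames: np.ndarray  # T x H x W
    pixel_size: float  # µm/px
    frame_interval: float = 1.0  # s
    channel: str = "Cy3"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be T x H x W with T >= 1")
        if not np.isfinite(self.frames.astype(float)).all():
            raise ValueError("frame intensities must be finite")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def write_stack(path: str | Path, frames: np.ndarray) -> Path:
    """Write a T x H x W array as a multi-page TIFF."""
    path = Path(path)
    arr = np.asarray(frames)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(path, arr)
    return path


def read_stack(
    path: str | Path,
    pixel_size: float,
    frame_interval: float = 1.0,
    channel: str = "Cy3",
) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return ImageStack(arr, pixel_size, frame_interval, channel)


def write_metadata(path: str | Path, **fields) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fields, indent=2, default=str))
    return path


def read_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
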