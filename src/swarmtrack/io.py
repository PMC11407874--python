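"""Image-stack and table I/O.

Image stacks are stored as multi-page grayscale TIFF plus a JSON sidecar
carrying the physical calibration (pixel size in µm/px, frame interval in
seconds) and an optional condition label.  All tables are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class FrameStack:
    """Time-ordered grayscale images with physical calibration.

    Coordinate convention: pixel (0, 0) is the top-left corner, x increases
    along columns and y along rows; a physical position (x, y) in µm maps to
    pixel-centre coordinates (col, row) = (x, y) / pixel_size.
    """

    frames: np.ndarray  # (T, H, W) non-negative intensities
    pixel_size: float  # µm per pixel
    frame_interval: float  # seconds between frames
    bit_depth: int = 8
    condition: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def field_um(self) -> tuple[float, float]:
        """Field of view (width, height) in µm."""
        h, w = self.shape
        return w * self.pixel_size, h * self.pixel_size


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a multi-page TIFF and its calibration sidecar JSON."""
    path = Path(path)
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    tifffile.imwrite(path, stack.frames.astype(dtype))
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "bit_depth": stack.bit_depth,
        "condition": stack.condition,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(sidecar_path(path).read_text())
    return FrameStack(
        frames=frames,
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_s"]),
        bit_depth=int(meta["bit_depth"]),
        condition=meta.get("condition"),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
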