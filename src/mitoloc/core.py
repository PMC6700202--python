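"""Core data containers and exceptions shared across the pipeline.

All images carry a physical pixel size (nm/px); all user-facing distances are
in nm. Pixel coordinates are 0-based ``(x, y)`` with ``x`` = column and ``y`` =
row (row index increases downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np


class PipelineError(RuntimeError):
    """Base class for errors raised by this package."""


class SizingError(PipelineError):
    """A phantom or kernel does not fit in the requested field."""


class MissingPixelSizeError(PipelineError):
    """No physical pixel size available for an image."""


class FitError(PipelineError):
    """A least-squares fit failed or produced unusable parameters."""


@dataclass
class Image2D:
    """A single-channel 2D intensity image with physical pixel size."""

    pixels: np.ndarray
    nm_per_px: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D requires finite pixel values")
        if not self.nm_per_px > 0:
            raise ValueError("nm_per_px must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack:
    """Ordered frames (time points or z-planes) sharing one pixel size."""

    frames: np.ndarray  # (n_frames, height, width)
    nm_per_px: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("ImageStack requires a 3D array (n, h, w)")
        if not self.nm_per_px > 0:
            raise ValueError("nm_per_px must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> Image2D:
        return Image2D(self.frames[i], self.nm_per_px, self.channel_label)


@dataclass
class Trace:
    """A time-stamped fluorescence series.

    ``baseline_window`` is an index range ``(start, stop)`` (stop exclusive)
    marking response-free samples used for baseline / bleach estimation.
    ``flags`` optionally marks unusable samples (True = flagged).
    """

    t: np.ndarray
    f: np.ndarray
    baseline_window: Optional[Tuple[int, int]] = None
    flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.shape != self.f.shape or self.t.ndim != 1:
            raise ValueError("t and f must be 1D arrays of equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time points must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def baseline_mean(self) -> float:
        if self.baseline_window is None:
            raise ValueError("trace has no baseline window")
        a, b = self.baseline_window
        return float(np.mean(self.f[a:b]))


@dataclass
class LineProfile:
    """An intensity profile sampled along a straight segment.

    Positions ``s`` are in nm with uniform spacing, 0 at the first sample.
    """

    s: np.ndarray
    v: np.ndarray
    endpoints_px: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None
    averaging_width_px: int = 1

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.s.shape != self.v.shape or self.s.ndim != 1:
            raise ValueError("s and v must be 1D arrays of equal length")
        if len(self.s) > 1:
            ds = np.diff(self.s)
            if not np.all(ds > 0):
                raise ValueError("profile positions must be strictly increasing")
            if not np.allclose(ds, ds[0], rtol=1e-6, atol=1e-9):
                raise ValueError("profile positions must be uniformly spaced")

    @property
    def spacing_nm(self) -> float:
        if len(self.s) < 2:
            raise ValueError("profile too short to define a spacing")
        return float(self.s[1] - self.s[0])

    def __len__(self) -> int:
        return len(self.s)
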