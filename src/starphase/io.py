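"""Image containers and TIFF/sidecar I/O.

The central container is :class:`ImageStack`: a ``frames x channels x rows x
cols`` array of nonnegative intensities together with the acquisition
metadata every downstream stage needs (pixel size in um/px, frame times,
channel names). Stacks round-trip through multi-page grayscale TIFF plus a
YAML sidecar, pages ordered channel-major (all frames of channel 0, then
channel 1, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["ImageStack", "load_stack"]


@dataclass
class ImageStack:
    """A time-lapse, multi-channel grayscale image with physical metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_frames, n_channels, rows, cols)`` with
        nonnegative intensities. Lower-dimensional arrays are promoted:
        2-D input becomes a single frame and channel, 3-D input is taken as
        ``(frames, rows, cols)`` with one channel.
    pixel_size:
        Lateral pixel size in micrometres per pixel.
    frame_times:
        Strictly increasing acquisition times, one per frame. Units are
        whatever the experiment used (minutes for fusion, seconds for FRAP).
    channel_names:
        One name per channel, e.g. ``["FITC", "Cy3"]``.
    """

    data: np.ndarray
    pixel_size: float
    frame_times: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        elif arr.ndim != 4:
            raise ValueError(f"expected 2-4 dimensional data, got {arr.ndim}")
        if np.any(arr < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/px)")
        self.data = arr
        if self.frame_times is None:
            self.frame_times = np.arange(arr.shape[0], dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (arr.shape[0],):
                raise ValueError("frame_times must have one entry per frame")
            if arr.shape[0] > 1 and np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(arr.shape[1])]
        if len(self.channel_names) != arr.shape[1]:
            raise ValueError("one channel name per channel required")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(rows, cols)``."""
        return self.data.shape[2:]

    def frame(self, t: int = 0, channel: int | str = 0) -> np.ndarray:
        """Return one ``rows x cols`` frame; channels may be named."""
        if isinstance(channel, str):
            channel = self.channel_names.index(channel)
        return self.data[t, channel]

    def channel_sum(self, t: int = 0) -> np.ndarray:
        """Sum of all channels at frame ``t`` (used for ROI segmentation)."""
        return self.data[t].sum(axis=0)

    def save(self, path: str | Path) -> Path:
        """Write a channel-major multi-page TIFF plus a ``.yaml`` sidecar."""
        path = Path(path)
        pages = self.data.transpose(1, 0, 2, 3).reshape(-1, *self.shape)
        tifffile.imwrite(path, pages.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".yaml")
        meta = {
            "pixel_size_um": float(self.pixel_size),
            "frame_times": [float(t) for t in self.frame_times],
            "channel_names": list(self.channel_names),
            "n_frames": int(self.n_frames),
            "n_channels": int(self.n_channels),
            "page_order": "channel-major",
        }
        sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
        return path


def load_stack(path: str | Path) -> ImageStack:
    """Load an :class:`ImageStack` written by :meth:`ImageStack.save`.

    A bare TIFF without sidecar is accepted and treated as a single-channel
    stack with unit pixel size.
    """
    path = Path(path)
    pages = np.asarray(tifffile.imread(path), dtype=float)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        n_frames = int(meta["n_frames"])
        n_channels = int(meta["n_channels"])
        data = pages.reshape(n_channels, n_frames, *pages.shape[-2:])
        data = data.transpose(1, 0, 2, 3)
        return ImageStack(
            data,
            pixel_size=float(meta["pixel_size_um"]),
            frame_times=np.asarray(meta["frame_times"], dtype=float),
            channel_names=list(meta["channel_names"]),
        )
    return ImageStack(pages[:, None], pixel_size=1.0)
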