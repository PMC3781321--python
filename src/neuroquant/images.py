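"""Multi-channel image container and TIFF round-trip helpers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MultiChannelImage:
    """A stack of equally shaped 2D channels with physical pixel size.

    ``data`` has shape ``(n_channels, H, W)``; ``channel_names`` gives one
    name per channel.  ``masks`` optionally carries ground-truth label masks
    (e.g. per-protrusion labels from a renderer), keyed by name.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, H, W)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one name per channel required")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    def channel(self, name: str) -> np.ndarray:
        """Return the 2D array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None
        return self.data[idx]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


def write_tiff(img: MultiChannelImage, path: str | Path) -> None:
    """Write channels as a multi-page TIFF with names and pixel size in metadata."""
    meta = {
        "channel_names": img.channel_names,
        "pixel_size_um": img.pixel_size_um,
    }
    tifffile.imwrite(
        str(path),
        np.asarray(img.data),
        metadata=None,
        description=json.dumps(meta),
    )


def read_tiff(path: str | Path) -> MultiChannelImage:
    """Read a multi-page TIFF written by :func:`write_tiff`."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    if data.ndim == 2:
        data = data[None]
    return MultiChannelImage(
        data=data,
        channel_names=list(meta["channel_names"]),
        pixel_size_um=float(meta["pixel_size_um"]),
    )
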