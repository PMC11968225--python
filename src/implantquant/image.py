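"""Multi-channel section image container and TIFF I/O.

The unit of image analysis is a set of aligned grayscale channels (one per
stain) sharing a physical pixel size in micrometres, plus the section
metadata (mouse, treatment group, timepoint, replicate) that every derived
record must carry downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MultiplexImage:
    """Aligned grayscale channels with a shared isotropic pixel size.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"DAPI"``, ``"CD68"``) to a 2D
        float array. All arrays must share one shape.
    pixel_size_um
        Physical size of one pixel in micrometres (isotropic).
    meta
        Section metadata: image id, mouse id, group, timepoint, replicate.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            )
        return self.channels[name]

    def to_tiff(self, path: str | Path) -> None:
        """Write all channels as one multi-page TIFF with JSON metadata."""
        names = list(self.channels)
        stack = np.stack([np.asarray(self.channels[n], dtype=np.float32) for n in names])
        desc = json.dumps(
            {"channels": names, "pixel_size_um": self.pixel_size_um, "meta": self.meta}
        )
        tifffile.imwrite(path, stack, description=desc)

    @classmethod
    def from_tiff(cls, path: str | Path) -> "MultiplexImage":
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description
        info = json.loads(desc)
        if stack.ndim == 2:
            stack = stack[None]
        channels = {n: stack[i] for i, n in enumerate(info["channels"])}
        return cls(channels, float(info["pixel_size_um"]), info.get("meta", {}))
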