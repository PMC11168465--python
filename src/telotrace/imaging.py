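"""Voxel containers and TIFF I/O.

All physical coordinates in this package are micrometres, ordered (z, y, x)
to match the axis order of the voxel arrays.  Voxel index (0, 0, 0) has its
centre at physical position (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]

#: default confocal voxel size in μm (z, y, x)
DEFAULT_VOXEL_SIZE = (0.3, 0.133, 0.133)


@dataclass
class ImageStack:
    """A multi-channel 3D image, optionally a time series.

    Parameters
    ----------
    voxels
        Intensity array, ``(channel, z, y, x)`` for a fixed image or
        ``(frame, channel, z, y, x)`` for a time-lapse movie.
    voxel_size
        Physical voxel dimensions in μm, ordered ``(z, y, x)``.
    frame_interval
        Seconds between frames; ``None`` for fixed images.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    frame_interval: float | None = None
    channel_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (4, 5):
            raise ValueError(
                "voxels must be (channel, z, y, x) or (frame, channel, z, y, x); "
                f"got ndim={self.voxels.ndim}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.voxel_size = vs
        if self.is_timelapse and self.frame_interval is None:
            raise ValueError("time-lapse stack requires frame_interval")
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    # -- shape helpers ----------------------------------------------------
    @property
    def is_timelapse(self) -> bool:
        return self.voxels.ndim == 5

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0] if self.is_timelapse else 1

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[1] if self.is_timelapse else self.voxels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Spatial (z, y, x) shape."""
        return tuple(self.voxels.shape[-3:])

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in μm³."""
        return float(np.prod(self.voxel_size))

    def channel(self, c: int) -> np.ndarray:
        """3D array for channel ``c`` (fixed images only)."""
        if self.is_timelapse:
            raise ValueError("use frame(t) then index channels for a time-lapse stack")
        return self.voxels[c]

    def frame(self, t: int) -> "ImageStack":
        """Single-frame view of a time-lapse stack."""
        if not self.is_timelapse:
            raise ValueError("not a time-lapse stack")
        return ImageStack(self.voxels[t], self.voxel_size, None, self.channel_names)

    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) * (self.frame_interval or 0.0)


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as OME-TIFF, preserving voxel size metadata."""
    axes = "TCZYX" if stack.is_timelapse else "CZYX"
    meta = {
        "axes": axes,
        "PhysicalSizeZ": stack.voxel_size[0],
        "PhysicalSizeY": stack.voxel_size[1],
        "PhysicalSizeX": stack.voxel_size[2],
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
    }
    if stack.frame_interval is not None:
        meta["TimeIncrement"] = stack.frame_interval
        meta["TimeIncrementUnit"] = "s"
    tifffile.imwrite(path, stack.voxels.astype(np.float32), ome=True, metadata=meta)


def read_stack(
    path,
    voxel_size: tuple[float, float, float] | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read an (OME-)TIFF stack written by :func:`write_stack`.

    ``voxel_size``/``frame_interval`` override whatever metadata carries.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        if voxel_size is None or frame_interval is None:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tf.ome_metadata or "")
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                px = root.find(".//ome:Pixels", ns)
                if voxel_size is None and px is not None:
                    voxel_size = (
                        float(px.get("PhysicalSizeZ", 0.3)),
                        float(px.get("PhysicalSizeY", 0.133)),
                        float(px.get("PhysicalSizeX", 0.133)),
                    )
                if frame_interval is None and px is not None and px.get("TimeIncrement"):
                    frame_interval = float(px.get("TimeIncrement"))
            except Exception:
                pass
    if voxel_size is None:
        voxel_size = DEFAULT_VOXEL_SIZE
    return ImageStack(arr, voxel_size, frame_interval)
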