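"""Channel-stack container and OME-TIFF I/O.

A :class:`ChannelStack` couples a single-channel intensity array with the
acquisition metadata (lateral/axial voxel size, frame interval) that the
downstream metrics need to report physical units.  Axis order is always a
suffix of ``(t, z, y, x)``; the ``axes`` string records which axes are
present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

VALID_AXES = ("YX", "TYX", "ZYX", "TZYX")


@dataclass
class ChannelStack:
    """Single-channel intensity grid with acquisition metadata.

    Parameters
    ----------
    data
        Non-negative intensities, shaped according to ``axes``.
    axes
        One of ``"YX"``, ``"TYX"``, ``"ZYX"``, ``"TZYX"``.
    voxel_size_xy
        Lateral pixel size in µm/pixel.
    voxel_size_z
        Axial step in µm/plane (``None`` for 2D data).
    frame_interval
        Seconds between frames (``None`` for single time points).
    channel
        Free-text channel label, e.g. ``"microglia"`` or ``"nodes"``.
    """

    data: np.ndarray
    axes: str = "YX"
    voxel_size_xy: float = 1.0
    voxel_size_z: float | None = None
    frame_interval: float | None = None
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.axes not in VALID_AXES:
            raise ValueError(f"axes must be one of {VALID_AXES}, got {self.axes!r}")
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dims but axes={self.axes!r}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.voxel_size_xy <= 0:
            raise ValueError("voxel_size_xy must be positive")
        if "Z" in self.axes and (self.voxel_size_z is None or self.voxel_size_z <= 0):
            raise ValueError("z-stack requires positive voxel_size_z")
        if "T" in self.axes and (self.frame_interval is None or self.frame_interval <= 0):
            raise ValueError("time-lapse requires positive frame_interval")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if "T" in self.axes else 1

    def frame(self, t: int) -> np.ndarray:
        """Spatial array at time ``t`` (the array itself if no T axis)."""
        return self.data[t] if "T" in self.axes else self.data

    def middle_plane(self) -> np.ndarray:
        """Central z-plane (2D, or (t, y, x) for movies); identity for 2D data."""
        if "Z" not in self.axes:
            return self.data
        z_axis = self.axes.index("Z")
        return np.take(self.data, self.data.shape[z_axis] // 2, axis=z_axis)


def write_stack(path, stack: ChannelStack) -> None:
    """Write a :class:`ChannelStack` as OME-TIFF, embedding pixel sizes."""
    meta = {"axes": stack.axes}
    if stack.frame_interval is not None:
        meta["TimeIncrement"] = stack.frame_interval
        meta["TimeIncrementUnit"] = "s"
    meta["PhysicalSizeX"] = stack.voxel_size_xy
    meta["PhysicalSizeY"] = stack.voxel_size_xy
    if stack.voxel_size_z is not None:
        meta["PhysicalSizeZ"] = stack.voxel_size_z
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        photometric="minisblack",
        metadata=meta,
        ome=True,
    )


def read_stack(path, channel: str = "") -> ChannelStack:
    """Read an OME-TIFF written by :func:`write_stack`."""
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.replace("Q", "T")  # tifffile may report unknown axis
        vx = 1.0
        vz = None
        dt = None
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                vx = float(px.get("PhysicalSizeX", 1.0))
                if px.get("PhysicalSizeZ") is not None:
                    vz = float(px.get("PhysicalSizeZ"))
                if px.get("TimeIncrement") is not None:
                    dt = float(px.get("TimeIncrement"))
    # drop axes outside our vocabulary (e.g. a singleton C axis)
    axes_clean = "".join(a for a in axes if a in "TZYX")
    if data.ndim != len(axes_clean):
        data = data.reshape([n for n, a in zip(data.shape, axes) if a in "TZYX"])
    if "Z" in axes_clean and vz is None:
        vz = 1.0
    if "T" in axes_clean and dt is None:
        dt = 1.0
    return ChannelStack(
        data=data,
        axes=axes_clean,
        voxel_size_xy=vx,
        voxel_size_z=vz,
        frame_interval=dt,
        channel=channel,
    )
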