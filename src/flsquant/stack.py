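"""Calibrated multichannel z-stack container and TIFF I/O.

A :class:`VoxelStack` is the unit of analysis for one imaged field of view:
a ``(channel, z, y, x)`` intensity array plus the voxel calibration needed
to report every downstream geometry in micrometres.

Coordinate convention: pixel indices are 0-based and refer to pixel
centres, so in-plane position in µm is ``index * pixel_size_xy`` and axial
position is ``z_index * z_spacing``.  ``base_slice`` marks the z-plane of
the supported lipid bilayer from which structures emanate (index 0 in
synthetic stacks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelStack", "read_stack", "write_stack"]


@dataclass
class VoxelStack:
    intensities: np.ndarray  # (C, Z, Y, X), arbitrary units
    pixel_size_xy: float  # µm
    z_spacing: float  # µm
    channel_names: tuple[str, ...] = ("actin", "probe")
    base_slice: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim == 3:  # single channel
            self.intensities = self.intensities[None]
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be a (C, Z, Y, X) array")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.intensities.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.intensities.shape[0]} channels"
            )
        if self.pixel_size_xy <= 0 or self.z_spacing <= 0:
            raise ValueError("voxel calibration must be positive")
        if not 0 <= self.base_slice < self.intensities.shape[1]:
            raise ValueError("base_slice outside z range")

    # -- convenience accessors -------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; available: {self.channel_names}"
            ) from None

    def channel(self, channel: str | int) -> np.ndarray:
        """(Z, Y, X) view of one channel."""
        return self.intensities[self.channel_index(channel)]

    def slice(self, channel: str | int, z: int) -> np.ndarray:
        if not 0 <= z < self.n_slices:
            raise IndexError(f"z={z} outside stack of {self.n_slices} slices")
        return self.intensities[self.channel_index(channel), z]


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with a JSON calibration sidecar.

    Calibration and channel names go into the OME metadata; the sidecar
    duplicates them so that round-tripping never depends on a particular
    TIFF reader's metadata handling.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.intensities.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_spacing,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_xy_um": stack.pixel_size_xy,
                "z_spacing_um": stack.z_spacing,
                "channel_names": list(stack.channel_names),
                "base_slice": stack.base_slice,
            },
            indent=2,
        )
    )
    return path


def read_stack(
    path: str | Path,
    pixel_size_xy: float | None = None,
    z_spacing: float | None = None,
    channel_names: tuple[str, ...] | None = None,
    base_slice: int | None = None,
) -> VoxelStack:
    """Read a TIFF/OME-TIFF stack written by :func:`write_stack`.

    Explicit keyword arguments override the sidecar/metadata, which lets
    the same reader ingest third-party TIFFs that carry no calibration.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size_xy if pixel_size_xy is not None else meta.get("pixel_size_xy_um")
    dz = z_spacing if z_spacing is not None else meta.get("z_spacing_um")
    names = channel_names if channel_names is not None else meta.get("channel_names")
    base = base_slice if base_slice is not None else meta.get("base_slice", 0)
    if px is None or dz is None:
        raise ValueError(
            f"no voxel calibration for {path}: pass pixel_size_xy and z_spacing"
        )
    if names is None:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return VoxelStack(
        intensities=data,
        pixel_size_xy=float(px),
        z_spacing=float(dz),
        channel_names=tuple(names),
        base_slice=int(base),
    )
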