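"""Image-stack container, TIFF/OME-TIFF I/O, Z-projection and channel splitting.

The in-memory container is :class:`ImageStack`: a ``(channel, z, y, x)``
float array plus the physical voxel size in µm.  All downstream coordinates
follow a 0-based, pixel-centre convention: the physical position of index
``i`` along an axis is ``i * voxel_um`` for that axis.

The Z-projection implemented here is the per-pixel *sample* standard
deviation (``ddof=1``) across slices — the "Standard Deviation" projection
of ImageJ — which turns a z-stack of blobs and puncta into a 2D image whose
local maxima sit at the lateral positions of the 3D objects.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .errors import MetadataError, ParameterError

__all__ = ["ImageStack", "read_stack", "write_stack", "project_z_sd", "split_channels"]


@dataclass
class ImageStack:
    """Multi-channel, multi-slice image with voxel-size metadata.

    Parameters
    ----------
    pixels
        Array of shape ``(n_channels, n_z, n_y, n_x)`` of non-negative
        intensities (float; negatives may appear after simulated read
        noise and are tolerated).
    voxel_um
        Physical voxel size ``(z, y, x)`` in µm, or ``None`` if unknown.
    channel_names
        One label per channel; defaults to ``ch0, ch1, ...``.
    """

    pixels: np.ndarray
    voxel_um: Optional[tuple[float, float, float]] = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ParameterError(
                f"pixels must be (c, z, y, x); got ndim={self.pixels.ndim}"
            )
        if self.voxel_um is not None:
            vz, vy, vx = self.voxel_um
            if not (vz > 0 and vy > 0 and vx > 0):
                raise ParameterError(f"voxel sizes must be > 0; got {self.voxel_um}")
            self.voxel_um = (float(vz), float(vy), float(vx))
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.pixels.shape[0])]
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ParameterError("channel_names length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.pixels.shape[1:]

    def channel_index(self, channel: Union[int, str]) -> int:
        if isinstance(channel, (int, np.integer)):
            idx = int(channel)
            if not 0 <= idx < self.n_channels:
                raise ParameterError(
                    f"channel index {idx} out of range 0..{self.n_channels - 1}"
                )
            return idx
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ParameterError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    def channel(self, channel: Union[int, str]) -> np.ndarray:
        """Pixel data ``(z, y, x)`` of one channel."""
        return self.pixels[self.channel_index(channel)]

    def require_voxel_um(self) -> tuple[float, float, float]:
        from .errors import UnitError

        if self.voxel_um is None:
            raise UnitError("voxel size is unknown; supply voxel_um explicitly")
        return self.voxel_um


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stack(path: Union[str, Path], stack: ImageStack) -> Path:
    """Write an :class:`ImageStack` as OME-TIFF with PhysicalSize metadata."""
    path = Path(path)
    metadata: dict = {"axes": "CZYX"}
    if stack.voxel_um is not None:
        vz, vy, vx = stack.voxel_um
        metadata.update(
            PhysicalSizeX=vx, PhysicalSizeXUnit="µm",
            PhysicalSizeY=vy, PhysicalSizeYUnit="µm",
            PhysicalSizeZ=vz, PhysicalSizeZUnit="µm",
        )
    metadata["Channel"] = {"Name": list(stack.channel_names)}
    tifffile.imwrite(
        path,
        np.asarray(stack.pixels, dtype=np.float32),
        ome=True,
        metadata=metadata,
    )
    return path


_UNIT_TO_UM = {"µm": 1.0, "um": 1.0, "micron": 1.0, "nm": 1e-3, "mm": 1e3}


def _parse_ome_voxel(ome_xml: str) -> tuple[Optional[tuple[float, float, float]], list[str]]:
    """Extract (z, y, x) voxel size in µm and channel names from OME-XML."""
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pix = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    if pix is None:
        return None, []

    def _size(axis: str) -> Optional[float]:
        v = pix.get(f"PhysicalSize{axis}")
        if v is None:
            return None
        unit = pix.get(f"PhysicalSize{axis}Unit", "µm")
        return float(v) * _UNIT_TO_UM.get(unit, 1.0)

    sx, sy, sz = _size("X"), _size("Y"), _size("Z")
    voxel = None
    if sx is not None and sy is not None and sz is not None:
        voxel = (sz, sy, sx)
    names = []
    ch_iter = pix.findall("ome:Channel", ns) if ns else pix.findall("Channel")
    for ch in ch_iter:
        names.append(ch.get("Name") or "")
    if any(not n for n in names):
        names = []
    return voxel, names


def read_stack(path: Union[str, Path]) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Axis order is taken from the file's series metadata and normalised to
    ``(c, z, y, x)``; missing C or Z axes get extent 1.  If no physical
    pixel size is recorded the stack is returned with ``voxel_um=None``
    and a warning (downstream stages that need µm will refuse to run).

    Raises
    ------
    OSError
        Unreadable or truncated file; no partial stack is returned.
    MetadataError
        The axis string contains axes other than C/Z/Y/X (plus a
        trivially squeezable sample/time axis).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes.upper()
        data = series.asarray()
        ome_xml = tf.ome_metadata

    # squeeze singleton non-spatial axes, map an unlabelled page axis
    # (plain multi-page TIFF: Q/I/S) to Z, then normalise to CZYX
    keep: list[str] = []
    shape: list[int] = []
    for ax, n in zip(axes, data.shape):
        if ax in "QIS" and n > 1 and "Z" not in axes and "Z" not in keep:
            ax = "Z"
        if ax in "CZYX":
            keep.append(ax)
            shape.append(n)
        elif n == 1:
            continue
        else:
            raise MetadataError(
                f"ambiguous axis order {axes!r} in {path.name}: "
                f"unsupported non-singleton axis {ax!r}"
            )
    data = data.reshape(shape)
    axes = "".join(keep)
    if "Y" not in axes or "X" not in axes:
        raise MetadataError(f"no spatial axes found in {path.name} (axes={axes!r})")
    for missing in ("C", "Z"):
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(ax) for ax in "CZYX"]
    data = np.transpose(data, order).astype(np.float32)

    voxel_um = None
    names: list[str] = []
    if ome_xml:
        try:
            voxel_um, names = _parse_ome_voxel(ome_xml)
        except ET.ParseError:
            voxel_um, names = None, []
    if voxel_um is None:
        warnings.warn(
            f"{path.name}: no physical voxel size in metadata; "
            "coordinates will be in pixels until voxel_um is set",
            stacklevel=2,
        )
    return ImageStack(pixels=data, voxel_um=voxel_um,
                      channel_names=names or [f"ch{i}" for i in range(data.shape[0])])


# ---------------------------------------------------------------------------
# Projection and splitting
# ---------------------------------------------------------------------------

def project_z_sd(stack: ImageStack, channel: Union[int, str]) -> np.ndarray:
    """Standard-deviation Z-projection of one channel.

    Returns the per-pixel sample standard deviation (``ddof=1``) across z,
    as a 2D ``(y, x)`` float64 array.  A stack with a single slice is
    returned unchanged with a warning (there is nothing to project).
    """
    data = stack.channel(channel)
    if data.shape[0] < 2:
        warnings.warn("z-extent is 1; returning the single slice unprojected",
                      stacklevel=2)
        return data[0].astype(np.float64)
    return np.std(data.astype(np.float64), axis=0, ddof=1)


def split_channels(stack: ImageStack) -> list[ImageStack]:
    """Split into single-channel stacks; metadata preserved.

    Concatenating the returned stacks' pixels along axis 0 reconstructs
    the original pixel array exactly.
    """
    return [
        replace(stack, pixels=stack.pixels[i : i + 1],
                channel_names=[stack.channel_names[i]])
        for i in range(stack.n_channels)
    ]
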