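"""Micrograph input/output and the internal image model.

Images are held as a ``(channel, z, y, x)`` float array together with the
in-plane physical pixel size in µm/pixel and ordered channel labels. All
downstream morphometry assumes an isotropic in-plane scale; anisotropic
calibration is rejected rather than averaged. Supported on-disk formats are
plain TIFF and OME-TIFF (axes YX, CYX or CZYX); the physical pixel size is
taken from OME metadata when present, otherwise a user override is required.

Coordinate convention throughout the package: 0-based, row-major ``(y, x)``
with the origin at the top-left.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "ChannelMap",
    "read_image",
    "write_image",
    "max_intensity_projection",
]


@dataclass(frozen=True)
class ImageStack:
    """A multi-channel, optionally z-stacked fluorescence image.

    Parameters
    ----------
    pixels
        Intensity grid indexed ``(channel, z, y, x)``; a single-plane image
        has z-extent 1. Intensities must be non-negative.
    pixel_size_um
        In-plane physical pixel size, µm/pixel (isotropic).
    channel_labels
        Ordered, unique channel names, e.g. ``("ARL13B", "DAPI")``.
    source_id
        Provenance string (file path or simulator tag).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_labels: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 4:
            raise ValueError(f"pixels must be (channel, z, y, x); got ndim={px.ndim}")
        if px.size and px.min() < 0:
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0; got {self.pixel_size_um}")
        labels = tuple(self.channel_labels)
        if len(labels) != px.shape[0]:
            raise ValueError(
                f"{len(labels)} channel labels for {px.shape[0]} channels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError(f"channel labels must be unique: {labels}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel_index(self, channel: str | int) -> int:
        """Resolve a channel given by name or integer index."""
        if isinstance(channel, (int, np.integer)):
            idx = int(channel)
            if not 0 <= idx < self.n_channels:
                raise KeyError(f"channel index {idx} out of range (n={self.n_channels})")
            return idx
        try:
            return self.channel_labels.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in {self.channel_labels}"
            ) from None


@dataclass(frozen=True)
class ChannelMap:
    """Names (or indices) of the cilium-marker and nuclear-stain channels."""

    cilia_channel: str | int = "ARL13B"
    nuclei_channel: str | int = "DAPI"

    def validate(self, stack: ImageStack) -> tuple[int, int]:
        ci = stack.channel_index(self.cilia_channel)
        ni = stack.channel_index(self.nuclei_channel)
        if ci == ni:
            raise ValueError("cilia and nuclei channels must be distinct")
        return ci, ni


def _parse_ome(ome_xml: str) -> tuple[float | None, float | None, list[str]]:
    """Extract (PhysicalSizeX, PhysicalSizeY, channel names) from OME XML."""
    root = ET.fromstring(ome_xml)
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    sx = sy = None
    names: list[str] = []
    for pixels in root.iter(f"{ns}Pixels"):
        if pixels.get("PhysicalSizeX") is not None:
            sx = float(pixels.get("PhysicalSizeX"))
        if pixels.get("PhysicalSizeY") is not None:
            sy = float(pixels.get("PhysicalSizeY"))
        for ch in pixels.iter(f"{ns}Channel"):
            name = ch.get("Name")
            if name:
                names.append(name)
        break
    return sx, sy, names


def _to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Normalise a tifffile array with known axes to (C, Z, Y, X)."""
    axes = axes.upper()
    # Unlabelled leading axes (plain TIFF reports Q/S/I): take the first
    # non-singleton one as channels, a second as z; drop singletons.
    relabelled = list(axes)
    for i, a in enumerate(relabelled):
        if a not in "CZYX" and data.shape[i] > 1:
            if "C" not in relabelled:
                relabelled[i] = "C"
            elif "Z" not in relabelled:
                relabelled[i] = "Z"
            else:
                raise ValueError(
                    f"unsupported axis {a!r} with extent {data.shape[i]}"
                )
    axes = "".join(relabelled)
    keep = [i for i, a in enumerate(axes) if a in "CZYX"]
    extra = [i for i in range(len(axes)) if i not in keep]
    for i in sorted(extra, reverse=True):
        data = np.squeeze(data, axis=i)
    axes = "".join(axes[i] for i in keep)
    for missing in "CZ":
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def read_image(
    path: str | Path,
    channel_map: ChannelMap | None = None,
    pixel_size_override: float | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF micrograph into an :class:`ImageStack`.

    The physical pixel size is taken from OME ``PhysicalSizeX`` /
    ``PhysicalSizeY`` metadata when present, otherwise from
    ``pixel_size_override``. Anisotropic calibration (X ≠ Y) is an error.
    Channel order matches the file; OME channel names are used as labels when
    available, else ``"C0", "C1", ...``.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If no pixel size is available, the calibration is anisotropic, or a
        channel named in ``channel_map`` is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        ome_xml = tif.ome_metadata

    pixels = _to_czyx(np.asarray(data), axes)

    size = None
    names: list[str] = []
    if ome_xml:
        sx, sy, names = _parse_ome(ome_xml)
        if sx is not None and sy is not None:
            if not np.isclose(sx, sy, rtol=1e-6):
                raise ValueError(
                    f"anisotropic pixel size not supported: X={sx}, Y={sy} µm"
                )
            size = sx
        elif sx is not None:
            size = sx
    if pixel_size_override is not None:
        size = float(pixel_size_override)
    if size is None:
        raise ValueError(
            f"{path}: no physical pixel size in metadata; pass pixel_size_override"
        )

    if len(names) != pixels.shape[0]:
        names = [f"C{i}" for i in range(pixels.shape[0])]

    stack = ImageStack(
        pixels=pixels.astype(np.float32, copy=False),
        pixel_size_um=size,
        channel_labels=tuple(names),
        source_id=str(path),
    )
    if channel_map is not None:
        channel_map.validate(stack)
    return stack


def write_image(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as OME-TIFF with physical pixel size.

    Pixels are stored as float32, so a write/read round trip preserves the
    grid bit-for-bit for float32 inputs.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        str(path),
        stack.pixels.astype(np.float32, copy=False),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": list(stack.channel_labels)},
        },
    )
    return path


def max_intensity_projection(stack: ImageStack, channel: str | int) -> np.ndarray:
    """Per-pixel maximum over z of one channel — the 2D working image.

    For a single-plane stack this is the plane itself. Idempotent and
    invariant to any permutation of the z planes.
    """
    idx = stack.channel_index(channel)
    return stack.pixels[idx].max(axis=0)
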