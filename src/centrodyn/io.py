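"""Image stack I/O.

Stacks are stored as OME-TIFF with axes T,C,Y,X.  Pixel size (μm/px) and
frame interval (min) travel in the OME metadata; a stack without either
calibration must be given an explicit override — positions are never
silently reported in pixel units.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


class CalibrationError(ValueError):
    """Raised when a stack carries no spatial/temporal calibration."""


@dataclass
class ImageStack:
    """A multi-channel time-lapse: data indexed (T, C, Y, X)."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    channels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim == 3:  # single channel: T,Y,X -> T,1,Y,X
            self.data = self.data[:, None, :, :]
        if self.data.ndim != 4:
            raise ValueError(f"expected T,C,Y,X data, got shape {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise CalibrationError("pixel size must be positive")
        if self.frame_interval_min <= 0:
            raise CalibrationError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """(T, Y, X) view of the channel playing `role`."""
        if role not in self.channels:
            raise KeyError(
                f"channel role {role!r} not in stack (have {sorted(self.channels)})"
            )
        return self.data[:, self.channels[role]]

    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an OME-TIFF with axes TCYX and physical calibration."""
    names = [None] * stack.n_channels
    for role, idx in stack.channels.items():
        names[idx] = role
    meta = {
        "axes": "TCYX",
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "TimeIncrement": stack.frame_interval_min,
        "TimeIncrementUnit": "min",
        "Channel": {"Name": [n or f"ch{i}" for i, n in enumerate(names)]},
    }
    tifffile.imwrite(path, stack.data, ome=True, metadata=meta)


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
    channels: dict[str, int] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack; overrides win over file metadata.

    Raises CalibrationError if neither the file nor the caller supplies
    pixel size and frame interval.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            px, dt, names = _parse_ome(tf.ome_metadata)
    except (tifffile.TiffFileError, IsADirectoryError) as exc:
        raise ValueError(f"not a readable TIFF file: {path}") from exc

    data = _to_tcyx(data, axes)

    px = pixel_size_um if pixel_size_um is not None else px
    dt = frame_interval_min if frame_interval_min is not None else dt
    if px is None:
        raise CalibrationError(
            f"{path}: no pixel size in metadata and no override given"
        )
    if dt is None:
        raise CalibrationError(
            f"{path}: no frame interval in metadata and no override given"
        )

    if channels is None:
        channels = {n: i for i, n in enumerate(names)} if names else {}
    return ImageStack(data, px, dt, channels)


def _parse_ome(xml_text: str | None):
    if not xml_text:
        return None, None, None
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None, None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pix = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pix is None:
        return None, None, None
    px = pix.get("PhysicalSizeX")
    dt = pix.get("TimeIncrement")
    chans = pix.findall("ome:Channel" if ns else "Channel", ns)
    names = [c.get("Name") for c in chans if c.get("Name")]
    return (
        float(px) if px else None,
        float(dt) if dt else None,
        names or None,
    )


def _to_tcyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Normalize any of T/C/Z/Y/X orders to T,C,Y,X (max-project Z)."""
    axes = axes.upper()
    if "Q" in axes:  # tifffile labels unknown axes Q
        axes = axes.replace("Q", "T", 1)
    for ax in "TC":
        if ax not in axes:
            data = data[None]
            axes = ax + axes
    order = [axes.index(a) for a in "TCYX" if a in axes]
    extra = [i for i, a in enumerate(axes) if a not in "TCYX"]
    data = np.transpose(data, order[:2] + extra + order[2:])
    # collapse Z (and anything else) by max projection, matching the
    # maximum-intensity-projection imaging regime
    while data.ndim > 4:
        data = data.max(axis=2)
    return data
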