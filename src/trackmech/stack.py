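"""Time-lapse image stack container and TIFF I/O.

The canonical in-memory layout is a ``(T, C, Y, X)`` float array with the
pixel size in µm/px and the frame interval in minutes.  Channels are named
by their biological role: ``reflection`` (collagen speckle signal),
``cytoplasm`` and ``nucleus``.  Stacks round-trip through multi-page TIFF
with a small YAML sidecar carrying the calibration (TIFF itself does not
reliably preserve a frame interval in minutes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

#: Channel roles recognised throughout the package.
REFLECTION = "reflection"
CYTOPLASM = "cytoplasm"
NUCLEUS = "nucleus"

KNOWN_ROLES = (REFLECTION, CYTOPLASM, NUCLEUS)


@dataclass
class TimelapseStack:
    """A ``(T, C, Y, X)`` time-lapse image stack with physical calibration.

    Parameters
    ----------
    data
        Intensities, shape ``(T, C, Y, X)``.
    pixel_size
        Lateral pixel size in µm/px (isotropic).
    frame_interval
        Time between frames in minutes.
    channel_roles
        One role string per channel, e.g. ``("reflection", "cytoplasm",
        "nucleus")``.  Every channel must be named.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_roles: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be (T, C, Y, X), got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.data.shape[1]:
            raise ValueError(
                f"channel_roles has {len(self.channel_roles)} entries for "
                f"{self.data.shape[1]} channels"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes."""
        return np.arange(self.n_frames) * float(self.frame_interval)

    # -- channel access -------------------------------------------------
    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}; have {self.channel_roles}") from None

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(T, Y, X)`` sub-stack for one channel role."""
        return self.data[:, self.channel_index(role)]

    def with_data(self, data: np.ndarray) -> "TimelapseStack":
        """New stack sharing this stack's calibration."""
        return TimelapseStack(
            data=data,
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            channel_roles=self.channel_roles,
        )

    # -- I/O -------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF (axes TCYX) plus a YAML calibration sidecar."""
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.data, dtype=np.float32),
                         photometric="minisblack", metadata={"axes": "TCYX"})
        sidecar = {
            "axes": "TCYX",
            "pixel_size_um": float(self.pixel_size),
            "frame_interval_min": float(self.frame_interval),
            "channel_roles": list(self.channel_roles),
        }
        Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "TimelapseStack":
        """Read a stack written by :meth:`save`."""
        path = Path(path)
        data = tifffile.imread(path)
        meta = yaml.safe_load(Path(str(path) + ".yaml").read_text())
        data = np.asarray(data)
        if data.ndim == 3:  # single channel collapsed by the writer
            data = data[:, None]
        return cls(
            data=data,
            pixel_size=float(meta["pixel_size_um"]),
            frame_interval=float(meta["frame_interval_min"]),
            channel_roles=tuple(meta["channel_roles"]),
        )
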