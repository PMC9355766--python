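"""Core image containers and TIFF + JSON-sidecar I/O.

A multiphoton acquisition is represented by :class:`MPImage` — one 2-D
grayscale intensity field tagged with its contrast channel (TPEF or SHG),
the incident linear-polarization angle (for polarimetric SHG frames), and
the physical pixel size.  Three co-registered SHG frames taken at different
polarization states form a :class:`PolarimetricStack`.

On disk each image is a single-channel TIFF next to a ``.json`` sidecar
carrying the metadata (specimen id, age, sex, channel, polarization angle,
pixel size, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile

CHANNELS = ("TPEF", "SHG")


class CoRegistrationError(ValueError):
    """Raised when paired images disagree in shape, pixel size or channel tag."""


@dataclass
class MPImage:
    """One 2-D multiphoton intensity field.

    Parameters
    ----------
    data
        2-D array of detected intensity (arbitrary detector units).
    channel
        ``"TPEF"`` or ``"SHG"``.
    pixel_size_um
        Physical size of one pixel in micrometres.
    polarization_deg
        Incident linear-polarization angle for polarimetric SHG frames,
        ``None`` for unpolarized acquisitions.
    meta
        Free-form metadata (specimen id, age, sex, region id, seed ...).
    """

    data: np.ndarray
    channel: str
    pixel_size_um: float
    polarization_deg: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"MPImage data must be 2-D, got shape {self.data.shape}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def field_um(self) -> float:
        """Physical width of the field of view in micrometres."""
        return self.data.shape[1] * self.pixel_size_um

    def sidecar(self) -> dict[str, Any]:
        """Metadata dictionary written next to the TIFF."""
        out = {
            "channel": self.channel,
            "polarization_deg": self.polarization_deg,
            "pixel_size_um": self.pixel_size_um,
        }
        out.update(self.meta)
        return out

    def save(self, path: str | Path) -> Path:
        """Write the image as TIFF plus a ``.json`` sidecar; returns the TIFF path."""
        path = Path(path)
        data = self.data
        if np.issubdtype(data.dtype, np.integer):
            arr = data.astype(np.uint16 if data.max(initial=0) < 2**16 else np.uint32)
        else:
            arr = data.astype(np.float32)
        tifffile.imwrite(path, arr)
        path.with_suffix(".json").write_text(
            json.dumps(self.sidecar(), indent=1, sort_keys=True)
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MPImage":
        """Read a TIFF written by :meth:`save`, restoring metadata from the sidecar."""
        path = Path(path)
        data = tifffile.imread(path)
        side = json.loads(path.with_suffix(".json").read_text())
        channel = side.pop("channel")
        pol = side.pop("polarization_deg", None)
        px = side.pop("pixel_size_um")
        return cls(data=data, channel=channel, pixel_size_um=px,
                   polarization_deg=pol, meta=side)


def check_coregistered(*images: MPImage) -> None:
    """Raise :class:`CoRegistrationError` unless all images share shape and pixel size."""
    ref = images[0]
    for im in images[1:]:
        if im.shape != ref.shape:
            raise CoRegistrationError(
                f"shape mismatch: {ref.shape} vs {im.shape}")
        if not np.isclose(im.pixel_size_um, ref.pixel_size_um):
            raise CoRegistrationError(
                f"pixel size mismatch: {ref.pixel_size_um} vs {im.pixel_size_um}")


@dataclass
class PolarimetricStack:
    """Three co-registered SHG frames at distinct linear polarization states.

    The default acquisition uses horizontal (0°), vertical (90°) and 60°
    incident polarization: two orthogonal states carry the magnitude
    information of the hyperpolarizability ratio and the oblique state
    resolves its sign.
    """

    images: Sequence[MPImage]

    def __post_init__(self) -> None:
        if len(self.images) != 3:
            raise ValueError("a polarimetric stack needs exactly 3 images")
        for im in self.images:
            if im.channel != "SHG":
                raise CoRegistrationError("polarimetric stacks are SHG-only")
            if im.polarization_deg is None:
                raise ValueError("every stack image needs a polarization angle")
        check_coregistered(*self.images)
        if len({round(im.polarization_deg % 180.0, 6) for im in self.images}) != 3:
            raise ValueError("polarization angles must be three distinct states")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([im.polarization_deg for im in self.images], dtype=float)

    @property
    def pixel_size_um(self) -> float:
        return self.images[0].pixel_size_um

    def intensity(self) -> np.ndarray:
        """Stack the three frames into one (3, H, W) float array."""
        return np.stack([np.asarray(im.data, dtype=float) for im in self.images])
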