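"""Cine-loop container and multi-frame TIFF I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["CineLoop", "write_cine", "read_cine"]


@dataclass(frozen=True)
class CineLoop:
    """Ordered grayscale image frames with physical calibration.

    ``frames`` has shape (n_frames, height, width), intensities in [0, 1].
    ``pixel_spacing`` is mm/px (isotropic), ``frame_rate`` in frames/s.
    Image coordinates follow the ultrasound convention: origin at the
    top-left pixel center, x lateral (columns), y axial/depth (rows).
    """

    frames: np.ndarray
    pixel_spacing: float
    frame_rate: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float32)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be (n_frames, height, width)")
        if self.pixel_spacing <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_spacing and frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate


def write_cine(path: str | Path, cine: CineLoop) -> None:
    """Write a cine as a multi-page 32-bit float TIFF.

    Pixel spacing and frame rate are stored as JSON in the ImageDescription
    tag so the loop round-trips without a sidecar file.
    """
    meta = {"pixel_spacing_mm": cine.pixel_spacing, "frame_rate_hz": cine.frame_rate}
    tifffile.imwrite(
        str(path),
        cine.frames.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_cine(
    path: str | Path,
    pixel_spacing: float | None = None,
    frame_rate: float | None = None,
) -> CineLoop:
    """Read a multi-frame TIFF cine.

    Calibration is taken from the embedded JSON description when present;
    explicit arguments override it (required for TIFFs from other sources).
    """
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        desc = tif.pages[0].description
    if frames.ndim == 2:
        frames = frames[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    ps = pixel_spacing if pixel_spacing is not None else meta.get("pixel_spacing_mm")
    fr = frame_rate if frame_rate is not None else meta.get("frame_rate_hz")
    if ps is None or fr is None:
        raise ValueError("pixel_spacing and frame_rate not embedded; pass explicitly")
    frames = frames.astype(np.float32)
    if frames.max() > 1.0:  # 8-bit export
        frames = frames / 255.0
    return CineLoop(frames=frames, pixel_spacing=float(ps), frame_rate=float(fr))
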