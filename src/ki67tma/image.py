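"""The core-image container and its file I/O (8-bit RGB TIFF or PNG)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

#: default pixel calibration, µm per pixel (a 250 µm counting field is
#: then exactly 500 px); always stored per image and never assumed.
DEFAULT_UM_PER_PX = 0.5


@dataclass
class CoreImage:
    """One RGB tissue-microarray core image with physical calibration.

    Attributes
    ----------
    pixels
        8-bit RGB array, shape (H, W, 3).
    um_per_px
        Physical calibration (micrometres per pixel).
    core_id, tma_id, subject_id, study_id
        Identifiers carried through scoring and reporting.
    """

    pixels: np.ndarray
    um_per_px: float = DEFAULT_UM_PER_PX
    core_id: str = ""
    tma_id: str = ""
    subject_id: str = ""
    study_id: str = ""
    is_control: bool = False
    control_kind: str = ""  # "positive" | "negative" | "blank" | ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError(
                f"CoreImage requires an RGB array of shape (H, W, 3); got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError("CoreImage pixels must be 8-bit (uint8)")
        if not (self.um_per_px > 0):
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def save(self, path: str | Path) -> Path:
        """Write the image as TIFF (``.tif``/``.tiff``) or PNG by extension."""
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(
                path,
                self.pixels,
                photometric="rgb",
                resolution=(1e4 / self.um_per_px, 1e4 / self.um_per_px),
                resolutionunit="CENTIMETER",
            )
        else:
            iio.imwrite(path, self.pixels)
        return path


def load_core_image(path: str | Path, um_per_px: float | None = None, **ids: str) -> CoreImage:
    """Load a TIFF/PNG core image.

    TIFF resolution tags are honoured when present; otherwise (or for
    PNG) ``um_per_px`` must be supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"core image not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            pixels = page.asarray()
            if um_per_px is None:
                try:
                    xres = page.tags["XResolution"].value
                    unit = page.tags["ResolutionUnit"].value
                    per_unit = xres[0] / xres[1]
                    um_in_unit = {2: 25.4e3, 3: 1e4}.get(int(unit))
                    if um_in_unit and per_unit > 0:
                        um_per_px = um_in_unit / per_unit
                except (KeyError, ZeroDivisionError):
                    um_per_px = None
    else:
        pixels = iio.imread(path)
    if um_per_px is None:
        raise ValueError(f"no pixel calibration stored in {path.name}; pass um_per_px")
    pixels = np.asarray(pixels)
    if pixels.ndim == 3 and pixels.shape[-1] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return CoreImage(pixels=pixels.astype(np.uint8, copy=False), um_per_px=float(um_per_px), **ids)
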