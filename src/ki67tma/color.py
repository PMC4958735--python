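"""Colour utilities: HSI conversion and stain (haematoxylin/DAB) unmixing.

Brightfield immunohistochemistry obeys the Beer-Lambert law: transmitted
intensity decays exponentially with the amount of stain, so stains mix
additively in optical-density (OD) space.  Separating a haematoxylin +
DAB image into per-stain density channels is the standard colour
deconvolution of Ruifrok & Johnston, available in scikit-image; this
module wraps it with a configurable stain matrix and adds the HSI
(hue-saturation-intensity) representation used for pixel gating.

HSI convention used throughout (instrument-style ranges):

* hue — degrees in [0, 360), the usual hexcone hue (0 = red, 120 =
  green, 240 = blue);
* saturation — ``255 * (1 - min(R,G,B) / mean(R,G,B))``, 0 for grey
  pixels, up to 255 for fully saturated ones;
* intensity — ``mean(R,G,B)`` on the 0-255 scale.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

# Ruifrok-Johnston H-E-DAB optical-density matrix (rows: haematoxylin,
# eosin, DAB; columns: R, G, B).  Shipped with scikit-image; used both to
# render synthetic stains and as the default deconvolution matrix, so the
# two sides of the pipeline share one calibration.
RGB_FROM_HED: np.ndarray = _skcolor.rgb_from_hed.copy()
HED_FROM_RGB: np.ndarray = _skcolor.hed_from_rgb.copy()

HEMATOXYLIN_OD = RGB_FROM_HED[0]
EOSIN_OD = RGB_FROM_HED[1]
DAB_OD = RGB_FROM_HED[2]


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Convert an optical-density image (H, W, 3 float) to 8-bit RGB."""
    rgb = 255.0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Optical density per channel; 8-bit input, zeros map to OD of 1/255."""
    scaled = np.maximum(np.asarray(rgb, dtype=float), 1.0) / 255.0
    return -np.log10(scaled)


def separate_stains(rgb: np.ndarray, conv_matrix: np.ndarray | None = None) -> np.ndarray:
    """Unmix an RGB image into (haematoxylin, eosin, DAB) density channels.

    Parameters
    ----------
    rgb
        8-bit RGB image, shape (H, W, 3).
    conv_matrix
        Colour-deconvolution matrix mapping OD to stain densities
        (defaults to the Ruifrok-Johnston H-E-DAB matrix).

    Returns
    -------
    float array (H, W, 3) of stain densities; small negative values are
    possible where the pixel lies outside the stain simplex.
    """
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an RGB image of shape (H, W, 3), got {rgb.shape}")
    matrix = HED_FROM_RGB if conv_matrix is None else np.asarray(conv_matrix, dtype=float)
    return rgb_to_od(rgb) @ matrix


def rgb_to_hsi(rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to the package HSI convention.

    Returns a float array (..., 3) with hue in degrees [0, 360),
    saturation and intensity on 0-255 (see module docstring).
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold R, G, B")
    hue = _skcolor.rgb2hsv(arr / 255.0)[..., 0] * 360.0
    intensity = arr.mean(axis=-1)
    mn = arr.min(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(intensity > 0, 255.0 * (1.0 - mn / intensity), 0.0)
    return np.stack([hue % 360.0, sat, intensity], axis=-1)


def hue_in_range(hue: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Membership of hue (degrees) in [lo, hi], wrapping modulo 360 when lo > hi."""
    hue = np.asarray(hue) % 360.0
    lo, hi = lo % 360.0, hi % 360.0
    if lo <= hi:
        return (hue >= lo) & (hue <= hi)
    return (hue >= lo) | (hue <= hi)
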