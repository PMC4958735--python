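"""Nucleus detection, classification and per-core Ki67 scoring.

Pipeline for one core image, mirroring a colour-first workflow:

1. ``classify_pixels`` — colour deconvolution into haematoxylin/DAB
   densities, then per-class HSI gating; pixels matching both colour
   classes are resolved by the larger deconvolved stain density.
2. ``detect_nuclei`` — the labelled foreground is split into nucleus
   candidates with a distance-transform watershed whose minima
   suppression is set by the class ``spot width``; each candidate is
   assigned the majority pixel colour class and kept only if every
   measured shape feature (width, compactness, roundness, axis ratio)
   lies inside that class's configured range.  Blobs below the width
   lower bound (typically lymphocytes) are discarded.
3. ``score_core`` — positive/negative counts and the Ki67 score, the
   percentage of positive nuclei over the whole core including hot
   spots.

Shape-feature definitions (per connected region, calibrated to µm):

* width — equivalent diameter, ``2 * sqrt(area / pi)``;
* compactness — ``perimeter^2 / (4 * pi * area)``, floored at 1 (the
  disc value); perimeter uses the two-direction Crofton estimator
  ``pi/4 * (exposed unit edges)``, which is unbiased for discs;
* roundness — ``4 * area / (pi * major_axis^2)``, capped at 1;
* axis ratio — major/minor ellipse axis lengths, ``4 * sqrt(eig)`` of
  the pixel-coordinate covariance eigenvalues (the normalised
  second central moments).

The features are computed for all watershed segments at once with
bincount-based moment accumulation, so scoring a dense core stays fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from .color import hue_in_range, rgb_to_hsi, rgb_to_od
from .config import ClassifierConfig
from .image import CoreImage

POSITIVE, NEGATIVE, BACKGROUND = 1, 2, 0


@dataclass(frozen=True)
class NucleusDetection:
    """One detected nucleus with its measured shape features."""

    centroid_um: tuple[float, float]  # (x, y)
    class_label: str
    area_um2: float
    width_um: float
    compactness: float
    roundness: float
    axis_ratio: float


@dataclass
class CoreResult:
    """Counts and Ki67 score for one core (QC status filled later)."""

    core_id: str
    n_positive: int
    n_negative: int
    qc_status: str = ""
    is_control: bool = False
    control_kind: str = ""

    @property
    def total_nuclei(self) -> int:
        return self.n_positive + self.n_negative

    @property
    def ki67_percent(self) -> float | None:
        """100 * positive / total; None (undefined) for empty cores."""
        if self.total_nuclei == 0:
            return None
        return 100.0 * self.n_positive / self.total_nuclei


def classify_pixels(image: CoreImage, config: ClassifierConfig) -> np.ndarray:
    """Label every pixel positive (1), negative (2) or background (0).

    A pixel joins a class when its hue/saturation/intensity fall inside
    that class's configured ranges; a pixel matching both classes is
    assigned by the argmax of the deconvolved DAB vs haematoxylin
    density.
    """
    pixels = image.pixels
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ValueError("classify_pixels requires an RGB image")
    hsi = rgb_to_hsi(pixels)
    densities = rgb_to_od(pixels) @ config.stain_od_matrix  # (H, W, 3): hem, eosin, dab

    def gate(label: str) -> np.ndarray:
        cc = config.colour[label]
        m = hue_in_range(hsi[..., 0], *cc.hue_range)
        m &= (hsi[..., 1] >= cc.saturation_range[0]) & (hsi[..., 1] <= cc.saturation_range[1])
        m &= (hsi[..., 2] >= cc.intensity_range[0]) & (hsi[..., 2] <= cc.intensity_range[1])
        return m

    pos, neg = gate("positive"), gate("negative")
    both = pos & neg
    dab_wins = densities[..., 2] >= densities[..., 0]
    mask = np.zeros(pixels.shape[:2], dtype=np.uint8)
    mask[pos] = POSITIVE
    mask[neg] = NEGATIVE
    mask[both & dab_wins] = POSITIVE
    mask[both & ~dab_wins] = NEGATIVE
    return mask


def _exposed_edges(labels: np.ndarray, n_labels: int) -> np.ndarray:
    """Per-label count of exposed unit edges (4-neighbour boundary)."""
    edges = np.zeros(n_labels + 1, dtype=np.int64)
    for axis in (0, 1):
        a = np.moveaxis(labels, axis, 0)
        diff = a[1:] != a[:-1]
        # each differing adjacent pair exposes one edge of each involved label
        np.add.at(edges, a[1:][diff], 1)
        np.add.at(edges, a[:-1][diff], 1)
        # image border counts as background
        np.add.at(edges, a[0], 1)
        np.add.at(edges, a[-1], 1)
    edges[0] = 0
    return edges


def region_features(labels: np.ndarray, um_per_px: float) -> dict[str, np.ndarray]:
    """Shape features of every labelled segment, vectorised.

    Returns arrays indexed by label 1..n (index 0 is a placeholder):
    ``area_um2``, ``width_um``, ``compactness``, ``roundness``,
    ``axis_ratio``, ``centroid_x_um``, ``centroid_y_um`` and a
    ``degenerate`` flag for regions too small for well-defined moments
    (single pixel or zero minor axis).
    """
    labels = np.asarray(labels)
    n = int(labels.max())
    out_keys = (
        "area_um2",
        "width_um",
        "compactness",
        "roundness",
        "axis_ratio",
        "centroid_x_um",
        "centroid_y_um",
    )
    if n == 0:
        zero = np.zeros(1)
        return {**{k: zero.copy() for k in out_keys}, "degenerate": np.zeros(1, dtype=bool)}

    ys, xs = np.nonzero(labels)
    lab = labels[ys, xs]
    area_px = np.bincount(lab, minlength=n + 1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cx = np.bincount(lab, weights=xs, minlength=n + 1) / area_px
        cy = np.bincount(lab, weights=ys, minlength=n + 1) / area_px
        # central second moments (normalised by area), as in standard
        # image-moment ellipse fitting
        mxx = np.bincount(lab, weights=xs * xs, minlength=n + 1) / area_px - cx**2
        myy = np.bincount(lab, weights=ys * ys, minlength=n + 1) / area_px - cy**2
        mxy = np.bincount(lab, weights=xs * ys, minlength=n + 1) / area_px - cx * cy
    tr = mxx + myy
    det = np.sqrt(np.clip(((mxx - myy) / 2.0) ** 2 + mxy**2, 0.0, None))
    eig_max = tr / 2.0 + det
    eig_min = np.clip(tr / 2.0 - det, 0.0, None)
    major_px = 4.0 * np.sqrt(np.clip(eig_max, 0.0, None))
    minor_px = 4.0 * np.sqrt(eig_min)

    perimeter_px = (math.pi / 4.0) * _exposed_edges(labels, n)

    area_um2 = area_px * um_per_px**2
    width_um = 2.0 * np.sqrt(area_um2 / math.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        compactness = np.maximum(
            1.0, (perimeter_px * um_per_px) ** 2 / (4.0 * math.pi * area_um2)
        )
        roundness = np.minimum(1.0, 4.0 * area_px / (math.pi * major_px**2))
        axis_ratio = np.maximum(1.0, major_px / minor_px)
    degenerate = (area_px < 2) | (minor_px <= 0) | ~np.isfinite(axis_ratio)
    axis_ratio = np.where(degenerate, np.inf, axis_ratio)
    roundness = np.where(np.isfinite(roundness), roundness, 0.0)
    return {
        "area_um2": area_um2,
        "width_um": width_um,
        "compactness": compactness,
        "roundness": roundness,
        "axis_ratio": axis_ratio,
        "centroid_x_um": cx * um_per_px,
        "centroid_y_um": cy * um_per_px,
        "degenerate": degenerate,
    }


def measure_shape(region_mask: np.ndarray, um_per_px: float) -> dict | None:
    """Shape features of one connected pixel region.

    Returns a dict with ``area_um2``, ``width_um``, ``compactness``,
    ``roundness``, ``axis_ratio`` and ``centroid_um`` (x, y), following
    the definitions in the module docstring.  Degenerate regions
    (single pixel, zero minor axis) return None and are dropped by the
    caller.  Raises on an empty region.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region is empty")
    feats = region_features(region_mask.astype(np.int32), um_per_px)
    if feats["degenerate"][1]:
        return None
    return {
        "area_um2": float(feats["area_um2"][1]),
        "width_um": float(feats["width_um"][1]),
        "compactness": float(feats["compactness"][1]),
        "roundness": float(feats["roundness"][1]),
        "axis_ratio": float(feats["axis_ratio"][1]),
        "centroid_um": (float(feats["centroid_x_um"][1]), float(feats["centroid_y_um"][1])),
    }


def split_objects(foreground: np.ndarray, spot_width_um: float, um_per_px: float) -> np.ndarray:
    """Split touching nuclei with a distance-transform watershed.

    Watershed seeds are regional maxima of the distance map under a
    square maximum filter of half the spot width — the scale that
    "marks the location of the nuclei and separates them by size".
    Returns an int32 label image.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if not foreground.any():
        return np.zeros(foreground.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(foreground)
    min_dist = max(1, int(round(spot_width_um / (2.0 * um_per_px))))
    # smooth before seeding so gentle EDT ridges of elongated nuclei do
    # not shed spurious maxima
    smooth = ndi.gaussian_filter(distance, sigma=max(1.0, min_dist / 6.0))
    maxf = ndi.maximum_filter(smooth, size=2 * min_dist + 1, mode="constant")
    peaks = foreground & (smooth >= maxf)
    markers, n_peaks = ndi.label(peaks)
    if n_peaks > 1:
        markers = _merge_close_markers(markers, n_peaks, min_dist)
    return watershed(-distance, markers, mask=foreground).astype(np.int32)


def _merge_close_markers(markers: np.ndarray, n: int, min_dist: float) -> np.ndarray:
    """Union seed components whose centroids fall within ``min_dist`` px."""
    from scipy.spatial import cKDTree

    centroids = np.asarray(ndi.center_of_mass(markers > 0, markers, range(1, n + 1)))
    pairs = cKDTree(centroids).query_pairs(min_dist, output_type="ndarray")
    if len(pairs) == 0:
        return markers
    parent = np.arange(n + 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs + 1:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    remap = np.array([find(i) for i in range(n + 1)])
    return remap[markers]


def detect_nuclei(
    mask: np.ndarray, config: ClassifierConfig, um_per_px: float
) -> list[NucleusDetection]:
    """Turn a pixel-label mask into filtered nucleus detections.

    Touching objects are split at the spot-width scale (the two
    classes' spot widths are averaged when they differ); each segment's
    class is the majority of its pixel colour labels (ties go to
    positive, keeping hot-spot sensitivity), and the segment is kept
    only if all its shape features pass that class's ranges.
    """
    mask = np.asarray(mask)
    foreground = mask > 0
    if not foreground.any():
        return []
    spot = 0.5 * (
        config.shape["positive"].spot_width_um + config.shape["negative"].spot_width_um
    )
    labels = split_objects(foreground, spot, um_per_px)
    n = int(labels.max())
    if n == 0:
        return []
    feats = region_features(labels, um_per_px)
    pos_counts = np.bincount(labels[mask == POSITIVE], minlength=n + 1)
    neg_counts = np.bincount(labels[mask == NEGATIVE], minlength=n + 1)
    is_positive = pos_counts >= neg_counts  # ties -> positive

    def in_range(values: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
        return (values >= bounds[0]) & (values <= bounds[1])

    keep = ~feats["degenerate"]
    for label_name, chosen in (("positive", is_positive), ("negative", ~is_positive)):
        shp = config.shape[label_name]
        ok = (
            in_range(feats["width_um"], shp.width_range_um)
            & in_range(feats["compactness"], shp.compactness_range)
            & in_range(feats["roundness"], shp.roundness_range)
            & in_range(feats["axis_ratio"], shp.axis_ratio_range)
        )
        keep &= ok | ~chosen
    keep[0] = False

    detections: list[NucleusDetection] = []
    for i in np.nonzero(keep)[0]:
        detections.append(
            NucleusDetection(
                centroid_um=(float(feats["centroid_x_um"][i]), float(feats["centroid_y_um"][i])),
                class_label="positive" if is_positive[i] else "negative",
                area_um2=float(feats["area_um2"][i]),
                width_um=float(feats["width_um"][i]),
                compactness=float(feats["compactness"][i]),
                roundness=float(feats["roundness"][i]),
                axis_ratio=float(feats["axis_ratio"][i]),
            )
        )
    return detections


def score_core(image: CoreImage, config: ClassifierConfig) -> CoreResult:
    """Classify, detect and score one core.

    Deterministic for fixed image and configuration.  The score is the
    percentage of positive nuclei over the entire core; empty cores get
    an undefined score (``ki67_percent`` is None).
    """
    mask = classify_pixels(image, config)
    detections = detect_nuclei(mask, config, image.um_per_px)
    n_pos = sum(1 for d in detections if d.class_label == "positive")
    n_neg = len(detections) - n_pos
    return CoreResult(
        core_id=image.core_id,
        n_positive=n_pos,
        n_negative=n_neg,
        is_control=image.is_control,
        control_kind=image.control_kind,
    )
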