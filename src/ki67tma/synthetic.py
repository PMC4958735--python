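"""Synthetic TMA-core image generator with exact ground truth.

Renders circular tissue-microarray cores populated by elliptical tumour
nuclei on an eosin-tinted stromal background.  Positive (Ki67-expressing)
nuclei are rendered in DAB brown, negative nuclei in haematoxylin blue,
using the same optical-density stain vectors the classifier deconvolves
with, so colour behaviour is controlled end to end.  Every core comes
with a per-nucleus ground-truth table and pixel-level class masks, which
makes each downstream stage testable without patient material.

Controllable artifact classes mimic the failure modes seen in real
cores: diffuse background DAB, membranous (non-nuclear) DAB rings,
lymphocytic infiltration (small haematoxylin blobs below tumour-nucleus
size), and a folded region (darkened, doubled-density cap).

Rendering model: stains add in optical density (Beer-Lambert), each
nucleus contributes ``alpha * amount * stain_od_vector`` with an
anti-aliased elliptical alpha profile and per-nucleus multiplicative
intensity noise; RGB = 255 * 10**(-OD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .color import DAB_OD, EOSIN_OD, HEMATOXYLIN_OD, od_to_rgb, rgb_to_od
from .image import DEFAULT_UM_PER_PX, CoreImage

ARTIFACT_KEYS = ("background_dab", "membrane_dab", "lymphocyte_count", "fold_fraction")

# optical-density amounts of the reference rendering (calibration constants)
_STROMA_EOSIN_OD = 0.12
_NEG_HEM_OD = 0.85
_POS_DAB_OD = 0.90
_POS_HEM_OD = 0.10
_NUCLEUS_OD_NOISE_SD = 0.12  # sd of log multiplicative intensity noise
_LYMPHOCYTE_DIAMETER_UM = 4.0


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested density."""


@dataclass
class CoreSpec:
    """Parameters of one synthetic core.

    ``artifact_levels`` maps artifact names (``background_dab``,
    ``membrane_dab``, ``lymphocyte_count``, ``fold_fraction``) to
    non-negative levels; empty means a clean core.
    """

    core_id: str
    n_nuclei: int
    positive_fraction: float
    core_diameter_um: float = 600.0
    nucleus_diameter_um_mean: float = 8.0
    nucleus_diameter_um_sd: float = 1.5
    artifact_levels: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    um_per_px: float = DEFAULT_UM_PER_PX
    axis_ratio_range: tuple[float, float] = (1.0, 1.6)
    max_overlap: float = 0.30
    subject_id: str = ""
    study_id: str = ""
    tma_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if not (self.core_diameter_um > 0):
            raise ValueError("core_diameter_um must be positive")
        if not (self.um_per_px > 0):
            raise ValueError("um_per_px must be positive")
        unknown = set(self.artifact_levels) - set(ARTIFACT_KEYS)
        if unknown:
            raise ValueError(f"unknown artifact levels: {sorted(unknown)}")
        for key, val in self.artifact_levels.items():
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"artifact level {key!r} must be finite and non-negative")


@dataclass
class GroundTruth:
    """Exact truth for one synthetic core.

    ``nuclei`` holds one row per rendered nucleus: ``x_um``, ``y_um``
    (centre, image coordinates), ``class`` (``positive`` / ``negative``
    / ``lymphocyte``), ``diameter_um``, ``axis_ratio``, ``angle_rad``.
    ``label_mask`` labels pixels 0 = background, 1 = positive nucleus,
    2 = negative nucleus, 3 = lymphocyte (pixel-level oracle for the
    classifier).  Lymphocytes never enter the true Ki67 score.
    """

    core_id: str
    nuclei: pd.DataFrame
    core_diameter_um: float
    um_per_px: float
    label_mask: np.ndarray | None = None

    @property
    def n_positive(self) -> int:
        return int((self.nuclei["class"] == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.nuclei["class"] == "negative").sum())

    @property
    def true_ki67(self) -> float | None:
        """Percentage of positive malignant nuclei; None for empty cores."""
        total = self.n_positive + self.n_negative
        if total == 0:
            return None
        return 100.0 * self.n_positive / total

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        cols = ["x_um", "y_um", "class", "diameter_um"]
        self.nuclei.loc[:, cols].to_csv(path, index=False)
        return path


def _empty_truth_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "class": pd.Series(dtype=str),
            "diameter_um": pd.Series(dtype=float),
            "axis_ratio": pd.Series(dtype=float),
            "angle_rad": pd.Series(dtype=float),
        }
    )


def _overlap_gap_factor(max_overlap: float) -> float:
    """Centre-distance fraction of r1+r2 at which two equal discs overlap
    by ``max_overlap`` of one disc's area (bisection on the lens formula)."""
    if max_overlap >= 1.0:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        d = 2.0 * mid  # in units of r
        lens = 2.0 * math.acos(min(1.0, d / 2.0)) - (d / 2.0) * math.sqrt(max(0.0, 4.0 - d * d))
        frac = lens / math.pi
        if frac > max_overlap:
            lo = mid
        else:
            hi = mid
    return hi


def _place_nuclei(
    rng: np.random.Generator,
    n: int,
    radius_um: float,
    diameters_um: np.ndarray,
    max_overlap: float,
) -> np.ndarray:
    """Rejection-sample (x, y) centres inside the core disc.

    Overlap is approximated on equivalent circles: a candidate is
    accepted when its distance to every placed nucleus exceeds
    ``gap_factor * (r_i + r_j)``, the equal-disc spacing at which lens
    overlap equals ``max_overlap``.  Hard cap of 500 * n total attempts.
    """
    if n == 0:
        return np.empty((0, 2))
    gap = _overlap_gap_factor(max_overlap)
    radii = diameters_um / 2.0
    cell = max(1e-9, 2.0 * float(diameters_um.max()))
    grid: dict[tuple[int, int], list[int]] = {}
    centres = np.empty((n, 2))
    placed = 0
    attempts_left = 500 * n
    while placed < n:
        if attempts_left <= 0:
            raise PlacementError(
                f"could not place {n} nuclei of mean diameter "
                f"{diameters_um.mean():.1f} um in a core of radius {radius_um:.0f} um "
                f"within the attempt budget (placed {placed})"
            )
        attempts_left -= 1
        # uniform in the disc, keeping the whole nucleus inside
        margin = radii[placed]
        r = (radius_um - margin) * math.sqrt(rng.random())
        theta = rng.random() * 2.0 * math.pi
        x, y = r * math.cos(theta), r * math.sin(theta)
        gx, gy = int(x // cell), int(y // cell)
        ok = True
        for ix in (gx - 1, gx, gx + 1):
            for iy in (gy - 1, gy, gy + 1):
                for j in grid.get((ix, iy), ()):
                    dx, dy = x - centres[j, 0], y - centres[j, 1]
                    min_d = gap * (radii[placed] + radii[j])
                    if dx * dx + dy * dy < min_d * min_d:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        centres[placed] = (x, y)
        grid.setdefault((gx, gy), []).append(placed)
        placed += 1
    return centres


def _render_ellipse(
    od: np.ndarray,
    label: np.ndarray | None,
    cx_px: float,
    cy_px: float,
    a_px: float,
    b_px: float,
    angle: float,
    od_vector: np.ndarray,
    label_value: int,
) -> None:
    """Accumulate one anti-aliased elliptical stain deposit in OD space."""
    h, w = od.shape[:2]
    rmax = max(a_px, b_px) + 1.5
    x0, x1 = max(0, int(cx_px - rmax)), min(w, int(cx_px + rmax) + 2)
    y0, y1 = max(0, int(cy_px - rmax)), min(h, int(cy_px + rmax) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx_px, yy - cy_px
    ca, sa = math.cos(angle), math.sin(angle)
    u = (dx * ca + dy * sa) / max(a_px, 1e-6)
    v = (-dx * sa + dy * ca) / max(b_px, 1e-6)
    rho = np.sqrt(u * u + v * v)
    # ~1 px anti-aliased edge
    alpha = np.clip((1.0 - rho) * min(a_px, b_px) + 0.5, 0.0, 1.0)
    od[y0:y1, x0:x1] += alpha[..., None] * od_vector
    if label is not None:
        core_px = alpha > 0.5
        label[y0:y1, x0:x1][core_px] = label_value


def _canvas_size(core_diameter_um: float, um_per_px: float) -> int:
    return int(math.ceil(core_diameter_um / um_per_px)) + 8


def generate_core(spec: CoreSpec) -> tuple[CoreImage, GroundTruth]:
    """Render one synthetic core and its ground truth.

    Deterministic: identical ``spec`` (including ``seed``) yields
    bit-identical pixels and truth.  Raises :class:`PlacementError` when
    the requested nucleus count cannot be placed at the overlap cap.
    """
    rng = np.random.default_rng(spec.seed)
    size = _canvas_size(spec.core_diameter_um, spec.um_per_px)
    cx = cy = size / 2.0
    radius_px = spec.core_diameter_um / (2.0 * spec.um_per_px)
    radius_um = spec.core_diameter_um / 2.0

    od = np.zeros((size, size, 3), dtype=float)
    yy, xx = np.mgrid[0:size, 0:size]
    core_mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    # eosin-tinted stroma with mild texture
    stroma = _STROMA_EOSIN_OD * (1.0 + 0.08 * rng.standard_normal((size, size)))
    od[core_mask] += np.clip(stroma[core_mask], 0.0, None)[:, None] * EOSIN_OD

    label = np.zeros((size, size), dtype=np.uint8)

    n = spec.n_nuclei
    n_pos = int(round(n * spec.positive_fraction))
    if n > 0:
        diameters = np.clip(
            rng.normal(spec.nucleus_diameter_um_mean, spec.nucleus_diameter_um_sd, n),
            3.0,
            None,
        )
        centres_um = _place_nuclei(rng, n, radius_um, diameters, spec.max_overlap)
        axis_ratios = rng.uniform(*spec.axis_ratio_range, n)
        angles = rng.uniform(0.0, math.pi, n)
        intensity = np.exp(rng.normal(0.0, _NUCLEUS_OD_NOISE_SD, n))
        classes = np.array(["positive"] * n_pos + ["negative"] * (n - n_pos))
        rng.shuffle(classes)
        for i in range(n):
            # ellipse with the requested equivalent diameter: a*b = (d/2)^2
            half_d_px = diameters[i] / (2.0 * spec.um_per_px)
            q = math.sqrt(axis_ratios[i])
            a_px, b_px = half_d_px * q, half_d_px / q
            if classes[i] == "positive":
                vec = intensity[i] * (_POS_DAB_OD * DAB_OD + _POS_HEM_OD * HEMATOXYLIN_OD)
                lab = 1
            else:
                vec = intensity[i] * _NEG_HEM_OD * HEMATOXYLIN_OD
                lab = 2
            _render_ellipse(
                od,
                label,
                cx + centres_um[i, 0] / spec.um_per_px,
                cy + centres_um[i, 1] / spec.um_per_px,
                a_px,
                b_px,
                angles[i],
                vec,
                lab,
            )
        frame = pd.DataFrame(
            {
                "x_um": cx * spec.um_per_px + centres_um[:, 0],
                "y_um": cy * spec.um_per_px + centres_um[:, 1],
                "class": classes,
                "diameter_um": diameters,
                "axis_ratio": axis_ratios,
                "angle_rad": angles,
            }
        )
    else:
        frame = _empty_truth_frame()

    image = CoreImage(
        pixels=od_to_rgb(od),
        um_per_px=spec.um_per_px,
        core_id=spec.core_id,
        tma_id=spec.tma_id,
        subject_id=spec.subject_id,
        study_id=spec.study_id,
    )
    truth = GroundTruth(
        core_id=spec.core_id,
        nuclei=frame,
        core_diameter_um=spec.core_diameter_um,
        um_per_px=spec.um_per_px,
        label_mask=label,
    )
    if spec.artifact_levels and any(v > 0 for v in spec.artifact_levels.values()):
        image = add_artifacts(image, truth, spec.artifact_levels, seed=spec.seed + 1)
    return image, truth


def add_artifacts(
    image: CoreImage,
    truth: GroundTruth,
    levels: dict[str, float],
    seed: int = 0,
) -> CoreImage:
    """Overlay staining/tissue artifacts on a rendered core.

    Levels (all default 0 = absent):

    * ``background_dab`` — diffuse DAB optical density added across the
      tissue (typical range 0-0.5);
    * ``membrane_dab`` — fraction of negative nuclei receiving a
      membranous DAB ring;
    * ``lymphocyte_count`` — number of small haematoxylin blobs
      (diameter 4 µm, below tumour-nucleus size) added and recorded in
      the ground truth as class ``lymphocyte``;
    * ``fold_fraction`` — area fraction of the core darkened and
      double-rendered as a tissue fold.

    All levels zero returns the input image unchanged.  Lymphocyte rows
    are appended to ``truth.nuclei`` in place.
    """
    unknown = set(levels) - set(ARTIFACT_KEYS)
    if unknown:
        raise ValueError(f"unknown artifact levels: {sorted(unknown)}")
    for key, val in levels.items():
        if not np.isfinite(val) or val < 0:
            raise ValueError(f"artifact level {key!r} must be finite and non-negative")
    if not any(levels.get(k, 0) > 0 for k in ARTIFACT_KEYS):
        return image

    rng = np.random.default_rng(seed)
    od = rgb_to_od(image.pixels)
    size = image.pixels.shape[0]
    cx = cy = size / 2.0
    radius_px = truth.core_diameter_um / (2.0 * image.um_per_px)
    radius_um = truth.core_diameter_um / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    core_mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    label = truth.label_mask

    bg = float(levels.get("background_dab", 0.0))
    if bg > 0:
        field_ = bg * (0.8 + 0.4 * rng.random((size, size)))
        od[core_mask] += field_[core_mask][:, None] * DAB_OD

    mem = float(levels.get("membrane_dab", 0.0))
    if mem > 0 and len(truth.nuclei):
        neg = truth.nuclei.index[truth.nuclei["class"] == "negative"].to_numpy()
        k = min(len(neg), int(round(min(mem, 1.0) * len(neg))))
        if k > 0:
            chosen = rng.choice(neg, size=k, replace=False)
            for idx in chosen:
                row = truth.nuclei.loc[idx]
                r_px = 1.25 * row["diameter_um"] / (2.0 * image.um_per_px)
                cxp = row["x_um"] / image.um_per_px
                cyp = row["y_um"] / image.um_per_px
                x0, x1 = max(0, int(cxp - r_px - 2)), min(size, int(cxp + r_px) + 3)
                y0, y1 = max(0, int(cyp - r_px - 2)), min(size, int(cyp + r_px) + 3)
                if x0 >= x1 or y0 >= y1:
                    continue
                dy, dx = np.mgrid[y0:y1, x0:x1]
                dist = np.sqrt((dx - cxp) ** 2 + (dy - cyp) ** 2)
                ring = np.clip(1.0 - np.abs(dist - r_px), 0.0, 1.0)
                od[y0:y1, x0:x1] += (0.55 * ring)[..., None] * DAB_OD

    lym = int(round(float(levels.get("lymphocyte_count", 0.0))))
    if lym > 0:
        rows = []
        for _ in range(lym):
            r = radius_um * math.sqrt(rng.random())
            theta = rng.random() * 2.0 * math.pi
            x_um = cx * image.um_per_px + r * math.cos(theta)
            y_um = cy * image.um_per_px + r * math.sin(theta)
            d = _LYMPHOCYTE_DIAMETER_UM * rng.uniform(0.85, 1.15)
            half_px = d / (2.0 * image.um_per_px)
            _render_ellipse(
                od,
                label,
                x_um / image.um_per_px,
                y_um / image.um_per_px,
                half_px,
                half_px,
                0.0,
                1.1 * _NEG_HEM_OD * HEMATOXYLIN_OD,
                3,
            )
            rows.append(
                {
                    "x_um": x_um,
                    "y_um": y_um,
                    "class": "lymphocyte",
                    "diameter_um": d,
                    "axis_ratio": 1.0,
                    "angle_rad": 0.0,
                }
            )
        add = pd.DataFrame(rows)
        truth.nuclei = (
            pd.concat([truth.nuclei, add], ignore_index=True) if len(truth.nuclei) else add
        )

    fold = float(levels.get("fold_fraction", 0.0))
    if fold > 0:
        fold = min(fold, 0.9)
        # circular cap with area fraction `fold`: bisect on the chord position
        lo, hi = -1.0, 1.0
        for _ in range(50):
            t = 0.5 * (lo + hi)
            frac = (math.acos(t) - t * math.sqrt(1 - t * t)) / math.pi
            if frac > fold:
                lo = t
            else:
                hi = t
        cap = core_mask & ((xx - cx) >= hi * radius_px)
        od[cap] *= 2.0  # doubled tissue thickness
        od[cap] += 0.25 * np.array([1.0, 1.0, 1.0])  # neutral darkening

    out = CoreImage(
        pixels=od_to_rgb(od),
        um_per_px=image.um_per_px,
        core_id=image.core_id,
        tma_id=image.tma_id,
        subject_id=image.subject_id,
        study_id=image.study_id,
        is_control=image.is_control,
        control_kind=image.control_kind,
    )
    return out


def uniform_truth(
    core_id: str,
    n_nuclei: int,
    positive_fraction: float,
    core_diameter_um: float = 600.0,
    seed: int = 0,
    um_per_px: float = DEFAULT_UM_PER_PX,
    nucleus_diameter_um: float = 8.0,
) -> GroundTruth:
    """Ground truth only — spatially uniform nuclei, no image rendered.

    For protocol-level studies (CAV sampling properties, aggregation
    logic) where rendering would add nothing: positions are uniform in
    the core disc, classes drawn by the positive fraction, no overlap
    constraint and no label mask.
    """
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if n_nuclei == 0:
        frame = _empty_truth_frame()
    else:
        radius = core_diameter_um / 2.0
        r = radius * np.sqrt(rng.random(n_nuclei))
        theta = rng.uniform(0.0, 2.0 * math.pi, n_nuclei)
        n_pos = int(round(n_nuclei * positive_fraction))
        classes = np.array(["positive"] * n_pos + ["negative"] * (n_nuclei - n_pos))
        rng.shuffle(classes)
        frame = pd.DataFrame(
            {
                "x_um": radius + r * np.cos(theta),
                "y_um": radius + r * np.sin(theta),
                "class": classes,
                "diameter_um": np.full(n_nuclei, float(nucleus_diameter_um)),
                "axis_ratio": np.ones(n_nuclei),
                "angle_rad": np.zeros(n_nuclei),
            }
        )
    return GroundTruth(
        core_id=core_id,
        nuclei=frame,
        core_diameter_um=core_diameter_um,
        um_per_px=um_per_px,
        label_mask=None,
    )


def _derived_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def control_specs(
    template: CoreSpec | None = None, seed: int = 0, tma_id: str = ""
) -> list[CoreSpec]:
    """The three per-TMA control cores: strongly positive, negative, blank."""
    base = template or CoreSpec(core_id="ctrl", n_nuclei=800, positive_fraction=0.0)
    mk = lambda cid, n, pf, i: replace(  # noqa: E731
        base,
        core_id=cid,
        n_nuclei=n,
        positive_fraction=pf,
        artifact_levels={},
        seed=_derived_seed(seed, 1_000_000 + i),
        subject_id="",
        study_id=base.study_id,
        tma_id=tma_id or base.tma_id,
    )
    return [
        mk(f"{tma_id}_ctrl_pos" if tma_id else "ctrl_pos", base.n_nuclei, 0.95, 0),
        mk(f"{tma_id}_ctrl_neg" if tma_id else "ctrl_neg", base.n_nuclei, 0.0, 1),
        mk(f"{tma_id}_ctrl_blank" if tma_id else "ctrl_blank", 0, 0.0, 2),
    ]


def generate_tma(
    layout: list[CoreSpec],
    include_controls: bool = True,
    seed: int = 0,
    tma_id: str = "",
) -> list[tuple[CoreImage, GroundTruth]]:
    """Generate all cores of one TMA.

    Per-core seeds are derived deterministically from ``seed`` and the
    core's position in the layout (overriding any seed on the spec), so
    one integer reproduces the whole array.  With ``include_controls``
    three flagged control cores are appended: strongly positive
    (positive fraction 0.95), negative (0.0) and blank (no tissue).
    """
    if not layout:
        raise ValueError("layout must contain at least one CoreSpec")
    cores: list[tuple[CoreImage, GroundTruth]] = []
    for i, spec in enumerate(layout):
        spec_i = replace(spec, seed=_derived_seed(seed, i), tma_id=tma_id or spec.tma_id)
        cores.append(generate_core(spec_i))
    if include_controls:
        kinds = ("positive", "negative", "blank")
        for kind, spec in zip(kinds, control_specs(layout[0], seed=seed, tma_id=tma_id)):
            img, truth = generate_core(spec)
            img.is_control = True
            img.control_kind = kind
            cores.append((img, truth))
    return cores


def write_tma(
    cores: list[tuple[CoreImage, GroundTruth]],
    outdir: str | Path,
    image_format: str = "tif",
) -> pd.DataFrame:
    """Write core images, per-core truth CSVs and the manifest CSV.

    Returns the manifest (core_id, tma_id, subject_id, study_id,
    is_control, control_kind, image_path, truth_path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, truth in cores:
        img_path = outdir / f"{img.core_id}.{image_format}"
        truth_path = outdir / f"{img.core_id}.truth.csv"
        img.save(img_path)
        truth.save(truth_path)
        rows.append(
            {
                "core_id": img.core_id,
                "tma_id": img.tma_id,
                "subject_id": img.subject_id,
                "study_id": img.study_id,
                "is_control": img.is_control,
                "control_kind": img.control_kind,
                "image_path": img_path.name,
                "truth_path": truth_path.name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
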