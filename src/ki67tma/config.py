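"""Classifier configuration: colour (HSI) classes and shape classes.

A classifier is fully described by, per nuclear class (``positive`` =
DAB-stained, ``negative`` = haematoxylin-stained):

* a colour gate — the range of hue, saturation and intensity accepted as
  that class, applied pixel-wise; and
* a shape gate — spot width (the scale at which touching nuclei are
  split), plus acceptance ranges for width (equivalent diameter),
  compactness, roundness and axis ratio, applied object-wise.

One such parameter set tuned across many TMAs is a "universal"
classifier; per-TMA tuning is just an alternate configuration file.
Configurations round-trip through YAML so tuned parameter sets can be
versioned and swapped without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import numpy as np
import yaml

from .color import HED_FROM_RGB

CLASS_LABELS = ("positive", "negative")


def _check_pair(name: str, pair: tuple[float, float], wrap_ok: bool = False) -> tuple[float, float]:
    lo, hi = float(pair[0]), float(pair[1])
    if not wrap_ok and lo > hi:
        raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
    return (lo, hi)


@dataclass(frozen=True)
class ColourClass:
    """HSI gate for one nuclear class (hue may wrap modulo 360)."""

    class_label: str
    hue_range: tuple[float, float]
    saturation_range: tuple[float, float]
    intensity_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        object.__setattr__(self, "hue_range", _check_pair("hue_range", self.hue_range, wrap_ok=True))
        object.__setattr__(
            self, "saturation_range", _check_pair("saturation_range", self.saturation_range)
        )
        object.__setattr__(
            self, "intensity_range", _check_pair("intensity_range", self.intensity_range)
        )


@dataclass(frozen=True)
class ShapeClass:
    """Object-level shape gate for one nuclear class (sizes in µm)."""

    class_label: str
    spot_width_um: float
    width_range_um: tuple[float, float]
    compactness_range: tuple[float, float]
    roundness_range: tuple[float, float]
    axis_ratio_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if not (self.spot_width_um > 0):
            raise ValueError("spot_width_um must be positive")
        for name in ("width_range_um", "compactness_range", "roundness_range", "axis_ratio_range"):
            object.__setattr__(self, name, _check_pair(name, getattr(self, name)))


@dataclass
class ClassifierConfig:
    """Complete nucleus-classifier parameter set (two classes + stain matrix)."""

    colour: dict[str, ColourClass]
    shape: dict[str, ShapeClass]
    stain_od_matrix: np.ndarray = field(default_factory=lambda: HED_FROM_RGB.copy())
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for mapping, kind in ((self.colour, ColourClass), (self.shape, ShapeClass)):
            if set(mapping) != set(CLASS_LABELS):
                raise ValueError(f"config must define exactly the classes {CLASS_LABELS}")
            for label, cls in mapping.items():
                if not isinstance(cls, kind) or cls.class_label != label:
                    raise ValueError(f"inconsistent {kind.__name__} entry for label {label!r}")
        self.stain_od_matrix = np.asarray(self.stain_od_matrix, dtype=float)
        if self.stain_od_matrix.shape != (3, 3):
            raise ValueError("stain_od_matrix must be 3x3")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {"version": self.version, "stain_od_matrix": self.stain_od_matrix.tolist(), "classes": {}}
        for label in CLASS_LABELS:
            col, shp = self.colour[label], self.shape[label]
            out["classes"][label] = {
                "hue": list(col.hue_range),
                "saturation": list(col.saturation_range),
                "intensity": list(col.intensity_range),
                "spot_width": shp.spot_width_um,
                "width": list(shp.width_range_um),
                "compactness": list(shp.compactness_range),
                "roundness": list(shp.roundness_range),
                "axis_ratio": list(shp.axis_ratio_range),
            }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ClassifierConfig":
        colour: dict[str, ColourClass] = {}
        shape: dict[str, ShapeClass] = {}
        try:
            for label, block in data["classes"].items():
                colour[label] = ColourClass(
                    class_label=label,
                    hue_range=tuple(block["hue"]),
                    saturation_range=tuple(block["saturation"]),
                    intensity_range=tuple(block["intensity"]),
                )
                shape[label] = ShapeClass(
                    class_label=label,
                    spot_width_um=float(block["spot_width"]),
                    width_range_um=tuple(block["width"]),
                    compactness_range=tuple(block["compactness"]),
                    roundness_range=tuple(block["roundness"]),
                    axis_ratio_range=tuple(block["axis_ratio"]),
                )
        except KeyError as exc:
            raise ValueError(f"classifier config missing required field: {exc}") from exc
        return cls(
            colour=colour,
            shape=shape,
            stain_od_matrix=np.asarray(data.get("stain_od_matrix", HED_FROM_RGB), dtype=float),
            version=str(data.get("version", "unversioned")),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: not a classifier config mapping")
        return cls.from_dict(data)


def universal_config() -> ClassifierConfig:
    """The bundled universal classifier configuration.

    Calibrated once against the synthetic core generator's reference
    stain rendering; swap in an alternate YAML for instrument-tuned
    parameter sets.
    """
    text = resources.files("ki67tma.data").joinpath("universal.yaml").read_text()
    return ClassifierConfig.from_dict(yaml.safe_load(text))
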