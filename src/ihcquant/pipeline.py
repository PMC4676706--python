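"""Run configuration, region cropping, and batch processing.

Coordinate convention, documented and enforced in tests: pixels are
0-based ``(row, col)``; crop rectangles are ``(x, y, w, h)`` with x the
column offset, half-open on both axes — ``[x, x+w) × [y, y+h)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .colorspace import (
    NUCLEAR_RANGE,
    STAIN_RANGE,
    RGBImage,
    ThresholdRange,
    read_image,
)
from .quantify import ClassifierConfig, quantify_section
from .segmentation import SegmentationConfig

__all__ = ["CropRect", "RunConfig", "crop_regions", "batch_run", "read_manifest"]

logger = logging.getLogger("ihcquant")


@dataclass(frozen=True)
class CropRect:
    """Half-open, 0-based crop rectangle [x, x+w) × [y, y+h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"crop {self} must have positive width and height")

    @classmethod
    def parse(cls, text: str) -> "CropRect":
        """Parse ``'x,y,w,h'``."""
        parts = [int(p) for p in str(text).split(",")]
        if len(parts) != 4:
            raise ValueError(f"expected 'x,y,w,h', got {text!r}")
        return cls(*parts)

    def __str__(self) -> str:
        return f"{self.x},{self.y},{self.w},{self.h}"


@dataclass(frozen=True)
class RunConfig:
    """Full effective configuration of a quantification run.

    Defaults are the published analysis parameters: nuclear box
    L*=[40,72], a*=[-11,20], b*=[-37,12]; stain box L*=[40,80],
    a*=[-6,20], b*=[-0.2,33]; ROI radius 5 px; positivity at >= 20
    stain pixels; 0.46 μm/px.  Serializes losslessly to and from JSON.
    """

    nuclear_range: ThresholdRange = field(default=NUCLEAR_RANGE)
    stain_range: ThresholdRange = field(default=STAIN_RANGE)
    seg: SegmentationConfig = field(default=SegmentationConfig())
    min_positive_pixels: int = 20
    pixel_size: Optional[float] = 0.46

    @property
    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(
            min_positive_pixels=self.min_positive_pixels, stain_range=self.stain_range
        )

    def to_dict(self) -> dict:
        return {
            "nuclear_range": list(self.nuclear_range.as_tuple()),
            "stain_range": list(self.stain_range.as_tuple()),
            "seg": dataclasses.asdict(self.seg),
            "min_positive_pixels": self.min_positive_pixels,
            "pixel_size": self.pixel_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            nuclear_range=ThresholdRange.from_sequence(d["nuclear_range"]),
            stain_range=ThresholdRange.from_sequence(d["stain_range"]),
            seg=SegmentationConfig(**d["seg"]),
            min_positive_pixels=int(d["min_positive_pixels"]),
            pixel_size=d["pixel_size"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def crop_regions(image: RGBImage, crops: Sequence[CropRect]) -> list[RGBImage]:
    """Cut sub-images, carrying provenance (source path and offsets).

    Every rectangle must lie fully inside the image; an out-of-bounds
    rectangle raises a ValueError naming it.
    """
    H, W = image.shape
    out = []
    for crop in crops:
        if crop.x < 0 or crop.y < 0 or crop.x + crop.w > W or crop.y + crop.h > H:
            raise ValueError(f"crop {crop} out of bounds for {W}x{H} image")
        sub = image.pixels[crop.y : crop.y + crop.h, crop.x : crop.x + crop.w]
        out.append(
            RGBImage(
                sub.copy(),
                pixel_size=image.pixel_size,
                source=image.source,
                origin=(image.origin[0] + crop.x, image.origin[1] + crop.y),
            )
        )
    return out


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a batch manifest CSV.

    Required column: ``image_path``; optional: ``crop`` ('x,y,w,h'),
    ``group``, ``animal_id``, ``antibody``.
    """
    df = pd.read_csv(path, dtype=str)
    if "image_path" not in df.columns:
        raise ValueError(f"manifest {path} lacks the required 'image_path' column")
    return df


def batch_run(
    manifest: pd.DataFrame,
    config: RunConfig = RunConfig(),
    base_dir: str | Path = ".",
) -> pd.DataFrame:
    """Quantify every (image, crop) row of a manifest.

    Row-level fault tolerance: an unreadable image flags that row's
    ``error`` column and the run continues, so one corrupt slide cannot
    void a cohort.  An empty manifest returns an empty table (with a
    warning) rather than failing.
    """
    base = Path(base_dir)
    rows = []
    if len(manifest) == 0:
        logger.warning("manifest is empty; producing an empty results table")
    for _, row in manifest.iterrows():
        record = {
            c: row.get(c) for c in ("image_path", "crop", "group", "animal_id", "antibody")
        }
        record.update(
            {"total_cells": None, "positive_cells": None, "area": None,
             "area_units": None, "density": None, "error": None}
        )
        try:
            path = base / str(row["image_path"])
            image = read_image(path, pixel_size=config.pixel_size)
            crop_text = row.get("crop")
            if isinstance(crop_text, str) and crop_text.strip():
                image = crop_regions(image, [CropRect.parse(crop_text)])[0]
            result, _ = quantify_section(
                image,
                nuclear_range=config.nuclear_range,
                classifier=config.classifier,
                seg=config.seg,
            )
            record.update(
                total_cells=result.total_cells,
                positive_cells=result.positive_cells,
                area=result.area,
                area_units=result.area_units,
                density=result.density,
            )
        except Exception as exc:  # row-level fault tolerance
            logger.error("row %r failed: %s", row.get("image_path"), exc)
            record["error"] = str(exc)
        rows.append(record)
    columns = [
        "image_path", "crop", "group", "animal_id", "antibody",
        "total_cells", "positive_cells", "area", "area_units", "density", "error",
    ]
    return pd.DataFrame(rows, columns=columns)
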