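"""Positive-cell classification and per-section quantification.

A detected cell is antibody-positive when its cytoplasmic ROI contains
at least ``min_positive_pixels`` (default 20) pixels whose color falls
inside the DAB stain threshold box.  Section-level output is the total
cell count, the positive count, the analyzed area, and the positive-cell
density (positives divided by area — in cells/mm² when the pixel size is
known, else cells per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .colorspace import (
    BinaryMask,
    RGBImage,
    ThresholdRange,
    NUCLEAR_RANGE,
    STAIN_RANGE,
    lab_threshold,
    rgb_to_lab,
)
from .segmentation import (
    DetectedCell,
    SegmentationConfig,
    cells_to_table,
    dilate_roi,
    particle_analysis,
)

__all__ = [
    "ClassifierConfig",
    "QuantResult",
    "classify_positive",
    "count_stain_pixels",
    "quantify_section",
    "density",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Positivity rule: ≥ ``min_positive_pixels`` stain-box pixels in the ROI."""

    min_positive_pixels: int = 20
    stain_range: ThresholdRange = field(default=STAIN_RANGE)

    def __post_init__(self) -> None:
        if self.min_positive_pixels < 1:
            raise ValueError("min_positive_pixels must be >= 1")


@dataclass(frozen=True)
class QuantResult:
    """Per-section totals.

    ``area`` is the analyzed region area — mm² when the image's pixel
    size was known, pixels otherwise (``area_units`` records which) —
    and ``density`` is ``positive_cells / area`` exactly.
    """

    total_cells: int
    positive_cells: int
    area: float
    area_units: str = "px"

    def __post_init__(self) -> None:
        if not (0 <= self.positive_cells <= self.total_cells):
            raise ValueError("need 0 <= positive_cells <= total_cells")
        if self.area <= 0:
            raise ValueError("analyzed area must be positive")

    @property
    def density(self) -> float:
        return self.positive_cells / self.area


def count_stain_pixels(cell: DetectedCell, stain_mask: BinaryMask) -> int:
    """Number of stain-mask-true pixels inside the cell's ROI."""
    if cell.roi_pixels is None:
        raise ValueError("cell has no ROI; run dilate_roi first")
    return sum(1 for (r, c) in cell.roi_pixels if stain_mask[r, c])


def classify_positive(
    cell: DetectedCell,
    stain_mask: BinaryMask,
    config: ClassifierConfig = ClassifierConfig(),
) -> bool:
    """True iff the ROI holds at least ``min_positive_pixels`` stain pixels.

    The bound is inclusive: exactly ``min_positive_pixels`` is positive.
    """
    return count_stain_pixels(cell, stain_mask) >= config.min_positive_pixels


def quantify_section(
    image: RGBImage,
    nuclear_range: ThresholdRange = NUCLEAR_RANGE,
    classifier: ClassifierConfig = ClassifierConfig(),
    seg: SegmentationConfig = SegmentationConfig(),
) -> tuple[QuantResult, pd.DataFrame]:
    """Run the full pipeline on one section image.

    Steps: sRGB→L*a*b* conversion, nuclear box threshold, particle
    analysis, radius-r ROI dilation, stain box threshold, and the
    pixel-count positivity rule per cell.  Returns the section totals
    and a per-cell table (label, centroid, areas, stain_pixels,
    positive) so downstream scoring and statistics stay auditable.
    """
    lab = rgb_to_lab(image)
    nuclear_mask = lab_threshold(lab, nuclear_range)
    stain_mask = lab_threshold(lab, classifier.stain_range)
    cells = particle_analysis(nuclear_mask, seg)
    cells = [dilate_roi(c, seg, image.shape) for c in cells]
    table = cells_to_table(cells)
    counts = [count_stain_pixels(c, stain_mask) for c in cells]
    table["stain_pixels"] = counts
    table["positive"] = [n >= classifier.min_positive_pixels for n in counts]
    result = QuantResult(
        total_cells=len(cells),
        positive_cells=int(table["positive"].sum()) if len(cells) else 0,
        area=image.area(),
        area_units=image.area_units,
    )
    return result, table


def density(result: QuantResult) -> float:
    """Positive-cell density: ``positive_cells / area``."""
    return result.density
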