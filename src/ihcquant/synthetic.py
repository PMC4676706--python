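"""Seeded synthetic histology slides and cohort score tables.

Slides emulate what the detection pipeline assumes about a brightfield
IHC section: elliptical hematoxylin-counterstained nuclei whose color
sits inside the nuclear L*a*b* threshold box, an annular brown DAB
cytoplasm around each positive cell whose color sits inside the stain
box, and a pale background outside both boxes.  The scene is composed
in L*a*b* — the space the thresholds live in — converted to sRGB,
quantized to 8 bits, and optionally degraded with Gaussian channel
noise.  Ground truth (per-cell center, radius, positivity) is emitted
alongside, so recovery by the pipeline is measurable exactly.

No attempt is made at photorealistic tissue texture: the generator
targets the algorithm's assumptions, not visual fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage import draw as _skdraw

from .colorspace import NUCLEAR_RANGE, STAIN_RANGE, RGBImage, ThresholdRange

__all__ = [
    "SlideSpec",
    "CellRecord",
    "GroundTruth",
    "CohortGroupSpec",
    "CohortSpec",
    "PackingError",
    "generate_slide",
    "generate_cohort_scores",
]

#: Default scan resolution (μm per pixel) of a 20x whole-slide image.
DEFAULT_PIXEL_SIZE_UM = 0.46


class PackingError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested overlap."""


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic slide.

    Defaults describe a 1024×1024 px field (≈471 μm square at the 20x
    scan resolution of 0.46 μm/px, i.e. a typical cropped synovial
    region) holding 100 nuclei of mean radius 6 px with 40% of cells
    DAB-positive — the regime of the quantitative IHC analysis this
    pipeline is validated for.  Color centers sit well inside their
    threshold boxes so that 8-bit sRGB quantization cannot push a clean
    pixel across a box face; the background is far outside both.

    ``max_overlap_fraction`` caps, per placed nucleus, the fraction of
    its area shared with previously placed nuclei; at 0 nuclei are kept
    strictly non-touching so every cell is a separate particle.  Cells
    are placed either well-separated (boundary gap ≥ ``min_clearance``,
    so a cell's dilated ROI can only see its own cytoplasm and truth
    labels are unambiguous) or genuinely overlapping within the cap
    (exercising the pipeline's touching-nuclei merge bias); the
    ambiguous in-between zone is excluded by design.

    ``marginal`` paints only 15–25 stain pixels per positive cell
    instead of the full cytoplasmic ring, to exercise the classifier's
    20-pixel decision boundary.
    """

    width: int = 1024
    height: int = 1024
    n_cells: int = 100
    positive_fraction: float = 0.4
    nucleus_radius_mean: float = 6.0
    nucleus_radius_sd: float = 1.0
    max_overlap_fraction: float = 0.0
    min_clearance: float = 10.0
    cytoplasm_width: float = 3.0
    nuclear_color_center: tuple[float, float, float] = (56.0, 4.5, -12.5)
    stain_color_center: tuple[float, float, float] = (60.0, 7.0, 16.5)
    background_color: tuple[float, float, float] = (95.0, 2.0, 4.0)
    color_jitter_sd: float = 1.0
    noise_sd: float = 2.0
    marginal: bool = False
    pixel_size: Optional[float] = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("slide must be at least 1x1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must be in [0, 1]")
        if not (0.0 <= self.max_overlap_fraction <= 1.0):
            raise ValueError("max_overlap_fraction must be in [0, 1]")
        if self.nucleus_radius_mean <= 0 or self.nucleus_radius_sd < 0:
            raise ValueError("nucleus radius parameters must be positive")
        if self.min_clearance < 0:
            raise ValueError("min_clearance must be >= 0")
        if not NUCLEAR_RANGE.contains(*self.nuclear_color_center):
            raise ValueError("nuclear_color_center must lie inside the nuclear box")
        if not STAIN_RANGE.contains(*self.stain_color_center):
            raise ValueError("stain_color_center must lie inside the stain box")
        if NUCLEAR_RANGE.contains(*self.background_color) or STAIN_RANGE.contains(
            *self.background_color
        ):
            raise ValueError("background_color must lie outside both threshold boxes")


@dataclass(frozen=True)
class CellRecord:
    """Ground truth for one simulated cell."""

    center: tuple[float, float]  # (row, col)
    radius: float
    is_positive: bool


@dataclass(frozen=True)
class GroundTruth:
    """Per-cell records plus consistent totals."""

    records: tuple[CellRecord, ...]

    @property
    def n_cells(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return sum(r.is_positive for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_row": [r.center[0] for r in self.records],
                "center_col": [r.center[1] for r in self.records],
                "radius": [r.radius for r in self.records],
                "is_positive": [r.is_positive for r in self.records],
            }
        )


_MAX_ATTEMPTS_PER_CELL = 10_000


def _ellipse_mask(
    center: tuple[float, float],
    r_radius: float,
    c_radius: float,
    rotation: float,
    shape: tuple[int, int],
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _skdraw.ellipse(
        center[0], center[1], r_radius, c_radius, shape=shape, rotation=rotation
    )
    mask[rr, cc] = True
    return mask



def generate_slide(spec: SlideSpec) -> tuple[RGBImage, GroundTruth]:
    """Render one synthetic slide and its ground truth.

    Nuclei are placed by rejection sampling honoring the overlap cap
    (bounded at 10⁴ attempts per cell, then :class:`PackingError`);
    exactly ``round(positive_fraction · n_cells)`` randomly chosen cells
    receive a DAB cytoplasm.  Identical specs (including seed) yield
    byte-identical images and truth tables.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    shape = (H, W)

    n_positive = int(round(spec.positive_fraction * spec.n_cells))
    positive_idx = set(rng.choice(spec.n_cells, size=n_positive, replace=False).tolist()) if spec.n_cells else set()

    occupancy = np.zeros(shape, dtype=bool)
    placed: list[dict] = []
    records: list[CellRecord] = []
    centers = np.empty((0, 2))
    majors = np.empty(0)
    for i in range(spec.n_cells):
        for _ in range(_MAX_ATTEMPTS_PER_CELL):
            radius = max(3.0, rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd))
            axis_ratio = rng.uniform(0.75, 1.0)
            rotation = rng.uniform(0.0, np.pi)
            margin = radius + spec.cytoplasm_width + 2
            if 2 * margin >= min(H, W):
                raise PackingError("slide too small for the requested nucleus size")
            center = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
            # Cheap prefilter on semi-major axes: accept outright when the
            # candidate keeps at least min_clearance of background between
            # nucleus boundaries; otherwise it must genuinely overlap a
            # neighbor within the cap, never merely graze one.
            if centers.shape[0]:
                dists = np.hypot(centers[:, 0] - center[0], centers[:, 1] - center[1])
                separated = bool(np.all(dists >= majors + radius + spec.min_clearance))
            else:
                separated = True
            nucleus = None
            if not separated:
                if spec.max_overlap_fraction == 0.0:
                    continue
                nucleus = _ellipse_mask(center, radius, radius * axis_ratio, rotation, shape)
                if nucleus.sum() == 0:
                    continue
                frac = int((nucleus & occupancy).sum()) / nucleus.sum()
                if frac == 0.0 or frac > spec.max_overlap_fraction:
                    continue
            if nucleus is None:
                nucleus = _ellipse_mask(center, radius, radius * axis_ratio, rotation, shape)
                if nucleus.sum() == 0:
                    continue
            occupancy |= nucleus
            centers = np.vstack([centers, np.asarray(center)[None, :]])
            majors = np.append(majors, radius)
            placed.append(
                {
                    "mask": nucleus,
                    "center": center,
                    "radius": radius,
                    "axis_ratio": axis_ratio,
                    "rotation": rotation,
                    "positive": i in positive_idx,
                }
            )
            records.append(CellRecord(center=center, radius=radius, is_positive=i in positive_idx))
            break
        else:
            raise PackingError(
                f"could not place nucleus {i + 1}/{spec.n_cells} after "
                f"{_MAX_ATTEMPTS_PER_CELL} attempts at overlap <= {spec.max_overlap_fraction}"
            )

    # Compose the scene in L*a*b*: background, then cytoplasm rings, then nuclei.
    scene = np.empty((H, W, 3), dtype=float)
    scene[:] = np.asarray(spec.background_color)

    jitter = lambda: rng.normal(0.0, spec.color_jitter_sd, size=3)  # noqa: E731

    for cell in placed:
        if not cell["positive"]:
            continue
        outer = _ellipse_mask(
            cell["center"],
            cell["radius"] + spec.cytoplasm_width,
            cell["radius"] * cell["axis_ratio"] + spec.cytoplasm_width,
            cell["rotation"],
            shape,
        )
        ring = outer & ~occupancy  # cytoplasm never paints over any nucleus
        color = np.asarray(spec.stain_color_center) + jitter()
        if spec.marginal:
            rr, cc = np.nonzero(ring)
            k = min(int(rng.integers(15, 26)), rr.size)
            pick = rng.choice(rr.size, size=k, replace=False)
            scene[rr[pick], cc[pick]] = color
        else:
            scene[ring] = color

    for cell in placed:
        scene[cell["mask"]] = np.asarray(spec.nuclear_color_center) + jitter()

    rgb = _skcolor.lab2rgb(scene)
    img8 = np.rint(rgb * 255.0)
    if spec.noise_sd > 0:
        img8 = img8 + rng.normal(0.0, spec.noise_sd, size=img8.shape)
    img8 = np.clip(np.rint(img8), 0, 255).astype(np.uint8)

    return RGBImage(img8, pixel_size=spec.pixel_size), GroundTruth(tuple(records))


@dataclass(frozen=True)
class CohortGroupSpec:
    """One experimental group: its size and per-scale score distributions.

    ``scale_probs`` maps a scale name to the probability of each score
    value 0..k on that scale (must sum to 1).
    """

    name: str
    n_animals: int
    scale_probs: tuple[tuple[str, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for scale, probs in self.scale_probs:
            p = np.asarray(probs, dtype=float)
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{self.name}/{scale}: probabilities must be >= 0 and sum to 1")

    @classmethod
    def build(cls, name: str, n_animals: int, scale_probs: dict[str, Sequence[float]]) -> "CohortGroupSpec":
        return cls(name, n_animals, tuple((k, tuple(v)) for k, v in scale_probs.items()))


@dataclass(frozen=True)
class CohortSpec:
    """A study-shaped cohort: named groups with seeded score draws."""

    groups: tuple[CohortGroupSpec, ...]
    seed: int = 0


def generate_cohort_scores(spec: CohortSpec) -> pd.DataFrame:
    """Draw a tidy score table (animal_id, group, scale, value).

    Each animal receives one independent draw per scale from its group's
    categorical distribution; identical specs give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    animal = 0
    for group in spec.groups:
        for _ in range(group.n_animals):
            animal += 1
            for scale, probs in group.scale_probs:
                value = int(rng.choice(len(probs), p=np.asarray(probs, dtype=float)))
                rows.append(
                    {
                        "animal_id": f"A{animal:03d}",
                        "group": group.name,
                        "scale": scale,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows, columns=["animal_id", "group", "scale", "value"])
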