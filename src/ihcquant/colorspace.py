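"""sRGB → CIE L*a*b* conversion and box thresholding.

All downstream detection works in CIE 1976 L*a*b* (D65 reference white,
sRGB companding — the convention of mainstream imaging libraries), with
L* on the 0–100 scale and a*, b* unscaled.  Nuclei counterstained with
hematoxylin and brown DAB reaction product are each identified by a
closed box threshold in this space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "RGBImage",
    "LabImage",
    "ThresholdRange",
    "BinaryMask",
    "NUCLEAR_RANGE",
    "STAIN_RANGE",
    "rgb_to_lab",
    "lab_threshold",
    "read_image",
    "write_image",
    "MalformedImageError",
]

#: A binary mask is a plain 2-D boolean numpy array with the same H×W as
#: the image it was derived from.
BinaryMask = np.ndarray


class MalformedImageError(ValueError):
    """Raised for images that are not 8-bit 3-channel sRGB."""


@dataclass(frozen=True)
class ThresholdRange:
    """A closed box in L*a*b* space.

    A pixel is inside the box iff ``L_min <= L* <= L_max`` and likewise
    for a* and b*; values exactly at a bound are inside.
    """

    L_min: float
    L_max: float
    a_min: float
    a_max: float
    b_min: float
    b_max: float

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.L_min, self.L_max, "L"),
            (self.a_min, self.a_max, "a"),
            (self.b_min, self.b_max, "b"),
        ):
            if lo > hi:
                raise ValueError(f"{name}_min ({lo}) exceeds {name}_max ({hi})")

    @classmethod
    def from_sequence(cls, values: Sequence[float]) -> "ThresholdRange":
        """Build from ``(L_min, L_max, a_min, a_max, b_min, b_max)``."""
        vals = [float(v) for v in values]
        if len(vals) != 6:
            raise ValueError("expected 6 values: L_min,L_max,a_min,a_max,b_min,b_max")
        return cls(*vals)

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.L_min, self.L_max, self.a_min, self.a_max, self.b_min, self.b_max)

    def contains(self, L: float, a: float, b: float) -> bool:
        return bool(
            self.L_min <= L <= self.L_max
            and self.a_min <= a <= self.a_max
            and self.b_min <= b <= self.b_max
        )


#: Box for hematoxylin-stained nuclei (bluish purple).
NUCLEAR_RANGE = ThresholdRange(40.0, 72.0, -11.0, 20.0, -37.0, 12.0)
#: Box for the brown DAB reaction product marking antibody binding.
STAIN_RANGE = ThresholdRange(40.0, 80.0, -6.0, 20.0, -0.2, 33.0)


@dataclass
class RGBImage:
    """An 8-bit sRGB brightfield image tile.

    Parameters
    ----------
    pixels
        ``H×W×3`` uint8 array of sRGB channel values.
    pixel_size
        Physical edge length of one pixel in micrometres, if known
        (0.46 μm/px for a 20× whole-slide scan).
    source
        Provenance: path of the file the tile came from, if any.
    origin
        ``(x, y)`` offset of this tile within its source image.
    """

    pixels: np.ndarray
    pixel_size: Optional[float] = None
    source: Optional[str] = None
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise MalformedImageError(
                f"expected an H×W×3 array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise MalformedImageError("image must have at least one pixel")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise MalformedImageError(
                    f"expected 8-bit channel values in [0,255], got dtype {px.dtype}"
                )
        self.pixels = px
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """``(H, W)`` of the image."""
        return self.pixels.shape[:2]

    def area(self) -> float:
        """Analyzed area: mm² when pixel_size (μm) is known, else pixels."""
        h, w = self.shape
        if self.pixel_size is not None:
            return h * w * (self.pixel_size ** 2) * 1e-6
        return float(h * w)

    @property
    def area_units(self) -> str:
        return "mm^2" if self.pixel_size is not None else "px"


@dataclass
class LabImage:
    """Per-pixel CIE L*a*b* values; channel 0 is L* in [0, 100]."""

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise MalformedImageError(
                f"expected an H×W×3 array, got shape {px.shape}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def rgb_to_lab(image: RGBImage) -> LabImage:
    """Convert an sRGB image to CIE L*a*b* (D65).

    Uses sRGB companding and the CIE 1976 formulas; white (255,255,255)
    maps to L*=100 with neutral a*, b*.
    """
    return LabImage(_skcolor.rgb2lab(image.pixels))


def lab_threshold(image: LabImage, range: ThresholdRange) -> BinaryMask:
    """Binary mask of pixels inside a closed L*a*b* box.

    True exactly where ``L_min <= L* <= L_max`` and the analogous bounds
    hold for a* and b*.
    """
    px = image.pixels
    L, a, b = px[..., 0], px[..., 1], px[..., 2]
    return (
        (L >= range.L_min) & (L <= range.L_max)
        & (a >= range.a_min) & (a <= range.a_max)
        & (b >= range.b_min) & (b <= range.b_max)
    )


def read_image(path: str | Path, pixel_size: Optional[float] = None) -> RGBImage:
    """Read an 8-bit RGB TIFF or PNG tile.

    Images with an alpha channel are accepted only when the alpha is
    fully opaque, in which case it is dropped; otherwise a
    :class:`MalformedImageError` is raised.
    """
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        alpha = arr[..., 3]
        opaque = np.iinfo(arr.dtype).max if arr.dtype.kind == "u" else 255
        if not np.all(alpha == opaque):
            raise MalformedImageError(f"{path}: alpha channel is not fully opaque")
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise MalformedImageError(f"{path}: expected a 3-channel RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise MalformedImageError(f"{path}: expected 8-bit channels, got {arr.dtype}")
    return RGBImage(arr, pixel_size=pixel_size, source=str(path))


def write_image(image: RGBImage, path: str | Path) -> None:
    """Write an RGB image as PNG or TIFF, chosen by file extension."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), image.pixels)
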