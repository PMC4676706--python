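"""Ordinal scoring scales for clinical, histological and IHC evaluation.

The adjuvant-induced arthritis study design uses fixed ordinal scales:
a 0–3 per-joint clinical inflammatory score (summed over affected
joints per animal), four 0–3/0–4 histological scores, and a 0–4
semi-quantitative IHC staining score binned on the positive-staining
fraction.  The fraction bins overlap at their boundaries as printed
("1: 0–25%, 2: 25–50%, ..."); here they are half-open, closed on the
right, with 0 reserved for exactly no staining.  That convention is
isolated in :func:`ihc_semiquant_score` so a reviewer can flip it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ScoreScale",
    "IHC_SCALE",
    "LINING_SCALE",
    "CLINICAL_SCALE",
    "INFILTRATION_SCALE",
    "EROSION_SCALE",
    "GLOBAL_SEVERITY_SCALE",
    "ALL_SCALES",
    "ihc_semiquant_score",
    "lining_layer_score",
    "clinical_score_from_label",
    "total_inflammatory_score",
]


@dataclass(frozen=True)
class ScoreScale:
    """An ordinal scale: consecutive integer scores with text labels."""

    name: str
    labels: tuple[str, ...]  # labels[k] describes score k

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("a scale needs at least one bin")

    @property
    def scores(self) -> range:
        return range(len(self.labels))

    def validate(self, value: int) -> int:
        v = int(value)
        if v != value or not (0 <= v < len(self.labels)):
            raise ValueError(
                f"{self.name}: score {value!r} outside 0..{len(self.labels) - 1}"
            )
        return v

    def score_of(self, label: str) -> int:
        """Score whose text label matches (case-insensitive)."""
        target = label.strip().lower()
        for k, text in enumerate(self.labels):
            if text.lower() == target:
                return k
        raise KeyError(f"{self.name}: no bin labeled {label!r}")


IHC_SCALE = ScoreScale(
    "ihc_staining",
    (
        "no staining",
        "0-25% staining",
        "25-50% staining",
        "50-75% staining",
        "more than 75% staining",
    ),
)

LINING_SCALE = ScoreScale(
    "lining_layer_cell_number",
    (
        "fewer than three layers",
        "three to four layers",
        "five to six layers",
        "more than six layers",
    ),
)

CLINICAL_SCALE = ScoreScale(
    "clinical_inflammatory",
    (
        "absence",
        "erythema",
        "erythema and swelling",
        "deformities and functional impairment",
    ),
)

# The two scales below encode pathologist judgments; the package
# provides the enumeration and validation but no image-derived mapping.
INFILTRATION_SCALE = ScoreScale(
    "sublining_layer_infiltration",
    (
        "none to diffuse infiltration",
        "lymphoid cell aggregate",
        "lymphoid follicles",
        "lymphoid follicles with germinal center formation",
    ),
)

EROSION_SCALE = ScoreScale(
    "bone_erosion",
    ("no erosions", "minimal", "mild", "moderate", "marked"),
)

GLOBAL_SEVERITY_SCALE = ScoreScale(
    "global_severity",
    ("no signs of inflammation", "mild", "moderate", "severe"),
)

ALL_SCALES = {
    s.name: s
    for s in (
        IHC_SCALE,
        LINING_SCALE,
        CLINICAL_SCALE,
        INFILTRATION_SCALE,
        EROSION_SCALE,
        GLOBAL_SEVERITY_SCALE,
    )
}


def ihc_semiquant_score(fraction_positive: float) -> int:
    """Semi-quantitative 0–4 IHC score from the positive-staining fraction.

    0 iff exactly no staining; otherwise (0, 0.25] → 1, (0.25, 0.5] → 2,
    (0.5, 0.75] → 3, (0.75, 1] → 4 (half-open bins, closed on the right).
    """
    f = float(fraction_positive)
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {f}")
    if f == 0.0:
        return 0
    for score, upper in ((1, 0.25), (2, 0.5), (3, 0.75)):
        if f <= upper:
            return score
    return 4


def lining_layer_score(layer_count: int) -> int:
    """0–3 synovial lining-layer score from the counted cell layers.

    Fewer than three layers → 0; three to four → 1; five to six → 2;
    more than six → 3.
    """
    n = int(layer_count)
    if n != layer_count or n < 0:
        raise ValueError(f"layer count must be a non-negative integer, got {layer_count}")
    if n < 3:
        return 0
    if n <= 4:
        return 1
    if n <= 6:
        return 2
    return 3


def clinical_score_from_label(label: str) -> int:
    """0–3 per-joint clinical score from its observed category.

    0 absence; 1 erythema; 2 erythema and swelling; 3 deformities and
    functional impairment.
    """
    return CLINICAL_SCALE.score_of(label)


def total_inflammatory_score(joints: Sequence[int]) -> int:
    """Total clinical score of an animal: the sum of its per-joint scores.

    Each element must be a valid 0–3 clinical score; an empty list
    (no affected joints) totals 0.
    """
    return sum(CLINICAL_SCALE.validate(j) for j in joints)
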