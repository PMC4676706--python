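# Methods

## Detection model

The pipeline assumes chromogenic brightfield IHC with a hematoxylin
nuclear counterstain and DAB (diaminobenzidine) development: nuclei are
bluish-purple, antibody-bound cytoplasm is brown, background tissue and
glass are pale. Detection is purely colorimetric — a pixel belongs to a
nucleus or to stain according to whether its CIE L\*a\*b\* value falls
in a fixed closed box:

| box | L\* | a\* | b\* |
|---|---|---|---|
| nuclear (hematoxylin) | [40, 72] | [−11, 20] | [−37, 12] |
| stain (DAB) | [40, 80] | [−6, 20] | [−0.2, 33] |

Both boxes are closed on all six faces (a value exactly at a bound is
inside, matching the bracket notation of the ranges). Because the
source of the ranges states neither the RGB working space nor the
illuminant, conversion uses sRGB companding with the D65 reference
white and the CIE 1976 formulas — the default of mainstream imaging
libraries — with L\* on 0–100 and a\*/b\* unscaled (the negative bounds
force the unscaled convention). If a scanner applies an ICC profile
before export, the thresholds are treated as applying to the exported
sRGB image; no profile handling is attempted.

Nucleus mask → cells by connected-component particle analysis.
Defaults: 8-connectivity (the common particle-analysis convention),
minimum particle area 10 px to suppress single-pixel chroma noise,
no maximum. Both are configurable; the analysis ranges were published
without a size filter, so the floor is an explicit, logged choice.
Touching nuclei merge into one particle — there is deliberately no
watershed splitting, and the synthetic generator's overlap parameter
exercises this bias.

Each cell's cytoplasmic ROI is the set of in-bounds pixels within
Euclidean distance 5 px of its nucleus (a disk structuring element,
dx² + dy² ≤ r², computed by exact distance transform). The ROI includes
the nucleus; an `annulus` switch subtracts it for users who read
"cytoplasmic area" strictly as the ring. ROIs of adjacent cells may
share pixels: positivity is evaluated per cell with no exclusivity, so
a shared stain pixel can count toward both cells.

A cell is antibody-positive iff its ROI contains **at least 20** pixels
inside the stain box — an inclusive boundary (exactly 20 is positive).
Density divides the positive count by the area of the analyzed cropped
region (not a tissue-masked area), in mm² when the pixel size is known
(default 0.46 μm/px, a 20× whole-slide scan) and in pixels otherwise.
This denominator choice changes absolute densities and is therefore
fixed and documented here.

## Scoring scales

All scales are total, deterministic, monotone maps. The printed
percentage bins of the 0–4 IHC score overlap at their boundaries
("1: 0–25%, 2: 25–50%, …"); the implementation uses half-open bins
closed on the right with 0 reserved for exactly zero staining, isolated
in one function so the convention can be flipped. The lining-layer
(0–3) and clinical joint (0–3) scales are direct bin maps; the total
inflammatory score of an animal is the sum of its per-joint clinical
scores (the joint census is left to the user — it is not fixed here).
The sublining-infiltration, bone-erosion, and global-severity scales
encode pathologist judgments, so they are provided as validated
enumerations with text labels but no image-derived mapping.

## Statistics

Small ordinal cohorts call for exact non-parametric tests.

- **Mann–Whitney (exact)** — two-sided p from the full permutation
  distribution of the rank sum over all C(N, n₁) group labelings,
  computed by subset-sum dynamic programming on doubled midranks
  (identical to literal enumeration; tests verify this). p is twice the
  smaller tail, clipped at 1. Above a combined n of 25 the test falls
  back to the tie-corrected normal approximation and says so in its
  `method` field; the switchover balances fidelity at the cohort sizes
  this package targets (5–15 per group) against tractability.
- **Kruskal–Wallis** — H with the standard tie correction
  1 − Σ(t³−t)/(N³−N); p from the χ² approximation with k−1 df. All
  observations identical degenerates to H = 0, p = 1.
- **Dunn's post hoc** — pairwise z on pooled midranks with the tie
  term Σ(t³−t)/(12(N−1)) in the variance; two-sided normal p multiplied
  by the k(k−1)/2 comparisons performed and clipped at 1
  (Bonferroni-style, the documented behavior of the graphing software
  these analyses are usually run in).
- **Spearman** — Pearson correlation of midranks (tie-corrected rho);
  exact permutation p (all n! pairings) for n ≤ 8, t-approximation with
  n−2 df above. rho² is reported alongside for r²-style summaries;
  whether a published "r²" is squared Spearman rho or a regression fit
  is left to the reader — both numbers are exposed.

Midranks are used throughout. Exact tests at these sample sizes are
conservative: at n = 5 vs 5 the smallest achievable two-sided p is
2/252 ≈ 0.0079, and the null rejection rate at α = 0.05 is below
nominal (verified by simulation in the test suite).

## Synthetic slides

The generator renders what the detector assumes, with known truth:
elliptical nuclei (axis ratio 0.75–1, random orientation) colored at
L\*a\*b\* (56, 4.5, −12.5) — inside the nuclear box with a wide margin —
on a (95, 2, 4) background outside both boxes; each positive cell gets
an annular cytoplasm of width 3 px at (60, 7, 16.5), inside the stain
box and comfortably above the 20-px rule (≥ 100 px for default radii),
so classifier recall on clean images is 100% by design. A `marginal`
mode paints only 15–25 stain pixels to exercise the decision boundary.
The scene is composed in L\*a\*b\* — the space the thresholds live
in — converted to sRGB, quantized to 8 bits (the realism floor), and
degraded with Gaussian channel noise (default sd 2 on 0–255 channels).
Identical specs and seeds are byte-identical.

Default geometry: a 1024×1024 px field (≈471 μm square at 0.46 μm/px,
a typical cropped synovial region) with 100 nuclei of mean radius
6 px — about 450 cells/mm², sparse enough that uniform placement rarely
produces touching nuclei. Placement is rejection sampling with a
bounded budget (10⁴ attempts per cell, then an explicit packing error):
a candidate is accepted when its boundary keeps ≥ 10 px of clearance
from every placed nucleus (so a cell's radius-5 ROI can only see its
own cytoplasm and truth labels stay unambiguous), or when it genuinely
overlaps a neighbor by at most `max_overlap_fraction` of its area
(exercising the merge bias). The ambiguous graze zone in between is
excluded by design. `n_positive = round(positive_fraction · n_cells)`
exactly, assigned to uniformly chosen cells.

What the generator does **not** emulate: stain intensity gradients,
nuclear texture and chromatin patterns, out-of-focus blur, tissue
autofluorescence/eosin background, folds and debris, and densely
packed epithelial sheets. Passing recovery tests therefore show the
algorithm is implemented correctly and is robust to quantization,
moderate sensor noise, and bounded nuclear overlap — not that the
published threshold boxes segment any particular scanner's output.

The cohort generator draws per-animal ordinal scores from per-group
categorical distributions over a scale's support, producing tidy
`(animal_id, group, scale, value)` tables for the statistics layer.

## Validation scale

The recovery suite runs 20 seeded slides at the default conditions
(100 cells, 40% positive, overlap cap 5%, noise sd 2); effect-direction
recovery uses 20 pairs of 512×512/60-cell slides at positive fractions
0.7 vs 0.2, and test power uses 200 replicates of n = 10 ordinal draws
with a 3-point median shift. The Monte-Carlo cross-check of the exact
Mann–Whitney p uses 10⁵ permutation draws.

## Known limitations

- Pure color thresholding: no stain-vector deconvolution, so heavily
  mixed hematoxylin/DAB pixels can fall outside both boxes.
- No splitting of touching nuclei; counts are biased low in dense
  tissue.
- The 20-px positivity rule is resolution-dependent; at pixel sizes
  other than 0.46 μm/px the threshold should be rescaled by the user.
- Crop rectangles are axis-aligned, 0-based, half-open
  ([x, x+w) × [y, y+h)); polygonal synovium outlines must be supplied
  as bounding rectangles.
- Whole-slide pyramidal formats (NDPI/SVS) are out of scope; users
  supply cropped 8-bit RGB TIFF/PNG tiles.
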