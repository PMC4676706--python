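# ihcquant

Quantitative immunohistochemistry (IHC) for brightfield histology:
detect hematoxylin-counterstained cell nuclei by color thresholding in
CIE L\*a\*b\* space, build a dilated cytoplasmic region of interest
(ROI) around each detected cell, classify cells as antibody-positive by
a DAB stain-pixel count, and report positive-cell densities — together
with the ordinal clinical/histological/IHC scoring scales and the exact
non-parametric statistics used to compare small animal cohorts.

It is written for researchers quantifying chromogenic IHC (e.g. CD68,
CD163, CD3, CD19, Ki67 in arthritic joint synovium) on cropped
whole-slide image tiles, and it ships a seeded synthetic-slide
generator with known per-cell ground truth so every stage of the
pipeline is testable without any slide data.

## Method

For an sRGB tile **I** (optionally with pixel size, default 0.46 μm/px
for a 20× scan):

1. **Color conversion** — I → CIE L\*a\*b\* (sRGB companding, D65).
2. **Nucleus detection** — binary mask of pixels inside the closed
   nuclear box L\* ∈ [40, 72], a\* ∈ [−11, 20], b\* ∈ [−37, 12],
   followed by particle analysis (8-connected components, ≥10 px).
3. **Cytoplasmic ROI** — each particle dilated by a Euclidean disk of
   radius 5 px (dx² + dy² ≤ r²).
4. **Positivity** — a cell is positive iff its ROI contains ≥ 20 pixels
   inside the stain box L\* ∈ [40, 80], a\* ∈ [−6, 20], b\* ∈ [−0.2, 33]
   (the brown DAB reaction product).
5. **Density** — positive cells divided by the analyzed region area
   (cells/mm² when the pixel size is known).

Ordinal scales: per-joint clinical score 0–3 (summed per animal), the
0–3 lining-layer and 0–4 bone-erosion histology scores, and the 0–4
semi-quantitative IHC score binned on the positive-staining fraction.
Statistics: exact two-sided Mann–Whitney (full permutation distribution
of the rank sum; at n = 5 vs 5 complete separation gives the floor
p = 2/252 ≈ 0.0079), tie-corrected Kruskal–Wallis H, Dunn's pairwise
post-hoc z tests with Bonferroni-style adjustment, and tie-corrected
Spearman correlation.

## Worked example

```python
import ihcquant as q

spec = q.SlideSpec(seed=42, max_overlap_fraction=0.05)   # 1024×1024 px, 100 cells, 40% positive
image, truth = q.generate_slide(spec)
result, per_cell = q.quantify_section(image)

print(f"truth: {truth.n_cells} cells, {truth.n_positive} positive")
print(f"measured: total_cells={result.total_cells} positive_cells={result.positive_cells}")
print(f"area={result.area:.4f} {result.area_units} density={result.density:.1f}")

frac = result.positive_cells / result.total_cells
print("IHC semi-quantitative score:", q.ihc_semiquant_score(frac))

r = q.mann_whitney_exact([410, 395, 388, 402, 371], [122, 140, 95, 133, 110])
print(f"MW exact: U={r.statistic:.1f} p={r.p_value:.4f}")
```

prints

```
truth: 100 cells, 40 positive
measured: total_cells=100 positive_cells=40
area=0.2219 mm^2 density=180.3
IHC semi-quantitative score: 2
MW exact: U=25.0 p=0.0079
```

The simulated slide holds 100 nuclei, 40 of them with DAB cytoplasm;
the pipeline recovers both counts. The analyzed field is
1024² px · (0.46 μm)² = 0.2219 mm², so 40 positives give 180.3
cells/mm². A measured positive fraction of 0.40 falls in the 25–50%
staining bin (score 2), and two completely separated density samples of
five animals each reach the smallest achievable exact two-sided p,
2/252 ≈ 0.0079.

The same pipeline is available from a shell:

```sh
ihcquant simulate --seed 42 --out-dir out/          # slide.png + truth.csv + spec.json
ihcquant quantify out/slide.png --out cells.csv
ihcquant batch slides/ --manifest manifest.csv --out results.csv
ihcquant stats results.csv --groups healthy,arthritic --value density --test mw
```

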