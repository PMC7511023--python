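# Methods

## Pipeline

A field enters as a PNG crop representing 500×500 µm of an H&E-stained
lung section. Processing is:

1. **Standardization.** Bilinear resize to 680×680 px (0.735 µm/px,
   treated as exact; the nominal field is then 499.8 µm wide) and
   conversion to 8-bit grayscale. RGB is collapsed with an unweighted
   channel mean; luminance weights can be supplied instead. Intensity
   standardization is deliberately absent: the batch contract assumes
   comparable staining and microscope settings, so one threshold serves
   a whole batch.
2. **Thresholding.** Tissue = intensity ≤ t (H&E tissue is darker than
   airspace). t is a per-batch constant: either user-supplied or
   suggested by Otsu's method on the first image of the batch
   (`threshold="otsu-first"`).
3. **Automatic exudate removal.** 8-connected tissue components of
   1–1000 px with no image-border contact are deleted. These are free
   exudate particles; anything larger or border/septum-connected is
   left for manual review.
4. **Manual selections.** ROI polygons (JSON, or binary PNG masks
   polygonized by contour tracing) mark non-parenchymal tissue and
   residual exudates. Both are blanked to air before cleaning, and
   non-parenchyma additionally suppresses grid points and intersection
   runs at counting time — a deliberate belt-and-braces rule against
   rim artifacts at blanked-region borders.
5. **Cleaning.** Air holes of 1–200 px fully enclosed by tissue
   (4-connected) are filled; a binary median (majority) filter over a
   radius-2 disk removes salt-and-pepper outliers; one closing
   (dilate–erode, 3×3 square) smooths the mask. The median footprint
   is chosen so walls of ≥ 2 px survive while isolated pixels do not;
   radius and closing iterations are configurable.
6. **Edges.** The air–tissue interface is the inner tissue boundary:
   the mask minus its erosion by the 3×3 cross, which is one pixel
   thick by construction. Erosion treats the image exterior as tissue,
   so the field border itself never counts as interface. An inner
   boundary shrinks objects by up to one pixel relative to their
   outline; this convention is applied consistently on both real and
   synthetic inputs.

## Test system

The counting frame is the central 567×567 px. n = 8 lines per
orientation are placed at `56 + round((k + 0.5)·567/8)` — one line
centered in each of 8 equal strips — and the 64 crossings form the
point grid. Any fixed, data-independent placement yields an unbiased
design when fields are randomly sampled; this one is frozen so counts
are reproducible. Points exactly on a polygon boundary count as
excluded (conservative). d is kept at the conventional 104 µm although
141.75 px × 0.735 µm/px = 104.19 µm; the 0.2% discrepancy is accepted
and d is configurable. A density multiplier k builds (8k)² -point
systems with d = 104/k µm, used for convergence checks.

An intersection is one maximal contiguous run of edge∧line pixels:
an interface grazing a line tangentially therefore counts once, not
once per pixel.

## Read-outs

Ratio-of-sums pooling across a subject's fields (ΣPsep/ΣPref etc.) is
used throughout, matching the estimators' derivation; mean-of-fields
ratios would weight sparse fields equally with dense ones. ΣI = 0 with
airspace points present raises an explicit undefined-read-out error
rather than returning infinity; the all-tissue case returns Lm = 0.
The Lmw (2dΣPsep/ΣI) and SVair (2ΣI/(dΣPref)) forms are the standard
stereological companions of the printed VVsep/Lm formulas, adopted here
as documented extensions.

## Synthetic ground truth

**Wallpapers.** 2040×2040 binary images, tiled; each tile carries the
same figure set, placed afresh per tile. Placement assigns each figure
its own cell of a g×g grid inside the tile and jitters it uniformly
within the cell: placements are random given the seed, while
non-overlap and no-border-crossing hold by construction (random
sequential placement cannot reach the high packing fractions the
validation series needs). Squares and rectangles rasterize exactly, so
the white pixel count equals the analytic ΣA; the theory values
VVsep = (W²−ΣA)/W² and Lm = 4ΣA/ΣP are exact. For axis-aligned
squares/rectangles, axis-aligned line counting estimates 4A/P without
systematic error; for circles its expectation is the mean chord
πA/P = (π/4)·4A/P, a known ~21% systematic gap between the two
definitions that the test suite asserts rather than hides. The default
validation series therefore uses squares and rectangles only: 11 images,
four figures per 340 px tile (two squares, two rectangles of mild
aspect ratio), integer dimensions chosen to span VVsep 0.3–0.9.

**Field sampling.** 680×680 fields are extracted at uniformly random
top-left corners, with replacement, overlap allowed; an optional
low-resolution tissue mask constrains the field center to tissue by
bounded rejection sampling (mirroring sampling "within the edges" of a
slide).

**Histology phantoms.** The septal network is the dilated boundary set
of a random nearest-seed (Voronoi) partition — closed polygonal
airspaces, as in distal lung. Defaults model neonatal distal lung at
0.735 µm/px: 60 airspaces per field (≈ 65 µm alveolar diameter), 7 px
(≈ 5 µm) walls, two vessel-like disks of 30–50 px radius, five exudate
disks of 100–900 px placed in airspace interiors at ≥ 2 px clearance
from any wall so they are genuinely unconnected. Phase intensities
(septa/vessels 70, exudates 90, air 220) with Gaussian noise σ = 8 give
a clean bimodal histogram, as in well-stained sections. What the
phantoms do *not* emulate: staining gradients, out-of-focus blur,
touching exudates, pleural margins, and anisotropic or collapsed
parenchyma — so passing phantom tests demonstrates the correctness of
the mask-and-count machinery, not robustness to poor histology. The
wallpaper validation likewise checks counting, not segmentation (its
pipeline variant skips the color-to-mask steps by design).

## Agreement statistics

Regression of the test method on the reference (R² = squared Pearson
r); Bland–Altman on relative differences (a−b)/pairmean with the
method under test passed first, so underestimation is a negative bias,
and limits of agreement at ±1.96 SD; ICC(2,1) — two-way random
effects, absolute agreement, single measurement — computed from the
ANOVA mean squares, the conservative choice where single vs average
measures is not dictated; Welch's t with Satterthwaite df for
two-group comparisons. Degenerate inputs (constant x, zero pair means,
incomplete rating matrices, constant groups) raise explicit errors.

## Numerical choices and degenerate inputs

- Polygon membership is boundary-inclusive everywhere (shapely point
  tests), and polygon rasterization selects pixels whose centers pass
  the same test, so point counting and mask blanking can never disagree
  on a grid point.
- "1–1000 px" and "1–200 px" component bounds are inclusive; area-0
  components do not exist.
- Tissue components use 8-connectivity, air holes 4-connectivity (the
  standard complementary pairing).
- Constant images yield threshold 0 with a warning; empty ROI files are
  valid and mean "no selections".
- All generators take explicit integer seeds and are bit-reproducible;
  batch CSV outputs are byte-identical across reruns of one config.

## Problem sizes

The validation experiment uses 11 images × 20 fields (the package's
standard configuration); the convergence check uses a 4×-densified
system over 20 seeded square placements; phantom-based recovery tests
run 20 seeds. These sizes keep the full suite under a minute on one
core while leaving the stochastic acceptance margins wide.

## Known limitations

- Segmentation is threshold-based; differential staining or uneven
  illumination within a batch violates the one-threshold contract.
- Non-parenchyma and large-exudate recognition is manual by design;
  ROI files must be prepared externally.
- The inner-boundary edge convention shrinks structures by up to 1 px;
  at 0.735 µm/px this is negligible for Lm but contributes a small
  negative bias for very fine structures.
- Lm from line counting and Lm = 4A/P agree only for figures whose
  mean chord equals 4A/P under the line orientations used; circles (and
  generally non-axis-aligned convex figures sampled with axis-aligned
  lines) differ systematically.
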