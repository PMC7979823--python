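# Methods

This note documents the models, parameter choices and numerical decisions
behind `melchist`, what the synthetic generator does and does not emulate,
and the known limits of the approach.

## Acquisition model and data layout

A MELC run is an ordered set of (cycle, channel) acquisitions on one tissue
section: per acquisition a fluorescence z-stack (2·z_steps + 1 planes,
1 µm step) and a matching post-bleach z-stack, plus one phase-contrast
reference image for the whole run and a pre-run blank bleach acquisition.
Pixels are 16-bit unsigned on disk and floats in [0, 1] internally;
coordinates are 0-based (row, col) with physical position = index ×
pixel pitch (default 0.325 µm/px, the sample-plane pixel of a 20×/0.8 NA
objective with a 6.5 µm camera pixel and no binning). Each acquisition
carries exactly one marker; (cycle, channel) pairs are unique within the
panel. The background for the first acquisition in a channel is the run
blank — a run without one is rejected rather than silently skipping
subtraction.

## Pre-processing

**Registration.** Integer-pixel normalized cross-correlation of each
cycle's summed central z-planes against the reference, searched over
|Δ| ≤ max_shift_px (default 50, automatically capped by the geometry's
maximum autofocus shift and min(shape)/4). Ties resolve to the smallest
|Δr| + |Δc|, then lexicographically — relevant only for pathological
periodic content, but it makes the operation a function. Sub-pixel
registration is deliberately out of scope: the instrument's autofocus
corrects displacement before acquisition, leaving integer-scale jitter.

**Stage order** is register → bleach-subtract → illumination-correct →
EDF-project → rolling-ball/stretch. Subtraction happens between
like-registered, like-illuminated images; the shading field divides the
*difference*, which is equivalent to correcting both terms since the field
multiplies everything the camera sees. EDF runs after correction so plane
selection responds to sharpness, not shading.

**Illumination field.** The same cycle's bleach stack (averaged over z for
√n noise reduction, lightly denoised with σ = 1.5 px) is tiled into a
16 × 16 block grid; per-block minimum intensities approximate the
stain-free background, which carries the shading field. The 16 × 16 min
grid is median-filtered (3 × 3) to reject blocks fully covered by residual
signal, and a smoothing bivariate cubic spline through the block-center /
minimum pairs is evaluated per pixel (constant extension beyond the
outermost centers — unconstrained cubic extrapolation oscillates at the
corners). The surface is normalized to unit spatial mean and clipped below
at 0.05. Small smoothing is preferred for the minima themselves: the
minimum of a noisy block sits a few noise SDs below the true background,
but that bias is *uniform* and cancels in the mean normalization, whereas
heavy pre-smoothing lets structured signal leak into the minima
non-uniformly. Degenerate inputs (near-zero bleach mean, fits that need
heavy floor-clipping) yield the flat field 1 — no information, no
correction. An edge band equal to the registration shift is excluded from
the block grid, since zero-filled frame edges would drag the surface down.
Accuracy on the default synthetic field (Gaussian bump, amplitude 0.25):
< 1 % noiseless, a few percent at the default noise level.

**Extended depth of field** selects, per pixel, the plane maximizing local
intensity variance in a 9 × 9 window; the selection-index map is median
filtered with the same window; ties go to the lowest z. This is the
classical variance-of-Laplacian family of focus measures reduced to its
simplest robust member — adequate because the synthetic defocus model is
Gaussian blur growing linearly in |z|.

**Rolling-ball normalization.** Background via `skimage`'s rolling ball
with two ImageJ conventions restored: intensities are rescaled to
8-bit-like counts before rolling (the ball lives in (x, y, intensity)
space; on [0, 1] floats it would sink into every structure), and for radii
≥ 16 px the image is shrunk 2× first and the background expanded back.
Default radius 50 px. After subtraction, a margin equal to the maximum
observed shift is cropped (those edges are zero-filled, not observed), and
the (0, 100) percentile range is mapped linearly onto [0, 65535]. All
stage outputs are clamped nonnegative; the model never propagates negative
intensities.

## Pixel classification

Three classes — nuclei, membrane, ECM — where ECM is the residual class
("neither nucleus nor membrane"), so the three probabilities are exhaustive
and sum to 1. Features: per input image (DAPI and the sum-of-membranes
composite) and per scale σ ∈ {0.7, 1.0, 1.6, 3.5, 5.0}: Gaussian
smoothing, gradient magnitude, Laplacian of Gaussian, and both
structure-tensor eigenvalues — 50 features, an Ilastik-like default.
Boundary mode is `nearest` everywhere (constant-padding would fabricate
edges at the frame). The forest has 100 trees, a fixed seed, class-balanced
subsampling of labeled pixels (at most 20 000 per class), and records its
out-of-bag accuracy. The feature recipe is frozen inside the model;
prediction on a permuted feature stack with a matching recipe reorders
columns and yields identical output. For synthetic data, training labels
are auto-scribbled: a random window covering 6 % of the image is fully
labeled with ground-truth classes eroded by 1 px (off the ambiguous
boundaries), emulating the sparse manual scribbles of an interactive
workflow while leaving the remaining 94 % as held-out evaluation data.

## Segmentation

Nuclei: threshold the nuclei probability map at 0.5 (the probability scale
is calibrated by construction, so Otsu adds nothing), split touching
objects by distance-transform watershed seeded at local distance maxima
(minimum peak separation derived from the size floor), drop objects
outside [40, 5000] px, relabel sequentially. 4-connectivity throughout.

Cells: seeded watershed on the membrane probability landscape growing each
nucleus outward, constrained to pixels within 12 px (≈ 3.9 µm) of *any*
nucleus, then trimmed per cell to within 12 px of its *own* nucleus. The
trim matters: the union-of-disks mask is connected between neighboring
cells, and without it the seed with the weakest membrane ridge floods the
background corridors. The result guarantees the bijection cell i ⊇
nucleus i, one cell per nucleus, mutually exclusive cells — the object
model of a cell as a nucleus plus surrounding membrane.

Quality is measured object-wise: greedy IoU matching (descending IoU,
each object used once, match iff IoU ≥ 0.5) and precision/recall/F1.

## Quantification and gating

MFI is the mean of the corrected, [0, 1]-scaled marker image over the cell
mask — except nuclear-localized markers, which are measured over the
nucleus mask. Default thresholds are per-marker Otsu on the per-cell MFI
distribution (256 bins), clipped to [0.05, 0.95]; constant markers get 0.5
with a warning; manual overrides replace defaults verbatim and are
recorded as such. Note that on a cleanly bimodal distribution the discrete
Otsu argmax sits at the low edge of the empty inter-mode gap — any value
in the gap separates the populations identically. Binarization is
threshold-inclusive (MFI ≥ t ⇒ positive) for determinism at the boundary.

Gating rules are declarative (YAML): required-positive, required-negative,
and disjunctive `any_of` clauses whose terms carry explicit signs
("CD56-", "CD16+") to express conjunctions like CD56⁻CD16⁺ inside a
disjunction. Rules evaluate in ascending priority; the first satisfied
rule wins; unmatched cells are "others". The shipped tonsil set orders
B < T helper < cytotoxic T < plasma < myeloid < endothelial < ILC, with
the ILC rule depending only on its own inclusion/exclusion markers so its
assignment is insensitive to the precedence of the others.

## Spatial analysis

A niche is the set of pixels within 10 µm (Euclidean, = 31 px at
0.325 µm/px) of the seed cell's *mask* — "pixels expanded from the seed
object", not a centroid disk. Membership defaults to
centroid-in-region (inclusive boundary; neighbors' masks can be arbitrary,
centroids are always defined); any-overlap is available. The seed never
counts in its own composition. Enrichment compares pooled niche
composition against whole-tissue frequencies computed *excluding the
seeds*, so both vectors answer "what surrounds a seed" vs "what is
anywhere else"; with an abundant seed type this exclusion makes the seed
type's own enrichment ill-defined, which is why the null-calibration test
uses a rare seed population. Structure proximity is the minimum Euclidean
distance from the cell mask to a structure mask via distance transform;
vessel masks come from thresholded CD31, fiber masks from binarized
structure-marker images.

Compartments: per compartment, binarized defining-marker images are summed
and Gaussian-smoothed (σ = 20 µm); pixels take the argmax score above a
floor of 0.1, else stay unassigned; the band within 10 µm outside the
follicle becomes `follicle_border`. Cells inherit the compartment of
their centroid pixel; unassigned cells are excluded from distribution
denominators.

## Phenotype clustering

MFIs are transformed with the cytometry cofactor convention
`asinh(x / 0.2)` — strictly monotone, rank-preserving per marker. (The
alternative reading `asinh(0.2·x)` is equally monotone and only changes
effective dynamic range; the cofactor convention is the field standard and
the scale is configurable.) An optional 0.1-MFI cut-off drops cells that
express no marker (the colon-mode default). PCA is centered but not
variance-scaled (the arcsinh already compresses scale); the component
count is 52 (tonsil) or 48 (colon), capped at the available
dimensionality. t-SNE runs at perplexity 30 for 1000 iterations with a
fixed seed and PCA initialization, making embeddings bit-reproducible.
Clusters come from k-means on the embedding with k chosen by silhouette
over 2–12 — a reproducible stand-in for manual polygon selection on the
map; small fields of view shrink the perplexity to (n−1)/3.5 instead of
failing. The heat-map is per-cluster mean MFI with each marker rescaled to
[0, 1] across clusters (constant markers map to 0 by convention), and
cluster-vs-gate agreement is the fraction of a focus cluster carrying a
focus gated type, alongside the full confusion table.

## Synthetic data: what it emulates, and what it does not

The generator renders non-overlapping round cells (nucleus disk r = 3 µm,
cell disk r = 5 µm, 3 px membrane annulus) on a jittered grid
(deterministic feasibility; an infeasible request fails loudly), assigns
types by largest-remainder rounding of the configured frequencies with a
guaranteed minimum of 2 ILCs, and renders per acquisition:

    I_z = field × shift( blur_z( scene + residual·scene_prev + autofluo ) ) + noise

with the matching bleach stack `field × shift(blur_z(residual·scene +
autofluo)) + noise`. Illumination is a Gaussian-bump multiplicative field
(amplitude 0.25) fixed to the camera; shifts are integer per cycle (≤ 8 px
by default); defocus is Gaussian blur growing 1 px σ per z-step; noise is
additive Gaussian (sd 0.05 default) clipped at zero. Autofluorescence
(0.12, with cell bodies at twice the background level) is deliberately
well above the noise floor — as in real tissue — because the min-based
illumination estimator needs a nonzero background to read the field from.
Structure markers render as sinusoidal fiber curves; the phase-contrast
reference shows cell bodies, nuclei and fibers, which is what makes
fluorescence-to-reference registration well-posed for structure-only
cycles. Expression is exactly the type mean (no per-cell variation), so
noiseless recovery is exact by construction.

Deliberately not modeled: photobleaching kinetics, PSF-accurate optics,
sub-pixel drift, 3D tissue, cell-shape variability, spatially organized
tissue architecture (cells are placed uniformly, so compartments on the
default scene are patchy and compartment logic is validated on constructed
geometry instead), and marker spillover. Passing tests therefore
demonstrate the correctness of the *algorithms* under controlled
corruption, not performance on real tissue — real data adds morphology,
texture and staining variability that the default random forest and fixed
thresholds may not absorb without retraining and threshold review.

## Problem sizes and determinism

The default study scene is 512 × 512 px (166 µm side) with 150 cells, a
12-marker panel over 6 cycles and ±2 z-steps; unit tests use 128–256 px
variants with 9–36 cells. These sizes keep the full pipeline at seconds
per run while leaving every stage's statistics meaningful (the rare ILC
population is held at ≥ 2 cells by construction). All randomness flows
from explicit seeds; the pipeline fans a single global seed out to stages
via SHA-256 of `"{seed}:{stage}"`, recorded in `provenance.json` together
with parameter hashes and the shift log, and a re-run with the same
configuration reproduces `cells.csv` byte-identically.

## Known limitations

- The illumination estimator assumes a smooth, slowly varying field and a
  nonzero stain-free background; vignetting sharper than the block grid or
  a fully stained field defeats it (it then degrades to no correction).
- Watershed cells are capped at 12 px beyond the nucleus; genuinely large
  or elongated cells are truncated.
- The gating rule set matches the shipped 12-marker panel; richer panels
  (CD20, CD123, CD141, FcεRIα, CD11c, CD56/CD16) need their rules added to
  the YAML, for which the clause syntax already suffices.
- Niche and compartment analysis is strictly 2D.
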