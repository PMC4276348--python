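# Methods

## Scope and data model

`ctstroke` operates on single axial non-contrast CT slices. Attenuation is
kept in Hounsfield units (HU) end to end; perceptual processing happens on
a display scale obtained with a linear brain window (default center 35 HU,
width 80 HU, configurable). DICOM input is rescaled to HU via the
slope/intercept tags; 8-bit PNG input is treated as already display-scaled
pseudo-HU so file-based tests need no DICOM machinery. The default pixel
spacing is 0.2 mm (0.04 mm² per pixel), matching 512×512 head acquisitions.

The windowing step is a necessary bridge: the tone curve, the
just-noticeable-difference threshold and the histogram machinery are all
defined on [0, 255], while the stroke window (30–36 HU) and the
darkest-fraction rule are defined on calibrated HU. Highlighting therefore
always consults the original HU image, never the enhanced one.

## Contrast enhancement

A single cubic `y = a x³ + b x² + c x` is fitted per slice. The four
constraints `f(0)=0`, `f(255)=255`, `f′(A)=0`, `f″(A)=0` admit the closed
form `a = 1/(255² − 3·255·A + 3A²)`, `b = −3aA`, `c = 1 − a·255² − b·255`;
the denominator of `a` has negative discriminant, so `a > 0` for every
real `A` and `f′(x) = 3a(x−A)² ≥ 0`: the map is monotone and cannot
reorder tissues. `A = min + 0.7·(max − min)` places the flat part of the S
in the bright tissue band; the 0.7 factor is exposed as a parameter but is
part of the method's definition. Enhanced intensities are kept real-valued
until final rendering so that later brightness comparisons are not
quantisation artifacts.

A brain-windowed head slice typically spans the full [0, 255] range (air
to clipped bone), giving `A = 178.5`: the curve then *brightens* tissue
(white ≈ 96 → 213, gray ≈ 143 → 235) and compresses contrast near the top
of the scale. Two consequences shaped the pipeline:

* **Brain extraction runs on the windowed image, not the enhanced one.**
  The compression narrows the gray/bone gap so much that a three-class
  Otsu split on the enhanced image classifies gray matter as bone and the
  mask collapses to the white core. On the plain windowed image the three
  populations (air, tissue, clipped bone) are cleanly separated. The
  enhanced variant remains available (`PipelineConfig.extract_on`).
* Later thresholds stated in HU (the CSF seeding ceiling) are mapped
  through the window *and* the fitted curve before use.

## Brain extraction

The slice holds three intensity populations — air, tissue, bone — so the
"Otsu threshold" is implemented as a three-class Otsu
(`skimage.filters.threshold_multiotsu`): the lower cut drops air, the
upper cut drops the skull ring. A disk erosion (radius 3) detaches thin
bridges, the largest 4-connected component is kept, dilated back (radius
3), clipped against the bone class, and hole-filled so interior CSF and
hypodense structures stay inside the mask. The radii suit a 1–3 px
residual rim on 256–512 px slices and are configurable. Selecting the
largest component is plumbing needed to discard head-holder artifacts.

The anisotropic smoother implements
`I′(x,y) = Σ I(x+i, y+j) G(x+i, y+j) / Σ G(x+i, y+j)` over the 3×3
neighbourhood with `G = exp(−(Gx²+Gy²)/(2k²))` from central-difference
gradients; `k` defaults to the image's mean gradient magnitude. Borders
use shrinking windows. Region statistics are taken on the smoothed
enhanced image; smoothing runs after thresholding, before morphology, in
the narrative order of the pipeline.

## Unsupervised region growing (URGA)

Seeds are intensities, not locations: a Canny edge map (hysteresis
thresholds default to Otsu-of-gradient-magnitude for `high` and
`0.4·high` for `low`; the Gaussian pre-smoothing step is Canny's
own first stage, so it is not applied separately) marks boundaries; the histogram of intensities within
Chebyshev radius 2 of any edge samples every tissue class; a width-3 mean
filter denoises it; a bin is a peak iff the smoothed histogram rises
strictly for four consecutive steps into it and falls strictly for four
steps out (a single flat step disqualifies — the strict reading of the
sign condition). Peaks below the CSF ceiling (15 HU, carried through
window + curve) are never seeded.

Growing admits a 4-connected neighbour iff its intensity is within
`tolerance` (default 4, the just-noticeable difference) of the *seed bin
value*. This frozen-mean rule is order-invariant, so the grown set is
exactly the connected components of the admissible set containing a seed
pixel — testable against a brute-force search. A running-mean variant is
available but order-dependent. The peak/grow cycle repeats on
still-unlabeled pixels (the edge map itself is fixed, so it is computed
once); iteration is capped at 10 rounds. Unlabeled leftovers are attached
to the region with the nearest mean intensity, ties toward the lower
label; if no peak is ever found the whole mask becomes one region and a
warning is emitted. Peaks are grown most-prominent-first, ties toward the
darker bin, purely for determinism.

The strict 4-step flank condition needs populated histogram shoulders:
on near-noiseless synthetic data the histogram collapses to 1–2 bins per
tissue, no bin qualifies, and the single-region fallback triggers. This
is the documented behaviour, not an error; realistic noise levels
(≥ ~1 HU) produce the intended per-tissue peaks.

## Eight-region partition

The mask's tight bounding rectangle (row/column projection) defines the
brain center; `row ≥ center_row` / `col ≥ center_col` (half-open, for a
disjoint exhaustive split) give quadrants; a concentric ellipse with both
semi-axes at 2/3 of the rectangle's half-dimensions (boundary counts as
inner) splits deep from peripheral tissue. Scaling only the minor axis is
available as a config option. Left/right are image coordinates.
Mirror symmetry of the partition is exact whenever the rectangle center
falls between pixel columns; when a pixel column sits exactly on the
center, the half-open rule assigns it to the right side on both the image
and its mirror — an unavoidable one-column asymmetry of any deterministic
tie rule.

## Lateralization

For each position pair (upper/lower × inner/outer) the side with the lower
mean brightness is selected (ties to the left). The 4-0 / 3-1 / 2-2 split
of selections maps to cases 1–3:

* **Case 1**: unanimous side wins.
* **Case 2**: if the minority region's cross-side difference is below the
  threshold δ = 4 display units it is merged into the majority; at or
  above δ it is flagged "dissimilar" in the trace. Either way the majority
  side is reported, so the procedure always terminates in one side.
* **Case 3**: when the two same-side duos group by half or by zone, the
  duo with the smaller mean cross-side difference merges into the other
  duo's side. For a diagonal split, the left-vs-right mean difference is
  computed within the upper and within the lower half and the darker side
  of the half with the larger difference wins. Both readings converge in
  one step; the full comparison sequence is recorded in the trace rather
  than asserted as the only possible interpretation of the procedure.

Exactly one hemisphere is always returned; bilateral stroke (clinically
under 20% of cases) is out of scope. Empty regions (possible on extreme
masks) are flagged, and their pair's selection defaults to the non-empty
side. The result is translation-invariant and mirror-antisymmetric for
non-tied inputs.

## Highlighting

Candidates must lie on the suspected side, have HU in [30, 36] (inclusive)
and fall at or below the darkest-30% cut of brain-tissue HU — the lower
empirical quantile, `sorted[ceil(0.3 n) − 1]`, computed over the whole
brain by default (suspected-side-only is a config option). The "darkest
fraction" reading of the 30% rule is deliberate: infarcts are hypodense,
and an anterior-spatial reading would be inconsistent with the
surrounding attenuation logic. Marked 4-connected components smaller than
500 px (20 mm² at 0.2 mm/px) are discarded: the floor must sit *below*
the smallest lesions of interest (25 mm² = 625 px) because pixel noise
removes ~9% of a lesion's pixels from the HU window (at noise sd 1.5 HU a
32 HU lesion loses the tail below 30 HU), while remaining far above any
noise speckle, which arrives as isolated pixels. Setting the floor at the
lesion size itself would erase exactly the smallest true lesions. The
overlay replicates the grayscale windowed image into RGB and sets marked
pixels to pure red; all other pixels are bit-identical to the input.

## Metrics

Specificity TNN/(TNN+FPN), precision TPN/(TPN+FPN), sensitivity (DR)
TPN/(TPN+FNN) and accuracy (CR) (TPN+TNN)/total are standard. The
false-alarm rate is FPN/(FPN+TNN) = 1 − specificity; the alternative
denominator (TNN+FNN) that sometimes appears in print is inconsistent
with specificity-complement reporting and is only available behind
`far_denominator="tnn_fnn"`. Zero denominators flag the metric as
undefined (`None`) instead of raising.

Consistency errors follow Martin's refinement framework: directional error
`E(A,B,p) = |R(A,p) \ R(B,p)|/|R(A,p)|`, LCE = mean of the per-pixel
minimum, GCE = minimum of the two directional means (so LCE ≤ GCE ≤ 1,
and GCE of a strict refinement is 0). The object-level consistency error
weights Jaccard overlaps of intersecting objects by their area share and
each reference object by its area fraction, taking the better direction;
it penalises over- and under-segmentation that GCE forgives. All three are
computed from the region contingency table, which makes them exact and
fast.

## Phantom

The phantom is a stylised axial slice in HU: elliptical skull ring
(1000 HU) around a brain ellipse (semi-axes 0.40/0.34 of the image side),
peripheral gray mantle (40 HU) over a white core (25 HU) at half the brain
semi-axes, small paired ventricles (8 HU), optional circular lesion
(default 32 HU, 27.5 mm²), additive Gaussian noise (sd 1.5 HU), air at
−1000 HU. The lesion is an exact-pixel-count disk (`round(area/spacing²)`
closest grid points) centered on the horizontal midline at the gray-white
interface and nudged outward so ~90% of it lies in gray matter — ischemic
infarcts favor gray matter, and the midline placement reflects the
clinical observation that infarcts typically span two of the eight
partition regions. Generation is deterministic per seed.

The white-core proportion (a quarter of the brain area) was chosen so the
sub-30-HU tissue (white + CSF, ~27% of the brain with the lesion) stays
below the 30% darkest-fraction cut, as in real slices where the infarct
falls inside the darkest tissue tercile; the cut then lands in the lower
tail of gray matter (≈ 37 HU), above the stroke window. What the phantom
does *not* model: gyral/sulcal texture, partial-volume blur at tissue
interfaces, beam hardening and streak artifacts, anatomical asymmetry,
old infarcts. Passing the phantom recovery tests therefore demonstrates
the pipeline's mechanics (windowing, masking, partitioning, the decision
rules, the HU logic) under controlled conditions — not clinical
sensitivity on patient images, where old lesions and structural asymmetry
are the documented failure modes of this class of methods.

## Problem sizes and determinism

Tests and the acceptance script use 256×256 phantoms at 0.2 mm spacing
(the generator default is 512, matching clinical acquisitions): lesion
*pixel* areas are identical at both sizes since areas are specified in
mm², and every stage is resolution-independent. The acceptance batch is
50 phantoms with lesion 32 HU, areas uniform in 25–30 mm², noise sd
1.5 HU, sides drawn fairly — the study conditions. The pipeline contains
no randomness of its own: all stochasticity lives in the phantom seed, and
reports are byte-identical across reruns.

## Known limitations

* Single-slice only; no volume aggregation, no hemorrhage (hyperdense)
  detection, no bilateral output.
* The lateralization threshold δ = 4 and the growing tolerance 4 are
  display-scale constants; rescaling the window changes their meaning.
* The strict peak condition can find no seeds on extremely clean or
  extremely quantised images (single-region fallback, with a warning).
* The 30% darkest-fraction rule assumes the infarct lies within the
  darkest tercile of brain attenuation; slices dominated by white matter
  and CSF can push the cut below the stroke window.
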