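# Methods

This note documents the models, conventions and parameter choices behind
`annosim`, and what its synthetic experiments do and do not demonstrate.

## Geometry and data model

Volumes and instance masks are 3D grids in stored order with per-axis
spacing in mm; no anatomical reorientation is performed. A configuration tag
names which stored axis is the *slicing axis* (sagittal for the bone task,
axial for the tumor task), and all per-slice work happens in the plane
orthogonal to it. Physical coordinates follow the voxel-center convention:
voxel `i` along an axis with spacing `s` is centered at `(i + 0.5)·s` mm.
This makes mm-valued jitter caps, distance transforms and the 1 mm
correction rule unambiguous. Instance labels are a single integer per voxel,
so overlapping instances are not representable; the phantom generator keeps
a one-voxel gap between instances.

## Preprocessing

CT intensities are windowed to [−55, 155] Hounsfield units and mapped
affinely onto [0, 255]; MR intensities are clipped at the volume-wide
1st/99th percentiles (linear interpolation between order statistics — the
single percentile convention used repo-wide) and mapped onto [0, 255].
Outputs stay floating point so metric computations are unaffected by
quantization; a constant MR volume maps to all zeros with a warning rather
than aborting batch runs. Ground-truth cleaning keeps only the largest 3D
connected component of a label under 26-connectivity (the most inclusive
choice, avoiding splits of thin diagonal structures); exact ties are broken
deterministically toward the component containing the smallest linear voxel
index. ROI cropping takes the axis-aligned bounding cuboid of a supplied
region mask plus a physical margin and returns offsets for mapping results
back.

## Metrics

DSC is plain voxel counting. NSD at tolerance τ (default 1 mm) counts
boundary elements of each mask within τ of the other mask's boundary,
divided by the total boundary size. Boundary elements are foreground voxels
with a background face-neighbor (4-connectivity in 2D, 6 in 3D; the image
border counts as background), and distances are Euclidean between voxel
centers under the anisotropic spacing. The tolerance comparison is
inclusive, so a one-voxel shift at exactly 1 mm spacing still scores a hit.
Empty-mask conventions, applied identically to both metrics: both masks
empty → 1.0 (predicting "no object" on an empty slice is a success), exactly
one empty → 0.0. The production implementation uses distance transforms; an
independent all-pairs implementation (`nsd_bruteforce`) is kept as a
cross-checking oracle and the tests require exact agreement between the two
routes.

## Prompts

The center slice of an object is the (unweighted) center of mass of its 3D
mask projected on the slicing axis, rounded to the nearest slice; if that
slice carries no foreground (concave objects), the nearest nonempty slice is
used. Jitter draws are uniform on the capped intervals — "up to ±x mm" is
read as a uniform distribution, the maximum-entropy choice given no stated
distribution:

- dot: per-axis shift within ±min(2 mm, 10 % of the larger in-plane extent),
  resampled (≤100 attempts) until the rasterized dot lands on foreground,
  then falling back to the centroid voxel or nearest foreground voxel;
- box: starting from the tight mm bounding box, width and height are
  independently changed within ±min(2 mm, 5 % of that dimension), applied
  symmetrically about the center so that scaling and shifting stay
  independent, then the box is translated per-axis within ±min(1 mm, 5 % of
  that dimension). Single-voxel-extent boxes are returned unjittered.

The percentage caps are read per-dimension for boxes (width cap from width,
height cap from height) and from the maximum extent for dots. The dot shift
cap is interpreted per-axis rather than as a Euclidean-norm bound.

## Surrogate segmenter

The surrogate implements the promptable-segmenter contract (reset, box/dot
prompt, mask re-prompt, per-slice predict) by deforming the true mask of the
prompted object. The deformation is a smooth radial boundary displacement: a
low-frequency field `d(θ) = Σ_{k=1..3} a_k cos kθ + b_k sin kθ` in polar
angle around the instance centroid, with coefficients drawn so that the
displacement's standard deviation equals an error scale σ, applied to the
signed Euclidean distance function of the slice. This produces connected,
plausibly-shaped wrong masks (rather than voxel noise), which keeps the
XOR-region correction operator meaningful. The error scale is

    σ = (base_boundary_sd_mm + drift_per_slice_mm · |i − j|)
        · dot_penalty^[dot prompt] · contrast_coupling^[low contrast]

for a query at slice `i` after a prompt at slice `j`. Low contrast means the
estimated foreground/background intensity gap of the bound volume, relative
to its intensity range, falls below 0.5. With probability `leak_prob` a
disjoint spurious blob (radius 2–4 mm) is added at least 5 mm from the true
object — guaranteed to qualify for correction under the 1 mm rule, giving
tests a correctable error class. All error scales at zero makes the
surrogate an exact oracle (predictions equal ground truth bit-for-bit),
which anchors several tests.

Randomness is keyed on (quality seed, volume index, label, prompt slice,
queried slice) only. Consequences: predictions are pure and reproducible;
state after a reset depends only on post-reset prompts; and the prompt kind
changes the error *amplitude* but not the underlying random field, so the
dot-vs-box comparison is exactly paired (dot penalty 1 gives identical
arms). The dataset stream and the segmenter stream are separate, so
generation and simulation are reproducible independently.

Default quality (base 2.0 mm, drift 0.5 mm/slice, contrast coupling 1.4,
leak probability 0.03, dot penalty 3) was chosen once so that on the default
tumor phantoms the correction-workload curve spans the 0–60 % calibration
targets with the calibrated thresholds falling well inside the standard DSC
sweep range (τ_low/τ_mod/τ_high ≈ 0.62/0.74/0.82), mirroring the interior
placement seen in real liver-tumor annotation studies. The dot penalty makes
the box-beats-dot finding reproducible as a property; it is a free surrogate
parameter, not an empirical claim about any particular model.

## Phantoms

Phantoms are superellipsoids (`Σ |x_a/r_a|^p ≤ 1`, p drawn in [2, 3], per-axis
radii wobbled ±15 %) on anisotropic grids, so every instance is convex,
simply connected per slice, and spans multiple slices. Defaults:

- tumor task: 32×128×128 grid at 1.5×0.8×0.8 mm (thick axial slices), 1–6
  instances per volume with radii 5–13 mm, contrast 0.35 (low, so the
  contrast coupling engages, as for subtle lesions), noise SD 0.05. Thirty
  volumes yield ≥1,000 instance slices, the scale used for calibration
  experiments.
- bone task: 160×96×96 grid at 1.0×0.5×0.5 mm (thin sagittal slices), one
  object with radius 12–15 mm stretched 4× along the slicing axis (spanning
  ~100+ slices), contrast 0.8, noise SD 0.02.

Intensities are two-level (background/foreground separated by `contrast` on
a nominal [0, 1] scale) plus Gaussian noise. Object placement is rejection
sampling with a one-voxel dilated overlap check and 200 attempts per object;
infeasible configurations raise instead of degrading silently.

## Simulated workflow

Per object: jittered box on the center slice; propagation outward one
direction at a time as one segmenter session per direction, with the same
center box prompt repeated for the second direction. Every visited slice
(the center included — nothing exempts it) is scored against its 2D ground
truth and accepted iff DSC ≥ τ_DSC and NSD ≥ τ_NSD. The comparison is
inclusive so that τ = (0, 0) accepts every slice, which is what the no-edits
scenario means. On rejection the human-like correction edits only XOR
regions (8-connected, so diagonal error filaments count as one user edit)
containing a voxel strictly more than 1 mm from the true boundary; the
segmenter is then reset and re-prompted with the corrected mask on that
slice, rebasing the drift anchor, and propagation continues. Only slices
inside the object's longitudinal extent (first to last nonempty ground-truth
slice — the extent a user is assumed to indicate) are visited; interior
empty slices are scored under the empty-mask conventions but not counted as
instance slices. Assisted masks are merged per volume with first-written
labels winning on (logged) overlap conflicts.

## Calibration

For each metric the thresholds are swept over a fixed grid (defaults mirror
standard practice: DSC 0.90–0.995 and NSD 0.70–0.99 for the bone task, DSC
0.30–0.95 and NSD 0.10–0.90 for the tumor task, 20 evenly spaced points)
with the other threshold at zero and the same RNG seed at every grid point,
so the curve reflects threshold changes only. Because sampling noise can
make the raw curve locally non-monotone, a non-decreasing isotonic
(pool-adjacent-violators) adjustment is applied before inversion; linear
interpolation of the adjusted curve at the target correction rate (0.2, 0.4,
0.6) yields the scenario thresholds, with out-of-range targets clamped to
the grid ends (logged) and plateaus resolved to the smallest threshold
(least user workload at equal quality). DSC and NSD are calibrated
marginally but applied jointly; joint AND-acceptance can only flag more
slices than either threshold alone.

## Statistics

Summaries are median and IQR (25th/75th percentiles, linear interpolation).
Paired comparisons use the two-sided Wilcoxon signed-rank test with zero
differences dropped, the exact null distribution for ≤25 nonzero untied
pairs and a tie-corrected normal approximation with continuity correction
otherwise; the all-zero case reports p = 1.0 with a warning. Families of
p-values use the Holm step-down correction.

## Problem sizes and determinism

The bundled experiments run on a single CPU core: the calibration closed
loop uses 30 tumor phantoms (~1,100 instance slices, a 20-point sweep,
roughly two minutes); metric-oracle equivalence uses 10⁴ random 8×8 mask
pairs; jitter bounds use 10⁴ draws; the prompt-mode experiment uses 100
objects. Every random quantity flows from explicit integer seeds, and
identical seeds give bit-identical datasets, simulations and reports.

## What the synthetic experiments do and do not show

The phantoms and surrogate reproduce the *structure* of the workflow — error
growth away from prompts, contrast dependence, correctable leak errors,
threshold-controlled workload — so they validate the pipeline's logic,
accounting and calibration behavior. They do not emulate real anatomy,
scanner artifacts, inter-rater ambiguity, or the actual error profile of any
specific promptable segmenter; absolute calibrated threshold values on
phantoms therefore transfer to real data only qualitatively. Downstream
model training on assisted labels is out of scope: the package writes
assisted-label NIfTI volumes consumable by external trainers. The real-model
adapter is an extension point defined by the `PromptableSegmenter` contract;
within-slice prompt geometry (box coordinates) does not influence the
surrogate's error model, only the prompt kind and slice do.
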