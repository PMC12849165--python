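# annosim

Simulation of promptable-segmenter-assisted annotation of 3D medical images,
with calibration of per-slice acceptance thresholds to target manual
correction workloads.

## The problem

Segmenting structures such as the femoral bone in knee MRI or liver tumors
in contrast CT slice-by-slice is one of the most expensive steps in building
medical segmentation datasets. Promptable video segmenters (SAM 2-style
models) can propagate a single prompted slice mask through a 3D volume, so a
human annotator only needs to place one bounding box, review each predicted
slice, and fix the bad ones. How much review effort is really needed before
the resulting labels are good enough to train downstream models? `annosim`
simulates exactly this interactive workflow, using ground-truth masks as the
stand-in for the reviewing human:

1. **Prompting.** For each object instance the center slice is found from the
   center of mass of its 3D mask. A bounding box (or centroid dot) is derived
   from the 2D mask and jittered to mimic user imprecision: box width/height
   scaled by up to ±2 mm (≤5 % of the dimension) and shifted by up to ±1 mm
   (≤5 %); dots shifted by up to ±2 mm (≤10 % of the maximum extent) while
   staying inside the object.
2. **Propagation and review.** The segmenter predicts each slice outward from
   the center within the object's longitudinal extent. A predicted slice is
   accepted only if both its Dice similarity coefficient (DSC) and its
   normalized surface dice at 1 mm tolerance (NSD) reach the scenario
   thresholds `τ = (τ_DSC, τ_NSD)`.
3. **Human-like correction.** Rejected slices are not replaced wholesale:
   the prediction/ground-truth disagreement (XOR) is grouped into connected
   regions, and a region is reset to ground truth only if some voxel of it
   lies more than 1 mm from the true boundary — large errors get fixed, minor
   boundary quibbles are tolerated. The corrected mask re-prompts the
   segmenter (after a state reset) and propagation continues.
4. **Calibration.** Sweeping candidate thresholds for one metric (the other
   fixed at zero) yields a monotone curve of correction workload vs
   threshold; linear interpolation of that curve gives the thresholds at
   which roughly 0 %, 20 %, 40 % or 60 % of instance slices need manual
   correction (the no-edits / low / moderate / high interaction scenarios).

Everything runs on synthetic phantoms (elongated bone-like objects or
multiple blob-like low-contrast tumors, anisotropic spacing) with a
**surrogate segmenter** whose boundary error grows with slice distance from
the last prompt and shrinks with image contrast — so the entire pipeline is
testable end-to-end without model weights, GPUs or dataset downloads. A real
SAM 2 adapter can be plugged in through the `PromptableSegmenter` contract.

## Core quantities

For binary masks A (prediction) and B (reference):

- `DSC(A, B) = 2|A∩B| / (|A| + |B|)`
- `NSD_τ(A, B) = (|{a ∈ ∂A : d(a, ∂B) ≤ τ}| + |{b ∈ ∂B : d(b, ∂A) ≤ τ}|) / (|∂A| + |∂B|)`
  with boundaries ∂ taken as foreground voxels with a background
  face-neighbor and distances Euclidean in mm (τ = 1 mm by default).

The unit of workload is the *instance slice*: one 2D slice of one object
instance with nonempty ground truth (two tumors on one slice count twice).
A scenario's workload is the proportion of instance slices accepted without
any edit.

## Worked example

```python
import numpy as np
from annosim import (PhantomConfig, ScenarioSpec, SurrogateQuality,
                     default_grid, generate_phantom_dataset, interpolate_tau,
                     simulate_dataset, surrogate_factory, sweep_thresholds)

dataset = generate_phantom_dataset(PhantomConfig.tumor_default(n_volumes=30, seed=1))
segment = surrogate_factory(SurrogateQuality(seed=2))

# no-edits scenario: everything is accepted by definition
summary, assisted, records = simulate_dataset(
    dataset, segment, ScenarioSpec.no_edits(), rng=3)
print(summary.total_instance_slices, summary.proportion_accepted)
# 1089 1.0

# calibrate the low-interaction DSC threshold (NSD fixed at 0) and re-run
curve = sweep_thresholds(dataset, segment, "dsc",
                         default_grid("tumor", "dsc"), seed=3)
tau_low = interpolate_tau(curve, 0.20)
summary, _, _ = simulate_dataset(dataset, segment,
                                 ScenarioSpec("low", tau_low, 0.0),
                                 rng=np.random.default_rng(3))
print(round(tau_low, 3), round(summary.proportion_corrected, 3))
# 0.611 0.197
```

The first run reports 1,089 tumor instance slices, all accepted (the
no-edits scenario accepts everything). Calibration then finds the DSC
threshold (≈0.61 for this surrogate quality) at which close to 20 % of
instance slices are flagged for correction; re-simulating at that threshold
lands at 19.7 %, confirming the closed loop.

The same pipeline is scriptable from the shell via the `annosim` CLI
(`generate`, `preprocess`, `score`, `compare-prompts`, `simulate`,
`calibrate`, `report`); run `annosim --help`.

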