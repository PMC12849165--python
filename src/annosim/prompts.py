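"""Center-slice selection and imprecision-simulating prompt generators.

A simulated annotator prompts the segmenter on each object's center slice
with either a dot near the 2D centroid or a bounding box around the 2D mask.
To mimic realistic user imprecision the prompts are jittered:

* dot: shifted per-axis by up to ±2 mm, but never more than 10% of the
  object's maximum in-plane extent, and always resampled until it lands on a
  foreground voxel;
* box: width and height independently changed by up to ±2 mm (capped at 5%
  of that dimension), applied symmetrically about the box center, then the
  whole box translated per-axis by up to ±1 mm (again capped at 5% of that
  dimension).

Jitter draws are uniform on the capped interval.  In-plane coordinates are
continuous mm under the voxel-center convention; plane axis 0 is "x" and
plane axis 1 is "y" throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .metrics import dice
from .volume_io import InstanceMask, Volume

DOT_SHIFT_CAP_MM = 2.0
DOT_SHIFT_CAP_FRAC = 0.10
BOX_SCALE_CAP_MM = 2.0
BOX_SCALE_CAP_FRAC = 0.05
BOX_SHIFT_CAP_MM = 1.0
BOX_SHIFT_CAP_FRAC = 0.05
_MAX_DOT_ATTEMPTS = 100


@dataclass(frozen=True)
class DotPrompt:
    """A point prompt on one slice, in continuous in-plane mm coordinates."""

    slice_index: int
    x: float
    y: float


@dataclass(frozen=True)
class BoxPrompt:
    """A rectangle prompt on one slice, in continuous in-plane mm coordinates."""

    slice_index: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")


def find_center_slice(mask3d: InstanceMask, label: int) -> int:
    """Center of mass of the object along the slicing axis, as a slice index.

    The unweighted 3D center of mass of the label's voxels is projected onto
    the slicing axis and rounded to the nearest slice.  If that slice happens
    to carry no foreground (possible for concave objects), the nearest
    nonempty slice is used, preferring the lower index on ties.
    """
    axis_coords = np.nonzero(mask3d.labels == label)[mask3d.slicing_axis]
    if axis_coords.size == 0:
        raise ValueError(f"label {label} is empty")
    center = int(np.floor(axis_coords.mean() + 0.5))
    nonempty = np.unique(axis_coords)
    if center in nonempty:
        return center
    return int(min(nonempty, key=lambda s: (abs(int(s) - center), int(s))))


def _extent_mm(mask2d: np.ndarray, spacing_mm: Sequence[float]) -> tuple[float, float]:
    idx = np.argwhere(mask2d)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    return tuple((hi[i] - lo[i] + 1) * spacing_mm[i] for i in range(2))


def _to_pixel(coord_mm: float, spacing: float, size: int) -> int:
    # voxel i covers [i*s, (i+1)*s); its center is at (i + 0.5)*s
    return int(np.clip(np.floor(coord_mm / spacing), 0, size - 1))


def jitter_dot(mask2d: np.ndarray, spacing_mm: Sequence[float],
               rng: np.random.Generator, slice_index: int = 0) -> DotPrompt:
    """Jittered centroid dot, guaranteed to rasterize onto a foreground voxel."""
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise ValueError("cannot place a dot on an empty mask")
    spacing = tuple(float(s) for s in spacing_mm)
    idx = np.argwhere(mask2d)
    centroid = (idx.mean(axis=0) + 0.5) * spacing  # mm
    w, h = _extent_mm(mask2d, spacing)
    cap = min(DOT_SHIFT_CAP_MM, DOT_SHIFT_CAP_FRAC * max(w, h))
    for _ in range(_MAX_DOT_ATTEMPTS):
        pos = centroid + rng.uniform(-cap, cap, size=2)
        px = tuple(_to_pixel(pos[i], spacing[i], mask2d.shape[i]) for i in range(2))
        if mask2d[px]:
            return DotPrompt(slice_index=slice_index, x=float(pos[0]), y=float(pos[1]))
    # fall back: exact centroid voxel, or the nearest foreground voxel to it
    px = tuple(_to_pixel(centroid[i], spacing[i], mask2d.shape[i]) for i in range(2))
    if not mask2d[px]:
        d2 = (((idx + 0.5) * spacing - centroid) ** 2).sum(axis=1)
        px = tuple(idx[int(np.argmin(d2))])
    pos = (np.asarray(px) + 0.5) * spacing
    return DotPrompt(slice_index=slice_index, x=float(pos[0]), y=float(pos[1]))


def tight_box_mm(mask2d: np.ndarray, spacing_mm: Sequence[float],
                 slice_index: int = 0) -> BoxPrompt:
    """Tight bounding box of the mask, using voxel outer edges in mm."""
    idx = np.argwhere(mask2d)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    s = spacing_mm
    return BoxPrompt(slice_index=slice_index,
                     x_min=float(lo[0] * s[0]), y_min=float(lo[1] * s[1]),
                     x_max=float((hi[0] + 1) * s[0]), y_max=float((hi[1] + 1) * s[1]))


def jitter_box(mask2d: np.ndarray, spacing_mm: Sequence[float],
               rng: np.random.Generator, slice_index: int = 0) -> BoxPrompt:
    """Tight bounding box, scaled then shifted within the capped jitter rules.

    A box degenerate in either dimension (single-voxel extent) is returned
    unjittered.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise ValueError("cannot box an empty mask")
    spacing = tuple(float(s) for s in spacing_mm)
    box = tight_box_mm(mask2d, spacing, slice_index)
    idx = np.argwhere(mask2d)
    extent_vox = idx.max(axis=0) - idx.min(axis=0) + 1
    if extent_vox[0] <= 1 or extent_vox[1] <= 1:
        return box
    lo = np.array([box.x_min, box.y_min])
    hi = np.array([box.x_max, box.y_max])
    dims = hi - lo
    scale_caps = np.minimum(BOX_SCALE_CAP_MM, BOX_SCALE_CAP_FRAC * dims)
    dw = rng.uniform(-scale_caps, scale_caps)
    lo = lo - dw / 2
    hi = hi + dw / 2
    shift_caps = np.minimum(BOX_SHIFT_CAP_MM, BOX_SHIFT_CAP_FRAC * dims)
    shift = rng.uniform(-shift_caps, shift_caps)
    lo = lo + shift
    hi = hi + shift
    return BoxPrompt(slice_index=slice_index,
                     x_min=float(lo[0]), y_min=float(lo[1]),
                     x_max=float(hi[0]), y_max=float(hi[1]))


@dataclass(frozen=True)
class PromptComparison:
    """Per-object paired center-slice DSC for dot vs box prompting."""

    records: pd.DataFrame  # columns: volume, label, dsc_dot, dsc_box
    median_dot: float
    iqr_dot: tuple[float, float]
    median_box: float
    iqr_box: tuple[float, float]
    p_value: float

    @property
    def n_objects(self) -> int:
        return len(self.records)


def compare_prompt_modes(
    dataset: Sequence[tuple[Volume, InstanceMask]],
    make_segmenter: Callable,
    rng: np.random.Generator,
) -> PromptComparison:
    """Segment each object's center slice from a dot and from a box prompt.

    Both arms use the same segmenter substream per object, so with a
    dot-penalty of 1 the arms are identical and all paired differences are
    zero.  The paired two-sided Wilcoxon signed-rank test is reported along
    with per-mode median and IQR.
    """
    from .reporting import paired_wilcoxon, summarize  # local to avoid cycle

    rows = []
    for vol_index, (vol, mask) in enumerate(dataset):
        sp2 = mask.inplane_spacing
        for label in mask.instance_labels:
            c = find_center_slice(mask, label)
            gt2d = mask.get_slice(c) == label
            box = jitter_box(gt2d, sp2, rng, slice_index=c)
            dot = jitter_dot(gt2d, sp2, rng, slice_index=c)
            seg = make_segmenter(vol, mask.binary(label), vol_index, label)
            seg.reset_state()
            seg.prompt_box(box)
            dsc_box = dice(seg.predict(c), gt2d)
            seg.reset_state()
            seg.prompt_dot(dot)
            dsc_dot = dice(seg.predict(c), gt2d)
            rows.append({"volume": vol_index, "label": label,
                         "dsc_dot": dsc_dot, "dsc_box": dsc_box})
    records = pd.DataFrame(rows)
    if len(records) < 6:
        warnings.warn("fewer than 6 objects: the paired test has little power")
    s_dot = summarize(records["dsc_dot"].to_numpy())
    s_box = summarize(records["dsc_box"].to_numpy())
    p = paired_wilcoxon(records["dsc_box"].to_numpy(), records["dsc_dot"].to_numpy())
    return PromptComparison(
        records=records,
        median_dot=s_dot.median, iqr_dot=(s_dot.iqr_lo, s_dot.iqr_hi),
        median_box=s_box.median, iqr_box=(s_box.iqr_lo, s_box.iqr_hi),
        p_value=p,
    )
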