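"""Simulated promptable-segmenter-assisted annotation workflow.

For each object the simulated annotator:

1. boxes the object's center slice (center of mass of the 3D ground truth)
   with realistic jitter and prompts the segmenter;
2. reviews predicted slices outward from the center, one direction at a
   time, within the object's longitudinal extent (first..last slice with
   nonempty ground truth, which the user is assumed to indicate);
3. accepts a predicted slice only if both its DSC and NSD reach the
   scenario's thresholds, otherwise applies a human-like correction: the
   prediction/ground-truth disagreement (element-wise XOR) is grouped into
   8-connected regions and a region is reset to ground truth only if at
   least one of its voxels lies more than 1 mm from the ground-truth
   boundary — major errors are fixed, minor inaccuracies tolerated;
4. after a correction, resets the segmenter and re-prompts it with the
   corrected mask on that slice, then continues outward.

The stored (assisted) mask per slice is the accepted prediction or the
corrected mask; slices outside the longitudinal extent are stored empty and
not counted.  The unit of workload accounting is the *instance slice*: one
(object, slice) pair with nonempty ground truth — several tumors on one
slice count separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import SliceScore, boundary_mask, score_slice
from .prompts import BoxPrompt, DotPrompt, find_center_slice, jitter_box
from .volume_io import InstanceMask, Volume

log = logging.getLogger(__name__)

_XOR_STRUCT_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity for edit regions


class PromptableSegmenter(Protocol):
    """Contract any promptable segmenter adapter must satisfy.

    Predictions after :meth:`reset_state` must depend only on prompts issued
    after the reset.  A real video-segmenter adapter (e.g. for SAM 2) is a
    documented extension point; the surrogate in
    :mod:`annosim.synthetic_data` is the bundled implementation.
    """

    def reset_state(self) -> None: ...
    def prompt_box(self, box: BoxPrompt) -> None: ...
    def prompt_dot(self, dot: DotPrompt) -> None: ...
    def prompt_mask(self, slice_index: int, mask2d: np.ndarray) -> None: ...
    def predict(self, slice_index: int) -> np.ndarray: ...


@dataclass(frozen=True)
class ScenarioSpec:
    """A named interaction scenario: joint (DSC, NSD) acceptance thresholds."""

    name: str
    tau_dsc: float
    tau_nsd: float

    def __post_init__(self):
        if not (0.0 <= self.tau_dsc and 0.0 <= self.tau_nsd):
            raise ValueError("thresholds must be >= 0")
        if self.name == "no_edits" and (self.tau_dsc != 0.0 or self.tau_nsd != 0.0):
            raise ValueError("the no_edits scenario must have tau_dsc = tau_nsd = 0")

    @classmethod
    def no_edits(cls) -> "ScenarioSpec":
        return cls("no_edits", 0.0, 0.0)


@dataclass(frozen=True)
class SliceRecord:
    """Outcome of reviewing one predicted slice of one object."""

    object_id: str
    slice_index: int
    has_foreground: bool  # ground truth nonempty => counts as an instance slice
    dsc_pre: float
    nsd_pre: float
    accepted: bool
    regions_corrected: int
    dsc_post: float
    nsd_post: float


@dataclass(frozen=True)
class WorkloadSummary:
    """Dataset-level acceptance accounting over instance slices."""

    total_instance_slices: int
    accepted_slices: int
    per_object: dict[str, tuple[int, int]]  # object_id -> (instance slices, accepted)

    @property
    def proportion_accepted(self) -> float:
        if self.total_instance_slices == 0:
            return float("nan")
        return self.accepted_slices / self.total_instance_slices

    @property
    def proportion_corrected(self) -> float:
        return 1.0 - self.proportion_accepted

    @classmethod
    def from_records(cls, records: Sequence[SliceRecord]) -> "WorkloadSummary":
        per_object: dict[str, list[int]] = {}
        for r in records:
            tally = per_object.setdefault(r.object_id, [0, 0])
            if r.has_foreground:
                tally[0] += 1
                tally[1] += int(r.accepted)
        total = sum(v[0] for v in per_object.values())
        accepted = sum(v[1] for v in per_object.values())
        return cls(total_instance_slices=total, accepted_slices=accepted,
                   per_object={k: tuple(v) for k, v in per_object.items()})


def records_to_frame(records: Sequence[SliceRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def accept_or_flag(pred: np.ndarray, gt: np.ndarray, spacing_mm: Sequence[float],
                   scenario: ScenarioSpec, tolerance_mm: float = 1.0
                   ) -> tuple[bool, SliceScore]:
    """Accept iff DSC >= tau_dsc and NSD >= tau_nsd (inclusive comparison).

    The inclusive comparison makes zero thresholds accept every slice, which
    is what defines the no-edits scenario.
    """
    score = score_slice(pred, gt, spacing_mm, tolerance_mm)
    accepted = score.dsc >= scenario.tau_dsc and score.nsd >= scenario.tau_nsd
    return accepted, score


def humanlike_correct(pred: np.ndarray, gt: np.ndarray, spacing_mm: Sequence[float],
                      tol_mm: float = 1.0) -> tuple[np.ndarray, int]:
    """Correct only disagreement regions reaching beyond ``tol_mm`` of the boundary.

    The prediction/ground-truth XOR is grouped into 8-connected regions; a
    region is reset to its ground-truth values only if at least one of its
    voxels lies strictly more than ``tol_mm`` (Euclidean, mm) from the
    ground-truth boundary.  Returns the corrected mask and the number of
    regions edited.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    disagreement = pred ^ gt
    corrected = pred.copy()
    if not disagreement.any():
        return corrected, 0
    gt_boundary = boundary_mask(gt)
    if gt_boundary.any():
        dist = ndimage.distance_transform_edt(~gt_boundary,
                                              sampling=tuple(float(s) for s in spacing_mm))
    else:  # empty ground truth: every spurious voxel is a major error
        dist = np.full(gt.shape, np.inf)
    regions, n_regions = ndimage.label(disagreement, structure=_XOR_STRUCT_2D)
    n_corrected = 0
    maxima = ndimage.maximum(dist, labels=regions, index=np.arange(1, n_regions + 1))
    for region_id, region_max in enumerate(np.atleast_1d(maxima), start=1):
        if region_max > tol_mm:
            sel = regions == region_id
            corrected[sel] = gt[sel]
            n_corrected += 1
    return corrected, n_corrected


def simulate_object_annotation(
    vol: Volume,
    mask: InstanceMask,
    label: int,
    segmenter: PromptableSegmenter,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    tolerance_mm: float = 1.0,
    object_id: str | None = None,
) -> tuple[list[SliceRecord], np.ndarray]:
    """Run the assisted workflow for one object; returns records and its 3D mask.

    Propagation runs as one segmenter session per direction, with the jittered
    center-slice box prompt repeated for the downward direction.  The center
    slice itself is reviewed like any other slice.
    """
    gt3d = np.moveaxis(mask.binary(label), mask.slicing_axis, 0)
    nonempty = np.flatnonzero(gt3d.reshape(gt3d.shape[0], -1).any(axis=1))
    if nonempty.size == 0:
        raise ValueError(f"label {label} is empty")
    first, last = int(nonempty[0]), int(nonempty[-1])
    center = find_center_slice(mask, label)
    sp2 = mask.inplane_spacing
    box = jitter_box(mask.get_slice(center) == label, sp2, rng, slice_index=center)
    if object_id is None:
        object_id = f"obj{label}"

    assisted = np.zeros_like(gt3d)
    records: list[SliceRecord] = []
    for direction, stop in ((1, last), (-1, first)):
        start = center if direction == 1 else center - 1
        if (direction == 1 and start > stop) or (direction == -1 and start < stop):
            continue
        segmenter.reset_state()
        segmenter.prompt_box(box)
        for s in range(start, stop + direction, direction):
            pred = segmenter.predict(s)
            gt2d = gt3d[s]
            accepted, pre = accept_or_flag(pred, gt2d, sp2, scenario, tolerance_mm)
            if accepted:
                stored, n_regions, post = pred, 0, pre
            else:
                stored, n_regions = humanlike_correct(pred, gt2d, sp2, tolerance_mm)
                post = score_slice(stored, gt2d, sp2, tolerance_mm)
                segmenter.reset_state()
                segmenter.prompt_mask(s, stored)
            assisted[s] = stored
            records.append(SliceRecord(
                object_id=object_id, slice_index=s,
                has_foreground=bool(gt2d.any()),
                dsc_pre=pre.dsc, nsd_pre=pre.nsd,
                accepted=accepted, regions_corrected=n_regions,
                dsc_post=post.dsc, nsd_post=post.nsd,
            ))
    return records, np.moveaxis(assisted, 0, mask.slicing_axis)


def simulate_dataset(
    dataset: Sequence[tuple[Volume, InstanceMask]],
    make_segmenter,
    scenario: ScenarioSpec,
    rng: np.random.Generator | int | None = None,
    tolerance_mm: float = 1.0,
) -> tuple[WorkloadSummary, list[InstanceMask], list[SliceRecord]]:
    """Run the workflow for every object of every volume.

    ``make_segmenter(volume, gt3d, volume_index, label)`` must return a
    promptable segmenter bound to that object (see
    :func:`annosim.synthetic_data.surrogate_factory`).  Objects are simulated
    independently; assisted masks are merged per volume with first-written
    labels winning on (logged) overlap conflicts.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    all_records: list[SliceRecord] = []
    assisted_masks: list[InstanceMask] = []
    conflicts = 0
    for vol_index, (vol, mask) in enumerate(dataset):
        merged = np.zeros_like(mask.labels)
        for label in mask.instance_labels:
            segmenter = make_segmenter(vol, mask.binary(label), vol_index, label)
            records, obj_mask = simulate_object_annotation(
                vol, mask, label, segmenter, scenario, rng, tolerance_mm,
                object_id=f"vol{vol_index:03d}_obj{label}",
            )
            all_records.extend(records)
            writable = obj_mask & (merged == 0)
            conflicts += int(obj_mask.sum() - writable.sum())
            merged[writable] = label
        assisted_masks.append(InstanceMask(labels=merged, spacing=mask.spacing,
                                           slicing_axis=mask.slicing_axis))
    if conflicts:
        log.info("%d overlapping assisted-mask voxels kept their first-written label",
                 conflicts)
    return WorkloadSummary.from_records(all_records), assisted_masks, all_records
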