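"""Overlap and boundary-agreement metrics for binary masks.

Two metrics drive the simulated accept/correct decision:

* DSC (Dice similarity coefficient): ``2|A∩B| / (|A| + |B|)``.
* NSD (normalized surface dice) at a physical tolerance: the fraction of the
  two masks' boundary elements lying within ``tolerance_mm`` of the other
  mask's boundary, with Euclidean distances measured in mm between voxel
  centers under anisotropic spacing.

Boundary elements are foreground voxels with at least one background
neighbor under 4-connectivity (2D) or 6-connectivity (3D); voxels on the
image border count as boundary (out-of-grid is background).  Empty-mask
conventions: both masks empty scores 1.0 (correctly predicting "no object"
is a success), exactly one empty scores 0.0.  The same conventions apply to
DSC and NSD.  The tolerance comparison is inclusive (``<=``).

``nsd`` uses a distance transform; ``nsd_bruteforce`` is an independent
all-pairs oracle retained for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class SliceScore:
    """Joint (DSC, NSD) quality of one predicted slice."""

    dsc: float
    nsd: float
    tolerance_mm: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.dsc <= 1.0 and 0.0 <= self.nsd <= 1.0):
            raise ValueError(f"scores must lie in [0, 1]: {self}")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    sa = int(a.sum())
    sb = int(b.sum())
    if sa == 0 and sb == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (sa + sb)


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a background face-neighbor (border = background)."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def nsd(a: np.ndarray, b: np.ndarray, spacing_mm: Sequence[float],
        tolerance_mm: float = 1.0) -> float:
    """Normalized surface dice at ``tolerance_mm`` (distance-transform route)."""
    a, b = _check_pair(a, b)
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be positive")
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != a.ndim or any(s <= 0 for s in spacing):
        raise ValueError(f"invalid spacing {spacing} for {a.ndim}D masks")
    ea, eb = not a.any(), not b.any()
    if ea and eb:
        return 1.0
    if ea or eb:
        return 0.0
    ba = boundary_mask(a)
    bb = boundary_mask(b)
    dist_to_bb = ndimage.distance_transform_edt(~bb, sampling=spacing)
    dist_to_ba = ndimage.distance_transform_edt(~ba, sampling=spacing)
    hits_a = int(np.count_nonzero(dist_to_bb[ba] <= tolerance_mm))
    hits_b = int(np.count_nonzero(dist_to_ba[bb] <= tolerance_mm))
    na = int(ba.sum())
    nb = int(bb.sum())
    return (hits_a + hits_b) / (na + nb)


def nsd_bruteforce(a: np.ndarray, b: np.ndarray, spacing_mm: Sequence[float],
                   tolerance_mm: float = 1.0) -> float:
    """All-pairs boundary-distance oracle for :func:`nsd` (same conventions)."""
    a, b = _check_pair(a, b)
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be positive")
    spacing = np.asarray(spacing_mm, dtype=float)
    ea, eb = not a.any(), not b.any()
    if ea and eb:
        return 1.0
    if ea or eb:
        return 0.0
    pa = np.argwhere(boundary_mask(a)) * spacing
    pb = np.argwhere(boundary_mask(b)) * spacing
    d = cdist(pa, pb)
    hits_a = int(np.count_nonzero(d.min(axis=1) <= tolerance_mm))
    hits_b = int(np.count_nonzero(d.min(axis=0) <= tolerance_mm))
    return (hits_a + hits_b) / (len(pa) + len(pb))


def score_slice(pred: np.ndarray, gt: np.ndarray, spacing_mm: Sequence[float],
                tolerance_mm: float = 1.0) -> SliceScore:
    """Joint DSC/NSD score of a predicted 2D slice against ground truth."""
    return SliceScore(
        dsc=dice(pred, gt),
        nsd=nsd(pred, gt, spacing_mm, tolerance_mm),
        tolerance_mm=tolerance_mm,
    )
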