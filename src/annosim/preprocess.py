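"""Intensity normalization and ground-truth cleaning applied before simulation.

CT volumes are windowed to [−55, 155] HU and rescaled to [0, 255]; MR volumes
are clipped at their 1st/99th intensity percentiles and rescaled likewise.
Intensities stay floating point — no uint8 quantization — so downstream
metric computations are unaffected by rounding.

Mask cleaning keeps only the largest 3D connected component of a label
(26-connectivity); ROI cropping reduces a volume to the bounding cuboid of a
region mask plus a physical margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import InstanceMask, Volume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessSpec:
    modality: str = "ct"
    ct_clip_lo: float = -55.0
    ct_clip_hi: float = 155.0
    mr_pct_lo: float = 1.0
    mr_pct_hi: float = 99.0
    out_lo: float = 0.0
    out_hi: float = 255.0

    def __post_init__(self):
        if self.modality not in ("ct", "mr"):
            raise ValueError(f"modality must be 'ct' or 'mr', got {self.modality!r}")
        if self.ct_clip_lo >= self.ct_clip_hi:
            raise ValueError("ct_clip_lo must be below ct_clip_hi")
        if self.out_lo >= self.out_hi:
            raise ValueError("out_lo must be below out_hi")


def clip_scale_ct(vol: Volume, spec: PreprocessSpec = PreprocessSpec("ct")) -> Volume:
    """Window to [clip_lo, clip_hi] HU and map affinely onto [out_lo, out_hi]."""
    x = np.clip(np.asarray(vol.intensities, dtype=np.float64),
                spec.ct_clip_lo, spec.ct_clip_hi)
    out = (x - spec.ct_clip_lo) / (spec.ct_clip_hi - spec.ct_clip_lo)
    out = spec.out_lo + out * (spec.out_hi - spec.out_lo)
    return vol.with_intensities(out)


def clip_scale_mr(vol: Volume, spec: PreprocessSpec = PreprocessSpec("mr")) -> Volume:
    """Clip at volume-wide percentiles, then map [p_lo, p_hi] onto [out_lo, out_hi].

    Percentiles use linear interpolation between order statistics.  A constant
    volume (p_lo == p_hi) maps to all zeros with a warning instead of failing,
    so degenerate inputs do not abort batch runs.
    """
    x = np.asarray(vol.intensities, dtype=np.float64)
    p_lo, p_hi = np.percentile(x, [spec.mr_pct_lo, spec.mr_pct_hi])
    if p_lo == p_hi:
        log.warning("constant volume: percentile window is degenerate, output all zeros")
        return vol.with_intensities(np.zeros_like(x))
    out = (np.clip(x, p_lo, p_hi) - p_lo) / (p_hi - p_lo)
    out = spec.out_lo + out * (spec.out_hi - spec.out_lo)
    return vol.with_intensities(out)


def preprocess_volume(vol: Volume, spec: PreprocessSpec) -> Volume:
    """Apply the modality-appropriate intensity rule."""
    if spec.modality == "ct":
        return clip_scale_ct(vol, spec)
    return clip_scale_mr(vol, spec)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def retain_largest_component(mask: InstanceMask, label: int) -> InstanceMask:
    """Keep only the largest 3D 26-connected component of ``label``.

    Smaller components are reclassified as background.  Ties on voxel count
    are broken deterministically by keeping the component containing the
    smallest linear voxel index.
    """
    binary = mask.labels == label
    if not binary.any():
        log.warning("label %d absent from mask; retain_largest_component is a no-op", label)
        return mask
    comps, n = ndimage.label(binary, structure=_STRUCT_26)
    if n <= 1:
        return mask
    counts = np.bincount(comps.ravel())[1:]  # component ids 1..n
    largest = counts.max()
    candidates = set(int(c) + 1 for c in np.flatnonzero(counts == largest))
    if len(candidates) == 1:
        keep = candidates.pop()
    else:
        flat = comps.ravel()
        keep = next(int(flat[i]) for i in np.flatnonzero(np.isin(flat, list(candidates))))
    out = mask.labels.copy()
    out[binary & (comps != keep)] = 0
    return InstanceMask(labels=out, spacing=mask.spacing, slicing_axis=mask.slicing_axis)


def crop_to_roi(vol: Volume, roi: InstanceMask, margin_mm: float = 0.0
                ) -> tuple[Volume, tuple[int, int, int]]:
    """Crop to the bounding cuboid of ``roi`` expanded by ``margin_mm``.

    Returns the cropped volume and the per-axis start offsets that map
    cropped coordinates back to the original grid.
    """
    region = roi.labels > 0
    if not region.any():
        raise ValueError("ROI mask is empty")
    lo, hi = [], []
    for axis in range(3):
        proj = np.any(region, axis=tuple(i for i in range(3) if i != axis))
        idx = np.flatnonzero(proj)
        pad = int(np.ceil(margin_mm / vol.spacing[axis]))
        lo.append(max(0, int(idx[0]) - pad))
        hi.append(min(region.shape[axis], int(idx[-1]) + 1 + pad))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return vol.with_intensities(vol.intensities[sl]), tuple(lo)


def uncrop(cropped: np.ndarray, offsets: tuple[int, int, int],
           full_shape: tuple[int, int, int], fill=0) -> np.ndarray:
    """Place a cropped array back into a full-size grid at ``offsets``."""
    out = np.full(full_shape, fill, dtype=cropped.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offsets, cropped.shape))
    out[sl] = cropped
    return out
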