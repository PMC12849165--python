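"""NIfTI volume and instance-mask I/O with explicit slicing geometry.

Volumes are kept in stored grid order; no anatomical reorientation is
performed.  A configuration tag (``slicing_axis``) names which stored grid
axis is the annotation direction (sagittal for the femoral-bone task, axial
for the liver-tumor task).  Physical positions follow the voxel-center
convention: the center of voxel ``i`` along an axis with spacing ``s`` sits
at ``(i + 0.5) * s`` mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import yaml

log = logging.getLogger(__name__)

SPACING_ATOL_MM = 1e-4


def _validate_geometry(grid: np.ndarray, spacing: tuple, slicing_axis: int) -> None:
    if grid.ndim != 3:
        raise ValueError(f"expected 3D volume, got {grid.ndim}D")
    if len(spacing) != 3:
        raise ValueError("spacing must have three components")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    if slicing_axis not in (0, 1, 2):
        raise ValueError(f"slicing_axis must be 0, 1 or 2, got {slicing_axis}")


def inplane_spacing(spacing: Sequence[float], slicing_axis: int) -> tuple[float, float]:
    """Spacing of the two axes orthogonal to the slicing axis, in grid order."""
    return tuple(s for i, s in enumerate(spacing) if i != slicing_axis)


@dataclass(frozen=True)
class Volume:
    """3D scalar intensity grid with per-axis spacing in mm."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    slicing_axis: int = 0

    def __post_init__(self):
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        _validate_geometry(self.intensities, self.spacing, self.slicing_axis)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[self.slicing_axis]

    @property
    def inplane_spacing(self) -> tuple[float, float]:
        return inplane_spacing(self.spacing, self.slicing_axis)

    def get_slice(self, index: int) -> np.ndarray:
        """2D plane ``index`` along the slicing axis (view, grid order)."""
        return np.moveaxis(self.intensities, self.slicing_axis, 0)[index]

    def with_intensities(self, intensities: np.ndarray) -> "Volume":
        return replace(self, intensities=intensities)


@dataclass(frozen=True)
class InstanceMask:
    """3D integer label grid: 0 = background, k >= 1 = instance k."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    slicing_axis: int = 0

    def __post_init__(self):
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        _validate_geometry(self.labels, self.spacing, self.slicing_axis)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("instance labels must be an integer grid")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("instance labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_slices(self) -> int:
        return self.labels.shape[self.slicing_axis]

    @property
    def inplane_spacing(self) -> tuple[float, float]:
        return inplane_spacing(self.spacing, self.slicing_axis)

    @property
    def n_instances(self) -> int:
        return int(self.labels.max())

    @property
    def instance_labels(self) -> list[int]:
        present = np.unique(self.labels)
        return [int(k) for k in present if k != 0]

    def binary(self, label: int) -> np.ndarray:
        return self.labels == label

    def get_slice(self, index: int) -> np.ndarray:
        return np.moveaxis(self.labels, self.slicing_axis, 0)[index]


def canonicalize_labels(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Relabel to contiguous {0, 1, ..., K}; returns (relabelled, old->new map)."""
    present = [int(k) for k in np.unique(labels) if k != 0]
    mapping = {old: new for new, old in enumerate(present, start=1)}
    if all(old == new for old, new in mapping.items()):
        return labels.astype(np.int32, copy=False), mapping
    out = np.zeros_like(labels, dtype=np.int32)
    for old, new in mapping.items():
        out[labels == old] = new
    return out, mapping


def _affine_from_spacing(spacing: Sequence[float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def read_volume(path: str | Path, slicing_axis: int = 0) -> Volume:
    """Read a 3D NIfTI image; spacing is taken from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(intensities=data, spacing=spacing, slicing_axis=slicing_axis)


def write_volume(path: str | Path, vol: Volume) -> None:
    img = nib.Nifti1Image(vol.intensities, _affine_from_spacing(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_instance_mask(path: str | Path, geometry: Volume) -> InstanceMask:
    """Read a label mask and check it shares the geometry of ``geometry``.

    Non-integer stored values are rejected; labels are canonicalized to a
    contiguous 1..K range (the applied mapping is logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D in {path}")
    if data.shape != geometry.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match volume shape {geometry.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not np.allclose(spacing, geometry.spacing, atol=SPACING_ATOL_MM, rtol=0):
        raise ValueError(
            f"mask spacing {spacing} does not match volume spacing "
            f"{geometry.spacing} within {SPACING_ATOL_MM} mm"
        )
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise ValueError(f"mask {path} contains non-integer label values")
        data = rounded.astype(np.int32)
    labels, mapping = canonicalize_labels(data)
    if any(old != new for old, new in mapping.items()):
        log.info("relabelled %s: %s", path.name, mapping)
    return InstanceMask(labels=labels, spacing=geometry.spacing,
                        slicing_axis=geometry.slicing_axis)


def write_instance_mask(path: str | Path, mask: InstanceMask) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int32), _affine_from_spacing(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def extract_slices(grid: Volume | InstanceMask) -> list[np.ndarray]:
    """Ordered 2D planes along the slicing axis (index 0..N-1, grid order)."""
    arr = grid.intensities if isinstance(grid, Volume) else grid.labels
    moved = np.moveaxis(arr, grid.slicing_axis, 0)
    return [moved[i] for i in range(moved.shape[0])]


def stack_slices(planes: Sequence[np.ndarray], slicing_axis: int) -> np.ndarray:
    """Inverse of :func:`extract_slices`: restack planes into the 3D grid."""
    return np.stack(planes, axis=slicing_axis)


# ---------------------------------------------------------------------------
# Dataset manifests

@dataclass(frozen=True)
class ManifestEntry:
    volume: str
    mask: str
    modality: str  # "ct" | "mr"
    slicing_axis: int = 0
    roi: str | None = None

    def __post_init__(self):
        if self.modality not in ("ct", "mr"):
            raise ValueError(f"modality must be 'ct' or 'mr', got {self.modality!r}")


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [ManifestEntry(**entry) for entry in raw]


def write_manifest(entries: Sequence[ManifestEntry], path: str | Path) -> None:
    payload = [
        {k: v for k, v in vars(e).items() if v is not None} for e in entries
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_dataset(manifest: Sequence[ManifestEntry], root: str | Path = ".") -> Iterator[tuple[Volume, InstanceMask, ManifestEntry]]:
    """Yield (volume, mask, entry) triples for each manifest row."""
    root = Path(root)
    for entry in manifest:
        vol = read_volume(root / entry.volume, slicing_axis=entry.slicing_axis)
        mask = read_instance_mask(root / entry.mask, geometry=vol)
        yield vol, mask, entry
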