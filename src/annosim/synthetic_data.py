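"""Phantom datasets and a surrogate promptable segmenter.

The phantom generator emulates the two task families the simulation targets:

* ``bone``: a single large, elongated, high-contrast object per volume
  (femoral-bone-like MRI, sliced sagittally), spanning most of the slicing
  axis;
* ``tumor``: 1–6 blob-like, low-contrast instances per volume
  (liver-tumor-like CT, sliced axially), with anisotropic spacing.

Objects are superellipsoids with randomized semi-axes and exponent, so every
instance is simply connected (no holes) and instances never overlap.

The surrogate segmenter implements the promptable-segmenter contract
(reset / box / dot / mask prompt / per-slice predict) with a controllable
error model: the ground-truth slice is deformed by a smooth low-frequency
radial boundary-displacement field whose amplitude grows linearly with the
slice distance from the most recent prompt, is inflated in low-contrast
volumes, and is multiplied by a penalty for dot prompts.  With some
probability a disjoint spurious blob ("leak") at least 5 mm away from the
object is added.  All error scales at zero makes the surrogate an exact
oracle: predictions equal ground truth bit-for-bit.

Two independent RNG streams are used: the dataset stream (from
``PhantomConfig.seed``) and the segmenter stream (from
``SurrogateQuality.seed``), so experiments are reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .prompts import BoxPrompt, DotPrompt
from .volume_io import (InstanceMask, ManifestEntry, Volume, write_instance_mask,
                        write_manifest, write_volume)

_N_HARMONICS = 3  # low-frequency angular harmonics of the displacement field
_LEAK_MIN_GAP_MM = 5.0


# ---------------------------------------------------------------------------
# Phantom generation

@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and appearance of a synthetic phantom dataset."""

    n_volumes: int = 10
    task: str = "tumor"  # "bone" | "tumor"
    grid_shape: tuple[int, int, int] = (32, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.5, 0.8, 0.8)
    slicing_axis: int = 0
    objects_per_volume: tuple[int, int] = (1, 6)
    object_radius_mm: tuple[float, float] = (5.0, 13.0)
    elongation: float = 1.0
    contrast: float = 0.35
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("bone", "tumor"):
            raise ValueError(f"task must be 'bone' or 'tumor', got {self.task!r}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.objects_per_volume[0] < 1 or self.objects_per_volume[0] > self.objects_per_volume[1]:
            raise ValueError(f"bad objects_per_volume range {self.objects_per_volume}")
        if self.object_radius_mm[0] <= 0 or self.object_radius_mm[0] > self.object_radius_mm[1]:
            raise ValueError(f"bad object_radius_mm range {self.object_radius_mm}")
        if self.elongation < 1.0:
            raise ValueError("elongation must be >= 1")

    @classmethod
    def tumor_default(cls, n_volumes: int = 10, seed: int = 0) -> "PhantomConfig":
        """Liver-tumor-like phantoms: several small low-contrast blobs, axial slicing."""
        return cls(n_volumes=n_volumes, seed=seed)

    @classmethod
    def bone_default(cls, n_volumes: int = 3, seed: int = 0) -> "PhantomConfig":
        """Femoral-bone-like phantoms: one elongated high-contrast object, sagittal slicing."""
        return cls(
            n_volumes=n_volumes,
            task="bone",
            grid_shape=(160, 96, 96),
            spacing_mm=(1.0, 0.5, 0.5),
            objects_per_volume=(1, 1),
            object_radius_mm=(12.0, 15.0),
            elongation=4.0,
            contrast=0.8,
            noise_sd=0.02,
            seed=seed,
        )

    @property
    def modality(self) -> str:
        return "mr" if self.task == "bone" else "ct"


def _superellipsoid_mask(shape, spacing, center_mm, semi_mm, exponent) -> np.ndarray:
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    terms = 0.0
    for axis in range(3):
        ax = np.abs(coords[axis] - center_mm[axis]) / semi_mm[axis]
        sh = [1, 1, 1]
        sh[axis] = -1
        terms = terms + ax.reshape(sh) ** exponent
    return terms <= 1.0


def _place_objects(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Instance-label grid for one phantom; raises if objects cannot fit."""
    shape = cfg.grid_shape
    spacing = cfg.spacing_mm
    extent_mm = np.array([n * s for n, s in zip(shape, spacing)])
    n_obj = int(rng.integers(cfg.objects_per_volume[0], cfg.objects_per_volume[1] + 1))
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    for k in range(1, n_obj + 1):
        placed = False
        for _ in range(200):
            radius = rng.uniform(*cfg.object_radius_mm)
            semi = np.array([radius * rng.uniform(0.85, 1.15) for _ in range(3)])
            semi[cfg.slicing_axis] *= cfg.elongation
            exponent = rng.uniform(2.0, 3.0)
            margin = semi + np.asarray(spacing)  # >= 1 voxel margin to the border
            if np.any(2 * margin >= extent_mm):
                continue
            center = rng.uniform(margin, extent_mm - margin)
            cand = _superellipsoid_mask(shape, spacing, center, semi, exponent)
            if not cand.any():
                continue
            # keep a one-voxel gap between instances so they never touch
            grown = ndimage.binary_dilation(cand, structure=structure)
            if (grown & occupied).any():
                continue
            labels[cand] = k
            occupied |= grown
            placed = True
            break
        if not placed:
            raise ValueError(
                f"infeasible geometry: could not place object {k}/{n_obj} "
                f"with radii {cfg.object_radius_mm} mm in grid {shape}"
            )
    return labels


def generate_phantom_dataset(cfg: PhantomConfig) -> list[tuple[Volume, InstanceMask]]:
    """Generate ``cfg.n_volumes`` phantom (volume, instance-mask) pairs.

    Foreground and background mean intensities differ by ``contrast`` on a
    nominal [0, 1] intensity scale, with additive Gaussian noise of scale
    ``noise_sd``.  Bit-identical for identical configs (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    bg = 0.5 - cfg.contrast / 2
    fg = 0.5 + cfg.contrast / 2
    out = []
    for _ in range(cfg.n_volumes):
        labels = _place_objects(cfg, rng)
        intensities = np.where(labels > 0, fg, bg).astype(np.float64)
        if cfg.noise_sd > 0:
            intensities = intensities + rng.normal(0.0, cfg.noise_sd, size=labels.shape)
        vol = Volume(intensities=intensities, spacing=cfg.spacing_mm,
                     slicing_axis=cfg.slicing_axis)
        mask = InstanceMask(labels=labels, spacing=cfg.spacing_mm,
                            slicing_axis=cfg.slicing_axis)
        out.append((vol, mask))
    return out


def write_phantom_dataset(dataset: Sequence[tuple[Volume, InstanceMask]],
                          out_dir: str | Path, modality: str = "ct") -> Path:
    """Write NIfTI volumes/masks plus the YAML manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (vol, mask) in enumerate(dataset):
        vname = f"phantom_{i:03d}_vol.nii.gz"
        mname = f"phantom_{i:03d}_mask.nii.gz"
        write_volume(out_dir / vname, vol)
        write_instance_mask(out_dir / mname, mask)
        entries.append(ManifestEntry(volume=vname, mask=mname, modality=modality,
                                     slicing_axis=vol.slicing_axis))
    manifest_path = out_dir / "manifest.yaml"
    write_manifest(entries, manifest_path)
    return manifest_path


# ---------------------------------------------------------------------------
# Surrogate segmenter

@dataclass(frozen=True)
class SurrogateQuality:
    """Error profile of the surrogate segmenter.

    ``base_boundary_sd_mm`` is the boundary-displacement scale at the
    prompted slice; each slice of distance from the most recent prompt adds
    ``drift_per_slice_mm``.  In low-contrast volumes (estimated
    foreground/background contrast below 0.5) the scale is multiplied by
    ``contrast_coupling``; dot prompts multiply it by ``dot_penalty``.  With
    probability ``leak_prob`` a spurious disjoint blob >= 5 mm from the
    object is added to a predicted slice.
    """

    base_boundary_sd_mm: float = 2.0
    drift_per_slice_mm: float = 0.5
    contrast_coupling: float = 1.4
    leak_prob: float = 0.03
    dot_penalty: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if min(self.base_boundary_sd_mm, self.drift_per_slice_mm) < 0:
            raise ValueError("error scales must be >= 0")
        if self.contrast_coupling < 0:
            raise ValueError("contrast_coupling must be >= 0")
        if not 0.0 <= self.leak_prob <= 1.0:
            raise ValueError("leak_prob must lie in [0, 1]")
        if self.dot_penalty < 1.0:
            raise ValueError("dot_penalty must be >= 1")

    @classmethod
    def perfect(cls, seed: int = 0) -> "SurrogateQuality":
        """Zero-error oracle: predictions equal ground truth exactly."""
        return cls(base_boundary_sd_mm=0.0, drift_per_slice_mm=0.0,
                   contrast_coupling=1.0, leak_prob=0.0, dot_penalty=1.0, seed=seed)


class SurrogateSegmenter:
    """Ground-truth-deforming stand-in for a promptable video segmenter.

    One instance is bound to one object (a binary 3D ground-truth mask within
    its volume).  Predictions are pure functions of (quality seed, object
    key, most recent prompt slice, queried slice), so repeated queries are
    reproducible and state after a reset depends only on post-reset prompts.
    The prompt *kind* affects only the error amplitude, never the random
    draws, so dot and box arms share identical noise fields.
    """

    def __init__(self, volume: Volume, gt3d: np.ndarray, quality: SurrogateQuality,
                 object_key: tuple[int, int] = (0, 1)):
        gt3d = np.asarray(gt3d, dtype=bool)
        if gt3d.shape != volume.shape:
            raise ValueError("ground-truth mask shape does not match the volume")
        self.volume = volume
        self.quality = quality
        self._gt = np.moveaxis(gt3d, volume.slicing_axis, 0)
        self._spacing2d = volume.inplane_spacing
        self._entropy = (int(quality.seed), int(object_key[0]), int(object_key[1]))
        self._prompt: tuple[str, int] | None = None
        self._low_contrast = self._estimate_contrast(volume, gt3d) < 0.5

    @staticmethod
    def _estimate_contrast(volume: Volume, gt3d: np.ndarray) -> float:
        x = volume.intensities
        rng_int = float(x.max() - x.min())
        if rng_int == 0 or not gt3d.any() or gt3d.all():
            return 1.0
        return abs(float(x[gt3d].mean()) - float(x[~gt3d].mean())) / rng_int

    # -- promptable-segmenter contract ------------------------------------

    def reset_state(self) -> None:
        self._prompt = None

    def prompt_box(self, box: BoxPrompt) -> None:
        self._prompt = ("box", int(box.slice_index))

    def prompt_dot(self, dot: DotPrompt) -> None:
        self._prompt = ("dot", int(dot.slice_index))

    def prompt_mask(self, slice_index: int, mask2d: np.ndarray) -> None:
        self._prompt = ("mask", int(slice_index))

    def predict(self, slice_index: int) -> np.ndarray:
        if self._prompt is None:
            raise RuntimeError("segmenter queried without a prompt since the last reset")
        kind, anchor = self._prompt
        q = self.quality
        sigma = q.base_boundary_sd_mm + q.drift_per_slice_mm * abs(slice_index - anchor)
        if kind == "dot":
            sigma *= q.dot_penalty
        if self._low_contrast:
            sigma *= q.contrast_coupling
        rng = np.random.default_rng(self._entropy + (anchor, int(slice_index)))
        gt2d = self._gt[slice_index]
        pred = self._deform(gt2d, sigma, rng)
        if rng.random() < q.leak_prob:
            pred = self._add_leak(pred, gt2d, rng)
        return pred

    # -- error model -------------------------------------------------------

    def _deform(self, gt2d: np.ndarray, sigma_mm: float, rng: np.random.Generator
                ) -> np.ndarray:
        # coefficients are always drawn so the stream is amplitude-invariant
        coeffs = rng.normal(0.0, 1.0, size=2 * _N_HARMONICS)
        if not gt2d.any():
            return np.zeros_like(gt2d)
        if sigma_mm == 0.0:
            return gt2d.copy()
        sp = self._spacing2d
        inside = ndimage.distance_transform_edt(gt2d, sampling=sp)
        outside = ndimage.distance_transform_edt(~gt2d, sampling=sp)
        signed = inside - outside  # > 0 strictly inside, < 0 outside
        idx = np.argwhere(gt2d)
        centroid = (idx.mean(axis=0) + 0.5) * np.asarray(sp)
        xx = (np.arange(gt2d.shape[0]) + 0.5) * sp[0] - centroid[0]
        yy = (np.arange(gt2d.shape[1]) + 0.5) * sp[1] - centroid[1]
        theta = np.arctan2(yy[None, :], xx[:, None])
        disp = np.zeros_like(theta)
        amp = sigma_mm / np.sqrt(2 * _N_HARMONICS)
        for k in range(1, _N_HARMONICS + 1):
            a, b = coeffs[2 * (k - 1)], coeffs[2 * (k - 1) + 1]
            disp += amp * (a * np.cos(k * theta) + b * np.sin(k * theta))
        return signed > -disp

    def _add_leak(self, pred: np.ndarray, gt2d: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
        sp = np.asarray(self._spacing2d)
        radius = float(rng.uniform(2.0, 4.0))
        if gt2d.any():
            dist_from_obj = ndimage.distance_transform_edt(~gt2d, sampling=tuple(sp))
        else:
            dist_from_obj = np.full(gt2d.shape, np.inf)
        # keep the blob clear of both the object and the image border
        border = np.zeros(gt2d.shape, dtype=bool)
        interior = tuple(
            slice(int(np.ceil(radius / s)) + 1, n - int(np.ceil(radius / s)) - 1)
            for s, n in zip(sp, gt2d.shape)
        )
        if any(sl.start >= sl.stop for sl in interior):
            return pred
        border[interior] = True
        candidates = np.argwhere((dist_from_obj >= _LEAK_MIN_GAP_MM + radius) & border)
        if len(candidates) == 0:
            return pred
        center = (candidates[rng.integers(len(candidates))] + 0.5) * sp
        xx = (np.arange(gt2d.shape[0]) + 0.5) * sp[0] - center[0]
        yy = (np.arange(gt2d.shape[1]) + 0.5) * sp[1] - center[1]
        blob = (xx[:, None] ** 2 + yy[None, :] ** 2) <= radius ** 2
        return pred | blob


SegmenterFactory = Callable[[Volume, np.ndarray, int, int], SurrogateSegmenter]


def surrogate_factory(quality: SurrogateQuality) -> SegmenterFactory:
    """Factory binding a surrogate to each (volume, object) of a dataset.

    The returned callable takes ``(volume, gt3d, volume_index, label)`` and
    yields a freshly reset segmenter whose RNG substream is keyed on
    (quality.seed, volume_index, label) — deterministic and independent of
    construction order.
    """
    def make(volume: Volume, gt3d: np.ndarray, volume_index: int, label: int
             ) -> SurrogateSegmenter:
        return SurrogateSegmenter(volume, gt3d, quality,
                                  object_key=(volume_index, label))
    return make
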