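"""Volumetric images, label masks, resampling and body-contour extraction.

The in-memory carrier for everything in this package is a plain real-valued
3D grid plus geometric metadata (voxel spacing and world origin, both in mm).
The same container holds SPECT count maps, absorbed-dose maps (Gy) and
attenuation-coefficient maps (mm^-1); the physical unit is the caller's
context, never inferred.

Conventions
-----------
* voxel indices are 0-based and ordered ``(i, j, k)`` = ``(x, y, z)``;
* world position of a voxel centre = ``origin + index * spacing``
  (direction cosines are assumed identity unless supplied);
* canonical on-disk format is NIfTI-1; MetaImage (.mha/.mhd) is accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumetricImage",
    "SegmentationSet",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "derive_body_mask",
]

Triple = Tuple[float, float, float]


class VolumeFormatError(ValueError):
    """File could not be read as a 3D volume."""


class GridMismatchError(ValueError):
    """Two volumes expected to share a grid do not."""


@dataclass(frozen=True)
class VolumetricImage:
    """A real-valued 3D grid with spacing/origin metadata.

    Parameters
    ----------
    values
        3D array; unit depends on role (counts, Gy, mm^-1, ...).
    spacing
        Voxel size ``(sx, sy, sz)`` in mm; all components > 0.
    origin
        World coordinate of voxel (0, 0, 0) in mm.
    direction
        3x3 direction-cosine matrix; identity by default.
    """

    values: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise VolumeFormatError(f"expected a 3D array, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        arr.setflags(write=False)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_values(self, values: np.ndarray) -> "VolumetricImage":
        """New image on the same grid carrying different values."""
        return VolumetricImage(np.asarray(values), self.spacing, self.origin,
                               self.direction)

    def same_grid(self, other: "VolumetricImage", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "VolumetricImage") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    def index_to_world(self, index: Iterable[float]) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_to_index(self, world: Iterable[float]) -> np.ndarray:
        return (np.asarray(world) - np.asarray(self.origin)) / np.asarray(self.spacing)


# Region names understood by SegmentationSet.  "WL" and "body" are composites
# of the primitive labels; everything else maps to a single label value.
PRIMITIVE_LABELS: Dict[str, int] = {
    "WNL": 1,       # whole normal liver = whole liver minus tumour
    "tumour": 2,
    "lungs": 3,
    "kidneys": 4,
    "stomach": 5,
    "body_other": 6,  # body voxels not in any named organ
}


class SegmentationSet:
    """Named binary masks stored as a single integer label volume.

    The label volume assigns each voxel to at most one primitive region
    (whole-normal-liver, tumour, lungs, kidneys, stomach, remaining body).
    Composite regions are derived, which makes the set identities
    ``WL = WNL | tumour``, ``WNL = WL & ~tumour`` and ``region subset of body``
    hold by construction, and keeps them exact under nearest-neighbour
    resampling.
    """

    def __init__(self, label_volume: VolumetricImage,
                 label_table: Mapping[str, int] | None = None) -> None:
        vals = np.asarray(label_volume.values)
        if not np.issubdtype(vals.dtype, np.integer):
            rounded = np.rint(vals)
            if not np.allclose(vals, rounded):
                raise ValueError("label volume must hold integer labels")
            label_volume = label_volume.with_values(rounded.astype(np.int32))
        self.label_volume = label_volume
        self.label_table = dict(label_table or PRIMITIVE_LABELS)

    @classmethod
    def from_masks(cls, grid: VolumetricImage,
                   masks: Mapping[str, np.ndarray]) -> "SegmentationSet":
        """Build from boolean masks; overlapping organs claim voxels in the
        order tumour > WNL > lungs > kidneys > stomach > body."""
        labels = np.zeros(grid.shape, dtype=np.int32)
        body = masks.get("body")
        if body is not None:
            labels[np.asarray(body, bool)] = PRIMITIVE_LABELS["body_other"]
        for name in ("stomach", "kidneys", "lungs", "WNL", "tumour"):
            m = masks.get(name)
            if m is not None:
                labels[np.asarray(m, bool)] = PRIMITIVE_LABELS[name]
        if "WL" in masks and "WNL" not in masks:
            wl = np.asarray(masks["WL"], bool)
            tum = np.asarray(masks.get("tumour", np.zeros_like(wl)), bool)
            labels[wl & ~tum] = PRIMITIVE_LABELS["WNL"]
        return cls(grid.with_values(labels))

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask for a primitive or composite region name."""
        lab = self.label_volume.values
        if name == "WL":
            return self.mask("WNL") | self.mask("tumour")
        if name in ("body", "whole_image"):
            return lab > 0
        if name not in self.label_table:
            raise KeyError(f"unknown region {name!r}; "
                           f"known: {sorted(self.label_table)} + WL/body")
        return lab == self.label_table[name]

    def region_names(self) -> Tuple[str, ...]:
        present = [n for n in ("tumour", "WNL", "lungs", "kidneys", "stomach")
                   if self.mask(n).any()]
        return tuple(present + ["WL", "body"])

    def resample_nearest(self, target_spacing: Triple) -> "SegmentationSet":
        res = resample_to_grid(self.label_volume, target_spacing, "nearest")
        return SegmentationSet(res, self.label_table)


def _sitk_read(path: Path) -> VolumetricImage:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D payload, got {arr.ndim}D")
    return VolumetricImage(
        np.ascontiguousarray(arr.transpose(2, 1, 0)),
        tuple(img.GetSpacing()),
        tuple(img.GetOrigin()),
        np.asarray(img.GetDirection()).reshape(3, 3),
    )


def read_volume(path: str | Path) -> VolumetricImage:
    """Read a NIfTI-1 or MetaImage volume from disk.

    The unit of the values is whatever the file encodes; the caller supplies
    the context (counts, Gy, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mha", ".mhd")):
        return _sitk_read(path)
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D payload, got {arr.ndim}D")
    affine = img.affine
    spacing = tuple(np.linalg.norm(affine[:3, i]) for i in range(3))
    origin = tuple(affine[:3, 3])
    with np.errstate(invalid="ignore"):
        direction = affine[:3, :3] / np.asarray(spacing)[None, :]
    return VolumetricImage(np.ascontiguousarray(arr), spacing, origin, direction)


def write_volume(image: VolumetricImage, path: str | Path) -> None:
    """Write a volume to NIfTI-1 (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(
            image.values.transpose(2, 1, 0)))
        img.SetSpacing(image.spacing)
        img.SetOrigin(image.origin)
        img.SetDirection(tuple(image.direction.ravel()))
        sitk.WriteImage(img, str(path))
        return
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = image.direction * np.asarray(image.spacing)[None, :]
    affine[:3, 3] = image.origin
    nib.save(nib.Nifti1Image(np.asarray(image.values), affine), str(path))


def write_label_table(table: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(table), indent=2))


def read_label_table(path: str | Path) -> Dict[str, int]:
    return {str(k): int(v) for k, v in json.loads(Path(path).read_text()).items()}


def resample_to_grid(image: VolumetricImage, target_spacing: Triple,
                     interpolation: str = "continuous",
                     extensive: bool = False) -> VolumetricImage:
    """Resample onto an isotropic-or-not grid with the given spacing.

    ``continuous`` uses trilinear interpolation and treats values as
    concentrations (per-voxel averages: the natural convention for dose in
    Gy); ``nearest`` is for label volumes.  With ``extensive=True`` values
    are additionally multiplied by the voxel-volume ratio so that the total
    (e.g. total counts) is preserved instead of the local density.
    """
    target_spacing = tuple(float(s) for s in np.atleast_1d(target_spacing).ravel()
                           ) if np.ndim(target_spacing) else (float(target_spacing),) * 3
    if len(target_spacing) == 1:
        target_spacing = target_spacing * 3
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if interpolation not in ("continuous", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    old = np.asarray(image.spacing)
    new = np.asarray(target_spacing)
    if np.allclose(old, new):
        return image
    shape = np.maximum(1, np.round(np.asarray(image.shape) * old / new)).astype(int)
    # sample new voxel centres in old index coordinates (shared origin)
    coords = np.meshgrid(
        *[(np.arange(n) * new[a]) / old[a] for a, n in enumerate(shape)],
        indexing="ij",
    )
    order = 1 if interpolation == "continuous" else 0
    vals = ndimage.map_coordinates(
        np.asarray(image.values, dtype=float if order else image.values.dtype),
        np.stack([c.ravel() for c in coords]),
        order=order, mode="nearest",
    ).reshape(shape)
    if extensive:
        vals = vals * (np.prod(new) / np.prod(old))
    return VolumetricImage(vals, tuple(new), image.origin, image.direction)


def derive_body_mask(image: VolumetricImage,
                     threshold_fraction: float = 0.01) -> np.ndarray:
    """Body contour: threshold, keep the largest 26-connected component, close.

    The threshold is ``threshold_fraction`` times a robust maximum (the 99.9th
    percentile), so single hot voxels do not dominate.  Returns a boolean
    mask; an all-zero image yields an empty mask.
    """
    from skimage import measure, morphology

    vals = np.asarray(image.values)
    if np.any(vals < 0):
        raise ValueError("body-mask derivation expects a non-negative image")
    robust_max = np.percentile(vals, 99.9)
    if robust_max <= 0:
        return np.zeros(image.shape, dtype=bool)
    raw = vals > threshold_fraction * robust_max
    labels = measure.label(raw, connectivity=3)
    if labels.max() == 0:
        return np.zeros(image.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    return morphology.closing(mask, morphology.ball(1)).astype(bool)
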