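"""Binary voxel volumes and labeled-segmentation handling.

The central container is :class:`VoxelVolume`: a 3D boolean occupancy grid
with physical voxel spacing in mm, stored in (x, y, z) index order with
0-based indices.  Labeled segmentations (e.g. FreeSurfer ``aseg`` volumes,
where the cerebellar cortex carries labels 8/left and 47/right) are reduced
to binary masks with :func:`extract_mask`, tightened with
:func:`crop_and_center`, and measured with :func:`mask_volume_mm3`.

No world-coordinate transforms are applied anywhere: the analysis is purely
grid-based, and spacing enters only through the mm^3 volume computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "VoxelVolume",
    "LabeledVolume",
    "extract_mask",
    "crop_and_center",
    "mask_volume_mm3",
    "read_mask",
    "write_mask",
    "read_labeled",
    "to_packed_bytes",
    "from_packed_bytes",
]

# FreeSurfer aseg convention: cerebellar cortex labels.
DEFAULT_LABEL_MAP: dict[str, int] = {"left": 8, "right": 47}


@dataclass(frozen=True)
class VoxelVolume:
    """A binary 3D occupancy grid with per-axis voxel spacing (mm).

    Parameters
    ----------
    occupancy
        3D boolean array; ``True`` marks voxels belonging to the object.
    spacing
        Edge length of a voxel along each axis, in mm.  Must be strictly
        positive.
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3D, got shape {occ.shape}")
        if occ.dtype != bool:
            occ = occ.astype(bool)
        object.__setattr__(self, "occupancy", occ)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())

    def anisotropy_ratio(self) -> float:
        """max/min spacing ratio; 1.0 for isotropic voxels."""
        return max(self.spacing) / min(self.spacing)


@dataclass(frozen=True)
class LabeledVolume:
    """An integer-labeled 3D segmentation (0 = background)."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {lab.dtype}")
        if lab.min() < 0:
            raise ValueError("labels must be nonnegative (0 is background)")
        object.__setattr__(self, "labels", lab)
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "spacing", sp)


def extract_mask(vol: LabeledVolume, label_ids: Iterable[int]) -> VoxelVolume:
    """Binary mask of all voxels carrying any of ``label_ids``.

    Raises
    ------
    ValueError
        If ``label_ids`` is empty or no voxel carries any requested label.
    """
    ids = sorted(set(int(i) for i in label_ids))
    if not ids:
        raise ValueError("label_ids must be nonempty")
    occ = np.isin(vol.labels, ids)
    if not occ.any():
        raise ValueError(f"no voxel carries any of the requested labels {ids}")
    return VoxelVolume(occ, vol.spacing)


def crop_and_center(vol: VoxelVolume, pad: int = 0) -> VoxelVolume:
    """Tight bounding box of the occupancy, expanded by ``pad`` empty voxels per face.

    Removing surrounding blank space and zero-padding symmetrically centers
    the object on its own grid; the occupied-voxel count is conserved and the
    operation is idempotent for a fixed ``pad``.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if vol.is_empty():
        raise ValueError("cannot crop an empty volume")
    occ = vol.occupancy
    slices = []
    for axis in range(3):
        proj = occ.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        slices.append(slice(idx[0], idx[-1] + 1))
    core = occ[tuple(slices)]
    if pad:
        core = np.pad(core, pad, mode="constant", constant_values=False)
    return VoxelVolume(core, vol.spacing)


def mask_volume_mm3(vol: VoxelVolume) -> float:
    """Physical volume of the mask: occupied-voxel count x voxel volume (mm^3)."""
    return float(vol.n_occupied) * float(np.prod(vol.spacing))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------
# Readers accept NIfTI (.nii/.nii.gz) and MGH/MGZ files via nibabel.  The
# on-disk array is taken as-is in its stored voxel order; zooms give spacing.


def _load_nib(path: str | Path):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_mask(path: str | Path) -> VoxelVolume:
    """Read a binary mask from NIfTI or MGH/MGZ (any nonzero voxel is occupied)."""
    data, zooms = _load_nib(path)
    return VoxelVolume(data != 0, zooms)


def write_mask(vol: VoxelVolume, path: str | Path) -> None:
    """Write a binary mask as uint8 NIfTI/MGZ with spacing on the affine diagonal."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    data = vol.occupancy.astype(np.uint8)
    path = str(path)
    if path.endswith((".mgz", ".mgh")):
        img = nib.MGHImage(data, affine)
    else:
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(vol.spacing)
    nib.save(img, path)


def read_labeled(path: str | Path, label_map: Mapping[str, int] | None = None) -> LabeledVolume:
    """Read an integer-labeled segmentation (e.g. FreeSurfer aseg.mgz)."""
    data, zooms = _load_nib(path)
    labels = np.rint(np.asarray(data)).astype(np.int32)
    return LabeledVolume(labels, zooms, dict(label_map or DEFAULT_LABEL_MAP))


def to_packed_bytes(vol: VoxelVolume) -> bytes:
    """Raw packed-bit dump of the occupancy (C order); shape/spacing not included."""
    return np.packbits(vol.occupancy.reshape(-1)).tobytes()


def from_packed_bytes(
    raw: bytes, shape: tuple[int, int, int], spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> VoxelVolume:
    """Inverse of :func:`to_packed_bytes` given the original grid shape."""
    n = int(np.prod(shape))
    bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8), count=n)
    return VoxelVolume(bits.reshape(shape).astype(bool), spacing)
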