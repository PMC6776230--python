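"""NRRD image/mask I/O and the masked-voxel lesion representation.

A lesion is a set of plaque voxels selected from a CT angiography volume by a
binary segmentation mask.  All downstream feature modules consume the
:class:`VoxelLesion` produced here: the Hounsfield-unit values, the integer
grid coordinates of each voxel, and the physical voxel spacing.

Files are NRRD (attached or detached header, raw or gzip encoding), read and
written through SimpleITK.  Images are int16 HU, masks uint8 with values in
{0, 1}; any other mask value is rejected rather than thresholded so that
segmentation-export bugs surface early.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VoxelLesion",
    "FormatError",
    "EmptyLesionError",
    "read_lesion",
    "write_lesion",
]


class FormatError(ValueError):
    """Image/mask pair is structurally invalid (shape, spacing or values)."""


class EmptyLesionError(ValueError):
    """The segmentation mask selects no voxels."""


@dataclass(frozen=True)
class VoxelLesion:
    """Masked voxel set of one cross-section lesion.

    Attributes
    ----------
    values : (n,) int array
        Hounsfield units of the masked voxels.
    coords : (n, 3) int array
        0-based (x, y, z) grid indices, one row per value.  Physical position
        is ``index * spacing``.
    spacing_mm : (3,) tuple of float
        Voxel spacing (x, y, z) in millimetres, strictly positive.
    lesion_id : str
        Identifier of the cross-section record.
    """

    values: np.ndarray
    coords: np.ndarray
    spacing_mm: tuple[float, float, float]
    lesion_id: str = field(default="lesion")

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        coords = np.asarray(self.coords)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "coords", coords)
        if values.ndim != 1 or len(values) < 1:
            raise EmptyLesionError("lesion must contain at least one voxel")
        if coords.shape != (len(values), 3):
            raise FormatError(
                f"coords shape {coords.shape} does not match {len(values)} values"
            )
        if len(np.unique(coords, axis=0)) != len(coords):
            raise FormatError("duplicate voxel coordinates")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be three positive numbers, got {spacing}")
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def n_voxels(self) -> int:
        return len(self.values)


def read_lesion(image_path, mask_path, lesion_id: str | None = None) -> VoxelLesion:
    """Read an NRRD image/mask pair and return the masked voxel set.

    The mask must be binary ({0, 1}) and share the image's grid shape and
    spacing.  Returns exactly the voxels where mask == 1, with HU values and
    (x, y, z) indices; spacing is taken from the image header.

    Raises
    ------
    FormatError
        On shape or spacing mismatch, or non-binary mask values.
    EmptyLesionError
        If the mask selects no voxels.
    """
    image = sitk.ReadImage(str(image_path))
    mask = sitk.ReadImage(str(mask_path))
    if image.GetSize() != mask.GetSize():
        raise FormatError(
            f"image size {image.GetSize()} != mask size {mask.GetSize()}"
        )
    if not np.allclose(image.GetSpacing(), mask.GetSpacing(), rtol=0, atol=1e-9):
        raise FormatError(
            f"image spacing {image.GetSpacing()} != mask spacing {mask.GetSpacing()}"
        )
    # SimpleITK arrays are (z, y, x); transpose to (x, y, z) index order.
    img_arr = sitk.GetArrayFromImage(image).transpose(2, 1, 0)
    mask_arr = sitk.GetArrayFromImage(mask).transpose(2, 1, 0)
    mask_values = np.unique(mask_arr)
    if not np.isin(mask_values, (0, 1)).all():
        raise FormatError(f"mask values must be in {{0, 1}}, found {mask_values}")
    coords = np.argwhere(mask_arr == 1)
    if len(coords) == 0:
        raise EmptyLesionError(f"mask {mask_path} selects no voxels")
    values = img_arr[coords[:, 0], coords[:, 1], coords[:, 2]].astype(np.int64)
    spacing = tuple(float(s) for s in image.GetSpacing())
    if lesion_id is None:
        import os

        lesion_id = os.path.splitext(os.path.basename(str(image_path)))[0]
    return VoxelLesion(values=values, coords=coords, spacing_mm=spacing,
                       lesion_id=lesion_id)


def write_lesion(volume: np.ndarray, mask: np.ndarray,
                 spacing_mm, image_path, mask_path) -> None:
    """Write a volume/mask pair as NRRD files readable by :func:`read_lesion`.

    ``volume`` and ``mask`` are (nx, ny, nz) arrays; the volume is stored as
    int16 HU and the mask as uint8.  Roundtrip is lossless for int16 values.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask)
    if volume.shape != mask.shape:
        raise FormatError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise FormatError("mask values must be in {0, 1}")
    spacing = tuple(float(s) for s in spacing_mm)
    for arr, dtype, path in ((volume, np.int16, image_path),
                             (mask, np.uint8, mask_path)):
        img = sitk.GetImageFromArray(arr.astype(dtype).transpose(2, 1, 0))
        img.SetSpacing(spacing)
        sitk.WriteImage(img, str(path), useCompression=False)
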