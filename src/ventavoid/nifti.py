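"""NIfTI serialization for volumes, masks and displacement fields.

Arrays are stored (x, y, z[, component]) on disk per NIfTI convention and
transposed back to this package's (z, y, x) layout on load; voxel spacing
rides in the affine diagonal.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from ventavoid.core import DisplacementField, ImageGrid


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing[2], spacing[1], spacing[0]
    aff[:3, 3] = (origin[2], origin[1], origin[0])
    return aff


def save_image(img: ImageGrid, path: str | Path, dtype=np.float32) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(img.data.T, dtype=dtype),
                             _affine(img.spacing, img.origin)), str(path))
    return path


def load_image(path: str | Path) -> ImageGrid:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=np.float64).T
    sp = nii.header.get_zooms()[:3]
    origin = nii.affine[:3, 3]
    return ImageGrid(data, spacing=(sp[2], sp[1], sp[0]),
                     origin=(origin[2], origin[1], origin[0]))


def save_mask(mask: np.ndarray, spacing, path: str | Path,
              origin=(0.0, 0.0, 0.0)) -> Path:
    grid = ImageGrid(np.asarray(mask, dtype=np.float64), spacing, origin)
    return save_image(grid, path, dtype=np.uint8)


def load_mask(path: str | Path) -> np.ndarray:
    return load_image(path).data > 0.5


def save_dvf(dvf: DisplacementField, path: str | Path) -> Path:
    # (x, y, z, component); components stay in (z, y, x) mm order
    arr = np.transpose(dvf.vectors, (3, 2, 1, 0)).astype(np.float32)
    nii = nib.Nifti1Image(arr, _affine(dvf.spacing, dvf.origin))
    nib.save(nii, str(path))
    return Path(path)


def load_dvf(path: str | Path) -> DisplacementField:
    nii = nib.load(str(path))
    arr = np.asarray(nii.dataobj, dtype=np.float64)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected a 4D displacement NIfTI, got shape {arr.shape}")
    vectors = np.transpose(arr, (3, 2, 1, 0))
    sp = nii.header.get_zooms()[:3]
    origin = nii.affine[:3, 3]
    return DisplacementField(vectors, spacing=(sp[2], sp[1], sp[0]),
                             origin=(origin[2], origin[1], origin[0]))
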