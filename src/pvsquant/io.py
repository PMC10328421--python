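"""NIfTI-1 and JSON/CSV I/O.

Volumes are stored as NIfTI-1 (.nii / .nii.gz) with the affine carried in
qform and sform; voxel indices are 0-based with world coordinates in mm
(RAS+). Masks round-trip as uint8, intensities as float32/float64.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .image import BinaryMask, ImageVolume


def read_volume(path: str | Path, modality: str = "derived") -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ImageVolume(data, np.asarray(img.affine), modality)


def write_volume(vol: ImageVolume, path: str | Path, dtype=np.float64) -> None:
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    img.header.set_qform(vol.affine, code=1)
    img.header.set_sform(vol.affine, code=1)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return BinaryMask(data > 0, np.asarray(img.affine))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_qform(mask.affine, code=1)
    img.header.set_sform(mask.affine, code=1)
    nib.save(img, str(path))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
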