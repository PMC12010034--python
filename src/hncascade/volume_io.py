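"""NIfTI volume I/O and cohort assembly.

All volumes are held in a canonical RAS+ axis order with a diagonal affine:
voxel (i, j, k) sits at physical position ``origin + (i*sx, j*sy, k*sz)`` mm.
Files read through :func:`read_volume` are reoriented to this convention, so
every downstream module (cropping, dilation, metrics) can assume one frame.

A cohort on disk is one directory per case::

    <root>/<case_id>/midRT_T2w.nii.gz
    <root>/<case_id>/preRT_T2w_registered.nii.gz
    <root>/<case_id>/preRT_mask_registered.nii.gz
    <root>/<case_id>/midRT_mask.nii.gz          (optional at inference)

Labels are 0 = background, 1 = GTVp (primary gross tumor volume),
2 = GTVn (metastatic lymph nodes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

VALID_LABELS = (0, 1, 2)

MID_IMAGE = "midRT_T2w.nii.gz"
PRE_IMAGE = "preRT_T2w_registered.nii.gz"
PRE_MASK = "preRT_mask_registered.nii.gz"
MID_MASK = "midRT_mask.nii.gz"


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel spacing (mm) and physical origin."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def physical_center(self) -> np.ndarray:
        """Physical coordinate (mm) of the grid's center."""
        n = np.asarray(self.shape, dtype=float)
        return np.asarray(self.origin) + (n - 1) / 2.0 * np.asarray(self.spacing)

    def like(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data, self.spacing, self.origin)


@dataclass
class LabelVolume(Volume3D):
    """A Volume3D whose voxels are class labels in {0, 1, 2}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=1e-6):
                raise ValueError("label volume has non-integer voxel values")
            self.data = rounded.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.data), VALID_LABELS)
        if bad.size:
            raise ValueError(f"label volume contains invalid labels {bad.tolist()}")

    def like(self, data: np.ndarray) -> "LabelVolume":
        return LabelVolume(data, self.spacing, self.origin)


@dataclass
class CaseRecord:
    """One patient's registered pre-/mid-radiotherapy bundle."""

    case_id: str
    mid_image: Volume3D
    pre_image_reg: Volume3D
    pre_mask_reg: LabelVolume
    mid_mask: Optional[LabelVolume] = None

    def __post_init__(self) -> None:
        self.validate()

    def volumes(self) -> list[Volume3D]:
        vols = [self.mid_image, self.pre_image_reg, self.pre_mask_reg]
        if self.mid_mask is not None:
            vols.append(self.mid_mask)
        return vols

    def validate(self) -> None:
        ref = self.mid_image
        for v in self.volumes():
            if v.shape != ref.shape:
                raise ValueError(
                    f"case {self.case_id}: volume shape {v.shape} != {ref.shape}"
                )
            if not np.allclose(v.spacing, ref.spacing, atol=1e-4):
                raise ValueError(
                    f"case {self.case_id}: spacing {v.spacing} != {ref.spacing}"
                )


def _canonical(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def read_volume(path: str | os.PathLike, as_label: bool = False) -> Volume3D:
    """Read a NIfTI-1 file into a :class:`Volume3D` (RAS+ canonical order).

    Parameters
    ----------
    path
        Path to a ``.nii`` / ``.nii.gz`` file holding a 3D image.
    as_label
        If True, validate and return a :class:`LabelVolume`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel raises varied types
        raise ValueError(f"unreadable NIfTI header: {path}: {exc}") from exc
    img = _canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    if as_label:
        return LabelVolume(data, zooms, origin)
    return Volume3D(np.asarray(data, dtype=np.float32), zooms, origin)


def write_volume(v: Volume3D, path: str | os.PathLike) -> Path:
    """Write a volume as NIfTI-1; labels are stored with an integer dtype."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(v.spacing) + [1.0])
    affine[:3, 3] = v.origin
    if isinstance(v, LabelVolume):
        data = v.data.astype(np.uint8)
    else:
        data = np.asarray(v.data, dtype=np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def load_case(case_dir: str | os.PathLike, require_mid_mask: bool = True) -> CaseRecord:
    case_dir = Path(case_dir)
    case_id = case_dir.name
    paths = {
        "mid_image": case_dir / MID_IMAGE,
        "pre_image_reg": case_dir / PRE_IMAGE,
        "pre_mask_reg": case_dir / PRE_MASK,
    }
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"case {case_id}: missing {name} file {p}")
    mid_mask_path = case_dir / MID_MASK
    mid_mask = None
    if mid_mask_path.exists():
        mid_mask = read_volume(mid_mask_path, as_label=True)
    elif require_mid_mask:
        raise FileNotFoundError(f"case {case_id}: missing required mid-RT mask {mid_mask_path}")
    return CaseRecord(
        case_id=case_id,
        mid_image=read_volume(paths["mid_image"]),
        pre_image_reg=read_volume(paths["pre_image_reg"]),
        pre_mask_reg=read_volume(paths["pre_mask_reg"], as_label=True),
        mid_mask=mid_mask,
    )


def load_cohort(root: str | os.PathLike, require_mid_mask: bool = True) -> list[CaseRecord]:
    """Load every case under ``root``, sorted by case id."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"cohort root not found: {root}")
    case_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not case_dirs:
        raise FileNotFoundError(f"no case subdirectories under {root}")
    return [load_case(d, require_mid_mask=require_mid_mask) for d in case_dirs]
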