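"""Intensity normalization, grid resampling, anisotropic mask dilation.

The preprocessing chain mirrors what a prior-conditioned longitudinal
segmentation pipeline needs before any network sees a voxel:

* percentile clipping computed over a reference region (the registered
  pre-treatment tumor mask by default) followed by whole-image z-scoring;
* resampling every volume onto one fixed network grid (shape + spacing),
  concentric with the source field of view;
* independent per-class binary dilation of the prior mask with an
  anisotropic structuring element, so that a tumor that shrank and shifted
  between timepoints remains covered by the dilated prior;
* the overlap-ratio audit quantifying exactly that coverage over a cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import CaseRecord, LabelVolume, Volume3D


@dataclass
class NormalizationSpec:
    """Percentile clipping window and the region it is estimated from."""

    low_pct: float = 0.5
    high_pct: float = 99.5
    region: str = "mask_foreground"  # or "nonzero_image"

    def __post_init__(self) -> None:
        if not 0 <= self.low_pct < self.high_pct <= 100:
            raise ValueError(f"need 0 <= low < high <= 100, got ({self.low_pct}, {self.high_pct})")
        if self.region not in ("mask_foreground", "nonzero_image"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class GridSpec:
    """Fixed target grid: shape in voxels and spacing in mm."""

    target_shape: tuple[int, int, int] = (336, 336, 160)
    target_spacing: tuple[float, float, float] = (0.5, 0.5, 2.0)

    def __post_init__(self) -> None:
        self.target_shape = tuple(int(n) for n in self.target_shape)
        self.target_spacing = tuple(float(s) for s in self.target_spacing)
        if any(n <= 0 for n in self.target_shape) or any(s <= 0 for s in self.target_spacing):
            raise ValueError("grid shape and spacing must be positive")


@dataclass
class DilationSpec:
    """Anisotropic dilation radii in voxels and the structuring element shape."""

    radii: tuple[int, int, int] = (6, 6, 3)
    element: str = "ellipsoid"  # or "box"

    def __post_init__(self) -> None:
        self.radii = tuple(int(r) for r in self.radii)
        if any(r < 0 for r in self.radii):
            raise ValueError("dilation radii must be non-negative")
        if self.element not in ("ellipsoid", "box"):
            raise ValueError(f"unknown structuring element {self.element!r}")


def structuring_element(spec: DilationSpec) -> np.ndarray:
    """Boolean footprint of shape (2rx+1, 2ry+1, 2rz+1).

    The ellipsoid contains the integer offsets with
    (dx/rx)^2 + (dy/ry)^2 + (dz/rz)^2 <= 1 (a zero radius pins that axis).
    """
    rx, ry, rz = spec.radii
    dx, dy, dz = np.ogrid[-rx : rx + 1, -ry : ry + 1, -rz : rz + 1]
    if spec.element == "box":
        return np.ones((2 * rx + 1, 2 * ry + 1, 2 * rz + 1), dtype=bool)
    q = np.zeros((2 * rx + 1, 2 * ry + 1, 2 * rz + 1), dtype=float)
    for d, r in ((dx, rx), (dy, ry), (dz, rz)):
        if r > 0:
            q = q + (d / r) ** 2
        else:
            # zero radius: only zero offset admissible along this axis
            q = q + np.where(d == 0, 0.0, np.inf)
    return q <= 1.0 + 1e-12


def clip_normalize(
    image: Volume3D,
    mask: Optional[LabelVolume],
    spec: NormalizationSpec = NormalizationSpec(),
) -> Volume3D:
    """Percentile-clip the whole image, then z-score it.

    Percentiles are computed over the region selected by ``spec`` only
    (tumor-mask foreground, or the nonzero image as fallback); the clip and
    the z-score statistics apply to all voxels.
    """
    data = np.asarray(image.data, dtype=np.float64)
    if spec.region == "mask_foreground":
        if mask is None:
            raise ValueError("mask_foreground normalization requires a mask")
        if mask.shape != image.shape:
            raise ValueError("image and mask shapes differ")
        region = data[mask.data > 0]
        if region.size == 0:
            raise ValueError(
                "normalization region is empty (all-background mask); "
                "fall back to region='nonzero_image'"
            )
    else:
        region = data[data != 0]
        if region.size == 0:
            raise ValueError("normalization region is empty (all-zero image)")
    low, high = np.percentile(region, [spec.low_pct, spec.high_pct])
    clipped = np.clip(data, low, high)
    mean = clipped.mean()
    sd = clipped.std()
    if sd == 0:
        warnings.warn("constant image after clipping; returning all zeros")
        return image.like(np.zeros_like(clipped, dtype=np.float32))
    return image.like(((clipped - mean) / sd).astype(np.float32))


def resample_to_grid(v: Volume3D, grid: GridSpec, is_label: Optional[bool] = None) -> Volume3D:
    """Resample onto the fixed grid, concentric with the source extent.

    Images are interpolated trilinearly, label volumes nearest-neighbor;
    voxels of the target grid outside the source extent become background
    (0 / the image's minimum is *not* used — normalization runs first, so 0
    is the sensible pad value).
    """
    if is_label is None:
        is_label = isinstance(v, LabelVolume)
    src_spacing = np.asarray(v.spacing)
    tgt_shape = np.asarray(grid.target_shape)
    tgt_spacing = np.asarray(grid.target_spacing)
    if tuple(tgt_shape) == v.shape and np.allclose(tgt_spacing, src_spacing):
        return v.like(v.data.copy())
    center = v.physical_center()
    tgt_origin = center - (tgt_shape - 1) / 2.0 * tgt_spacing
    # target index -> source fractional index, axis-separable (diagonal affine)
    coords = np.meshgrid(
        *[
            (tgt_origin[a] + np.arange(tgt_shape[a]) * tgt_spacing[a] - v.origin[a]) / src_spacing[a]
            for a in range(3)
        ],
        indexing="ij",
    )
    order = 0 if is_label else 1
    stacked = np.stack(coords)
    # a voxel has physical extent: only coordinates beyond half a voxel past
    # the edge centers lie outside the source field of view
    valid = np.ones(stacked.shape[1:], dtype=bool)
    for a in range(3):
        valid &= (stacked[a] >= -0.5 - 1e-9) & (stacked[a] <= v.shape[a] - 0.5 + 1e-9)
    out = ndimage.map_coordinates(
        np.asarray(v.data, dtype=np.float32 if not is_label else v.data.dtype),
        stacked,
        order=order,
        mode="nearest",
        prefilter=False,
    )
    out[~valid] = 0
    origin = tuple(float(x) for x in tgt_origin)
    if is_label:
        return LabelVolume(out.astype(np.int16), tuple(tgt_spacing), origin)
    return Volume3D(out.astype(np.float32), tuple(tgt_spacing), origin)


def dilate_mask(mask: LabelVolume, spec: DilationSpec = DilationSpec()) -> LabelVolume:
    """Dilate each tumor class independently with the anisotropic element.

    A voxel reached by both classes keeps its original label if it had one;
    otherwise it takes the class whose nearest original-foreground voxel is
    closer in physical (mm) distance, ties going to GTVn (label 2).
    """
    if all(r == 0 for r in spec.radii):
        return mask.like(mask.data.copy())
    selem = structuring_element(spec)
    data = mask.data
    dil = {}
    for cls in (1, 2):
        m = data == cls
        dil[cls] = ndimage.binary_dilation(m, structure=selem) if m.any() else m
    out = np.zeros_like(data)
    only1 = dil[1] & ~dil[2]
    only2 = dil[2] & ~dil[1]
    both = dil[1] & dil[2]
    out[only1] = 1
    out[only2] = 2
    if both.any():
        resolved = np.where(data[both] > 0, data[both], 0)
        undecided = resolved == 0
        if undecided.any():
            sampling = mask.spacing
            d1 = ndimage.distance_transform_edt(data != 1, sampling=sampling)
            d2 = ndimage.distance_transform_edt(data != 2, sampling=sampling)
            # tie -> GTVn: nodal coverage is the stronger constraint
            nearest = np.where(d1[both][undecided] < d2[both][undecided], 1, 2)
            resolved[undecided] = nearest
        out[both] = resolved
    # original foreground always survives
    fg = data > 0
    out[fg] = data[fg]
    return mask.like(out)


def overlap_ratio(
    mid_mask: LabelVolume, dilated_pre_mask: LabelVolume, class_id: int
) -> Optional[float]:
    """Fraction of mid-RT voxels of ``class_id`` covered by the dilated prior.

    Returns None (undefined) when the mid-RT class is empty; cohort means
    exclude undefined cases.
    """
    if mid_mask.shape != dilated_pre_mask.shape:
        raise ValueError("mask shapes differ")
    mid = mid_mask.data == class_id
    n = int(mid.sum())
    if n == 0:
        return None
    covered = int((mid & (dilated_pre_mask.data == class_id)).sum())
    return covered / n


def cohort_overlap_report(
    cases: Iterable[CaseRecord], spec: DilationSpec = DilationSpec()
) -> pd.DataFrame:
    """Per-case and mean coverage of the mid-RT tumors by the dilated prior.

    One row per case with columns ``gtvp`` / ``gtvn`` (NaN when that class is
    absent at mid-RT), plus a final ``mean`` row averaging the defined cases.
    """
    rows = []
    for case in cases:
        if case.mid_mask is None:
            raise ValueError(f"case {case.case_id} has no mid-RT mask")
        dil = dilate_mask(case.pre_mask_reg, spec)
        r1 = overlap_ratio(case.mid_mask, dil, 1)
        r2 = overlap_ratio(case.mid_mask, dil, 2)
        rows.append(
            {"case_id": case.case_id, "gtvp": np.nan if r1 is None else r1,
             "gtvn": np.nan if r2 is None else r2}
        )
    if not rows:
        raise ValueError("empty cohort")
    df = pd.DataFrame(rows)
    mean_row = {"case_id": "mean", "gtvp": df["gtvp"].mean(), "gtvn": df["gtvn"].mean()}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
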