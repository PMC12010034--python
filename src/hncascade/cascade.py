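"""Coarse-to-fine cascade: input assembly, bounding boxes, crop, paste-back.

The coarse network sees the full fixed grid with an input recipe of one to
three channels (mid-RT image, optionally the dilated pre-RT prior mask and
the registered pre-RT image). Its prediction, unioned with the dilated
prior, anchors a fixed-size crop; the fine network refines inside the crop
from [coarse output, cropped mid-RT image] and the result is pasted back
onto the full grid.

Bounding boxes are half-open voxel intervals [lo, hi), 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np

from . import nn
from .preprocessing import DilationSpec, dilate_mask
from .unet3d import ResUNet3D, predict_scores
from .volume_io import CaseRecord, LabelVolume, Volume3D


class InputRecipe(str, Enum):
    MID_ONLY = "mid_only"
    PREMASK_MID = "premask_mid"
    PREIMG_PREMASK_MID = "preimg_premask_mid"

    @property
    def channels(self) -> int:
        return {InputRecipe.MID_ONLY: 1, InputRecipe.PREMASK_MID: 2,
                InputRecipe.PREIMG_PREMASK_MID: 3}[self]


@dataclass(frozen=True)
class BoundingBox:
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]  # exclusive

    def __post_init__(self):
        if any(l > h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"invalid box lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def center(self) -> tuple[int, int, int]:
        """Truncated integer midpoint of the box."""
        return tuple((l + h) // 2 for l, h in zip(self.lo, self.hi))

    def union(self, other: "BoundingBox") -> "BoundingBox":
        return BoundingBox(tuple(min(a, b) for a, b in zip(self.lo, other.lo)),
                           tuple(max(a, b) for a, b in zip(self.hi, other.hi)))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


@dataclass
class CropSpec:
    crop_shape: tuple[int, int, int] = (256, 256, 96)

    def __post_init__(self):
        self.crop_shape = tuple(int(n) for n in self.crop_shape)
        if any(n <= 0 for n in self.crop_shape):
            raise ValueError("crop shape must be positive")


def assemble_coarse_input(case: CaseRecord, dilated_pre_mask: Optional[LabelVolume],
                          recipe: InputRecipe) -> np.ndarray:
    """Stack the coarse-stage input channels: [pre_image?, prior_mask?, mid].

    The prior-mask channel carries its integer class labels cast to float.
    All volumes must already live on the fixed network grid.
    """
    channels = []
    if recipe == InputRecipe.PREIMG_PREMASK_MID:
        channels.append(np.asarray(case.pre_image_reg.data, dtype=np.float32))
    if recipe in (InputRecipe.PREMASK_MID, InputRecipe.PREIMG_PREMASK_MID):
        if dilated_pre_mask is None:
            raise ValueError(f"recipe {recipe.value} requires the dilated prior mask")
        channels.append(np.asarray(dilated_pre_mask.data, dtype=np.float32))
    channels.append(np.asarray(case.mid_image.data, dtype=np.float32))
    return np.stack(channels)


def mask_bbox(mask: Union[LabelVolume, np.ndarray]) -> Optional[BoundingBox]:
    """Tightest half-open box over all nonzero voxels; None when empty."""
    data = mask.data if isinstance(mask, LabelVolume) else mask
    fg = np.nonzero(data)
    if fg[0].size == 0:
        return None
    lo = tuple(int(ax.min()) for ax in fg)
    hi = tuple(int(ax.max()) + 1 for ax in fg)
    return BoundingBox(lo, hi)


def combined_crop_box(coarse_bbox: Optional[BoundingBox],
                      prior_bbox: Optional[BoundingBox],
                      crop: CropSpec,
                      grid_shape: tuple[int, int, int]) -> BoundingBox:
    """Fixed-shape crop centered on the union of the two boxes, clamped
    inside the grid. With one box empty the other anchors the crop alone."""
    if coarse_bbox is None and prior_bbox is None:
        raise ValueError("both bounding boxes empty; fall back to the grid center")
    if any(c > g for c, g in zip(crop.crop_shape, grid_shape)):
        raise ValueError(f"crop {crop.crop_shape} exceeds grid {grid_shape}")
    if coarse_bbox is None:
        box = prior_bbox
    elif prior_bbox is None:
        box = coarse_bbox
    else:
        box = coarse_bbox.union(prior_bbox)
    center = box.center()
    lo = []
    for c, ext, g in zip(center, crop.crop_shape, grid_shape):
        l = c - ext // 2
        l = max(0, min(l, g - ext))  # translate flush to the faces
        lo.append(l)
    lo = tuple(lo)
    return BoundingBox(lo, tuple(l + e for l, e in zip(lo, crop.crop_shape)))


def grid_center_box(crop: CropSpec, grid_shape: tuple[int, int, int]) -> BoundingBox:
    lo = tuple((g - e) // 2 for g, e in zip(grid_shape, crop.crop_shape))
    return BoundingBox(lo, tuple(l + e for l, e in zip(lo, crop.crop_shape)))


def crop(volume: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Extract the box; works on (X,Y,Z) or leading-channel (C,X,Y,Z) arrays."""
    shape = volume.shape[-3:]
    if any(l < 0 or h > s for l, h, s in zip(box.lo, box.hi, shape)):
        raise ValueError(f"box {box} out of bounds for shape {shape}")
    return volume[(..., *box.slices())]


def paste_back(cropped_labels: np.ndarray, box: BoundingBox,
               grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Write labels into a background-initialized full grid."""
    if tuple(cropped_labels.shape) != box.shape:
        raise ValueError(f"labels shape {cropped_labels.shape} != box shape {box.shape}")
    if any(h > s for h, s in zip(box.hi, grid_shape)):
        raise ValueError(f"box {box} out of bounds for grid {grid_shape}")
    full = np.zeros(grid_shape, dtype=cropped_labels.dtype)
    full[box.slices()] = cropped_labels
    return full


def soft_label_channel(scores: np.ndarray) -> np.ndarray:
    """Differentiable class-expectation channel sum_c c * softmax_c.

    Equals the integer label map wherever the prediction is confident; used
    as the fine stage's coarse-output channel so fine-stage gradients reach
    the coarse network during end-to-end training.
    """
    m = scores.max(axis=0, keepdims=True)
    e = np.exp(scores - m)
    p = e / e.sum(axis=0, keepdims=True)
    classes = np.arange(scores.shape[0], dtype=np.float32).reshape(-1, 1, 1, 1)
    return (p * classes).sum(axis=0)


def coarse_feed_channel(scores: np.ndarray, mode: str = "soft") -> np.ndarray:
    """Encode coarse scores for the fine net: 'soft' expectation, hard
    'labels', or 'onehot' (3 channels)."""
    if mode == "soft":
        return soft_label_channel(scores)[None]
    labels = np.argmax(scores, axis=0)
    if mode == "labels":
        return labels[None].astype(np.float32)
    if mode == "onehot":
        return np.stack([(labels == c) for c in range(scores.shape[0])]).astype(np.float32)
    raise ValueError(f"unknown coarse feed mode {mode!r}")


def fine_in_channels(mode: str = "soft") -> int:
    return 4 if mode == "onehot" else 2


def run_cascade(case: CaseRecord, coarse_net: ResUNet3D, fine_net: ResUNet3D,
                recipe: InputRecipe, crop_spec: CropSpec,
                dilation: DilationSpec = DilationSpec(),
                dilated_prior: Optional[LabelVolume] = None,
                coarse_feed: str = "soft",
                box_anchor: str = "union") -> LabelVolume:
    """Full inference: coarse prediction, anchored crop, fine refinement.

    ``box_anchor``: 'union' centers the crop on the union of the coarse
    foreground box and the dilated-prior box; 'prior_only' ignores the
    coarse box. Falls back to the prior box when the coarse prediction is
    empty, and to the grid center when both are.
    """
    if dilated_prior is None:
        dilated_prior = dilate_mask(case.pre_mask_reg, dilation)
    x = assemble_coarse_input(case, dilated_prior, recipe)
    grid_shape = x.shape[1:]
    scores = predict_scores(coarse_net, x)
    coarse_labels = np.argmax(scores, axis=0)
    coarse_box = None if box_anchor == "prior_only" else mask_bbox(coarse_labels)
    prior_box = mask_bbox(dilated_prior)
    if coarse_box is None and prior_box is None:
        box = grid_center_box(crop_spec, grid_shape)
    else:
        box = combined_crop_box(coarse_box, prior_box, crop_spec, grid_shape)
    feed = coarse_feed_channel(scores, coarse_feed)
    fine_x = np.concatenate([crop(feed, box),
                             crop(case.mid_image.data.astype(np.float32), box)[None]])
    fine_scores = predict_scores(fine_net, fine_x)
    fine_labels = np.argmax(fine_scores, axis=0).astype(np.int16)
    full = paste_back(fine_labels, box, tuple(grid_shape))
    return LabelVolume(full, case.mid_image.spacing, case.mid_image.origin)
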