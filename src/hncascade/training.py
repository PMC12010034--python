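"""End-to-end training of the coarse+fine cascade.

The two stage losses are DiceCE (soft multi-class Dice + cross-entropy),
combined with epoch-dependent weights: the coarse weight decays linearly
from 0.9 to 0.1 over training while the fine weight rises from 0.1 to 0.9,
so early epochs stabilize the localizer and later epochs concentrate on the
refinement. Optimization is AdamW with a triangular cyclic learning rate,
batch size 1. Gradients flow through both stages via the soft coarse-output
channel; the integer crop-box computation is non-differentiable routing.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .cascade import (CropSpec, InputRecipe, assemble_coarse_input,
                      coarse_feed_channel, combined_crop_box, crop,
                      fine_in_channels, grid_center_box, mask_bbox,
                      run_cascade)
from .metrics import EvalPair, dsc_agg
from .preprocessing import (DilationSpec, GridSpec, NormalizationSpec,
                            clip_normalize, dilate_mask, resample_to_grid)
from .unet3d import NetworkSpec, ResUNet3D, build_network
from .volume_io import CaseRecord, LabelVolume


# ---- schedules and configs ----------------------------------------------

@dataclass
class LossSchedule:
    w_coarse_start: float = 0.9
    w_coarse_end: float = 0.1
    w_fine_start: float = 0.1
    w_fine_end: float = 0.9
    total_epochs: int = 200

    def __post_init__(self):
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        for e in (0, self.total_epochs - 1):
            w = self._weights(e)
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("coarse and fine weights must sum to 1")

    def _weights(self, epoch: int) -> tuple[float, float]:
        if self.total_epochs == 1:
            return self.w_coarse_start, self.w_fine_start
        t = epoch / (self.total_epochs - 1)
        wc = self.w_coarse_start + t * (self.w_coarse_end - self.w_coarse_start)
        wf = self.w_fine_start + t * (self.w_fine_end - self.w_fine_start)
        return wc, wf


def loss_weights(epoch: int, sched: LossSchedule) -> tuple[float, float]:
    """Linearly interpolated (w_coarse, w_fine) at ``epoch``; sums to 1."""
    if not 0 <= epoch < sched.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {sched.total_epochs})")
    return sched._weights(epoch)


@dataclass
class AugmentationSpec:
    rotate90: bool = True
    zoom_range: tuple[float, float] = (0.9, 1.1)
    affine_scale_range: tuple[float, float, float] = (0.1, 0.1, 0.1)
    contrast_gamma: tuple[float, float] = (0.9, 1.1)
    gaussian_noise: bool = True
    noise_sd: float = 0.05
    prob: float = 0.2  # per-transform probability


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 1
    learning_rate: float = 3e-5
    weight_decay: float = 1e-2
    lr_cycle_epochs: int = 20
    folds: int = 3
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    augment: bool = True
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    val_interval: int = 1
    include_background_dice: bool = False
    coarse_feed: str = "soft"  # or "labels" / "onehot"

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-6:
            raise ValueError("split fractions must sum to 1")


# ---- losses --------------------------------------------------------------

DICE_SMOOTH = 1e-5


def dice_ce_loss(scores: nn.Tensor, truth: np.ndarray,
                 include_background: bool = False) -> nn.Tensor:
    """Soft multi-class Dice loss + mean voxel-wise cross-entropy.

    ``scores``: (N, 3, X, Y, Z) unnormalized; ``truth``: (X, Y, Z) or
    (N, X, Y, Z) integer labels. The Dice term averages the tumor classes
    (background excluded by default); smoothing 1e-5 guards empty classes.
    """
    if truth.ndim == scores.ndim - 2:
        truth = truth[None]
    n_cls = scores.shape[1]
    if truth.shape != (scores.shape[0],) + scores.shape[2:]:
        raise ValueError(f"truth shape {truth.shape} incompatible with scores {scores.shape}")
    onehot = np.stack([(truth == c) for c in range(n_cls)], axis=1).astype(np.float32)
    logp = nn.log_softmax(scores, axis=1)
    nvox = float(truth.size)
    ce = nn.mul(nn.tsum(nn.mul(logp, nn.Tensor(onehot))), -1.0 / nvox)
    p = nn.exp(logp)
    classes = range(n_cls) if include_background else range(1, n_cls)
    dice_losses = []
    for c in classes:
        pc = p[:, c]
        tc = onehot[:, c]
        inter = nn.tsum(nn.mul(pc, nn.Tensor(tc)))
        denom = nn.tsum(pc) + float(tc.sum())
        dice = nn.div(2.0 * inter + DICE_SMOOTH, denom + DICE_SMOOTH)
        dice_losses.append(1.0 - dice)
    dice_term = dice_losses[0]
    for d in dice_losses[1:]:
        dice_term = dice_term + d
    return ce + nn.mul(dice_term, 1.0 / len(dice_losses))


def total_loss(coarse_loss: nn.Tensor, fine_loss: nn.Tensor, epoch: int,
               sched: LossSchedule) -> nn.Tensor:
    wc, wf = loss_weights(epoch, sched)
    return nn.mul(coarse_loss, wc) + nn.mul(fine_loss, wf)


# ---- folds ---------------------------------------------------------------

def make_folds(case_ids: Sequence[str], k: int = 3,
               split: tuple[float, float, float] = (0.8, 0.1, 0.1),
               seed: int = 0) -> list[dict[str, list[str]]]:
    """k rotations of a seeded train/val/test partition.

    The ids are shuffled once; fold i rotates the shuffled list by
    ``i * n // k`` and takes the leading val/test fractions, so folds share
    one permutation and differ only in which slices are held out.
    """
    ids = list(case_ids)
    n = len(ids)
    n_val = max(1, round(split[1] * n))
    n_test = max(1, round(split[2] * n))
    if n_val + n_test >= n:
        raise ValueError(f"too few cases ({n}) for split {split}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    folds = []
    for i in range(k):
        rot = perm[i * n // k:] + perm[: i * n // k]
        folds.append({"val": sorted(rot[:n_val]),
                      "test": sorted(rot[n_val:n_val + n_test]),
                      "train": sorted(rot[n_val + n_test:])})
    return folds


# ---- data preparation ----------------------------------------------------

@dataclass
class PreparedCase:
    """A case normalized, resampled to the network grid, prior dilated."""
    case: CaseRecord          # normalized volumes on the fixed grid
    prior: LabelVolume        # dilated pre-RT mask on the fixed grid


def prepare_case(case: CaseRecord, grid: GridSpec,
                 norm: NormalizationSpec = NormalizationSpec(),
                 dilation: DilationSpec = DilationSpec()) -> PreparedCase:
    """Normalize (prior-mask region, nonzero fallback), resample, dilate."""
    try:
        mid = clip_normalize(case.mid_image, case.pre_mask_reg, norm)
        pre = clip_normalize(case.pre_image_reg, case.pre_mask_reg, norm)
    except ValueError:
        fallback = replace(norm, region="nonzero_image")
        mid = clip_normalize(case.mid_image, None, fallback)
        pre = clip_normalize(case.pre_image_reg, None, fallback)
    mid = resample_to_grid(mid, grid, is_label=False)
    pre = resample_to_grid(pre, grid, is_label=False)
    pre_mask = resample_to_grid(case.pre_mask_reg, grid, is_label=True)
    mid_mask = (resample_to_grid(case.mid_mask, grid, is_label=True)
                if case.mid_mask is not None else None)
    prior = dilate_mask(pre_mask, dilation)
    prepped = CaseRecord(case.case_id, mid, pre, pre_mask, mid_mask)
    return PreparedCase(prepped, prior)


# ---- augmentation --------------------------------------------------------

def augment_arrays(images: list[np.ndarray], labels: list[np.ndarray],
                   spec: AugmentationSpec, rng: np.random.Generator
                   ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Seeded augmentation; geometric transforms hit images and labels
    identically, intensity transforms hit images only."""
    images = [im.copy() for im in images]
    labels = [lb.copy() for lb in labels]

    if spec.rotate90 and rng.random() < spec.prob:
        k = int(rng.integers(1, 4))
        images = [np.rot90(im, k, axes=(0, 1)).copy() for im in images]
        labels = [np.rot90(lb, k, axes=(0, 1)).copy() for lb in labels]

    scale = np.ones(3)
    if rng.random() < spec.prob:  # isotropic zoom
        scale *= rng.uniform(*spec.zoom_range)
    if rng.random() < spec.prob:  # anisotropic affine scaling
        s = np.asarray(spec.affine_scale_range)
        scale *= 1.0 + rng.uniform(-s, s)
    if not np.allclose(scale, 1.0):
        shape = np.asarray(images[0].shape, dtype=float)
        center = (shape - 1) / 2.0
        matrix = np.diag(1.0 / scale)
        offset = center - matrix @ center
        images = [ndimage.affine_transform(im, matrix, offset=offset, order=1,
                                           mode="constant", cval=0.0) for im in images]
        labels = [ndimage.affine_transform(lb, matrix, offset=offset, order=0,
                                           mode="constant", cval=0.0,
                                           output=lb.dtype) for lb in labels]

    if rng.random() < spec.prob:  # gamma contrast, images only
        gamma = rng.uniform(*spec.contrast_gamma)
        out = []
        for im in images:
            lo, hi = im.min(), im.max()
            if hi > lo:
                im = ((im - lo) / (hi - lo)) ** gamma * (hi - lo) + lo
            out.append(im.astype(np.float32))
        images = out
    if spec.gaussian_noise and rng.random() < spec.prob:
        images = [im + rng.normal(0, spec.noise_sd, im.shape).astype(np.float32)
                  for im in images]
    return images, labels


# ---- training loop -------------------------------------------------------

@dataclass
class TrainResult:
    coarse_net: ResUNet3D
    fine_net: ResUNet3D
    history: pd.DataFrame
    best_epoch: int
    best_val: float
    mode: str


def _val_dscagg(prepared: list[PreparedCase], coarse: ResUNet3D, fine: ResUNet3D,
                recipe: InputRecipe, crop_spec: CropSpec, coarse_feed: str
                ) -> tuple[float, float]:
    pairs = []
    for pc in prepared:
        pred = run_cascade(pc.case, coarse, fine, recipe, crop_spec,
                           dilated_prior=pc.prior, coarse_feed=coarse_feed)
        pairs.append(EvalPair(truth=pc.case.mid_mask, pred=pred))
    v1 = dsc_agg(pairs, 1)
    v2 = dsc_agg(pairs, 2)
    return (np.nan if v1 is None else v1, np.nan if v2 is None else v2)


def train(train_cases: list[PreparedCase], val_cases: list[PreparedCase],
          recipe: InputRecipe, network: NetworkSpec, crop_spec: CropSpec,
          config: TrainConfig, sched: Optional[LossSchedule] = None,
          mode: str = "end_to_end", verbose: bool = False) -> TrainResult:
    """Train the cascade on prepared cases.

    ``mode='end_to_end'`` optimizes both networks jointly under the
    dynamically weighted total loss; ``mode='separate'`` first trains the
    coarse net alone, then the fine net against the frozen coarse output.
    """
    if mode not in ("end_to_end", "separate"):
        raise ValueError(f"unknown mode {mode!r}")
    sched = sched or LossSchedule(total_epochs=config.epochs)
    coarse_spec = replace(network, in_channels=recipe.channels)
    fine_spec = replace(network, in_channels=fine_in_channels(config.coarse_feed))
    coarse = build_network(coarse_spec, seed=config.seed)
    fine = build_network(fine_spec, seed=config.seed + 1)
    params = coarse.parameters() + fine.parameters()
    opt = nn.AdamW(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    lr_sched = nn.CyclicLR(opt, base_lr=config.learning_rate / 10,
                           max_lr=config.learning_rate,
                           cycle_epochs=config.lr_cycle_epochs)
    opt_coarse = nn.AdamW(coarse.parameters(), lr=config.learning_rate,
                          weight_decay=config.weight_decay)
    opt_fine = nn.AdamW(fine.parameters(), lr=config.learning_rate,
                        weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 12345)
    class_vals = None
    rows = []
    best = (-np.inf, 0, None, None)  # (score, epoch, coarse_state, fine_state)

    def forward_case(pc: PreparedCase, epoch: int, phase: str):
        """Returns (loss1, loss2) tensors; loss2 None in coarse-only phase."""
        nonlocal class_vals
        mid = pc.case.mid_image.data.astype(np.float32)
        pre = pc.case.pre_image_reg.data.astype(np.float32)
        prior = pc.prior.data
        truth = pc.case.mid_mask.data
        if config.augment and phase != "eval":
            images, lbls = augment_arrays([mid, pre], [prior, truth],
                                          config.augmentation, rng)
            mid, pre = images
            prior, truth = lbls
        channels = []
        if recipe == InputRecipe.PREIMG_PREMASK_MID:
            channels.append(pre)
        if recipe in (InputRecipe.PREMASK_MID, InputRecipe.PREIMG_PREMASK_MID):
            channels.append(prior.astype(np.float32))
        channels.append(mid)
        x = nn.Tensor(np.stack(channels)[None])
        s1 = coarse(x)
        loss1 = dice_ce_loss(s1, truth, config.include_background_dice)
        if phase == "coarse_only":
            return loss1, None
        if phase == "fine_only":
            s1 = nn.Tensor(s1.data)  # frozen coarse: cut the graph
        grid_shape = mid.shape
        coarse_labels = np.argmax(s1.data[0], axis=0)
        cb = mask_bbox(coarse_labels)
        pb = mask_bbox(prior)
        if cb is None and pb is None:
            box = grid_center_box(crop_spec, grid_shape)
        else:
            box = combined_crop_box(cb, pb, crop_spec, grid_shape)
        sl = (slice(None), slice(None)) + box.slices()
        if config.coarse_feed == "soft" and phase == "joint":
            if class_vals is None or class_vals.shape[1] != s1.shape[1]:
                class_vals = np.arange(s1.shape[1], dtype=np.float32).reshape(1, -1, 1, 1, 1)
            p = nn.softmax(s1, axis=1)
            feed = nn.tsum(nn.mul(p, nn.Tensor(class_vals)), axis=1, keepdims=True)
            feed_c = feed[sl]
        else:
            feed_np = coarse_feed_channel(s1.data[0], config.coarse_feed)
            feed_c = nn.Tensor(crop(feed_np, box)[None])
        mid_c = nn.Tensor(crop(mid, box)[None, None])
        s2 = fine(nn.concat([feed_c, mid_c], axis=1))
        loss2 = dice_ce_loss(s2, crop(truth, box), config.include_background_dice)
        return loss1, loss2

    def run_epochs(n_epochs: int, phase: str, optimizer, label: str):
        nonlocal best
        for epoch in range(n_epochs):
            optimizer.lr = lr_sched.lr_at(epoch)
            wc, wf = loss_weights(min(epoch, sched.total_epochs - 1), sched)
            order = rng.permutation(len(train_cases))
            l1s, l2s, tots = [], [], []
            t0 = time.time()
            for idx in order:
                coarse.train(phase != "fine_only")
                fine.train(phase in ("joint",) or phase == "fine_only")
                loss1, loss2 = forward_case(train_cases[idx], epoch, phase)
                if phase == "joint":
                    loss = total_loss(loss1, loss2, min(epoch, sched.total_epochs - 1), sched)
                elif phase == "coarse_only":
                    loss = loss1
                else:
                    loss = loss2
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"non-finite loss at {label} epoch {epoch} "
                        f"(loss1={loss1.item() if loss1 else None})")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                l1s.append(loss1.item() if loss1 is not None else np.nan)
                l2s.append(loss2.item() if loss2 is not None else np.nan)
                tots.append(loss.item())
            row = {"phase": label, "epoch": epoch, "lr": optimizer.lr,
                   "w_coarse": wc, "w_fine": wf,
                   "loss1": float(np.nanmean(l1s)) if np.isfinite(l1s).any() else np.nan,
                   "loss2": float(np.nanmean(l2s)) if np.isfinite(l2s).any() else np.nan,
                   "total": float(np.mean(tots)),
                   "val_dscagg_gtvp": np.nan, "val_dscagg_gtvn": np.nan}
            validate = (val_cases and phase != "coarse_only"
                        and (epoch % config.val_interval == 0 or epoch == n_epochs - 1))
            if validate:
                coarse.eval(); fine.eval()
                v1, v2 = _val_dscagg(val_cases, coarse, fine, recipe, crop_spec,
                                     config.coarse_feed)
                row["val_dscagg_gtvp"], row["val_dscagg_gtvn"] = v1, v2
                score = np.nanmean([v1, v2])
                if np.isfinite(score) and score > best[0]:
                    best = (score, epoch, coarse.state_dict(), fine.state_dict())
            rows.append(row)
            if verbose:
                print(f"[{label}] epoch {epoch:3d} total {row['total']:.4f} "
                      f"val ({row['val_dscagg_gtvp']:.3f}, {row['val_dscagg_gtvn']:.3f}) "
                      f"{time.time()-t0:.1f}s", flush=True)

    if mode == "end_to_end":
        run_epochs(config.epochs, "joint", opt, "joint")
    else:
        # same total epoch budget as the joint run, split across the two
        # phases, so the comparison is at equal compute
        n_coarse = config.epochs // 2
        run_epochs(n_coarse, "coarse_only", opt_coarse, "coarse")
        run_epochs(config.epochs - n_coarse, "fine_only", opt_fine, "fine")

    if best[2] is not None:
        coarse.load_state_dict(best[2])
        fine.load_state_dict(best[3])
    coarse.eval(); fine.eval()
    history = pd.DataFrame(rows)
    return TrainResult(coarse, fine, history, best_epoch=best[1],
                       best_val=best[0] if np.isfinite(best[0]) else np.nan,
                       mode=mode)
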