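"""Synthetic longitudinal phantom cohorts.

Each case is a registered pre-/mid-treatment pair on one grid: ellipsoidal
GTVp and GTVn lesions with smoothly perturbed boundaries over a textured
background. Between timepoints each lesion shrinks (sub-level set of the
same lesion field, so regression removes the outer shell first), shifts by
an integer voxel offset, and nodes may disappear entirely; the mid image is
regenerated with fresh noise and a global intensity drift.

With integer shifts inside the dilation footprint and shrink factors <= 1,
the mid-treatment lesion is a shifted subset of the pre-treatment lesion,
so coverage by the dilated prior holds exactly — the geometric premise of
prior-mask conditioning, testable without approximation.

Contrast defaults are deliberately low (lesion offset comparable to the
noise), so segmenting the mid image alone at miniature scale is hard and
the benefit of the prior channel is visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .preprocessing import GridSpec
from .volume_io import (MID_IMAGE, MID_MASK, PRE_IMAGE, PRE_MASK, CaseRecord,
                        LabelVolume, Volume3D, write_volume)


@dataclass
class PhantomSpec:
    grid: GridSpec = field(default_factory=lambda: GridSpec((48, 48, 32), (1.0, 1.0, 2.0)))
    n_cases: int = 15
    gtvp_count: int = 1
    gtvn_count_range: tuple[int, int] = (2, 3)
    gtvp_radius_range_mm: tuple[float, float] = (5.0, 9.0)
    gtvn_radius_range_mm: tuple[float, float] = (4.0, 6.5)
    shrink_factor_range: tuple[float, float] = (0.6, 1.0)
    shift_range_voxels: tuple[int, int, int] = (3, 3, 1)
    background_level: float = 100.0
    texture_sd: float = 10.0
    texture_sigma_mm: float = 4.0
    lesion_contrast: dict[int, float] = field(default_factory=lambda: {1: 10.0, 2: 12.0})
    noise_sd: float = 6.0
    boundary_perturbation: float = 0.12
    drift_sd: float = 0.03
    gtvn_disappear_prob: float = 0.1
    # confounder lesions: tumor-like bright structures (vessels, glands,
    # normal nodes on T2w) present at both timepoints but absent from the
    # masks; they are what makes intensity-only segmentation ambiguous and
    # the prior informative. Kept outside the dilated prior's reach.
    confounder_count_range: tuple[int, int] = (2, 4)
    confounder_gap_mm: float = 8.0
    # minimum separation between GTVp and GTVn structures; kept above twice
    # the largest shift so every mid-RT voxel is nearer its own class's
    # pre-RT lesion than the other class's (exact prior coverage)
    min_class_gap_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.gtvn_disappear_prob <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if self.shrink_factor_range[0] <= 0:
            raise ValueError("shrink factors must be positive")


@dataclass
class LesionRecord:
    class_id: int
    center_vox: tuple[int, int, int]
    radii_mm: tuple[float, float, float]
    shrink: float
    shift_vox: tuple[int, int, int]
    disappeared: bool


def _smooth_field(shape, spacing, sigma_mm, rng) -> np.ndarray:
    sigma_vox = [sigma_mm / s for s in spacing]
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def _lesion_field(shape, spacing, center_vox, radii_mm, perturbation, rng
                  ) -> np.ndarray:
    """Normalized 'radius' field: the lesion is the sub-level set <= 1."""
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                         indexing="ij")
    q = np.zeros(shape)
    for ax in range(3):
        c = center_vox[ax] * spacing[ax]
        q += ((coords[ax] - c) / radii_mm[ax]) ** 2
    r = np.sqrt(q)
    if perturbation > 0:
        r = r + perturbation * _smooth_field(shape, spacing, 4.0, rng) * np.clip(r, 0, 2) / 2
    return r


def _draw_lesion(shape, spacing, radius_range, shift_range, margin_extra, rng
                 ) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Sample center and radii such that the dilated lesion plus the largest
    admissible shift stays inside the grid (bounded retries)."""
    for _ in range(100):
        radii = tuple(float(rng.uniform(*radius_range)) for _ in range(3))
        ok = True
        center = []
        for ax in range(3):
            # 1.3x pads for the smooth boundary perturbation's outward reach
            margin = int(np.ceil(1.3 * radii[ax] / spacing[ax])) + shift_range[ax] + margin_extra[ax] + 1
            if 2 * margin >= shape[ax]:
                ok = False
                break
            center.append(int(rng.integers(margin, shape[ax] - margin)))
        if ok:
            return tuple(center), radii
    raise RuntimeError("could not place lesion inside the grid; enlarge it or shrink lesions")


def generate_case(spec: PhantomSpec, case_seed: int, case_id: Optional[str] = None
                  ) -> tuple[CaseRecord, list[LesionRecord]]:
    """Generate one registered pre/mid phantom pair plus its manifest."""
    rng = np.random.default_rng(case_seed)
    shape = spec.grid.target_shape
    spacing = spec.grid.target_spacing
    case_id = case_id or f"case_{case_seed:05d}"

    lesions: list[LesionRecord] = []
    pre_mask = np.zeros(shape, dtype=np.int16)
    mid_mask = np.zeros(shape, dtype=np.int16)
    n_gtvn = int(rng.integers(spec.gtvn_count_range[0], spec.gtvn_count_range[1] + 1))
    classes = [1] * spec.gtvp_count + [2] * n_gtvn
    for cls in classes:
        rng_lesion = np.random.default_rng(rng.integers(0, 2**31))
        radius_range = (spec.gtvp_radius_range_mm if cls == 1
                        else spec.gtvn_radius_range_mm)
        # redraw until the lesion is disjoint from every earlier one: each
        # pre-RT voxel must keep its own class for the dilated prior to
        # cover the shifted mid-RT lesion exactly
        other = pre_mask == (2 if cls == 1 else 1)
        if other.any():
            other_dist = ndimage.distance_transform_edt(~other, sampling=spacing)
        else:
            other_dist = None
        placed = False
        for _ in range(60):
            center, radii = _draw_lesion(shape, spacing, radius_range,
                                         spec.shift_range_voxels, (0, 0, 0), rng_lesion)
            field_r = _lesion_field(shape, spacing, center, radii,
                                    spec.boundary_perturbation, rng_lesion)
            pre_set = field_r <= 1.0
            if not pre_set.any() or (pre_set & (pre_mask > 0)).any():
                continue
            if other_dist is not None and other_dist[pre_set].min() < spec.min_class_gap_mm:
                continue
            placed = True
            break
        if not placed:
            if cls == 2:
                continue  # drop an unplaceable node; count is random anyway
            raise RuntimeError("could not place the primary lesion disjointly")
        shrink = float(rng_lesion.uniform(*spec.shrink_factor_range))
        shift = tuple(int(rng_lesion.integers(-s, s + 1)) for s in spec.shift_range_voxels)
        disappeared = cls == 2 and rng_lesion.random() < spec.gtvn_disappear_prob
        # mid lesion: sub-level set of the same field (outer shell regresses
        # first), then an integer shift -> exact subset of the shifted pre set
        mid_set = np.roll(field_r <= min(shrink, 1.0), shift, axis=(0, 1, 2))
        pre_mask[pre_set] = cls
        if not disappeared:
            mid_set &= mid_mask == 0
            mid_mask[mid_set] = cls
        lesions.append(LesionRecord(cls, center, radii, shrink, shift, disappeared))

    # confounders: same intensity profile as a tumor class, in the image at
    # both timepoints, never in a mask, never within reach of the dilated prior
    conf_offset = np.zeros(shape, dtype=np.float64)
    n_conf = int(rng.integers(spec.confounder_count_range[0],
                              spec.confounder_count_range[1] + 1))
    if n_conf and (pre_mask > 0).any():
        lesion_dist = ndimage.distance_transform_edt(pre_mask == 0, sampling=spacing)
    else:
        lesion_dist = None
    n_placed_conf = 0
    for _ in range(n_conf):
        rng_conf = np.random.default_rng(rng.integers(0, 2**31))
        cls_like = 1 if rng_conf.random() < 0.3 else 2
        radius_range = (spec.gtvp_radius_range_mm if cls_like == 1
                        else spec.gtvn_radius_range_mm)
        for _ in range(60):
            center, radii = _draw_lesion(shape, spacing, radius_range,
                                         (0, 0, 0), (0, 0, 0), rng_conf)
            field_r = _lesion_field(shape, spacing, center, radii,
                                    spec.boundary_perturbation, rng_conf)
            conf_set = field_r <= 1.0
            if not conf_set.any() or (conf_set & (conf_offset > 0)).any():
                continue
            if lesion_dist is not None and lesion_dist[conf_set].min() < spec.confounder_gap_mm:
                continue
            conf_offset[conf_set] = spec.lesion_contrast[cls_like]
            n_placed_conf += 1
            break

    def image_from(mask: np.ndarray, rng_img: np.random.Generator, drift: float
                   ) -> np.ndarray:
        img = np.full(shape, spec.background_level, dtype=np.float64)
        img += spec.texture_sd * _smooth_field(shape, spacing, spec.texture_sigma_mm, rng_img)
        for cls, offset in spec.lesion_contrast.items():
            img[mask == cls] += offset
        img += conf_offset
        img += rng_img.normal(0, spec.noise_sd, shape)
        return (img * drift).astype(np.float32)

    pre_img = image_from(pre_mask, np.random.default_rng(rng.integers(0, 2**31)), 1.0)
    drift = float(1.0 + rng.normal(0, spec.drift_sd))
    mid_img = image_from(mid_mask, np.random.default_rng(rng.integers(0, 2**31)), drift)

    record = CaseRecord(
        case_id=case_id,
        mid_image=Volume3D(mid_img, spacing),
        pre_image_reg=Volume3D(pre_img, spacing),
        pre_mask_reg=LabelVolume(pre_mask, spacing),
        mid_mask=LabelVolume(mid_mask, spacing),
    )
    return record, lesions, n_placed_conf


def generate_cases(spec: PhantomSpec) -> tuple[list[CaseRecord], list[dict]]:
    """Generate the in-memory cohort; all randomness flows from spec.seed."""
    master = np.random.default_rng(spec.seed)
    case_seeds = master.integers(0, 2**31, size=spec.n_cases)
    records, manifest = [], []
    for i, cs in enumerate(case_seeds):
        case_id = f"case_{i:03d}"
        rec, lesions, n_conf = generate_case(spec, int(cs), case_id)
        records.append(rec)
        manifest.append({
            "case_id": case_id, "case_seed": int(cs),
            "n_confounders": n_conf,
            "lesions": [vars(l) for l in lesions],
        })
    return records, manifest


def generate_cohort(spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write the cohort in the on-disk layout plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, manifest = generate_cases(spec)
    for rec in records:
        d = out_dir / rec.case_id
        d.mkdir(exist_ok=True)
        write_volume(rec.mid_image, d / MID_IMAGE)
        write_volume(rec.pre_image_reg, d / PRE_IMAGE)
        write_volume(rec.pre_mask_reg, d / PRE_MASK)
        write_volume(rec.mid_mask, d / MID_MASK)
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=_default, sort_keys=True))
    return out_dir
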