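"""Cohort evaluation metrics: aggregated Dice, surface Dice, 95% HD.

Aggregated Dice (DSCagg) pools intersections and mask sizes over the whole
cohort before taking the ratio::

    DSCagg = 2 * sum_i |A_i ∩ B_i| / sum_i (|A_i| + |B_i|)

which is *not* the mean of per-case Dice scores: a case where both truth
and prediction are empty contributes nothing instead of an arbitrary 0/0.

Surfaces are discretized as the exposed faces of foreground voxels: every
face between a foreground voxel and a 6-neighbor background voxel (or the
volume edge) contributes its center point in physical mm coordinates, with
the face's physical area as weight. Surface Dice at tolerance τ is the
area-weighted fraction of each surface lying within τ of the other,
symmetrized. HD95 takes the 95th percentile (linear interpolation) of the
directed boundary-voxel-center distances in each direction and returns the
larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume_io import LabelVolume

CLASS_NAMES = {1: "GTVp", 2: "GTVn"}


@dataclass
class EvalPair:
    truth: LabelVolume
    pred: LabelVolume

    def __post_init__(self):
        if self.truth.shape != self.pred.shape:
            raise ValueError(f"shape mismatch {self.truth.shape} vs {self.pred.shape}")
        if not np.allclose(self.truth.spacing, self.pred.spacing, atol=1e-4):
            raise ValueError("spacing mismatch between truth and prediction")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.truth.spacing


@dataclass
class SurfaceSpec:
    tolerance_mm: float = 2.0

    def __post_init__(self):
        if self.tolerance_mm < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class CohortScore:
    """Per-class scores and their arithmetic mean; NaN marks undefined."""

    per_class: dict[str, float]

    @property
    def mean(self) -> float:
        vals = [v for v in self.per_class.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        """Report values at print precision (round-half-even, as Python's
        round), mean included."""
        out = {k: round(v, ndigits) for k, v in self.per_class.items()}
        out["mean"] = round(self.mean, ndigits)
        return out


# ---- surface machinery ---------------------------------------------------

_FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def surface_points(mask: np.ndarray, spacing: Sequence[float]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Exposed-face centers (M, 3) in mm and their areas (M,).

    Array edges count as background, so surfaces are always closed.
    """
    sx, sy, sz = spacing
    areas_by_axis = (sy * sz, sy * sz, sx * sz, sx * sz, sx * sy, sx * sy)
    pts, areas = [], []
    m = np.asarray(mask, dtype=bool)
    for (dx, dy, dz), area in zip(_FACE_OFFSETS, areas_by_axis):
        shifted = np.zeros_like(m)
        src = tuple(slice(max(0, -d), m.shape[a] - max(0, d)) for a, d in enumerate((dx, dy, dz)))
        dst = tuple(slice(max(0, d), m.shape[a] - max(0, -d)) for a, d in enumerate((dx, dy, dz)))
        shifted[src] = m[dst]
        exposed = m & ~shifted
        idx = np.argwhere(exposed).astype(float)
        if idx.size == 0:
            continue
        centers = idx * np.asarray(spacing) + 0.5 * np.asarray([dx * sx, dy * sy, dz * sz])
        pts.append(centers)
        areas.append(np.full(len(centers), area))
    if not pts:
        return np.empty((0, 3)), np.empty(0)
    return np.concatenate(pts), np.concatenate(areas)


def boundary_voxel_points(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Centers (mm) of foreground voxels with at least one 6-neighbor
    outside the mask (array edges count as outside)."""
    m = np.asarray(mask, dtype=bool)
    interior = np.ones_like(m)
    for (dx, dy, dz) in _FACE_OFFSETS:
        shifted = np.zeros_like(m)
        src = tuple(slice(max(0, -d), m.shape[a] - max(0, d)) for a, d in enumerate((dx, dy, dz)))
        dst = tuple(slice(max(0, d), m.shape[a] - max(0, -d)) for a, d in enumerate((dx, dy, dz)))
        shifted[src] = m[dst]
        interior &= shifted
    boundary = m & ~interior
    return np.argwhere(boundary) * np.asarray(spacing, dtype=float)


# ---- metrics -------------------------------------------------------------

def dsc_agg(pairs: Sequence[EvalPair], class_id: int) -> Optional[float]:
    """Cohort-aggregated Dice; None when the pooled denominator is zero."""
    if not pairs:
        raise ValueError("empty cohort")
    inter = 0
    sizes = 0
    for p in pairs:
        a = p.truth.data == class_id
        b = p.pred.data == class_id
        inter += int((a & b).sum())
        sizes += int(a.sum()) + int(b.sum())
    if sizes == 0:
        return None
    return 2.0 * inter / sizes


def surface_dsc(pair: EvalPair, class_id: int,
                spec: SurfaceSpec = SurfaceSpec()) -> float:
    """Symmetric surface Dice at tolerance τ (area-weighted).

    Both masks empty → 1.0; exactly one empty → 0.0.
    """
    a = pair.truth.data == class_id
    b = pair.pred.data == class_id
    if not a.any() and not b.any():
        return 1.0
    if not a.any() or not b.any():
        return 0.0
    pa, wa = surface_points(a, pair.spacing)
    pb, wb = surface_points(b, pair.spacing)
    tol = spec.tolerance_mm + 1e-9  # absorb float rounding at exact tolerance
    da = cKDTree(pb).query(pa, k=1)[0]
    db = cKDTree(pa).query(pb, k=1)[0]
    num = wa[da <= tol].sum() + wb[db <= tol].sum()
    return float(num / (wa.sum() + wb.sum()))


def hd95(pair: EvalPair, class_id: int, percentile: float = 95.0) -> Optional[float]:
    """95th-percentile symmetric Hausdorff distance in mm.

    Computed between boundary-voxel centers; each direction is summarized
    by its ``percentile`` (linear interpolation) and the max of the two
    directions is returned. None (undefined) when either mask is empty.
    """
    a = pair.truth.data == class_id
    b = pair.pred.data == class_id
    if not a.any() or not b.any():
        return None
    pa = boundary_voxel_points(a, pair.spacing)
    pb = boundary_voxel_points(b, pair.spacing)
    dab = cKDTree(pb).query(pa, k=1)[0]
    dba = cKDTree(pa).query(pb, k=1)[0]
    return float(max(np.percentile(dab, percentile), np.percentile(dba, percentile)))


def score_cohort(pairs: Sequence[EvalPair],
                 metrics: Sequence[str] = ("dscagg", "surface", "hd95"),
                 surface_spec: SurfaceSpec = SurfaceSpec(),
                 class_ids: Sequence[int] = (1, 2)
                 ) -> tuple[dict[str, CohortScore], pd.DataFrame]:
    """Cohort summary per metric plus the per-case long-format table.

    DSCagg is pooled per its formula; surface Dice and HD95 are averaged
    over the cases where they are defined.
    """
    if not pairs:
        raise ValueError("empty cohort")
    rows = []
    for i, pair in enumerate(pairs):
        for cid in class_ids:
            cname = CLASS_NAMES.get(cid, str(cid))
            if "surface" in metrics:
                v = surface_dsc(pair, cid, surface_spec)
                rows.append({"case": i, "class": cname, "metric": "surface",
                             "value": v, "defined": True})
            if "hd95" in metrics:
                v = hd95(pair, cid)
                rows.append({"case": i, "class": cname, "metric": "hd95",
                             "value": np.nan if v is None else v,
                             "defined": v is not None})
    percase = pd.DataFrame(rows, columns=["case", "class", "metric", "value", "defined"])
    scores: dict[str, CohortScore] = {}
    if "dscagg" in metrics:
        per = {}
        for cid in class_ids:
            v = dsc_agg(pairs, cid)
            per[CLASS_NAMES.get(cid, str(cid))] = np.nan if v is None else v
        scores["dscagg"] = CohortScore(per)
    for metric in ("surface", "hd95"):
        if metric in metrics:
            per = {}
            for cid in class_ids:
                cname = CLASS_NAMES.get(cid, str(cid))
                sel = percase[(percase["metric"] == metric)
                              & (percase["class"] == cname) & percase["defined"]]
                per[cname] = float(sel["value"].mean()) if len(sel) else np.nan
            scores[metric] = CohortScore(per)
    return scores, percase
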