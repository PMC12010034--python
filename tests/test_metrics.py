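import numpy as np
import pytest

from hncascade.metrics import (CohortScore, EvalPair, SurfaceSpec, dsc_agg,
                               hd95, score_cohort, surface_dsc)
from hncascade.volume_io import LabelVolume

from conftest import random_label_volume


# ---- brute-force oracles (independent of the implementation) -------------

FACES = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def oracle_surface(mask, spacing):
    """Loop-based exposed-face enumeration: (points_mm, areas)."""
    pts, areas = [], []
    sx, sy, sz = spacing
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for (dx, dy, dz) in FACES:
                    n = (x + dx, y + dy, z + dz)
                    outside = not (0 <= n[0] < nx and 0 <= n[1] < ny and 0 <= n[2] < nz)
                    if outside or not mask[n]:
                        pts.append((x * sx + dx * sx / 2,
                                    y * sy + dy * sy / 2,
                                    z * sz + dz * sz / 2))
                        areas.append({0: sy * sz, 1: sx * sz, 2: sx * sy}[
                            (0 if dx else (1 if dy else 2))])
    return np.array(pts), np.array(areas)


def oracle_surface_dsc(a, b, spacing, tol):
    if not a.any() and not b.any():
        return 1.0
    if not a.any() or not b.any():
        return 0.0
    pa, wa = oracle_surface(a, spacing)
    pb, wb = oracle_surface(b, spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    t = tol + 1e-9
    num = wa[d.min(axis=1) <= t].sum() + wb[d.min(axis=0) <= t].sum()
    return num / (wa.sum() + wb.sum())


def oracle_boundary(mask, spacing):
    pts = []
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for (dx, dy, dz) in FACES:
                    n = (x + dx, y + dy, z + dz)
                    outside = not (0 <= n[0] < nx and 0 <= n[1] < ny and 0 <= n[2] < nz)
                    if outside or not mask[n]:
                        pts.append((x * spacing[0], y * spacing[1], z * spacing[2]))
                        break
    return np.array(pts)


def oracle_hd95(a, b, spacing, pct=95.0):
    pa = oracle_boundary(a, spacing)
    pb = oracle_boundary(b, spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(np.percentile(d.min(axis=1), pct), np.percentile(d.min(axis=0), pct))


def _pair(truth, pred, spacing=(1, 1, 2)):
    return EvalPair(LabelVolume(truth, spacing), LabelVolume(pred, spacing))


class TestDscAgg:
    def test_perfect_prediction(self, rng):
        vols = [random_label_volume(rng) for _ in range(3)]
        pairs = [EvalPair(v, v.like(v.data.copy())) for v in vols]
        assert dsc_agg(pairs, 1) == 1.0

    def test_all_empty_predictions(self, rng):
        vols = [random_label_volume(rng) for _ in range(3)]
        pairs = [EvalPair(v, v.like(np.zeros_like(v.data))) for v in vols]
        assert dsc_agg(pairs, 1) == 0.0

    def test_pooled_aggregation_not_mean_of_dice(self):
        """(|A∩B|,|A|,|B|) = (3,4,5) and (0,2,0) pool to 6/11 — while the
        mean of per-case Dice would be (2*3/9 + 0)/2 = 1/3."""
        t1 = np.zeros((4, 4, 2), dtype=np.int16); t1[0, :4, 0] = 1
        p1 = np.zeros_like(t1); p1[0, 1:4, 0] = 1; p1[1, 0:2, 0] = 1
        t2 = np.zeros_like(t1); t2[2, 0:2, 0] = 1
        p2 = np.zeros_like(t1)
        pairs = [_pair(t1, p1), _pair(t2, p2)]
        assert dsc_agg(pairs, 1) == pytest.approx(6 / 11)

    def test_undefined_when_class_absent_everywhere(self, rng):
        z = np.zeros((4, 4, 2), dtype=np.int16)
        assert dsc_agg([_pair(z, z)], 1) is None

    def test_symmetric_and_order_invariant(self, rng):
        pairs = [EvalPair(random_label_volume(rng), random_label_volume(rng))
                 for _ in range(4)]
        swapped = [EvalPair(p.pred, p.truth) for p in pairs]
        assert dsc_agg(pairs, 2) == pytest.approx(dsc_agg(swapped, 2))
        assert dsc_agg(pairs[::-1], 2) == pytest.approx(dsc_agg(pairs, 2))

    def test_invariant_to_splitting_a_case(self, rng):
        t = random_label_volume(rng, shape=(10, 8, 6))
        p = random_label_volume(rng, shape=(10, 8, 6))
        whole = [EvalPair(t, p)]
        halves = [
            _pair(t.data[:5], p.data[:5], t.spacing),
            _pair(t.data[5:], p.data[5:], t.spacing),
        ]
        assert dsc_agg(whole, 1) == pytest.approx(dsc_agg(halves, 1))

    def test_single_pair_equals_classic_dice(self, rng):
        t = random_label_volume(rng)
        p = random_label_volume(rng)
        a, b = t.data == 1, p.data == 1
        classic = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dsc_agg([EvalPair(t, p)], 1) == pytest.approx(classic)


class TestSurfaceDsc:
    def test_identical_masks_any_tolerance(self, rng):
        v = random_label_volume(rng)
        pair = EvalPair(v, v.like(v.data.copy()))
        for tol in (0.0, 1.0, 5.0):
            assert surface_dsc(pair, 1, SurfaceSpec(tol)) == 1.0

    def test_tolerance_beyond_diagonal_gives_one(self, rng):
        t = random_label_volume(rng, shape=(6, 6, 4))
        p = random_label_volume(rng, shape=(6, 6, 4))
        if not (t.data == 1).any() or not (p.data == 1).any():
            pytest.skip("need foreground")
        assert surface_dsc(EvalPair(t, p), 1, SurfaceSpec(1000.0)) == 1.0

    def test_empty_mask_conventions(self):
        z = np.zeros((4, 4, 2), dtype=np.int16)
        f = z.copy(); f[1, 1, 1] = 1
        assert surface_dsc(_pair(z, z), 1) == 1.0
        assert surface_dsc(_pair(z, f), 1) == 0.0
        assert surface_dsc(_pair(f, z), 1) == 0.0

    @pytest.mark.parametrize("spacing", [(1, 1, 1), (1, 1, 2), (0.7, 1.1, 2.3)])
    def test_matches_brute_force_oracle(self, rng, spacing):
        for _ in range(4):
            t = rng.random((7, 6, 5)) < 0.25
            p = rng.random((7, 6, 5)) < 0.25
            if not t.any() or not p.any():
                continue
            pair = _pair(t.astype(np.int16), p.astype(np.int16), spacing)
            for tol in (0.0, 1.0, 2.0):
                got = surface_dsc(pair, 1, SurfaceSpec(tol))
                want = oracle_surface_dsc(t, p, spacing, tol)
                assert got == pytest.approx(want, abs=1e-12)


class TestHd95:
    def test_identical_masks_zero(self, rng):
        v = random_label_volume(rng)
        if not (v.data == 1).any():
            pytest.skip("need foreground")
        assert hd95(EvalPair(v, v.like(v.data.copy())), 1) == 0.0

    def test_singletons_three_voxels_apart(self):
        t = np.zeros((8, 4, 4), dtype=np.int16); t[1, 1, 1] = 1
        p = np.zeros_like(t); p[4, 1, 1] = 1
        assert hd95(_pair(t, p, (1, 1, 2)), 1) == pytest.approx(3.0)

    def test_empty_mask_undefined(self):
        z = np.zeros((4, 4, 2), dtype=np.int16)
        f = z.copy(); f[1, 1, 1] = 1
        assert hd95(_pair(f, z), 1) is None

    @pytest.mark.parametrize("spacing", [(1, 1, 1), (1, 1, 2), (0.6, 1.3, 2.1)])
    def test_matches_brute_force_oracle(self, rng, spacing):
        for _ in range(4):
            t = rng.random((7, 6, 5)) < 0.25
            p = rng.random((7, 6, 5)) < 0.25
            if not t.any() or not p.any():
                continue
            pair = _pair(t.astype(np.int16), p.astype(np.int16), spacing)
            assert hd95(pair, 1) == pytest.approx(oracle_hd95(t, p, spacing), abs=1e-9)


class TestScoreCohort:
    def test_perfect_case(self, rng):
        v = random_label_volume(rng, density=0.3)
        scores, percase = score_cohort([EvalPair(v, v.like(v.data.copy()))])
        assert scores["dscagg"].mean == 1.0
        assert scores["surface"].mean == 1.0
        assert scores["hd95"].mean == 0.0
        assert set(percase.columns) == {"case", "class", "metric", "value", "defined"}

    def test_mean_of_classes_reporting(self):
        cs = CohortScore({"GTVp": 0.500, "GTVn": 0.625})
        assert cs.mean == pytest.approx(0.5625)
        assert cs.rounded(3)["mean"] in (0.562, 0.563)

    def test_undefined_hd_case_excluded_from_mean_only(self, rng):
        t1 = random_label_volume(rng, density=0.3)
        p1 = t1.like(t1.data.copy())
        z = np.zeros(t1.shape, dtype=np.int16)
        t2 = t1.like(t1.data.copy())
        p2 = t1.like(z)  # empty prediction -> HD undefined, surface defined
        scores, percase = score_cohort([EvalPair(t1, p1), EvalPair(t2, p2)])
        hd_rows = percase[(percase.metric == "hd95") & (percase["class"] == "GTVp")]
        assert hd_rows.defined.tolist() == [True, False]
        assert scores["hd95"].per_class["GTVp"] == 0.0  # only the defined case
        assert scores["surface"].per_class["GTVp"] == pytest.approx(0.5)
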