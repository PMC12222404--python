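"""Gamma analysis: brute-force oracle equivalence, worked examples,
monotonicity in the criteria."""

import itertools
import math

import numpy as np
import pytest

from dosekit import (DoseMap, GammaCriteria, SIRT_CRITERIA, VolumetricImage,
                     gamma_map, gamma_pass_table)
from conftest import smooth_random_volume


def _img(values, spacing=4.795):
    return VolumetricImage(np.asarray(values, float), (spacing,) * 3)


def brute_force_gamma(ref: np.ndarray, ev: np.ndarray, spacing: float,
                      dta_mm: float, dd_pct: float, gamma_cap: float = 2.0,
                      refinement: int = 3) -> np.ndarray:
    """Exhaustive gamma: triple loop over every refinement offset in the
    search radius, per-voxel trilinear sampling written independently of the
    production code."""
    ref = np.asarray(ref, float)
    ev = np.asarray(ev, float)
    n = np.asarray(ref.shape)
    dd_abs = dd_pct / 100.0 * ref.max()
    radius = math.ceil(gamma_cap * dta_mm)
    step = spacing / refinement
    m = int(math.floor(radius / step))
    grid = np.stack(np.indices(ref.shape).reshape(3, -1)).astype(float)
    best = np.full(ref.size, gamma_cap ** 2)
    flat_ref = ref.ravel()
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for k in range(-m, m + 1):
                d_mm = np.array([i, j, k]) * step
                dist2 = float(d_mm @ d_mm)
                if dist2 > radius * radius:
                    continue
                p = grid + (d_mm / spacing)[:, None]
                valid = np.all((p >= 0) & (p <= (n - 1)[:, None]), axis=0)
                if not valid.any():
                    continue
                pv = p[:, valid]
                f = np.floor(pv).astype(int)
                w = pv - f
                val = np.zeros(pv.shape[1])
                for corner in itertools.product(*[(0,) if w[a].max() == 0
                                                  else (0, 1)
                                                  for a in range(3)]):
                    wt = np.ones(pv.shape[1])
                    idx = []
                    for a in range(3):
                        wt = wt * (w[a] if corner[a] else 1.0 - w[a])
                        idx.append(np.minimum(f[a] + corner[a], n[a] - 1))
                    val += wt * ev[idx[0], idx[1], idx[2]]
                cand = dist2 / dta_mm ** 2 + (val - flat_ref[valid]) ** 2 / dd_abs ** 2
                best[valid] = np.minimum(best[valid], cand)
    return np.sqrt(np.minimum(best, gamma_cap ** 2)).reshape(ref.shape)


def _seeded_pair(seed, shape=(14, 14, 14), wobble=3.0):
    rng = np.random.default_rng(seed)
    ref = smooth_random_volume(shape, rng, lo=0, hi=100)
    ev = np.abs(ref.values + rng.normal(0, wobble, shape))
    return ref.values, ev


class TestWorkedExamples:
    def test_identity_gamma_zero_and_full_pass(self, rng):
        v = smooth_random_volume((12, 12, 12), rng, lo=0, hi=100)
        for crit in SIRT_CRITERIA:
            res = gamma_map(_img(v.values), _img(v.values.copy()), crit)
            np.testing.assert_allclose(res.gamma, 0.0, atol=1e-12)
            assert res.pass_rate() == 100.0

    def test_single_hot_voxel_half_percent_difference(self):
        ref = np.zeros((9, 9, 9))
        ref[4, 4, 4] = 100.0
        ev = ref.copy()
        ev[4, 4, 4] = 100.5
        res = gamma_map(_img(ref), _img(ev), GammaCriteria(4.795, 1.0))
        # one-term closed form: dose diff 0.5 Gy over a 1 Gy tolerance, no shift
        assert res.gamma[4, 4, 4] == pytest.approx(0.5, abs=1e-9)
        assert res.pass_rate() == 100.0

    def test_hot_voxel_displaced_by_one_voxel_passes(self):
        ref = np.zeros((9, 9, 9))
        ref[4, 4, 4] = 100.0
        ev = np.zeros((9, 9, 9))
        ev[5, 4, 4] = 100.0
        crit = GammaCriteria(4.795, 1.0)
        res = gamma_map(_img(ref), _img(ev), crit)
        assert res.gamma[4, 4, 4] <= 1.0 + 1e-9
        # cross-check against the exhaustive search
        bf = brute_force_gamma(ref, ev, 4.795, 4.795, 1.0)
        assert res.gamma[4, 4, 4] == pytest.approx(bf[4, 4, 4], abs=1e-9)

    def test_half_percent_global_scale_error_full_pass(self):
        ref, _ = _seeded_pair(0)
        res = gamma_map(_img(ref), _img(1.005 * ref), GammaCriteria(4.795, 1.0))
        assert res.pass_rate() == 100.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_tightest_criterion(self, seed):
        ref, ev = _seeded_pair(seed)
        opt = gamma_map(_img(ref), _img(ev), GammaCriteria(4.795, 1.0))
        bf = brute_force_gamma(ref, ev, 4.795, 4.795, 1.0)
        np.testing.assert_allclose(opt.gamma, bf, atol=1e-9)

    @pytest.mark.parametrize("dta,dd,seed", [(10.0, 5.0, 0), (10.0, 5.0, 1),
                                             (15.0, 10.0, 2)])
    def test_matches_brute_force_loose_criteria(self, dta, dd, seed):
        ref, ev = _seeded_pair(seed, shape=(10, 10, 10), wobble=8.0)
        opt = gamma_map(_img(ref), _img(ev), GammaCriteria(dta, dd))
        bf = brute_force_gamma(ref, ev, 4.795, dta, dd)
        np.testing.assert_allclose(opt.gamma, bf, atol=1e-9)


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(10))
    def test_pass_rates_non_decreasing_across_criteria(self, seed):
        ref, ev = _seeded_pair(seed, wobble=6.0)
        rates = [gamma_map(_img(ref), _img(ev), c).pass_rate()
                 for c in SIRT_CRITERIA]
        assert rates[0] <= rates[1] + 1e-12
        assert rates[1] <= rates[2] + 1e-12
        assert all(0 <= r <= 100 for r in rates)

    def test_gamma_non_negative_and_capped(self, rng):
        ref, ev = _seeded_pair(3, wobble=30.0)
        res = gamma_map(_img(ref), _img(ev), GammaCriteria(4.795, 1.0))
        assert (res.gamma >= 0).all()
        assert (res.gamma <= res.gamma_cap + 1e-12).all()


class TestPassTable:
    def test_identity_pair_all_cells_100(self, desk_triplet):
        d = desk_triplet.doses["ASC"]
        small = DoseMap(VolumetricImage(
            d.values[10:26, 10:26, 10:26], d.image.spacing), "ASC")
        table = gamma_pass_table(small, small, _crop_masks(desk_triplet, 10, 26),
                                 SIRT_CRITERIA[:1],
                                 regions=("whole_image", "tumour", "WNL"))
        assert (table.values == 100.0).all()

    def test_grid_mismatch_raises(self, rng):
        a = smooth_random_volume((8, 8, 8), rng)
        b = smooth_random_volume((9, 9, 9), rng)
        with pytest.raises(Exception):
            gamma_map(_img(a.values), VolumetricImage(b.values, (4.795,) * 3),
                      GammaCriteria(4.795, 1.0))


def _crop_masks(triplet, lo, hi):
    from dosekit import SegmentationSet

    lab = triplet.masks.label_volume
    return SegmentationSet(VolumetricImage(
        lab.values[lo:hi, lo:hi, lo:hi], lab.spacing),
        triplet.masks.label_table)
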