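"""Organ-level dosimetry: MADs, DVH properties, rank-sum oracle."""

import itertools

import numpy as np
import pytest

from dosekit import (DoseMap, SegmentationSet, VolumetricImage,
                     compare_mad_distributions, dvh, region_report)
from conftest import smooth_random_volume


def _dose(values, spacing=4.795):
    return DoseMap(VolumetricImage(np.asarray(values, float), (spacing,) * 3),
                   "ASC")


def _two_region_masks(shape=(12, 12, 12)):
    grid = VolumetricImage(np.zeros(shape), (4.795,) * 3)
    tum = np.zeros(shape, bool)
    tum[3:6, 3:6, 3:6] = True
    wl = np.zeros(shape, bool)
    wl[2:10, 2:10, 2:10] = True
    body = np.ones(shape, bool)
    return SegmentationSet.from_masks(grid, {"body": body, "WL": wl,
                                             "tumour": tum})


class TestRegionReport:
    def test_identity_all_zero_errors(self, rng):
        masks = _two_region_masks()
        d = _dose(smooth_random_volume((12, 12, 12), rng).values)
        rep = region_report(d, d, masks, regions=("tumour", "WNL", "WL"))
        for stats in rep.regions.values():
            assert stats.me_gy == 0 and stats.mae_gy == 0
            assert stats.re_pct == 0 and stats.median_shift_gy == 0
            assert stats.mad_pred_gy == stats.mad_ref_gy

    def test_uniform_region_hand_arithmetic(self):
        masks = _two_region_masks()
        ref = _dose(np.full((12, 12, 12), 50.0))
        pred = _dose(np.full((12, 12, 12), 55.0))
        s = region_report(pred, ref, masks, regions=("tumour",)).regions["tumour"]
        assert s.mad_pred_gy - s.mad_ref_gy == pytest.approx(5.0)
        assert s.re_pct == pytest.approx(10.0)
        assert s.rae_pct == pytest.approx(10.0)
        assert s.median_shift_gy == pytest.approx(5.0)

    def test_wl_mad_is_volume_weighted_combination(self, rng):
        masks = _two_region_masks()
        pred = _dose(smooth_random_volume((12, 12, 12), rng).values)
        ref = _dose(smooth_random_volume((12, 12, 12), rng, smooth=2.0).values)
        rep = region_report(pred, ref, masks, regions=("tumour", "WNL", "WL"))
        nt = rep.regions["tumour"].n_voxels
        nw = rep.regions["WNL"].n_voxels
        combined = (rep.regions["tumour"].mad_pred_gy * nt
                    + rep.regions["WNL"].mad_pred_gy * nw) / (nt + nw)
        assert rep.regions["WL"].mad_pred_gy == pytest.approx(combined, rel=1e-12)
        lo = min(rep.regions["tumour"].mad_pred_gy, rep.regions["WNL"].mad_pred_gy)
        hi = max(rep.regions["tumour"].mad_pred_gy, rep.regions["WNL"].mad_pred_gy)
        assert lo <= rep.regions["WL"].mad_pred_gy <= hi

    def test_empty_region_warns_and_skips(self, rng):
        masks = _two_region_masks()
        d = _dose(smooth_random_volume((12, 12, 12), rng).values)
        with pytest.warns(UserWarning):
            rep = region_report(d, d, masks, regions=("lungs", "tumour"))
        assert "lungs" not in rep.regions


class TestDVH:
    def test_uniform_region_step_function(self):
        masks = _two_region_masks()
        curve = dvh(_dose(np.full((12, 12, 12), 50.0)), masks.mask("tumour"))
        assert curve.v_at(0.0) == 100.0
        assert curve.v_at(49.9) == pytest.approx(100.0, abs=1)
        assert curve.v_at(51.0) == 0.0

    def test_half_half_region(self):
        vals = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        mask[:4] = True
        vals[:2] = 20.0
        vals[2:4] = 100.0
        curve = dvh(_dose(vals), mask, dose_step_gy=1.0)
        assert curve.v_at(50.0) == pytest.approx(50.0)
        assert curve.v_at(10.0) == pytest.approx(100.0)
        assert curve.v_at(101.0) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_endpoints_and_layer_cake(self, seed):
        """Every curve: V(0)=100, non-increasing, integral recovers MAD
        within one bin width."""
        rng = np.random.default_rng(seed)
        vol = smooth_random_volume((10, 10, 10), rng, lo=0,
                                   hi=float(rng.uniform(30, 300)))
        mask = rng.random((10, 10, 10)) > 0.4
        if not mask.any():
            mask[0, 0, 0] = True
        step = 0.5
        curve = dvh(_dose(vol.values), mask, step)
        assert curve.volume_pct[0] == 100.0
        assert (np.diff(curve.volume_pct) <= 1e-12).all()
        assert curve.volume_pct[-1] == 0.0
        mad = vol.values[mask].mean()
        assert abs(curve.mean_dose_from_integral() - mad) <= step

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            dvh(_dose(np.ones((4, 4, 4))), np.zeros((4, 4, 4), bool))


def exact_ranksum_p(a, b):
    """Oracle: enumerate all C(n+m, n) assignments of the pooled ranks."""
    pooled = list(a) + list(b)
    n = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        us.append(ranks[list(combo)].sum() - n * (n + 1) / 2)
    us = np.asarray(us)
    # two-sided: as or more extreme in either direction from the mean
    mean_u = len(a) * len(b) / 2
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return u_obs, float(p)


class TestRankSum:
    def test_identical_samples_not_significant(self):
        res = compare_mad_distributions([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.p_value > 0.05 and not res.significant_at_05

    def test_disjoint_triplets_exact_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        res = compare_mad_distributions(a, b)
        u_oracle, p_oracle = exact_ranksum_p(a, b)
        assert res.u_statistic == pytest.approx(u_oracle)  # U = 0
        assert res.u_statistic == 0.0
        assert p_oracle == pytest.approx(0.1)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_large_shift_significant(self, rng):
        a = rng.normal(50, 5, 20)
        res = compare_mad_distributions(a, a + 30.0)
        assert res.p_value < 0.05 and res.significant_at_05

    def test_matches_enumeration_on_random_small_samples(self, rng):
        for _ in range(3):
            a = list(np.round(rng.uniform(0, 100, 4), 3))
            b = list(np.round(rng.uniform(0, 100, 5), 3))
            res = compare_mad_distributions(a, b)
            _, p_oracle = exact_ranksum_p(a, b)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_degenerate_pool_warns(self):
        with pytest.warns(UserWarning):
            res = compare_mad_distributions([5.0, 5.0], [5.0, 5.0])
        assert not res.significant_at_05
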