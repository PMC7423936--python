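"""Kernel smoother, permutation engine, and map-level corrections."""

import dataclasses

import numpy as np
import pytest

from spread_dti import (
    FieldSpec,
    KernelConfig,
    PermutationPlan,
    adjust_bh,
    adjust_wy,
    generate_pair,
    nw_smooth,
    observed_statistic,
    permutation_pvalues,
    run_spread,
)
from spread_dti.spread_core import SpreadResult

from conftest import brute_force_nw


class TestNWSmooth:
    def test_constant_field_is_fixed_point(self):
        fg = np.zeros((8, 8, 8), dtype=bool)
        fg[2:6, 2:6, 2:6] = True
        out = nw_smooth(np.full((8, 8, 8), 0.37), fg, KernelConfig(bandwidth_vox=2))
        np.testing.assert_allclose(out[fg], 0.37, atol=1e-12)
        np.testing.assert_array_equal(out[~fg], 0.0)

    def test_subvoxel_cutoff_is_identity(self):
        rng = np.random.default_rng(1)
        field = rng.random((6, 6, 6))
        fg = np.ones((6, 6, 6), dtype=bool)
        cfg = KernelConfig(bandwidth_vox=0.2, truncation_radius_vox=0.9)
        np.testing.assert_allclose(nw_smooth(field, fg, cfg), field, atol=1e-12)

    def test_matches_double_loop_oracle_on_random_field(self):
        rng = np.random.default_rng(42)
        field = rng.random((5, 5, 5))
        fg = rng.random((5, 5, 5)) < 0.8
        fg[2, 2, 2] = True
        cfg = KernelConfig(bandwidth_vox=1.5)
        expected = brute_force_nw(field, fg, 1.5, cfg.truncation_radius_vox)
        np.testing.assert_allclose(nw_smooth(field, fg, cfg), expected, atol=1e-10)

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            KernelConfig(bandwidth_vox=0)
        with pytest.raises(ValueError):
            KernelConfig(bandwidth_vox=2, truncation_radius_vox=1)


class TestObservedStatistic:
    def test_identical_scans_give_zero(self):
        pair = generate_pair(FieldSpec(shape=(16, 16, 16), mask_margin=3, noise_sd=0.0))
        t = observed_statistic(pair, KernelConfig(bandwidth_vox=2))
        np.testing.assert_array_equal(t, 0.0)

    def test_constant_shift_is_preserved(self):
        pair = generate_pair(FieldSpec(shape=(16, 16, 16), mask_margin=3, noise_sd=0.0, seed=2))
        shifted = dataclasses.replace(
            pair,
            post=dataclasses.replace(
                pair.post,
                values=np.where(pair.foreground, pair.post.values + 0.1, 0.0),
            ),
        )
        t = observed_statistic(shifted, KernelConfig(bandwidth_vox=2))
        np.testing.assert_allclose(t[pair.foreground], 0.1, atol=1e-12)

    def test_lesion_statistic_peaks_at_center_and_decays(self, lesioned_pair_factory):
        pair, lesion = lesioned_pair_factory(radius=3, delta=-0.1, noise_sd=0.0)
        t = observed_statistic(pair, KernelConfig(bandwidth_vox=2))
        c = lesion.center
        assert t[c] == t.max()
        assert t[c] > t[c[0] + 4, c[1], c[2]] > t[c[0] + 7, c[1], c[2]]

    def test_linearity_identity(self, small_pair):
        cfg = KernelConfig(bandwidth_vox=2)
        fg = small_pair.foreground
        via_scans = np.abs(
            nw_smooth(small_pair.post.values, fg, cfg) - nw_smooth(small_pair.pre.values, fg, cfg)
        )
        via_diff = np.abs(nw_smooth(small_pair.difference(), fg, cfg))
        np.testing.assert_allclose(via_scans, via_diff, atol=1e-10)


class TestPermutationPValues:
    def test_zero_statistic_has_pvalue_one(self):
        pair = generate_pair(FieldSpec(shape=(14, 14, 14), mask_margin=3, noise_sd=0.0))
        res = permutation_pvalues(pair, KernelConfig(bandwidth_vox=2), PermutationPlan(20, seed=0))
        np.testing.assert_array_equal(res.raw[pair.foreground], 1.0)

    def test_pvalues_on_permutation_lattice(self, small_pair):
        plan = PermutationPlan(50, seed=1)
        res = permutation_pvalues(small_pair, KernelConfig(bandwidth_vox=2), plan)
        vals = res.raw[small_pair.foreground]
        assert vals.min() >= 1 / 51 and vals.max() <= 1.0
        np.testing.assert_allclose(np.round(vals * 51), vals * 51, atol=1e-9)

    def test_matches_direct_enumeration_on_1d_toy(self):
        # 4-voxel line, K=8 drawn flip patterns: recompute every permuted
        # statistic with the brute-force smoother and count by hand.
        fg = np.ones((4, 1, 1), dtype=bool)
        diff = np.array([0.3, -0.1, 0.2, 0.05]).reshape(4, 1, 1)
        base = np.full((4, 1, 1), 0.5)
        from spread_dti.volume_prep import FAVolume, ScanPair

        pair = ScanPair(FAVolume(base, fg, 2.0), FAVolume(base + diff, fg, 2.0))
        cfg = KernelConfig(bandwidth_vox=1.0)
        plan = PermutationPlan(8, seed=9)
        res = permutation_pvalues(pair, cfg, plan)

        t_obs = np.abs(brute_force_nw(diff, fg, 1.0, cfg.truncation_radius_vox))
        counts = np.zeros_like(t_obs)
        for flips in plan.flip_iter(4):
            signs = np.where(flips, -1.0, 1.0).reshape(4, 1, 1)
            t_k = np.abs(brute_force_nw(diff * signs, fg, 1.0, cfg.truncation_radius_vox))
            counts += t_k >= t_obs - 1e-12
        np.testing.assert_allclose(res.raw, (1 + counts) / 9.0, atol=1e-12)

    def test_invariant_to_swapping_pre_and_post(self, small_pair):
        cfg = KernelConfig(bandwidth_vox=2)
        plan = PermutationPlan(30, seed=5)
        res = permutation_pvalues(small_pair, cfg, plan)
        swapped = dataclasses.replace(small_pair, pre=small_pair.post, post=small_pair.pre)
        res_swapped = permutation_pvalues(swapped, cfg, plan)
        np.testing.assert_allclose(res.raw, res_swapped.raw, equal_nan=True)
        np.testing.assert_allclose(res.stat, res_swapped.stat, atol=1e-15)

    def test_plan_rejects_zero_permutations(self):
        with pytest.raises(ValueError):
            PermutationPlan(0)


def _reference_bh(p):
    """Textbook step-up: adjusted p_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj[order[rank - 1]] = running
    return adj


class TestAdjustBH:
    def test_worked_example(self):
        fg = np.ones((4, 1, 1), dtype=bool)
        raw = np.array([0.01, 0.02, 0.03, 0.04]).reshape(4, 1, 1)
        np.testing.assert_allclose(adjust_bh(raw, fg).ravel(), [0.04] * 4, atol=1e-12)

    def test_equal_pvalues_unchanged(self):
        fg = np.ones((5, 1, 1), dtype=bool)
        raw = np.full((5, 1, 1), 0.2)
        np.testing.assert_allclose(adjust_bh(raw, fg).ravel(), 0.2, atol=1e-12)

    def test_matches_reference_step_up_on_random_vector(self):
        rng = np.random.default_rng(3)
        raw = rng.random((100, 1, 1))
        fg = np.ones((100, 1, 1), dtype=bool)
        np.testing.assert_allclose(
            adjust_bh(raw, fg).ravel(), _reference_bh(raw.ravel()), atol=1e-12
        )


class TestAdjustWY:
    @staticmethod
    def _result(stat, raw, perm_max, fg):
        return SpreadResult(
            stat=stat, fitted_diff=stat, raw=raw, foreground=fg,
            perm_max=np.asarray(perm_max, dtype=float),
            perm_norms=np.zeros((len(perm_max), 3)),
            cfg=KernelConfig(bandwidth_vox=1), plan=PermutationPlan(len(perm_max)),
        )

    def test_two_voxel_hand_computation(self):
        fg = np.ones((2, 1, 1), dtype=bool)
        stat = np.array([0.5, 0.1]).reshape(2, 1, 1)
        raw = np.array([1 / 5, 4 / 5]).reshape(2, 1, 1)
        # K=4 permutation map-maxima: {0.4, 0.6, 0.2, 0.1}
        res = self._result(stat, raw, [0.4, 0.6, 0.2, 0.1], fg)
        wy = adjust_wy(res)
        # voxel 0: maxima >= 0.5 -> {0.6}: (1+1)/5; voxel 1: all four >= 0.1 -> 1
        np.testing.assert_allclose(wy.ravel(), [2 / 5, 1.0], atol=1e-12)

    def test_wy_and_bh_dominate_raw_everywhere(self, small_pair):
        res = run_spread(small_pair, KernelConfig(bandwidth_vox=2), PermutationPlan(40, seed=8))
        fg = small_pair.foreground
        assert np.all(res.wy[fg] >= res.raw[fg] - 1e-12)
        assert np.all(res.bh[fg] >= res.raw[fg] - 1e-12)

    def test_exceeding_every_maximum_gives_minimum_p(self):
        fg = np.ones((3, 1, 1), dtype=bool)
        stat = np.array([9.0, 0.0, 0.0]).reshape(3, 1, 1)
        raw = np.array([1 / 11, 1.0, 1.0]).reshape(3, 1, 1)
        res = self._result(stat, raw, list(np.linspace(0.1, 1.0, 10)), fg)
        assert adjust_wy(res)[0, 0, 0] == pytest.approx(1 / 11)

    def test_missing_maxima_rejected(self):
        fg = np.ones((1, 1, 1), dtype=bool)
        res = self._result(np.ones((1, 1, 1)), np.ones((1, 1, 1)), [0.5], fg)
        res.perm_max = np.empty(0)
        with pytest.raises(ValueError, match="maxima"):
            adjust_wy(res)


def test_single_voxel_wy_equals_raw():
    """On a one-voxel foreground the map-wide maximum is the voxel itself."""
    fg = np.zeros((5, 5, 5), dtype=bool)
    fg[2, 2, 2] = True
    from spread_dti.volume_prep import FAVolume, ScanPair

    rng = np.random.default_rng(0)
    pre = np.where(fg, 0.5 + 0.02 * rng.standard_normal((5, 5, 5)), 0.0)
    post = np.where(fg, 0.5 + 0.02 * rng.standard_normal((5, 5, 5)), 0.0)
    pair = ScanPair(FAVolume(pre, fg, 2.0), FAVolume(post, fg, 2.0))
    res = run_spread(pair, KernelConfig(bandwidth_vox=1), PermutationPlan(30, seed=4))
    assert res.wy[fg][0] == pytest.approx(res.raw[fg][0])
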