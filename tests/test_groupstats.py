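"""TFCE, sign-flip inference, network decomposition, lateralization index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olfparc.connectivity import voxelwise_connectivity
from olfparc.groupstats import (
    GroupStatResult, TFCEParams, atlas_volume_table, lateralization_index,
    seed_zmap, signflip_ttest, tfce, unique_common_masks,
)

from conftest import tfce_bruteforce


class TestSeedZmap:
    def test_single_voxel_seed_matches_connectivity_row(self, small_dataset):
        ds = small_dataset
        coords = np.argwhere(ds.seed_mask)
        one = np.zeros_like(ds.seed_mask)
        one[tuple(coords[0])] = True
        zm = seed_zmap(ds.bolds[0], one, ds.brain_mask)
        m = voxelwise_connectivity(ds.bolds[0], one, ds.brain_mask)
        z_expected = np.arctanh(np.clip(m.values[0], -1 + 1e-6, 1 - 1e-6))
        got = zm.zmap[m.target_index[:, 0], m.target_index[:, 1], m.target_index[:, 2]]
        assert np.allclose(got, z_expected, atol=1e-10)

    def test_orthogonal_voxel_near_zero(self, small_dataset):
        ds = small_dataset
        zm = seed_zmap(ds.bolds[0], ds.seed_mask, ds.brain_mask)
        # pure-noise voxels are independent of the seed average
        noise = ds.brain_mask & ~ds.seed_mask & ~ds.shared_mask
        for m in ds.target_maps.values():
            noise &= ~m
        t = ds.bolds[0].n_timepoints
        assert np.abs(zm.zmap[noise]).mean() < 3 / np.sqrt(t)

    def test_degenerate_target_clipped_with_warning(self):
        from olfparc.volume import Bold4D
        x = np.sin(np.arange(30.0))
        data = np.stack([x, x.copy()])[:, None, None, :]
        bold = Bold4D(data)
        seed = np.zeros((2, 1, 1), bool)
        seed[0] = True
        with pytest.warns(UserWarning, match="clipped"):
            zm = seed_zmap(bold, seed, np.ones((2, 1, 1), bool))
        assert np.isfinite(zm.zmap).all()

    def test_constant_seed_rejected(self):
        from olfparc.volume import Bold4D
        data = np.ones((2, 1, 1, 20))
        data[1, 0, 0] = np.sin(np.arange(20.0))
        seed = np.zeros((2, 1, 1), bool)
        seed[0] = True
        with pytest.raises(ValueError, match="constant"):
            seed_zmap(Bold4D(data), seed, np.ones((2, 1, 1), bool))


class TestTFCE:
    def test_zero_map(self):
        assert np.all(tfce(np.zeros((4, 4, 4))) == 0)

    def test_all_negative_map(self):
        assert np.all(tfce(-np.ones((4, 4, 4))) == 0)

    def test_single_voxel_hand_sum(self):
        # E=0.5, H=2, dh=0.1: 0.1 * sum_{h=0.1..1.0} h^2 = 0.385
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = 1.0
        out = tfce(vol, TFCEParams(E=0.5, H=2.0, n_steps=10))
        assert out[1, 1, 1] == pytest.approx(0.385, abs=1e-12)

    def test_two_voxel_plateau_hand_sum(self):
        # dh = 0.5: sqrt(2) * (0.25 + 1.0) * 0.5 = 0.8838834...
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 0] = vol[1, 1, 1] = 1.0
        out = tfce(vol, TFCEParams(E=0.5, H=2.0, n_steps=2))
        assert out[1, 1, 1] == pytest.approx(0.8838834764831844, abs=1e-12)
        assert out[1, 1, 0] == out[1, 1, 1]

    @pytest.mark.parametrize("neighbourhood", [6, 18, 26])
    def test_matches_bruteforce_oracle(self, rng, neighbourhood):
        params = TFCEParams(n_steps=12, connectivity_neighbourhood=neighbourhood)
        for _ in range(3):
            vol = rng.standard_normal((6, 6, 6))
            got = tfce(vol, params)
            want = tfce_bruteforce(vol, 0.5, 2.0, 12, neighbourhood)
            assert np.allclose(got, want, atol=1e-10)

    def test_monotone_under_fixed_grid(self, rng):
        params = TFCEParams(n_steps=20)
        base = np.abs(rng.standard_normal((6, 6, 6)))
        bigger = base + rng.uniform(0, 0.5, base.shape)
        a = tfce(base, params, h_max=3.0)
        b = tfce(bigger, params, h_max=3.0)
        assert np.all(b >= a - 1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.2, 4.0))
    def test_scaling_property_any_map(self, seed, c):
        # sizes are scale-free and (h^H dh) picks up c^(H+1): exact c^3 law
        params = TFCEParams(E=0.5, H=2.0, n_steps=30)
        vol = np.abs(np.random.default_rng(seed).standard_normal((4, 4, 4)))
        assert np.allclose(tfce(c * vol, params), c ** 3 * tfce(vol, params),
                           rtol=1e-9)

    def test_cubic_scaling(self, rng):
        params = TFCEParams(E=0.5, H=2.0, n_steps=200)
        vol = np.abs(rng.standard_normal((5, 5, 5)))
        c = 1.7
        assert np.allclose(tfce(c * vol, params), c ** 3 * tfce(vol, params),
                           rtol=1e-10)


class TestSignFlip:
    def one_voxel_maps(self, values):
        return np.asarray(values, float)[:, None, None, None]

    def test_exhaustive_enumeration_small_n(self):
        res = signflip_ttest(self.one_voxel_maps([1.0, 2.0, 3.0]),
                             TFCEParams(n_steps=10), n_perm=100, alpha=0.2,
                             rng_seed=0, mask=np.ones((1, 1, 1), bool))
        assert res.n_permutations == 8
        assert res.t_map[0, 0, 0] == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert res.fwe_p_map[0, 0, 0] == pytest.approx(1 / 8)

    def test_all_zero_maps_nothing_significant(self):
        maps = np.zeros((6, 4, 4, 4))
        res = signflip_ttest(maps, TFCEParams(n_steps=10), n_perm=100,
                             alpha=0.05, rng_seed=0, mask=np.ones((4, 4, 4), bool))
        assert not res.sig_mask.any()
        assert np.all(res.fwe_p_map == 1.0)

    def test_identity_flip_in_random_null(self, rng):
        maps = rng.standard_normal((12, 5, 5, 5)) + 2.0
        res = signflip_ttest(maps, TFCEParams(n_steps=10), n_perm=200,
                             alpha=0.05, rng_seed=1, mask=np.ones((5, 5, 5), bool))
        assert res.n_permutations == 200
        assert np.all(res.fwe_p_map[res.mask] >= 1 / 200)

    def test_strong_signal_detected(self, rng):
        maps = rng.standard_normal((10, 5, 5, 5)) * 0.1
        maps[:, 2, 2, 2] += 1.0
        res = signflip_ttest(maps, TFCEParams(n_steps=20), n_perm=500,
                             alpha=0.01, rng_seed=2, mask=np.ones((5, 5, 5), bool))
        assert res.sig_mask[2, 2, 2]

    def test_deterministic(self, rng):
        maps = rng.standard_normal((8, 4, 4, 4))
        kw = dict(n_perm=300, alpha=0.05, rng_seed=5, mask=np.ones((4, 4, 4), bool))
        a = signflip_ttest(maps, TFCEParams(n_steps=10), **kw)
        b = signflip_ttest(maps, TFCEParams(n_steps=10), **kw)
        assert np.array_equal(a.fwe_p_map, b.fwe_p_map)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            signflip_ttest(np.ones((2, 2, 2, 2)), n_perm=100,
                           mask=np.ones((2, 2, 2), bool))


class TestUniqueCommon:
    def make_result(self, sig):
        shape = sig.shape
        return GroupStatResult(np.zeros(shape), np.zeros(shape), np.ones(shape),
                               sig, 100, 0, 0.05)

    def test_all_seeds_significant_is_common(self):
        sig = np.ones((2, 2, 2), bool)
        results = {s: self.make_result(sig.copy()) for s in "abcd"}
        unique, common = unique_common_masks(results)
        assert common.all()
        assert not any(u.any() for u in unique.values())

    def test_single_seed_unique(self):
        base = np.zeros((2, 2, 2), bool)
        only = base.copy()
        only[0, 0, 0] = True
        results = {"s1": self.make_result(only), "s2": self.make_result(base.copy())}
        unique, common = unique_common_masks(results)
        assert unique["s1"][0, 0, 0] and not common.any()

    def test_partition_over_all_patterns(self, rng):
        # every significant voxel is in exactly one of: a unique mask,
        # shared-but-not-all, or the common mask (2^4 patterns exercised)
        sigs = {f"s{i}": rng.uniform(size=(4, 4, 4)) < 0.5 for i in range(4)}
        results = {k: self.make_result(v) for k, v in sigs.items()}
        unique, common = unique_common_masks(results)
        stack = np.stack(list(sigs.values()))
        n_sig = stack.sum(axis=0)
        uni_any = np.stack(list(unique.values())).any(axis=0)
        shared_not_all = (n_sig > 1) & (n_sig < 4)
        cats = uni_any.astype(int) + shared_not_all.astype(int) + common.astype(int)
        assert np.all(cats[n_sig > 0] == 1)
        assert np.all(cats[n_sig == 0] == 0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            unique_common_masks({
                "a": self.make_result(np.zeros((2, 2, 2), bool)),
                "b": self.make_result(np.zeros((3, 3, 3), bool)),
            })


class TestAtlasVolumes:
    def test_ten_voxels_at_2mm_is_80mm3(self):
        mask = np.zeros((5, 5, 5), bool)
        mask.ravel()[:10] = True
        atlas = np.ones((5, 5, 5), int)
        df = atlas_volume_table(mask, atlas, voxel_volume_mm3=8.0)
        assert df.loc[0, "volume_mm3"] == 80.0
        assert not df.loc[0, "suppressed"]

    def test_small_entries_suppressed(self):
        # counts {25, 3} at 2 mm isotropic -> {200 mm3, suppressed}
        atlas = np.zeros((6, 6, 6), int)
        atlas[:3] = 1
        atlas[3:] = 2
        mask = np.zeros((6, 6, 6), bool)
        mask.reshape(-1)[:25] = True                 # 25 voxels in region 1
        mask[3, 0, :3] = True                        # 3 voxels in region 2
        df = atlas_volume_table(mask, atlas, voxel_volume_mm3=8.0).set_index("label")
        assert df.loc[1, "volume_mm3"] == 200.0 and not df.loc[1, "suppressed"]
        assert df.loc[2, "volume_mm3"] == 24.0 and df.loc[2, "suppressed"]

    def test_empty_mask_empty_table(self):
        df = atlas_volume_table(np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), int), 8.0)
        assert len(df) == 0


class TestLateralization:
    def test_equal_maps_zero_index(self, rng):
        z = np.abs(rng.standard_normal((6, 6, 6)))
        li = lateralization_index(z, z.copy(), np.eye(4), sigma_mm=0.0)
        assert np.allclose(li.li, 0.0)

    def test_direct_formula(self):
        zl = np.full((3, 3, 3), 0.3)
        zr = np.full((3, 3, 3), 0.1)
        li = lateralization_index(zl, zr, np.eye(4), sigma_mm=0.0)
        assert np.allclose(li.li, 0.5)

    def test_antisymmetry(self, rng):
        zl = np.abs(rng.standard_normal((5, 5, 5))) + 0.1
        zr = np.abs(rng.standard_normal((5, 5, 5))) + 0.1
        a = lateralization_index(zl, zr, np.eye(4), sigma_mm=0.0)
        b = lateralization_index(zr, zl, np.eye(4), sigma_mm=0.0)
        assert np.allclose(a.li, -b.li, atol=1e-14)

    def test_bounded_on_nonnegative_maps(self, rng):
        zl = np.abs(rng.standard_normal((5, 5, 5)))
        zr = np.abs(rng.standard_normal((5, 5, 5)))
        li = lateralization_index(zl, zr, np.eye(4), sigma_mm=0.0)
        assert np.all(np.abs(li.li[li.valid_mask]) <= 1 + 1e-12)

    def test_near_zero_denominator_masked(self):
        zl = np.zeros((3, 3, 3))
        zr = np.zeros((3, 3, 3))
        li = lateralization_index(zl, zr, np.eye(4), sigma_mm=0.0)
        assert not li.valid_mask.any()
        assert np.allclose(li.li, 0.0)
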