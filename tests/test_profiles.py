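import numpy as np
import pytest

import tractwing as tw
from conftest import small_grid


def brute_entropy(slice2d):
    """Independent literal evaluation of -sum p ln p."""
    s = np.asarray(slice2d, dtype=float).ravel()
    p = s / s.sum()
    h = 0.0
    for v in p:
        if v > 0:
            h -= v * np.log(v)
    return h


def brute_cosine(d, r):
    d, r = np.asarray(d, float).ravel(), np.asarray(r, float).ravel()
    num = sum(x * y for x, y in zip(d, r))
    return num / (np.sqrt(sum(x * x for x in d)) * np.sqrt(sum(y * y for y in r)))


class TestSliceEntropy:
    def test_delta_distribution_has_zero_entropy(self):
        s = np.zeros((4, 4))
        s[2, 2] = 7.0
        assert tw.slice_entropy(s) == 0.0

    @pytest.mark.parametrize("n", [2, 5, 16])
    def test_uniform_over_n_voxels_gives_ln_n(self, n):
        s = np.zeros(20)
        s[:n] = 3.3
        assert abs(tw.slice_entropy(s) - np.log(n)) < 1e-12

    def test_hand_computed_three_mass_example(self):
        h = tw.slice_entropy(np.array([0.5, 0.25, 0.25]))
        assert abs(h - 1.5 * np.log(2)) < 1e-12

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            tw.slice_entropy(np.array([1.0, -0.1]))

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tw.slice_entropy(np.zeros(4))

    def test_matches_brute_force_on_random_slices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = rng.uniform(size=(6, 6)) * (rng.uniform(size=(6, 6)) > 0.3)
            if s.sum() == 0:
                continue
            assert abs(tw.slice_entropy(s) - brute_entropy(s)) < 1e-12


class TestInverseDiversityProfile:
    def test_delta_slice_gives_one_uniform_gives_reciprocal(self):
        g = small_grid(shape=(5, 5, 4))
        g.data[2, 2, 0] = 9.0  # delta
        g.data[:, :, 1] = 2.0  # uniform over 25
        prof = tw.inverse_diversity_profile(g, axis="z")
        assert prof.inverse_diversity[0] == 1.0
        assert abs(prof.inverse_diversity[1] - 1 / 25) < 1e-12

    def test_empty_slice_flagged_as_zero_not_one(self):
        g = small_grid(shape=(3, 3, 3))
        g.data[1, 1, 0] = 1.0
        prof = tw.inverse_diversity_profile(g, axis="z")
        assert prof.inverse_diversity[1] == 0.0
        assert np.isnan(prof.entropy_nats[1])
        assert prof.n_nonzero[1] == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        g = small_grid(shape=(6, 6, 5))
        g.data[:] = rng.uniform(size=(6, 6, 5))
        p1 = tw.inverse_diversity_profile(g, axis="z")
        g2 = tw.VoxelGrid(g.data * 37.5, g.affine)
        p2 = tw.inverse_diversity_profile(g2, axis="z")
        np.testing.assert_allclose(p1.inverse_diversity, p2.inverse_diversity, atol=1e-12)

    def test_perplexity_bounded_by_support_size(self):
        rng = np.random.default_rng(10)
        g = small_grid(shape=(6, 6, 8))
        g.data[:] = rng.uniform(size=(6, 6, 8)) * (rng.uniform(size=(6, 6, 8)) > 0.5)
        g.data[:, :, 0] = 1.0  # uniform slice: equality case
        prof = tw.inverse_diversity_profile(g, axis="z")
        for k in range(8):
            if prof.n_nonzero[k] == 0:
                continue
            perplexity = 1.0 / prof.inverse_diversity[k]
            assert perplexity <= prof.n_nonzero[k] + 1e-9
        assert abs(1.0 / prof.inverse_diversity[0] - 36) < 1e-9

    def test_all_empty_volume_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tw.inverse_diversity_profile(small_grid(), axis="z")


class TestFindBottlenecks:
    def test_unimodal_profile_returns_its_argmax(self):
        g = small_grid(shape=(3, 3, 21))
        for k in range(21):
            n = 1 + abs(k - 10)  # tightest at the middle slice
            g.data[0, :, k] = 0
            g.data.reshape(9, 21)[:n, k] = 1.0
        prof = tw.inverse_diversity_profile(g, axis="z")
        peaks = tw.find_bottlenecks(prof)
        assert list(peaks) == [10.0]

    def test_flat_profile_has_no_peaks(self):
        g = small_grid(shape=(3, 3, 10))
        g.data[1, 1, :] = 1.0
        prof = tw.inverse_diversity_profile(g, axis="z")
        assert len(tw.find_bottlenecks(prof)) == 0

    def test_phantom_bottlenecks_at_planted_planes(self, drtx_density):
        prof = tw.inverse_diversity_profile(drtx_density, axis="z")
        zmax = prof.slice_coords[np.nanargmax(prof.inverse_diversity)]
        assert abs(zmax - (-6.0)) <= 1.0
        peaks = tw.find_bottlenecks(prof)
        for planted in (-25.0, -15.0, -6.0):
            assert np.min(np.abs(peaks - planted)) <= 1.0

    def test_uncrossed_bundle_has_no_rw_peak(self, drtu_density):
        prof = tw.inverse_diversity_profile(drtu_density, axis="z")
        peaks = tw.find_bottlenecks(prof)
        assert all(abs(z - (-6.0)) > 3.0 for z in peaks)


class TestCosineProfile:
    def test_proportional_slices_score_one(self):
        g = small_grid(shape=(4, 4, 2))
        rng = np.random.default_rng(3)
        g.data[:, :, 0] = rng.uniform(size=(4, 4))
        ref = tw.Mask(
            tw.VoxelGrid(np.clip(g.data * 0.5, 0, 1), g.affine), kind="probability"
        )
        prof = tw.cosine_profile(g, ref, axis="z")
        assert abs(prof.cosine["reference"][0] - 1.0) < 1e-12
        assert np.isnan(prof.cosine["reference"][1])  # both empty: undefined

    def test_disjoint_supports_score_zero(self):
        g = small_grid(shape=(4, 4, 1))
        g.data[0, 0, 0] = 5.0
        ref_grid = small_grid(shape=(4, 4, 1))
        ref_grid.data[3, 3, 0] = 1.0
        prof = tw.cosine_profile(g, tw.Mask(ref_grid, kind="binary"), axis="z")
        assert prof.cosine["reference"][0] == 0.0

    def test_worked_half_overlap_example(self):
        g = small_grid(shape=(3, 1, 1))
        g.data[:, 0, 0] = [1, 1, 0]
        ref_grid = small_grid(shape=(3, 1, 1))
        ref_grid.data[:, 0, 0] = [0, 1, 1]
        # single z slice holds both 3-vectors: (1,1,0).(0,1,1)/2 = 0.5
        prof = tw.cosine_profile(g, tw.Mask(ref_grid, kind="binary"), axis="z")
        assert abs(prof.cosine["reference"][0] - 0.5) < 1e-12

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(12)
        d = small_grid(shape=(5, 5, 3))
        d.data[:] = rng.uniform(size=(5, 5, 3))
        r = rng.uniform(size=(5, 5, 3))
        ref = tw.Mask(tw.VoxelGrid(r, d.affine), kind="probability")
        p1 = tw.cosine_profile(d, ref, axis="z").cosine["reference"]
        swapped = tw.cosine_profile(
            tw.VoxelGrid(r, d.affine),
            tw.Mask(tw.VoxelGrid(np.clip(d.data, 0, 1), d.affine), kind="probability"),
            axis="z",
        ).cosine["reference"]
        d_scaled = tw.VoxelGrid(d.data * 11.0, d.affine)
        p3 = tw.cosine_profile(d_scaled, ref, axis="z").cosine["reference"]
        # symmetric up to the clip (values already < 1 with rng.uniform)
        np.testing.assert_allclose(p1, swapped, atol=1e-12)
        np.testing.assert_allclose(p1, p3, atol=1e-12)

    def test_matches_brute_force_on_random_slices(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            d = rng.uniform(size=36) * (rng.uniform(size=36) > 0.3)
            r = rng.uniform(size=36) * (rng.uniform(size=36) > 0.3)
            if d.sum() == 0 or r.sum() == 0:
                continue
            g = small_grid(shape=(6, 6, 1))
            g.data[:, :, 0] = d.reshape(6, 6)
            ref = tw.Mask(tw.VoxelGrid(r.reshape(6, 6, 1), g.affine), kind="probability")
            got = tw.cosine_profile(g, ref, axis="z").cosine["reference"][0]
            assert abs(got - brute_cosine(d, r)) < 1e-12

    def test_grid_mismatch_rejected(self):
        g = small_grid(shape=(4, 4, 4))
        g.data[0, 0, 0] = 1.0
        ref = tw.Mask(small_grid(shape=(5, 5, 5)), kind="binary")
        with pytest.raises(ValueError, match="grid"):
            tw.cosine_profile(g, ref)

    def test_rw_dominates_other_nuclei_at_the_rw_plane(self, atlas, drtx_density):
        refs = {k: atlas[f"{k}_left"] for k in ("rw", "rn", "vim")}
        prof = tw.cosine_profile(drtx_density, refs, axis="z")
        k = int(-6.0 - prof.slice_coords[0])
        rw = prof.cosine["rw"][k]
        rn = np.nan_to_num(prof.cosine["rn"][k])
        vim = np.nan_to_num(prof.cosine["vim"][k])
        assert rw > rn and rw > vim
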