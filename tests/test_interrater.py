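import numpy as np
import pytest

import tractwing as tw
from conftest import binary_mask_from_indices, small_grid


def mask_of(*indices):
    return binary_mask_from_indices(small_grid(), list(indices))


class TestDice:
    def test_identical_masks_score_one(self):
        m = mask_of((1, 1, 1), (2, 2, 2))
        assert tw.dice(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        assert tw.dice(mask_of((1, 1, 1)), mask_of((5, 5, 5))) == 0.0

    def test_worked_two_voxel_example(self):
        a = mask_of((1, 1, 1), (2, 2, 2))
        b = mask_of((2, 2, 2), (3, 3, 3))
        assert tw.dice(a, b) == 0.5

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = tw.Mask(
                tw.VoxelGrid((rng.uniform(size=(6, 6, 6)) > 0.6).astype(float), np.eye(4)),
                kind="binary",
            )
            b = tw.Mask(
                tw.VoxelGrid((rng.uniform(size=(6, 6, 6)) > 0.6).astype(float), np.eye(4)),
                kind="binary",
            )
            d = tw.dice(a, b)
            assert 0.0 <= d <= 1.0
            assert d == tw.dice(b, a)

    def test_empty_vs_empty_is_one_with_warning(self):
        a, b = mask_of(), mask_of()
        with pytest.warns(UserWarning, match="empty"):
            assert tw.dice(a, b) == 1.0

    def test_grid_mismatch_rejected(self):
        b = tw.Mask(small_grid(shape=(5, 5, 5)), kind="binary")
        with pytest.raises(ValueError):
            tw.dice(mask_of((1, 1, 1)), b)


class TestCogDistance:
    def test_identical_masks_have_zero_distance(self):
        m = mask_of((2, 3, 4), (4, 3, 2))
        assert tw.cog_distance(m, m) == 0.0

    def test_single_voxels_three_mm_apart(self):
        assert tw.cog_distance(mask_of((1, 1, 1)), mask_of((4, 1, 1))) == 3.0

    def test_reported_cog_pair_arithmetic(self):
        """Distance between the left RW COG and the left contact-cluster COG."""
        g = tw.VoxelGrid(np.zeros((25, 25, 25)), np.diag([0.1, 0.1, 0.1, 1.0]))
        g.affine[:3, 3] = (-12.2, -18.5, -5.7)
        a = g.empty_like()
        a.data[0, 9, 11] = 1.0  # (-12.2, -17.6, -4.6)
        b = g.empty_like()
        b.data[17, 0, 0] = 1.0  # (-10.5, -18.5, -5.7)
        d = tw.cog_distance(tw.Mask(a), tw.Mask(b))
        assert abs(d - np.sqrt(1.7**2 + 0.9**2 + 1.1**2)) < 1e-9

    def test_triangle_inequality_across_three_raters(self):
        rng = np.random.default_rng(8)
        masks = []
        for _ in range(3):
            data = (rng.uniform(size=(8, 8, 8)) > 0.7).astype(float)
            data[4, 4, 4] = 1.0  # never empty
            masks.append(tw.Mask(tw.VoxelGrid(data, np.eye(4)), kind="binary"))
        a, b, c = masks
        assert tw.cog_distance(a, c) <= tw.cog_distance(a, b) + tw.cog_distance(b, c) + 1e-12

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tw.cog_distance(mask_of(), mask_of((1, 1, 1)))


def make_rater_sets(n_subjects, masks_by_rater, hemis=("left", "right")):
    out = []
    for s in range(n_subjects):
        for h in hemis:
            out.append(
                tw.RaterSet(subject_id=f"sub-{s}", hemisphere=h, masks=dict(masks_by_rater))
            )
    return out


class TestInterraterTable:
    def test_row_combinatorics(self):
        m = mask_of((1, 1, 1))
        rs = make_rater_sets(2, {"r1": m, "r2": m, "r3": m})
        table = tw.interrater_table(rs)
        assert len(table) == 12  # 2 subjects x 2 hemis x 3 pairs

    def test_identical_raters_agree_perfectly(self):
        m = mask_of((1, 1, 1), (1, 2, 1))
        table = tw.interrater_table(make_rater_sets(2, {"r1": m, "r2": m}))
        assert (table["dice"] == 1.0).all()
        assert (table["cog_dist_mm"] == 0.0).all()

    def test_missing_rater_rows_skipped(self):
        m = mask_of((1, 1, 1))
        rs = make_rater_sets(1, {"r1": m, "r2": m}, hemis=("left",))
        rs.append(tw.RaterSet(subject_id="sub-x", hemisphere="left", masks={"r1": m}))
        table = tw.interrater_table(rs)
        assert len(table) == 1

    def test_median_dice_decreases_with_boundary_noise(self, atlas):
        truth = atlas["rw_left"].binarize(0.5)
        medians = []
        for jitter in (0.0, 1.0, 2.5):
            spec = tw.PhantomSpec(seed=21, rater_boundary_jitter=jitter, n_subjects=8)
            table = tw.interrater_table(tw.make_raters(spec, truth))
            medians.append(table["dice"].median())
        assert medians[0] == 1.0
        assert medians[0] > medians[1] > medians[2]


class TestVolumeCorrelation:
    def test_identical_raters_give_perfect_correlation(self):
        rng = np.random.default_rng(2)
        rs = []
        for s in range(6):
            data = (rng.uniform(size=(8, 8, 8)) > rng.uniform(0.4, 0.8)).astype(float)
            data[3, 3, 3] = 1.0
            m = tw.Mask(tw.VoxelGrid(data, np.eye(4)), kind="binary")
            rs.append(tw.RaterSet(subject_id=f"s{s}", hemisphere="left", masks={"a": m, "b": m}))
        r, p = tw.volume_correlation(rs, ("a", "b"))
        assert abs(r - 1.0) < 1e-12

    def test_constant_volume_rater_rejected(self):
        rng = np.random.default_rng(3)
        rs = []
        const_data = np.zeros((8, 8, 8))
        const_data[1, 1, 1] = 1.0
        const = tw.Mask(tw.VoxelGrid(const_data, np.eye(4)), kind="binary")
        for s in range(5):
            data = (rng.uniform(size=(8, 8, 8)) > 0.5).astype(float)
            data[2, 2, 2] = 1.0
            m = tw.Mask(tw.VoxelGrid(data, np.eye(4)), kind="binary")
            rs.append(
                tw.RaterSet(subject_id=f"s{s}", hemisphere="left", masks={"a": m, "b": const})
            )
        with pytest.raises(ValueError, match="zero-variance"):
            tw.volume_correlation(rs, ("a", "b"))

    def test_independent_volumes_are_uncorrelated_on_average(self):
        """Under the null, |r| stays small for n = 77 subjects."""
        rng = np.random.default_rng(4)
        vols_a = rng.integers(20, 200, size=77)
        vols_b = rng.integers(20, 200, size=77)
        rs = []
        for s, (va, vb) in enumerate(zip(vols_a, vols_b)):
            ga = small_grid(shape=(12, 12, 12))
            ga.data.reshape(-1)[:va] = 1.0
            gb = small_grid(shape=(12, 12, 12))
            gb.data.reshape(-1)[:vb] = 1.0
            rs.append(
                tw.RaterSet(
                    subject_id=f"s{s}",
                    hemisphere="left",
                    masks={"a": tw.Mask(ga), "b": tw.Mask(gb)},
                )
            )
        r, p = tw.volume_correlation(rs, ("a", "b"))
        assert abs(r) < 0.35
        assert p > 0.01


def test_load_rater_sets_directory_layout(tmp_path):
    g = small_grid()
    g.data[1, 1, 1] = 1.0
    for sub in ("sub-001", "sub-002"):
        for rater in ("rater-1", "rater-2"):
            d = tmp_path / sub / rater
            d.mkdir(parents=True)
            tw.write_nifti(g, d / "hemi-L_rw.nii.gz")
    from tractwing.interrater import load_rater_sets

    rs = load_rater_sets(tmp_path)
    assert len(rs) == 2
    assert all(set(x.masks) == {"rater-1", "rater-2"} for x in rs)
    table = tw.interrater_table(rs)
    assert (table["dice"] == 1.0).all()
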