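import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ichseg.volume_core import (
    BinaryMask,
    IntensityVolume,
    binarize_nonzero,
    connected_components,
    dice_score,
    hole_filling_closing,
    load_volume,
    save_volume,
    shape_score,
)
from oracles import bbox_volume_bruteforce, fill_holes_bruteforce, union_find_components

small_masks = arrays(dtype=bool, shape=(8, 8, 8), elements=st.booleans())


class TestNiftiIO:
    def test_round_trip_preserves_data_and_spacing(self, tmp_path, rng):
        vol = IntensityVolume(rng.random((5, 6, 7)), spacing=(0.9, 1.1, 2.5))
        save_volume(vol, tmp_path / "v.nii.gz")
        back = load_volume(tmp_path / "v.nii.gz")
        np.testing.assert_array_equal(back.data, vol.data)
        np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)

    def test_singleton_fourth_dimension_is_squeezed(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.ones((4, 4, 4, 1)), np.eye(4)), tmp_path / "v4.nii.gz")
        vol = load_volume(tmp_path / "v4.nii.gz")
        assert vol.shape == (4, 4, 4)
        assert vol.data.sum() == 64

    def test_missing_file_and_bad_dimensionality_rejected(self, tmp_path):
        import nibabel as nib

        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "absent.nii.gz")
        nib.save(nib.Nifti1Image(np.ones((4, 4, 4, 2)), np.eye(4)), tmp_path / "v5.nii.gz")
        with pytest.raises(ValueError):
            load_volume(tmp_path / "v5.nii.gz")

    def test_nan_voxels_are_mapped_to_zero(self):
        data = np.ones((3, 3, 3))
        data[1, 1, 1] = np.nan
        vol = IntensityVolume(data)
        assert vol.data[1, 1, 1] == 0.0


class TestBinarize:
    def test_all_zero_and_all_one_volumes(self):
        assert binarize_nonzero(IntensityVolume(np.zeros((4, 4, 4)))).count == 0
        assert binarize_nonzero(IntensityVolume(np.ones((4, 4, 4)))).count == 64

    def test_count_matches_nonzero_voxels(self, rng):
        data = np.where(rng.random((6, 6, 6)) < 0.3, rng.normal(size=(6, 6, 6)), 0.0)
        assert binarize_nonzero(IntensityVolume(data)).count == int((data != 0).sum())


class TestHoleFillingClosing:
    def test_centred_solid_cube_is_unchanged(self):
        data = np.zeros((15, 15, 15), dtype=bool)
        data[5:10, 5:10, 5:10] = True
        out = hole_filling_closing(BinaryMask(data), 1)
        np.testing.assert_array_equal(out.data, data)

    def test_cube_shell_cavity_is_filled(self):
        shell = np.zeros((15, 15, 15), dtype=bool)
        shell[5:10, 5:10, 5:10] = True
        shell[6:9, 6:9, 6:9] = False
        out = hole_filling_closing(BinaryMask(shell), 1)
        expected = fill_holes_bruteforce(shell)
        np.testing.assert_array_equal(out.data, expected)
        assert out.data[7, 7, 7]  # cavity centre now solid

    def test_empty_mask_stays_empty(self):
        assert hole_filling_closing(BinaryMask(np.zeros((6, 6, 6), bool)), 2).count == 0

    @given(mask=small_masks, n=st.integers(1, 2))
    def test_extensive_on_random_masks(self, mask, n):
        out = hole_filling_closing(BinaryMask(mask), n)
        assert np.all(out.data[mask])


class TestConnectedComponents:
    def test_two_isolated_voxels(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[1, 1, 1] = data[3, 3, 3] = True
        comps = connected_components(BinaryMask(data), 6)
        assert len(comps) == 2 and all(c.volume == 1 for c in comps)

    def test_diagonal_neighbours_split_by_connectivity(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[1, 1, 1] = data[1, 2, 2] = True  # share an edge, not a face
        assert len(connected_components(BinaryMask(data), 6)) == 2
        assert len(connected_components(BinaryMask(data), 26)) == 1

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_union_find_oracle_and_partitions_mask(self, connectivity, rng):
        data = rng.random((10, 10, 10)) < 0.35
        comps = connected_components(BinaryMask(data), connectivity)
        got = {frozenset(map(tuple, c.voxels)) for c in comps}
        assert got == union_find_components(data, connectivity)
        assert sum(c.volume for c in comps) == int(data.sum())

    def test_ordering_is_volume_descending_then_lexicographic(self, rng):
        data = rng.random((10, 10, 10)) < 0.2
        comps = connected_components(BinaryMask(data), 6)
        keys = [(-c.volume, tuple(c.voxels[0])) for c in comps]
        assert keys == sorted(keys)


class TestShapeScore:
    def test_full_cuboid_scores_its_volume(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[1:4, 2:6, 3:5] = True
        (c,) = connected_components(BinaryMask(data), 6)
        assert shape_score(c) == pytest.approx(3 * 4 * 2, abs=1e-12)

    def test_single_voxel_scores_one(self):
        data = np.zeros((3, 3, 3), dtype=bool)
        data[1, 1, 1] = True
        (c,) = connected_components(BinaryMask(data), 6)
        assert shape_score(c) == 1.0

    def test_plus_sign_in_cube(self):
        # 7-voxel 3-D plus sign spans a 3x3x3 bounding box
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        for ax in range(3):
            for d in (-1, 1):
                idx = [2, 2, 2]
                idx[ax] += d
                data[tuple(idx)] = True
        (c,) = connected_components(BinaryMask(data), 6)
        assert c.volume == 7 and c.bbox_volume == bbox_volume_bruteforce(c.voxels) == 27
        assert shape_score(c) == pytest.approx(343 / 729, abs=1e-12)

    @given(mask=small_masks)
    def test_score_never_exceeds_volume(self, mask):
        for c in connected_components(BinaryMask(mask), 26):
            assert shape_score(c) <= c.volume + 1e-12
            assert c.bbox_volume == bbox_volume_bruteforce(c.voxels)


class TestDice:
    def test_identity_disjoint_and_half_overlap(self):
        a = np.zeros((5, 5, 5), dtype=bool)
        a[0, 0, :] = True
        b = np.zeros((5, 5, 5), dtype=bool)
        b[1, 1, :] = True
        assert dice_score(BinaryMask(a), BinaryMask(a)) == 1.0
        assert dice_score(BinaryMask(a), BinaryMask(b)) == 0.0
        x = np.zeros((5, 5, 5), dtype=bool)
        y = np.zeros((5, 5, 5), dtype=bool)
        x.ravel()[:10] = True
        y.ravel()[5:15] = True  # |X|=|Y|=10, overlap 5
        assert dice_score(BinaryMask(x), BinaryMask(y)) == 0.5

    def test_symmetric_and_bounded(self, rng):
        a = BinaryMask(rng.random((6, 6, 6)) < 0.4)
        b = BinaryMask(rng.random((6, 6, 6)) < 0.4)
        assert dice_score(a, b) == dice_score(b, a)
        assert 0.0 <= dice_score(a, b) <= 1.0

    def test_empty_vs_empty_is_one_and_shape_mismatch_rejected(self):
        e = BinaryMask(np.zeros((4, 4, 4), bool))
        assert dice_score(e, e) == 1.0
        with pytest.raises(ValueError):
            dice_score(e, BinaryMask(np.zeros((5, 5, 5), bool)))
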