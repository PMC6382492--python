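import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ichseg.haematoma_seg import (
    NoHaematomaError,
    break_weak_links,
    component_weight,
    haemorrhage_threshold,
    select_t2s_component,
)
from ichseg.pipeline import run_volumes
from ichseg.volume_core import BinaryMask, Component


def _component(volume=1, bbox=1, o=0, s=0, l=0):
    vox = np.zeros((volume, 3), dtype=int)
    vox[:, 0] = np.arange(volume)
    c = Component(voxels=vox, volume=volume, bbox_volume=max(bbox, volume), shape_score=volume**3 / max(bbox, volume) ** 2)
    c.o, c.s, c.l = o, s, l
    c.w = component_weight(c)
    return c


class TestComponentWeight:
    @pytest.mark.parametrize(
        "o,s,l,expected",
        [
            (0, 0, 0, 0.0),
            (0, 5, 9, 0.0),  # no adjacent hyper-intensity: weight vanishes
            (2, 1, 3, 8.0),  # 4 * 4/2
            (5, 0, 0, 25.0),
        ],
    )
    def test_weight_formula(self, o, s, l, expected):
        assert component_weight(_component(volume=10, bbox=10, o=o, s=s, l=l)) == expected


class TestSelection:
    def test_single_positive_component_selected(self):
        c = _component(volume=10, bbox=10, o=2)
        assert select_t2s_component([c]) is c

    def test_weight_times_shape_score_decides(self):
        # scores 8 * 10 = 80 vs 25 * 2 = 50
        a = _component(volume=10, bbox=10, o=2, s=1, l=3)
        b = _component(volume=2, bbox=2, o=5)
        assert select_t2s_component([a, b]) is a

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(20):
            comps = [
                _component(
                    volume=int(rng.integers(1, 30)),
                    bbox=int(rng.integers(30, 60)),
                    o=int(rng.integers(0, 10)),
                    s=int(rng.integers(0, 5)),
                    l=int(rng.integers(0, 5)),
                )
                for _ in range(8)
            ]
            if all(c.w * c.shape_score == 0 for c in comps):
                continue
            best = max(range(8), key=lambda i: comps[i].w * comps[i].shape_score)
            # linear-scan oracle: first index attaining the maximum
            scores = [c.w * c.shape_score for c in comps]
            assert select_t2s_component(comps) is comps[scores.index(max(scores))] is comps[best]

    def test_all_zero_scores_raise(self):
        with pytest.raises(NoHaematomaError):
            select_t2s_component([_component(volume=5, bbox=5, o=0)])


class TestHaemorrhageThreshold:
    def test_symmetric_input_uses_mean(self):
        thr = haemorrhage_threshold([1.0, 2.0, 3.0])
        assert thr.H == thr.mu == 2.0 and not thr.corrected

    def test_negative_skew_is_corrected_downwards(self):
        thr = haemorrhage_threshold([0.0, 10.0, 11.0, 12.0, 13.0])
        assert thr.mu == pytest.approx(9.2)
        assert thr.nu == 11.0
        assert thr.corrected
        assert thr.H == pytest.approx(9.2 + 6 * (9.2 - 11.0), abs=1e-12)  # -1.6

    def test_constant_sequence_returns_that_constant(self):
        thr = haemorrhage_threshold([7.5] * 9)
        assert thr.H == 7.5 and thr.sigma == 0.0

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40))
    def test_corrected_branch_sits_two_k_sigmas_below_mean(self, values):
        thr = haemorrhage_threshold(values)
        if thr.corrected and thr.sigma > 0:
            assert thr.H - thr.mu == pytest.approx(2 * thr.k * thr.sigma, rel=1e-9, abs=1e-9)
            assert thr.H < thr.mu
        else:
            assert thr.H == thr.mu


class TestBreakWeakLinks:
    def test_axis_segment_loses_its_middle_voxel(self):
        for axis in range(3):
            data = np.zeros((7, 7, 7), dtype=bool)
            idx = [3, 3, 3]
            for d in (-1, 0, 1):
                idx2 = list(idx)
                idx2[axis] += d
                data[tuple(idx2)] = True
            out = break_weak_links(BinaryMask(data))
            assert out.count == 2 and not out.data[3, 3, 3]

    def test_solid_cube_and_isolated_voxel_unchanged(self):
        cube = np.zeros((7, 7, 7), dtype=bool)
        cube[2:5, 2:5, 2:5] = True
        np.testing.assert_array_equal(break_weak_links(BinaryMask(cube)).data, cube)
        single = np.zeros((5, 5, 5), dtype=bool)
        single[2, 2, 2] = True
        np.testing.assert_array_equal(break_weak_links(BinaryMask(single)).data, single)

    def test_diagonal_segment_is_not_broken(self):
        data = np.zeros((7, 7, 7), dtype=bool)
        for d in (-1, 0, 1):
            data[3 + d, 3 + d, 3] = True
        np.testing.assert_array_equal(break_weak_links(BinaryMask(data)).data, data)

    @given(mask=arrays(dtype=bool, shape=(7, 7, 7), elements=st.booleans()))
    def test_anti_extensive_and_matches_neighbourhood_oracle(self, mask):
        out = break_weak_links(BinaryMask(mask)).data
        assert not np.any(out & ~mask)
        # per-voxel oracle: remove iff exactly the two opposite face
        # neighbours along one axis are true and the other 24 are false
        padded = np.pad(mask, 1)
        for v in np.argwhere(mask):
            x, y, z = v + 1
            nb = padded[x - 1 : x + 2, y - 1 : y + 2, z - 1 : z + 2].copy()
            nb[1, 1, 1] = False
            expect_removed = int(nb.sum()) == 2 and (
                (nb[0, 1, 1] and nb[2, 1, 1]) or (nb[1, 0, 1] and nb[1, 2, 1]) or (nb[1, 1, 0] and nb[1, 1, 2])
            )
            assert out[tuple(v)] == (not expect_removed)


class TestSegmentationInvariance:
    def test_affine_intensity_rescaling_preserves_masks(self, clean_case, clean_result):
        from ichseg.volume_core import IntensityVolume

        t2s = IntensityVolume(3.0 * clean_case.t2s.data + 50.0, spacing=clean_case.t2s.spacing)
        flair = IntensityVolume(2.0 * clean_case.flair.data + 25.0, spacing=clean_case.flair.spacing)
        rescaled = run_volumes(t2s, flair, clean_case.labels, clean_case.svd)
        np.testing.assert_array_equal(rescaled.haematoma.data, clean_result.haematoma.data)
        np.testing.assert_array_equal(rescaled.oedema.data, clean_result.oedema.data)

    def test_final_mask_avoids_ventricles_and_stays_near_selection(self, clean_case, clean_result):
        assert not (clean_result.haematoma.data & clean_result.bundle.ventricle.data).any()
        from scipy import ndimage

        # final mask must lie within the 3-voxel dilation of the true lesion area
        cand = clean_case.truth_haematoma.data | clean_case.truth_oedema.data
        grown = ndimage.binary_dilation(cand, np.ones((3, 3, 3), bool), iterations=3)
        assert not (clean_result.haematoma.data & ~grown).any()
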