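"""H index: centroid, distance weights, sign rule and the full index."""

import numpy as np
import pytest

from hetindex import (
    HConfig,
    SUVVolume,
    TumorMask,
    ValidationError,
    distance_weights,
    h_index,
    h_sign,
    single_sphere,
    sphere_mask,
    build_phantom,
    suv_centroid,
)

from conftest import naive_h_index, random_volume_and_mask


def _row(values, spacing=(1.0, 1.0, 1.0)):
    vol = SUVVolume(np.asarray(values, float).reshape(-1, 1, 1), spacing)
    return vol, TumorMask(np.ones(vol.shape, bool))


class TestCentroid:
    def test_suv_weighted_mean(self):
        vol, mask = _row([1.0, 3.0])
        assert suv_centroid(vol, mask) == pytest.approx([0.75, 0.0, 0.0])

    def test_constant_suv_gives_geometric_centroid(self):
        vol = SUVVolume(np.full((4, 3, 2), 7.0))
        mask = TumorMask(np.ones((4, 3, 2), bool))
        assert suv_centroid(vol, mask) == pytest.approx([1.5, 1.0, 0.5])

    def test_spacing_scales_position(self):
        vol, mask = _row([1.0, 3.0], spacing=(2.0, 1.0, 1.0))
        assert suv_centroid(vol, mask)[0] == pytest.approx(1.5)

    def test_symmetric_phantom_centroid_is_center(self):
        spec = single_sphere(8.0, grid_shape=(48, 48, 48), r_max=20.0)
        vol = build_phantom(spec)
        c = suv_centroid(vol, sphere_mask(spec))
        assert np.allclose(c, [23.5, 23.5, 23.5], atol=1e-6)

    def test_empty_and_zero_masks_rejected(self):
        vol = SUVVolume(np.zeros((2, 2, 2)))
        with pytest.raises(ValidationError):
            suv_centroid(vol, TumorMask(np.zeros((2, 2, 2), bool)))
        with pytest.raises(ValidationError):
            suv_centroid(vol, TumorMask(np.ones((2, 2, 2), bool)))


class TestDistanceWeights:
    def test_three_voxel_row(self):
        vol, mask = _row([1.0, 1.0, 1.0])
        d, w = distance_weights(vol, mask, np.array([1.0, 0.0, 0.0]))
        assert d.tolist() == [1.0, 0.0, 1.0]
        assert w.tolist() == [1.0, 0.0, 1.0]

    def test_single_voxel_degenerates_to_zero_weight(self):
        vol, mask = _row([5.0])
        d, w = distance_weights(vol, mask, np.zeros(3))
        assert d.tolist() == [0.0] and w.tolist() == [0.0]

    def test_full_cube_dmax_is_corner_distance(self):
        vol = SUVVolume(np.ones((3, 3, 3)))
        mask = TumorMask(np.ones((3, 3, 3), bool))
        c = suv_centroid(vol, mask)
        d, w = distance_weights(vol, mask, c)
        # brute-force maximum over the 27 voxels
        brute = max(
            np.sqrt(((np.array(t) - c) ** 2).sum()) for t in np.ndindex(3, 3, 3)
        )
        assert d.max() == pytest.approx(np.sqrt(3)) == pytest.approx(brute)

    def test_index_space_option_ignores_spacing(self):
        vol, mask = _row([1.0, 1.0, 1.0], spacing=(5.0, 1.0, 1.0))
        c = suv_centroid(vol, mask)  # physical (5, 0, 0)
        d_phys, _ = distance_weights(vol, mask, c, use_physical_spacing=True)
        d_idx, _ = distance_weights(vol, mask, c, use_physical_spacing=False)
        assert d_phys.max() == pytest.approx(5.0)
        assert d_idx.max() == pytest.approx(1.0)


class TestSign:
    def test_center_peaked_phantom_is_positive(self):
        spec = single_sphere(8.0, grid_shape=(48, 48, 48), r_max=20.0)
        vol = build_phantom(spec)
        assert h_index(vol, sphere_mask(spec)).sign == 1

    def test_inverted_profile_is_negative(self):
        spec = single_sphere(8.0, grid_shape=(48, 48, 48), r_max=20.0)
        vol, mask = build_phantom(spec), sphere_mask(spec)
        inv = vol.values.copy()
        lo, hi = inv[mask.member].min(), inv[mask.member].max()
        inv[mask.member] = hi + lo - inv[mask.member]
        assert h_index(SUVVolume(inv), mask).sign == -1

    def test_constant_mask_takes_tie_branch(self):
        vol = SUVVolume(np.full((4, 4, 4), 3.0))
        mask = TumorMask(np.ones((4, 4, 4), bool))
        res = h_index(vol, mask)
        assert res.sign == 1 and res.mean_suv_whole == res.mean_suv_inner

    def test_h_sign_direct(self):
        vol, mask = _row([4.0, 2.0, 4.0])
        d = np.array([1.0, 0.0, 1.0])
        assert h_sign(vol, mask, d, 1.0) == -1


class TestHIndex:
    def test_three_voxel_worked_example(self):
        vol, mask = _row([4.0, 2.0, 4.0])
        res = h_index(vol, mask, HConfig(suv_th=2.5))
        assert res.centroid == pytest.approx([1.0, 0.0, 0.0])
        assert res.magnitude == pytest.approx(1.6 / 3)
        assert res.sign == -1
        assert res.h == pytest.approx(-1.6 / 3)
        assert res.d_max == pytest.approx(1.0)
        assert res.m == 3

    def test_constant_mask_is_zero(self):
        vol = SUVVolume(np.full((5, 4, 3), 9.0))
        mask = TumorMask(np.ones((5, 4, 3), bool))
        assert h_index(vol, mask).h == 0.0

    def test_single_voxel_is_zero_by_convention(self):
        member = np.zeros((3, 3, 3), bool)
        member[1, 1, 1] = True
        vol = SUVVolume(np.full((3, 3, 3), 5.0))
        res = h_index(vol, TumorMask(member))
        assert res.h == 0.0 and res.d_max == 0.0 and res.m == 1

    def test_empty_mask_rejected(self):
        vol = SUVVolume(np.ones((2, 2, 2)))
        with pytest.raises(ValidationError):
            h_index(vol, TumorMask(np.zeros((2, 2, 2), bool)))

    def test_isolated_islands_contribute_zero(self):
        member = np.zeros((5, 1, 1), bool)
        member[0] = member[4] = True  # two voxels, not adjacent
        vol = SUVVolume(np.array([8.0, 0, 0, 0, 4.0]).reshape(5, 1, 1))
        assert h_index(vol, TumorMask(member)).h == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle(self, seed):
        values, member = random_volume_and_mask(seed, max_edge=6)
        got = h_index(SUVVolume(values), TumorMask(member)).h
        want = naive_h_index(values, member)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_oracle_agreement_with_anisotropic_spacing(self):
        values, member = random_volume_and_mask(99, max_edge=6)
        spacing = (2.0, 0.8, 3.5)
        got = h_index(SUVVolume(values, spacing), TumorMask(member)).h
        want = naive_h_index(values, member, spacing=spacing)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_contrast_scaling_linearity(self):
        values, member = random_volume_and_mask(7, max_edge=6)
        mask = TumorMask(member)
        base = h_index(SUVVolume(values), mask)
        scaled = h_index(SUVVolume(3.0 * values), mask)
        assert scaled.magnitude == pytest.approx(3.0 * base.magnitude, rel=1e-12)
        assert np.allclose(scaled.centroid, base.centroid)
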