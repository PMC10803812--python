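"""Confocal stack quantification: filtering, Otsu, base removal, metrics."""

import numpy as np
import pytest

from aquage import (
    BinaryStack,
    FormatError,
    InsufficientDepthError,
    ParameterError,
    ZStack,
    biovolume,
    max_area,
    max_biofilm_height,
    median_denoise,
    merge_binary,
    otsu_binarize,
    quantify_stack,
    remove_base_slices,
    slice_areas,
)
from aquage.synthetic import Cluster, StackScenario, simulate_zstack


def _stack(channel0, pixel_um=1.0, slice_um=1.0):
    """Three-channel stack with the test pattern in channel 0, rest zero."""
    data = np.zeros((3,) + channel0.shape, dtype=np.uint8)
    data[0] = channel0
    return ZStack(data=data, pixel_um=pixel_um, slice_um=slice_um)


def _binary(mask, pixel_um=1.0, slice_um=1.0):
    return BinaryStack(np.asarray(mask, bool), pixel_um, slice_um)


def _otsu_oracle(values):
    """Exhaustive 0..254 search maximizing between-class variance."""
    best_t, best_var = 0, -1.0
    v = values.ravel().astype(float)
    for t in range(255):
        lo, hi = v[v <= t], v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / v.size, hi.size / v.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestMedianDenoise:
    def test_constant_unchanged(self):
        stack = _stack(np.full((5, 8, 8), 7, dtype=np.uint8))
        out = median_denoise(stack, 3)
        assert np.array_equal(out.data, stack.data)

    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(0)
        stack = _stack(rng.integers(0, 255, (4, 6, 6), dtype=np.uint8))
        assert np.array_equal(median_denoise(stack, 1).data, stack.data)

    def test_hot_pixel_removed(self):
        img = np.zeros((5, 9, 9), dtype=np.uint8)
        img[2, 4, 4] = 255
        out = median_denoise(_stack(img), 3)
        assert out.data.sum() == 0

    def test_even_kernel_rejected(self):
        with pytest.raises(ParameterError):
            median_denoise(_stack(np.zeros((5, 4, 4), np.uint8)), 2)


class TestOtsuBinarize:
    def test_bimodal_image_detects_bright_class(self):
        img = np.full((1, 100, 10), 10, dtype=np.uint8)
        img.ravel()[:100] = 200  # 100 px at 200, 900 at 10
        mask = otsu_binarize(_stack(img), "syto9")
        assert mask.mask.sum() == 100

    def test_constant_channel_degenerate(self):
        mask = otsu_binarize(_stack(np.zeros((5, 4, 4), np.uint8)), "syto9")
        assert mask.degenerate and mask.mask.sum() == 0

    def test_two_level_even_split(self):
        img = np.zeros((1, 10, 10), dtype=np.uint8)
        img.ravel()[:50] = 255
        mask = otsu_binarize(_stack(img), "syto9")
        assert mask.mask.sum() == 50

    def test_agrees_with_exhaustive_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            img = rng.integers(0, 256, (3, 16, 16)).astype(np.uint8)
            if np.ptp(img) == 0:
                continue
            mask = otsu_binarize(_stack(img), "syto9")
            assert np.array_equal(mask.mask, img > _otsu_oracle(img))


class TestBaseSliceRemoval:
    def test_drops_first_four(self):
        mask = _binary(np.ones((30, 4, 4)))
        assert remove_base_slices(mask, 4).mask.shape[0] == 26

    def test_artifact_confined_to_base_vanishes(self):
        m = np.zeros((10, 4, 4), bool)
        m[:4] = True
        assert remove_base_slices(_binary(m), 4).mask.sum() == 0

    def test_zero_is_identity(self):
        mask = _binary(np.ones((6, 2, 2)))
        assert np.array_equal(remove_base_slices(mask, 0).mask, mask.mask)

    def test_too_shallow_raises(self):
        with pytest.raises(InsufficientDepthError):
            remove_base_slices(_binary(np.ones((4, 2, 2))), 4)


class TestMergeBinary:
    def test_identity_with_empty(self):
        m = np.zeros((3, 4, 4), bool)
        m[1, 1, 1] = True
        merged = merge_binary([_binary(m), _binary(np.zeros_like(m))])
        assert np.array_equal(merged.mask, m)

    def test_disjoint_union_counts_add(self):
        a = np.zeros((2, 5, 5), bool)
        b = np.zeros((2, 5, 5), bool)
        a.ravel()[:10] = True
        b.ravel()[20:40] = True
        assert merge_binary([_binary(a), _binary(b)]).mask.sum() == 30

    def test_idempotent(self):
        m = np.random.default_rng(3).random((3, 4, 4)) > 0.5
        assert np.array_equal(
            merge_binary([_binary(m), _binary(m)]).mask, m
        )

    def test_order_invariant(self):
        rng = np.random.default_rng(5)
        masks = [_binary(rng.random((3, 4, 4)) > 0.5) for _ in range(3)]
        forward = merge_binary(masks).mask
        backward = merge_binary(masks[::-1]).mask
        assert np.array_equal(forward, backward)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FormatError):
            merge_binary(
                [_binary(np.ones((2, 3, 3))), _binary(np.ones((2, 4, 4)))]
            )


class TestScalarMetrics:
    def test_slice_areas_and_max_area(self):
        m = np.zeros((3, 10, 10), bool)
        m[0, :1, :] = True          # 10 px
        m[1].ravel()[:47] = True    # 47 px
        m[2].ravel()[:23] = True    # 23 px
        areas = slice_areas(_binary(m))
        assert areas.tolist() == [10.0, 47.0, 23.0]
        peak, coverage = max_area(_binary(m))
        assert peak == 47.0 and coverage == pytest.approx(0.47)

    def test_full_slice_at_one_micron(self):
        m = np.zeros((1, 10, 10), bool)
        m[0] = True
        assert slice_areas(_binary(m))[0] == 100.0

    def test_mbh_counts_noncontiguous_slices(self):
        m = np.zeros((20, 4, 4), bool)
        occupied = [0, 2, 3, 7, 19]
        for z in occupied:
            m[z, 0, 0] = True
        assert max_biofilm_height(_binary(m)) == len(occupied) * 1.0

    def test_empty_stack_metrics_zero(self):
        empty = _binary(np.zeros((5, 4, 4), bool))
        assert max_area(empty) == (0.0, 0.0)
        assert max_biofilm_height(empty) == 0.0
        assert biovolume(empty) == 0.0

    def test_biovolume_sums_slice_areas(self):
        m = np.zeros((3, 10, 10), bool)
        m[0] = True
        m[1].ravel()[:50] = True
        m[2].ravel()[:25] = True
        assert biovolume(_binary(m)) == 175.0

    def test_biovolume_bounded_by_imaged_volume(self):
        rng = np.random.default_rng(11)
        m = _binary(rng.random((6, 8, 8)) > 0.4)
        assert biovolume(m) <= 6 * 64 * 1.0


class TestHemisphereGeometry:
    """Voxelized hemisphere against closed-form solid geometry."""

    def _hemisphere_mask(self, radius_um=20.0):
        scn = StackScenario(
            frame_px=64, n_slices=25, pixel_um=1.0, slice_um=1.0,
            clusters=(Cluster(center_um=(32.0, 32.0), radius_um=radius_um),),
            background_density=0.0, seed=0,
        )
        sim = simulate_zstack(scn)
        return _binary(sim.truth.mask_total)

    def test_equatorial_area_near_pi_r_squared(self):
        r = 20.0
        peak, _ = max_area(self._hemisphere_mask(r))
        assert peak == pytest.approx(np.pi * r**2, rel=0.05)

    def test_height_equals_radius(self):
        assert max_biofilm_height(self._hemisphere_mask(20.0)) == 20.0

    def test_biovolume_near_two_thirds_pi_r_cubed(self):
        r = 10.0
        mask = self._hemisphere_mask(r)
        assert biovolume(mask) == float(mask.mask.sum())  # voxel count x 1 µm^3
        assert biovolume(mask) == pytest.approx(2 / 3 * np.pi * r**3, rel=0.10)


class TestQuantifyStack:
    def test_blank_noise_only_stack_is_all_zero(self):
        scn = StackScenario(frame_px=64, n_slices=26, pixel_um=1.0,
                            background_density=0.01, seed=9)
        sim = simulate_zstack(scn)
        m = quantify_stack(ZStack(sim.data, 1.0, 1.0))
        assert m.biovolume_um3 == 0.0 and m.mbh_um == 0.0
        assert m.eps_fraction is None

    def test_pipeline_equals_manual_composition(self, small_cluster_stack):
        sim, scn = small_cluster_stack
        stack = ZStack(sim.data, scn.pixel_um, scn.slice_um)
        m = quantify_stack(stack, kernel=3, base_slices=4)

        den = median_denoise(stack, 3)
        parts = [
            remove_base_slices(otsu_binarize(den, ch), 4)
            for ch in stack.channels
        ]
        total = merge_binary(parts)
        eps = merge_binary(parts[1:])
        peak, coverage = max_area(total)
        assert m.max_area_um2 == peak
        assert m.area_coverage == coverage
        assert m.mbh_um == max_biofilm_height(total)
        assert m.biovolume_um3 == biovolume(total)
        assert m.eps_biovolume_um3 == biovolume(eps)

    def test_channel_permutation_leaves_total_metrics_unchanged(
        self, small_cluster_stack
    ):
        sim, scn = small_cluster_stack
        stack = ZStack(sim.data, scn.pixel_um, scn.slice_um)
        permuted = ZStack(sim.data[[2, 0, 1]], scn.pixel_um, scn.slice_um)
        a = quantify_stack(stack)
        b = quantify_stack(permuted)
        assert (a.biovolume_um3, a.mbh_um, a.max_area_um2) == (
            b.biovolume_um3, b.mbh_um, b.max_area_um2
        )

    def test_adding_voxels_never_decreases_metrics(self, noise_free_cluster_stack):
        sim, scn = noise_free_cluster_stack
        base = quantify_stack(ZStack(sim.data, 1.0, 1.0), kernel=1)
        grown = sim.data.copy()
        grown[0, 10:14, 100:110, 100:110] = 200  # extra detached colony
        more = quantify_stack(ZStack(grown, 1.0, 1.0), kernel=1)
        assert more.biovolume_um3 >= base.biovolume_um3
        assert more.mbh_um >= base.mbh_um
        assert more.max_area_um2 >= base.max_area_um2

    def test_too_few_slices_rejected(self):
        with pytest.raises(InsufficientDepthError):
            quantify_stack(_stack(np.zeros((4, 4, 4), np.uint8)))
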