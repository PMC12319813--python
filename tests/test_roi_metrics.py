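"""ROI statistics, erosion, spatial gradients and volume metrics against
definitional oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmrinorm import (
    LabelMap,
    QuantitativeMap,
    VoxelPhantomSpec,
    combine_labels,
    erode_mask,
    fit_spatial_gradient,
    generate_voxel_phantom,
    roi_statistics,
    volume_metrics,
    volume_pct,
)


def _wrap(values):
    """Embed a 1D value list as an ROI (label 1) in a padded 3D grid."""
    v = np.asarray(values, dtype=float)
    data = np.zeros((1, 1, len(v) + 2))
    data[0, 0, 1:-1] = v
    labels = np.zeros_like(data, dtype=int)
    labels[0, 0, 1:-1] = 1
    eye = np.eye(4)
    return QuantitativeMap(data, eye), LabelMap(labels, eye)


def erosion_oracle(mask: np.ndarray) -> np.ndarray:
    """Voxel kept iff its full 3x3x3 neighbourhood lies inside the mask."""
    out = np.zeros_like(mask, dtype=bool)
    nx, ny, nz = mask.shape
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(1, nz - 1):
                out[i, j, k] = mask[i - 1:i + 2, j - 1:j + 2, k - 1:k + 2].all()
    return out


class TestROIStatistics:
    @pytest.mark.parametrize(
        "values, median, iqr, skew",
        [
            ([1, 2, 3], 2.0, 1.0, 0.0),
            ([1, 2, 3, 4], 2.5, 1.5, 0.0),  # linear-interpolated quantiles
            ([-1, 0, 1], 0.0, 1.0, 0.0),
        ],
    )
    def test_hand_examples(self, values, median, iqr, skew):
        st_ = roi_statistics(*_wrap(values), 1)
        assert st_.median == pytest.approx(median, abs=1e-12)
        assert st_.iqr == pytest.approx(iqr, abs=1e-12)
        assert st_.skewness == pytest.approx(skew, abs=1e-12)

    def test_matches_sort_based_oracle(self, rng):
        values = rng.normal(2.0, 1.5, 4001)
        st_ = roi_statistics(*_wrap(values), 1)
        v = np.sort(values)
        n = len(v)

        def quantile(q):  # linear interpolation between order statistics
            h = (n - 1) * q
            lo = int(np.floor(h))
            return v[lo] + (h - lo) * (v[min(lo + 1, n - 1)] - v[lo])

        assert st_.median == pytest.approx(quantile(0.5), abs=1e-12)
        assert st_.iqr == pytest.approx(quantile(0.75) - quantile(0.25), abs=1e-12)
        m = values.mean()
        g1 = np.mean((values - m) ** 3) / np.mean((values - m) ** 2) ** 1.5
        skew_corr = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        assert st_.skewness == pytest.approx(skew_corr, abs=1e-12)

    def test_invalid_voxels_excluded(self):
        qmap, labels = _wrap([1.0, np.nan, 3.0])
        st_ = roi_statistics(qmap, labels, 1)
        assert st_.median == 2.0 and st_.n_invalid == 1 and st_.n_voxels == 2

    def test_single_voxel_skewness_undefined(self):
        st_ = roi_statistics(*_wrap([4.2]), 1)
        assert st_.median == 4.2 and np.isnan(st_.skewness)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_statistics(*_wrap([1.0]), 99)


class TestErodeMask:
    def test_cube_erodes_to_centre(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True  # 3x3x3 solid cube
        out = erode_mask(mask, 1)
        expected = np.zeros_like(mask)
        expected[2, 2, 2] = True
        assert np.array_equal(out, expected)

    def test_double_erosion_of_5cube(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[1:6, 1:6, 1:6] = True
        out = erode_mask(mask, 2)
        expected = np.zeros_like(mask)
        expected[3, 3, 3] = True
        assert np.array_equal(out, expected)

    def test_single_voxel_erodes_to_empty_error(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="empty"):
            erode_mask(mask, 1, roi_name="SNc")

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_definitional_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((7, 7, 7)) < 0.8
        oracle = erosion_oracle(mask)
        if not oracle.any():
            with pytest.raises(ValueError):
                erode_mask(mask, 1)
        else:
            assert np.array_equal(erode_mask(mask, 1), oracle)


class TestSpatialGradient:
    def test_noiseless_recovery(self):
        spec = VoxelPhantomSpec(gradient_truth=((2.0, -1.0, 0.5),), mean_truth=(10.0,))
        qmap, labels = generate_voxel_phantom(spec, seed=0)
        fit = fit_spatial_gradient(qmap, erode_mask(labels.data == 1, 1))
        assert np.allclose(fit.gradient, [2.0, -1.0, 0.5], atol=1e-10)
        assert fit.p0 == pytest.approx(10.0, abs=1e-10)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_field(self):
        spec = VoxelPhantomSpec(gradient_truth=((0.0, 0.0, 0.0),), mean_truth=(3.3,))
        qmap, labels = generate_voxel_phantom(spec, seed=0)
        fit = fit_spatial_gradient(qmap, labels.data == 1)
        assert np.allclose(fit.gradient, 0.0, atol=1e-12)
        assert fit.p0 == pytest.approx(3.3)

    def test_translation_invariance(self):
        base = VoxelPhantomSpec(
            roi_centres=((20.0, 16.0, 20.0),), gradient_truth=((1.5, 0.7, -0.2),),
            mean_truth=(5.0,),
        )
        moved = VoxelPhantomSpec(
            roi_centres=((20.0, 24.0, 20.0),), gradient_truth=((1.5, 0.7, -0.2),),
            mean_truth=(5.0,),
        )
        fits = []
        for spec in (base, moved):
            qmap, labels = generate_voxel_phantom(spec, seed=0)
            fits.append(fit_spatial_gradient(qmap, labels.data == 1))
        assert np.allclose(fits[0].gradient, fits[1].gradient, atol=1e-10)

    def test_right_hemisphere_flips_lm_sign(self):
        spec = VoxelPhantomSpec(gradient_truth=((2.0, 1.0, 0.0),), mean_truth=(1.0,))
        qmap, labels = generate_voxel_phantom(spec, seed=0)
        mask = labels.data == 1
        left = fit_spatial_gradient(qmap, mask, hemisphere="L")
        right = fit_spatial_gradient(qmap, mask, hemisphere="R")
        assert right.p1 == pytest.approx(-left.p1, abs=1e-10)
        assert right.p2 == pytest.approx(left.p2, abs=1e-10)

    def test_planar_mask_flags_degenerate_axis(self):
        data = np.zeros((10, 10, 10))
        mask = np.zeros_like(data, dtype=bool)
        mask[4, 2:8, 2:8] = True  # flat along x
        data[mask] = 1.0
        fit = fit_spatial_gradient(QuantitativeMap(data, np.eye(4)), mask)
        assert fit.degenerate_axes == (0,)
        assert np.isnan(fit.p1) and np.isfinite(fit.p2)

    def test_too_few_voxels_rejected(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1, 1, 1:4] = True
        with pytest.raises(ValueError, match=">= 8"):
            fit_spatial_gradient(QuantitativeMap(np.zeros((5, 5, 5)), np.eye(4)), mask)


class TestVolumeMetrics:
    def _setup(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[2:4, 2:4, 2:4] = 1  # 8 voxels
        icv = np.ones_like(labels, dtype=bool)
        return LabelMap(labels, np.eye(4)), icv

    def test_fraction_and_pct_arithmetic(self):
        labels, icv = self._setup()
        vm = volume_metrics(labels, 1, icv, population_values=[8 / 1000])
        assert vm.v_roi == pytest.approx(8 / 1000)
        assert vm.v_pct == pytest.approx(0.0, abs=1e-12)  # v_roi equals the mean
        assert volume_pct(1.1 * vm.v_mean, vm.v_mean) == pytest.approx(10.0, abs=1e-10)

    def test_population_pct_mean_is_zero(self, rng):
        pop = rng.uniform(0.001, 0.01, 200)
        pcts = [volume_pct(v, pop.mean()) for v in pop]
        assert np.mean(pcts) == pytest.approx(0.0, abs=1e-10)

    def test_missing_roi_rejected(self):
        labels, icv = self._setup()
        with pytest.raises(ValueError, match="absent"):
            volume_metrics(labels, 9, icv)


class TestCombineLabels:
    def test_union_statistics_match(self, rng):
        data = rng.normal(size=(8, 8, 8))
        labels = np.zeros_like(data, dtype=int)
        labels[1:3, 1:3, 1:3] = 31
        labels[5:7, 5:7, 5:7] = 32
        lm = LabelMap(labels, np.eye(4))
        qmap = QuantitativeMap(data, np.eye(4))
        combined = combine_labels(lm, {31, 32}, 30)
        st_union = roi_statistics(qmap, combined, 30)
        vals = np.concatenate([data[labels == 31], data[labels == 32]])
        assert st_union.median == pytest.approx(np.median(vals))
        assert st_union.n_voxels == (labels == 31).sum() + (labels == 32).sum()

    def test_absent_labels_rejected(self):
        lm = LabelMap(np.ones((3, 3, 3), dtype=int), np.eye(4))
        with pytest.raises(ValueError, match="none of the labels"):
            combine_labels(lm, {5, 6}, 7)

    def test_collision_with_unlisted_label_rejected(self):
        labels = np.ones((3, 3, 3), dtype=int)
        labels[0] = 2
        lm = LabelMap(labels, np.eye(4))
        with pytest.raises(ValueError, match="collides"):
            combine_labels(lm, {1}, 2)
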