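"""Vegetation indices, feature-cube assembly and PCA reduction."""

import numpy as np
import pytest

from cropseg.features import (
    FeatureCube,
    PCAReduced,
    assemble_feature_cube,
    compute_evi,
    compute_ndvi,
    pca_reduce,
    scale_for_model,
)
from cropseg.raster_io import BAND_ROLES, SceneBundle


class TestNDVI:
    def test_hand_value(self):
        out = compute_ndvi(np.array([[0.5]]), np.array([[0.1]]))
        np.testing.assert_allclose(out, 0.4 / 0.6, rtol=1e-6)

    def test_zero_when_equal(self):
        nir = np.full((3, 3), 0.3)
        np.testing.assert_array_equal(compute_ndvi(nir, nir), 0.0)

    def test_upper_bound(self):
        np.testing.assert_allclose(compute_ndvi(np.array([0.8]), np.array([0.0])), 1.0)

    def test_zero_denominator_masked(self):
        out, mask = compute_ndvi(np.zeros(2), np.zeros(2), return_mask=True)
        assert np.all(out == 0) and np.all(mask)

    def test_bounded_for_nonneg_reflectance(self, rng):
        nir, red = rng.random((2, 50, 50))
        out = compute_ndvi(nir, red)
        assert np.all(out >= -1) and np.all(out <= 1)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compute_ndvi(np.zeros((2, 2)), np.zeros((3, 3)))


class TestEVI:
    def test_zero_numerator(self):
        nir = np.full((2, 2), 0.4)
        np.testing.assert_array_equal(compute_evi(nir, nir, np.full((2, 2), 0.1)), 0.0)

    def test_hand_value(self):
        out = compute_evi(np.array([0.5]), np.array([0.1]), np.array([0.04]))
        np.testing.assert_allclose(out, 1.0 / 1.8, rtol=1e-6)

    def test_degenerate_denominator_finite(self):
        # NIR + 6R − 7.5B + 1 = 0 for NIR=0, R=0, B=2/15
        out, mask = compute_evi(
            np.array([0.0]), np.array([0.0]), np.array([2.0 / 15]), return_mask=True
        )
        assert np.isfinite(out).all() and out[0] == 0 and mask[0]


class TestFeatureCube:
    def test_assembly(self, small_scene):
        cube = assemble_feature_cube(small_scene)
        assert cube.values.shape[2] == 12
        np.testing.assert_array_equal(cube.values[:, :, :10], small_scene.bands)
        assert cube.feature_names[-2:] == ("ndvi", "evi")

    def test_ndvi_plane_zero_when_nir_equals_red(self):
        bands = np.full((8, 8, 10), 0.2, dtype=np.float32)
        scene = SceneBundle(
            bands=bands,
            labels=np.zeros((8, 8), np.int64),
            plots=np.ones((8, 8), np.int64),
        )
        cube = assemble_feature_cube(scene)
        np.testing.assert_array_equal(cube.values[:, :, 10], 0.0)

    def test_wrong_depth_rejected(self, rng):
        with pytest.raises(ValueError):
            FeatureCube(values=rng.random((4, 4, 11)))


def _random_cube(rng, h=12, w=9, rank=None):
    if rank is None:
        vals = rng.random((h, w, 12))
    else:
        latent = rng.normal(size=(h * w, rank))
        mix = rng.normal(size=(rank, 12))
        vals = (latent @ mix).reshape(h, w, 12)
    return FeatureCube(values=vals.astype(np.float32))


class TestPCA:
    def test_rank3_explains_everything(self, rng):
        red = pca_reduce(_random_cube(rng, rank=3))
        assert abs(red.explained_variance_ratio.sum() - 1.0) < 1e-6

    def test_loadings_orthonormal(self, rng):
        red = pca_reduce(_random_cube(rng))
        np.testing.assert_allclose(red.loadings.T @ red.loadings, np.eye(3), atol=1e-8)

    def test_variance_ratio_nonincreasing(self, rng):
        red = pca_reduce(_random_cube(rng))
        assert np.all(np.diff(red.explained_variance_ratio) <= 1e-12)

    def test_two_pixel_symmetry(self):
        """Two opposite pixels: PC1 scores are ±c around zero."""
        cube = FeatureCube(values=np.stack([np.zeros((1, 12)), np.ones((1, 12))]))
        red = pca_reduce(cube, n_components=1)
        s = red.values.ravel()
        np.testing.assert_allclose(s[0], -s[1], atol=1e-8)
        assert abs(s[0]) > 0

    def test_pixel_order_invariance(self, rng):
        cube = _random_cube(rng)
        red = pca_reduce(cube)
        perm = rng.permutation(cube.values.shape[0] * cube.values.shape[1])
        shuffled = FeatureCube(
            values=cube.values.reshape(-1, 12)[perm].reshape(cube.values.shape)
        )
        red_p = pca_reduce(shuffled)
        np.testing.assert_allclose(red_p.loadings, red.loadings, atol=1e-8)
        np.testing.assert_allclose(
            red_p.explained_variance_ratio, red.explained_variance_ratio, atol=1e-10
        )

    def test_feature_permutation_equivariance(self, rng):
        """Permuting features permutes the loading rows accordingly."""
        cube = _random_cube(rng)
        perm = rng.permutation(12)
        red = pca_reduce(cube)
        red_p = pca_reduce(FeatureCube(values=cube.values[:, :, perm]))
        np.testing.assert_allclose(red_p.loadings, red.loadings[perm], atol=1e-7)

    def test_zero_variance_feature_warns(self, rng):
        vals = rng.random((6, 6, 12)).astype(np.float32)
        vals[:, :, 4] = 0.7
        with pytest.warns(UserWarning, match="zero-variance"):
            pca_reduce(FeatureCube(values=vals))

    def test_reconstruction_error_rank3(self, rng):
        cube = _random_cube(rng, rank=3)
        red = pca_reduce(cube)
        x = cube.values.reshape(-1, 12).astype(np.float64)
        mean, scale = red.scaler
        xs = (x - mean) / scale
        recon = red.values.reshape(-1, 3) @ red.loadings.T
        rel = np.linalg.norm(xs - recon) / np.linalg.norm(xs)
        assert rel < 1e-6


class TestScaleForModel:
    def _pca(self, values):
        return PCAReduced(
            values=np.asarray(values, np.float32),
            explained_variance_ratio=np.array([1.0]),
            loadings=np.zeros((12, 1)),
            scaler=(np.zeros(12), np.ones(12)),
        )

    def test_midpoint(self):
        out = scale_for_model(self._pca([[[-2.0]], [[2.0]], [[0.0]]]))
        # channel spans [-2, 2]; the 0 pixel lands at 0.5
        assert out[2, 0, 0] == pytest.approx(0.5)

    def test_range_is_unit(self, rng):
        out = scale_for_model(self._pca(rng.normal(size=(6, 5, 1))))
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)

    def test_constant_channel(self):
        out = scale_for_model(self._pca(np.full((4, 4, 1), 7.0)))
        np.testing.assert_array_equal(out, 0.5)
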