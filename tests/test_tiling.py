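"""Patch extraction, augmentation, plot-level splits and tile blending."""

import numpy as np
import pytest

from cropseg.features import scene_to_model_input
from cropseg.synthetic_data import SceneParams, generate_scene
from cropseg.tiling import (
    PatchSet,
    apply_dihedral,
    augment,
    blend_tiles,
    extract_patches,
    split_by_plot,
    tile_offsets,
)


@pytest.fixture(scope="module")
def scene_and_input():
    scene = generate_scene(
        SceneParams(height=96, width=96, n_plots=12, signature_sd=0.02, seed=6)
    )
    return scene, scene_to_model_input(scene)


class TestExtractPatches:
    def test_single_patch_when_exact(self, scene_and_input):
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=96, stride=96)
        assert len(ps) == 1
        np.testing.assert_array_equal(ps.inputs[0], x)

    def test_sliding_window_count(self):
        # (512-256)/128 + 1 = 3 starts per axis → 9 patches
        assert len(tile_offsets(512, 512, 256, 128)) == 9

    def test_top_left_patch_is_identity_crop(self, scene_and_input):
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=32, stride=32)
        np.testing.assert_array_equal(ps.inputs[0], x[:32, :32])
        np.testing.assert_array_equal(ps.labels[0], scene.labels[:32, :32])

    def test_small_scene_reflection_padded(self, scene_and_input):
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=128, stride=128)
        assert ps.inputs.shape[1:3] == (128, 128)

    def test_bad_stride(self, scene_and_input):
        scene, x = scene_and_input
        with pytest.raises(ValueError):
            extract_patches(scene, x, size=32, stride=0)


class TestAugment:
    def test_flip_is_involution(self, rng):
        patch = rng.random((16, 16, 3))
        once = apply_dihedral(patch, True, False, 0)
        assert np.any(once != patch)
        np.testing.assert_array_equal(apply_dihedral(once, True, False, 0), patch)

    def test_input_label_alignment(self, scene_and_input):
        """The same geometric transform hits input and label: class regions
        still overlay the same input pixels."""
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=32, stride=32)
        aug = augment(ps, seed=123)
        for i in range(len(ps)):
            # each (input-pixel, label) pair from the original must exist
            # with identical multiplicity after augmentation
            orig = np.concatenate(
                [ps.inputs[i].reshape(-1, 3), ps.labels[i].reshape(-1, 1)], axis=1
            )
            new = np.concatenate(
                [aug.inputs[i].reshape(-1, 3), aug.labels[i].reshape(-1, 1)], axis=1
            )
            np.testing.assert_array_equal(
                orig[np.lexsort(orig.T)], new[np.lexsort(new.T)]
            )

    def test_class_counts_preserved(self, scene_and_input):
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=32, stride=32)
        aug = augment(ps, seed=7)
        for i in range(len(ps)):
            np.testing.assert_array_equal(
                np.bincount(ps.labels[i].ravel() + 1, minlength=4),
                np.bincount(aug.labels[i].ravel() + 1, minlength=4),
            )

    def test_reproducible(self, scene_and_input):
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=32, stride=32)
        a, b = augment(ps, seed=5), augment(ps, seed=5)
        np.testing.assert_array_equal(a.inputs, b.inputs)


class TestSplitByPlot:
    def test_no_plot_shared(self, scene_and_input):
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=32, stride=16)
        tr, va = split_by_plot(ps, (0.7, 0.3), seed=1)
        tr_plots = set().union(*tr.plot_ids) if len(tr) else set()
        va_plots = set().union(*va.plot_ids) if len(va) else set()
        assert tr_plots and va_plots
        assert not (tr_plots & va_plots)

    def test_label_masking_is_exclusive(self, scene_and_input):
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=32, stride=16)
        tr, va = split_by_plot(ps, (0.7, 0.3), seed=1)
        va_plots = set().union(*va.plot_ids)
        for i in range(len(tr)):
            labeled = tr.labels[i] != -1
            assert not np.isin(tr.plots[i][labeled], sorted(va_plots)).any()

    def test_all_train_when_full_fraction(self, scene_and_input):
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=32, stride=32)
        tr, va = split_by_plot(ps, (1.0, 0.0), seed=0)
        assert len(tr) == len(ps)
        assert len(va) == 0
        np.testing.assert_array_equal(tr.labels, ps.labels)

    def test_deterministic(self, scene_and_input):
        scene, x = scene_and_input
        ps = extract_patches(scene, x, size=32, stride=16)
        a = split_by_plot(ps, (0.7, 0.3), seed=9)
        b = split_by_plot(ps, (0.7, 0.3), seed=9)
        np.testing.assert_array_equal(a[0].labels, b[0].labels)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_too_few_plots(self):
        ps = PatchSet(
            inputs=np.zeros((1, 8, 8, 3), np.float32),
            labels=np.zeros((1, 8, 8), np.int64),
            plot_ids=[frozenset({1})],
            plots=np.ones((1, 8, 8), np.int64),
        )
        with pytest.raises(ValueError):
            split_by_plot(ps, (0.5, 0.5), seed=0)


class TestBlendTiles:
    def test_single_tile_identity(self, rng):
        tile = rng.dirichlet(np.ones(3), size=(8, 8)).astype(np.float32)
        out = blend_tiles([(tile, (0, 0))], 8, 8)
        np.testing.assert_allclose(out, tile, atol=1e-7)

    def test_identical_overlap_idempotent(self, rng):
        tile = rng.dirichlet(np.ones(3), size=(8, 8)).astype(np.float32)
        out = blend_tiles([(tile, (0, 0)), (tile, (0, 0))], 8, 8)
        np.testing.assert_allclose(out, tile, atol=1e-7)

    def test_hand_average(self):
        a = np.zeros((4, 4, 3)); a[..., 0] = 1.0
        b = np.zeros((4, 4, 3)); b[..., 1] = 1.0
        out = blend_tiles([(a, (0, 0)), (b, (0, 2))], 4, 6)
        np.testing.assert_allclose(out[0, 2], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(out[0, 0], [1.0, 0.0, 0.0])

    def test_rows_sum_to_one(self, rng):
        tiles = [
            (rng.dirichlet(np.ones(3), size=(8, 8)), (r, c))
            for r in (0, 4) for c in (0, 4)
        ]
        out = blend_tiles(tiles, 12, 12)
        np.testing.assert_allclose(out.sum(axis=2), 1.0, atol=1e-6)

    def test_uncovered_pixel_raises(self, rng):
        tile = rng.dirichlet(np.ones(3), size=(4, 4))
        with pytest.raises(ValueError, match="not covered"):
            blend_tiles([(tile, (0, 0))], 8, 8)


def test_extract_then_blend_reconstructs_labels(scene_and_input):
    """Identity check: one-hot label tiles blended back equal the raster."""
    scene, x = scene_and_input
    labels = scene.labels
    size, stride = 32, 16
    tiles = []
    for r, c in tile_offsets(*labels.shape, size, stride):
        crop = labels[r : r + size, c : c + size]
        onehot = np.eye(3)[np.clip(crop, 0, 2)]
        onehot[crop < 0] = 1.0 / 3  # uniform where unlabeled
        tiles.append((onehot, (r, c)))
    blended = blend_tiles(tiles, *labels.shape)
    covered = labels >= 0
    np.testing.assert_array_equal(blended.argmax(axis=2)[covered], labels[covered])
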