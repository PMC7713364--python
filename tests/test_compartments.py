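"""Pixel classification and watershed compartment splitting."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import dice
from sxtmorph import RunConfig
from sxtmorph.compartments import (
    CRISTAE,
    MATRIX,
    FeatureConfigError,
    TrainingError,
    classify_compartments,
    seeds_from_masks,
    train_pixel_classifier,
    watershed_interior_split,
)
from sxtmorph.grid import Units, VoxelGrid3D
from sxtmorph.phantom import PhantomSpec, make_phantom

_CONN6 = ndimage.generate_binary_structure(3, 1)


@pytest.fixture(scope="module")
def two_level_phantom():
    spec = PhantomSpec(
        n_objects=1, shape=(72, 72, 72), length_sd=0.0, width_sd=0.0,
        random_orientation=False, seed=9,
    )
    truth = make_phantom(spec)
    obj = truth.objects[0]
    seeds = seeds_from_masks(obj.cristae_mask, obj.matrix_mask, fraction=0.03, rng=9)
    return truth, obj, seeds


def _held_out_accuracy(volume, obj, seeds, cfg):
    clf = train_pixel_classifier(volume, seeds, cfg)
    _, hard = classify_compartments(volume, obj.object_mask, clf)
    held_out = (seeds == 0) & obj.object_mask
    pred_cristae = hard[held_out]
    true_cristae = obj.cristae_mask[held_out]
    return (pred_cristae == true_cristae).mean()


class TestPixelClassifier:
    def test_noiseless_two_level_phantom_separable(self, two_level_phantom):
        truth, obj, seeds = two_level_phantom
        acc = _held_out_accuracy(truth.lac_volume, obj, seeds, RunConfig(seed=9))
        assert acc == 1.0

    def test_gaussian_noise_accuracy(self, two_level_phantom):
        truth, obj, seeds = two_level_phantom
        rng = np.random.default_rng(10)
        noisy = truth.lac_volume.with_data(
            np.clip(truth.lac_volume.data + rng.normal(0, 0.03, truth.lac_volume.shape), 0, None)
        )
        acc = _held_out_accuracy(noisy, obj, seeds, RunConfig(seed=9))
        assert acc >= 0.95

    def test_identical_seed_identical_predictions(self, two_level_phantom):
        truth, obj, seeds = two_level_phantom
        cfg = RunConfig(seed=9)
        a = train_pixel_classifier(truth.lac_volume, seeds, cfg)
        b = train_pixel_classifier(truth.lac_volume, seeds, cfg)
        pa, ha = classify_compartments(truth.lac_volume, obj.object_mask, a)
        pb, hb = classify_compartments(truth.lac_volume, obj.object_mask, b)
        np.testing.assert_array_equal(pa, pb)
        np.testing.assert_array_equal(ha, hb)

    def test_probabilities_normalized(self, two_level_phantom):
        truth, obj, seeds = two_level_phantom
        clf = train_pixel_classifier(truth.lac_volume, seeds, RunConfig(seed=9))
        prob, _ = classify_compartments(truth.lac_volume, obj.object_mask, clf)
        assert prob.min() >= 0.0 and prob.max() <= 1.0
        assert (prob[~obj.object_mask] == 0).all()

    def test_single_class_seeds_rejected(self, two_level_phantom):
        truth, obj, _ = two_level_phantom
        seeds = np.zeros(truth.lac_volume.shape, dtype=np.int8)
        seeds[obj.cristae_mask] = CRISTAE
        with pytest.raises(TrainingError):
            train_pixel_classifier(truth.lac_volume, seeds, RunConfig())

    def test_too_few_seed_voxels_rejected(self, two_level_phantom):
        truth, obj, _ = two_level_phantom
        seeds = np.zeros(truth.lac_volume.shape, dtype=np.int8)
        cz = np.argwhere(obj.cristae_mask)[:60]
        mz = np.argwhere(obj.matrix_mask)[:10]
        seeds[tuple(cz.T)] = CRISTAE
        seeds[tuple(mz.T)] = MATRIX
        with pytest.raises(TrainingError):
            train_pixel_classifier(truth.lac_volume, seeds, RunConfig())

    def test_feature_config_mismatch_detected(self, two_level_phantom):
        truth, obj, seeds = two_level_phantom
        clf = train_pixel_classifier(truth.lac_volume, seeds, RunConfig(seed=9))
        with pytest.raises(FeatureConfigError):
            classify_compartments(truth.lac_volume, obj.object_mask, clf, sigmas=(1.0, 3.0))

    def test_uniform_cristae_volume_labeled_all_cristae(self):
        data = np.full((40, 40, 40), 0.30)
        data[:5] = 0.18  # token matrix region so both classes exist
        g = VoxelGrid3D(data, 0.02, Units.LAC)
        seeds = np.zeros(g.shape, dtype=np.int8)
        seeds[10:12, 10:30, 10:30] = CRISTAE
        seeds[0:2, 10:30, 10:30] = MATRIX
        clf = train_pixel_classifier(g, seeds, RunConfig(seed=0))
        mask = np.zeros(g.shape, dtype=bool)
        mask[20:30, 20:30, 20:30] = True  # uniform cristae-valued region
        _, hard = classify_compartments(g, mask, clf)
        assert hard[mask].all()


def _spherical_shell(shape=(40, 40, 40), inner=10, outer=14):
    c = np.asarray(shape) // 2
    ax = [np.arange(s) for s in shape]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij")
    r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
    shell = (r2 <= outer**2) & (r2 > inner**2)
    obj = r2 <= outer**2
    return shell, obj


class TestWatershedSplit:
    def test_hollow_shell_matrix_is_interior_ball(self):
        shell, obj = _spherical_shell()
        seg = watershed_interior_split(shell, obj)
        expected = 4.0 / 3.0 * np.pi * 10**3
        assert seg.matrix_label.sum() == pytest.approx(expected, rel=0.05)
        np.testing.assert_array_equal(seg.cristae_label | seg.matrix_label, obj)

    def test_solid_ball_has_no_matrix(self):
        _, obj = _spherical_shell()
        seg = watershed_interior_split(obj, obj)  # the whole ball is cristae
        assert not seg.matrix_label.any()

    def test_lamella_splits_matrix_into_two_basins(self):
        shell, obj = _spherical_shell()
        lamella = np.zeros_like(shell)
        lamella[19:21] = True  # plane through the interior
        cristae = shell | (lamella & obj)
        seg = watershed_interior_split(cristae, obj)
        _, n = ndimage.label(seg.matrix_label, structure=_CONN6)
        assert n == 2
        assert not (seg.matrix_label & cristae).any()

    def test_empty_cristae_mask_rejected(self):
        _, obj = _spherical_shell()
        with pytest.raises(ValueError):
            watershed_interior_split(np.zeros_like(obj), obj)

    def test_partition_and_background_isolation(self, fixture_suite):
        for obj, seg in zip(fixture_suite.objects, fixture_suite.segmentations):
            n_c = seg.cristae_label.sum()
            n_m = seg.matrix_label.sum()
            assert n_c + n_m == obj.mask.sum()
            grown = ndimage.binary_dilation(seg.matrix_label, structure=_CONN6)
            assert not (grown & ~obj.mask).any()


class TestRecoveryOnFixtureSuite:
    def test_cristae_dice_and_matrix_volume(self, fixture_suite):
        voxvol = fixture_suite.lac.voxel_volume
        for seg, t in zip(fixture_suite.segmentations, fixture_suite.matched_truth):
            assert dice(seg.cristae_label, t.cristae_mask) >= 0.85
            vm = seg.matrix_label.sum() * voxvol
            vm_true = t.matrix_mask.sum() * voxvol
            assert abs(vm / vm_true - 1) <= 0.10
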