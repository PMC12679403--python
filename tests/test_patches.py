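"""Patch sampling (weighted, rejection-based) and augmentation."""

import warnings

import numpy as np
import pytest
from scipy import stats

from vesselseg.metrics import dice_score
from vesselseg.patches import (AugmentationConfig, SamplerPolicy,
                               apply_augmentation, augment_pair,
                               draw_augmentation_params,
                               invert_augmentation_params, make_batch,
                               sample_origin)
from vesselseg.phantom import PhantomConfig, make_phantom_store
from vesselseg.store import build_store


@pytest.fixture(scope="module")
def four_stores(tmp_path_factory):
    base = tmp_path_factory.mktemp("four")
    return [make_phantom_store(
        PhantomConfig(shape=(64, 64, 64), seed=100 + i), base / f"s{i}",
        chunk_shape=(32, 32, 32)) for i in range(4)]


class TestSampleOrigin:
    def test_origins_uniform_over_valid_grid(self, small_phantom_store):
        policy = SamplerPolicy(patch_shape=(32, 32, 32),
                               vessel_fraction_threshold=0.0,
                               background_retain_prob=1.0)
        rng = np.random.default_rng(0)
        n = 10_000
        # n_valid = 96 - 32 + 1 = 65 origins per axis: 5 bins of 13 each
        counts = np.zeros((5, 3))
        for _ in range(n):
            _, origin = sample_origin([small_phantom_store], policy, rng)
            for ax in range(3):
                counts[origin[ax] // 13, ax] += 1
        for ax in range(3):
            chi2, p = stats.chisquare(counts[:, ax])
            assert p > 0.01, f"axis {ax} non-uniform (p={p})"

    def test_dataset_weights_5411(self, four_stores):
        """Store selection honours the 5:4:1:1 dataset weighting."""
        policy = SamplerPolicy(patch_shape=(32, 32, 32),
                               dataset_weights=(5.0, 4.0, 1.0, 1.0),
                               vessel_fraction_threshold=0.0)
        rng = np.random.default_rng(1)
        n = 11_000
        picks = np.array([sample_origin(four_stores, policy, rng)[0]
                          for _ in range(n)])
        for store_idx, w in enumerate((5, 4, 1, 1)):
            p = w / 11
            freq = (picks == store_idx).mean()
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) <= 3 * sd, (store_idx, freq, p)

    def test_rejection_raises_vessel_positive_rate(self, small_phantom_store):
        """Brute-force census: the accepted-patch vessel rate must exceed
        the unconditioned rate over all valid origins."""
        store = small_phantom_store
        labels = store.read_full("labels").astype(np.int64)
        patch = 32
        threshold = 0.001
        # integral image census of all valid origins
        c = labels.cumsum(0).cumsum(1).cumsum(2)
        cp = np.pad(c, ((1, 0), (1, 0), (1, 0)))
        n_valid = labels.shape[0] - patch + 1
        sums = (cp[patch:, patch:, patch:]
                - cp[:-patch, patch:, patch:]
                - cp[patch:, :-patch, patch:]
                - cp[patch:, patch:, :-patch]
                + cp[:-patch, :-patch, patch:]
                + cp[:-patch, patch:, :-patch]
                + cp[patch:, :-patch, :-patch]
                - cp[:-patch, :-patch, :-patch])
        unconditioned = (sums / patch ** 3 >= threshold).mean()
        assert 0.0 < unconditioned < 1.0

        policy = SamplerPolicy(patch_shape=(patch,) * 3,
                               vessel_fraction_threshold=threshold,
                               background_retain_prob=0.1)
        rng = np.random.default_rng(2)
        hits = 0
        n = 400
        for _ in range(n):
            _, origin = sample_origin([store], policy, rng)
            win = store.read_subvolume(origin, (patch,) * 3, "labels")
            hits += win.mean() >= threshold
        assert hits / n > unconditioned

    def test_store_smaller_than_patch_rejected(self, tiny_phantom_store):
        policy = SamplerPolicy(patch_shape=(64, 64, 64))
        with pytest.raises(ValueError, match="smaller than patch"):
            sample_origin([tiny_phantom_store], policy,
                          np.random.default_rng(0))

    def test_all_background_store_terminates(self, tmp_path):
        store = build_store(np.random.default_rng(0).random((40, 40, 40)),
                            labels=np.zeros((40, 40, 40), dtype=np.uint8),
                            out_path=tmp_path / "bg")
        policy = SamplerPolicy(patch_shape=(32, 32, 32),
                               vessel_fraction_threshold=0.001,
                               background_retain_prob=0.0)
        with pytest.warns(UserWarning, match="rejection cap"):
            idx, origin = sample_origin([store], policy,
                                        np.random.default_rng(0))
        assert idx == 0


class TestAugmentation:
    def _patch(self, rng, n=32):
        img = rng.random((n, n, n)).astype(np.float32)
        lab = np.zeros((n, n, n), dtype=np.uint8)
        lab[:, n // 4: n // 2, n // 4: 3 * n // 4] = 1
        return img, lab

    def test_identity_draw_is_bitwise_noop(self, rng):
        img, lab = self._patch(rng)
        params = {"angle_deg": 0.0, "scale": 1.0, "flip_axes": ()}
        img2, lab2 = apply_augmentation(img, lab, params)
        np.testing.assert_array_equal(img2, img)
        np.testing.assert_array_equal(lab2, lab)

    def test_reflection_is_involution(self, rng):
        img, lab = self._patch(rng)
        params = {"angle_deg": 0.0, "scale": 1.0, "flip_axes": (1, 2)}
        once = apply_augmentation(img, lab, params)
        twice = apply_augmentation(*once, params)
        np.testing.assert_array_equal(twice[0], img)
        np.testing.assert_array_equal(twice[1], lab)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_inverse_transform_consistency(self, seed):
        """Applying recorded params then their inverse restores the label
        up to interpolation (DICE >= 0.95)."""
        rng = np.random.default_rng(seed)
        img, lab = self._patch(rng)
        config = AugmentationConfig()
        params = draw_augmentation_params(config, rng)
        img_t, lab_t = apply_augmentation(img, lab, params)
        inv = invert_augmentation_params(params)
        _, lab_b = apply_augmentation(img_t, lab_t, inv)
        assert dice_score(lab_b, lab) >= 0.95

    def test_label_stays_binary_image_stays_unit(self, rng):
        img, lab = self._patch(rng)
        config = AugmentationConfig()
        for seed in range(5):
            r = np.random.default_rng(seed)
            img_t, lab_t, params = augment_pair(img, lab, config, r)
            assert set(np.unique(lab_t)) <= {0, 1}
            assert img_t.min() >= 0.0 and img_t.max() <= 1.0
            assert img_t.shape == img.shape
            assert lab_t.shape == lab.shape

    def test_rotation_range_validated(self):
        with pytest.raises(ValueError):
            AugmentationConfig(rotation_range_deg=(-200.0, 30.0))


class TestMakeBatch:
    def test_batch_of_six_64cubed(self, small_phantom_store):
        policy = SamplerPolicy(patch_shape=(64, 64, 64),
                               vessel_fraction_threshold=0.0)
        batch = make_batch([small_phantom_store], policy,
                           AugmentationConfig(), 6,
                           np.random.default_rng(0))
        assert batch.images.shape == (6, 64, 64, 64)
        assert batch.labels.shape == (6, 64, 64, 64)
        assert len(batch.provenance) == 6
        assert batch.provenance[0]["store"] == small_phantom_store.name

    def test_same_seed_identical_batches(self, small_phantom_store):
        policy = SamplerPolicy(patch_shape=(32, 32, 32))
        b1 = make_batch([small_phantom_store], policy, AugmentationConfig(),
                        4, np.random.default_rng(42))
        b2 = make_batch([small_phantom_store], policy, AugmentationConfig(),
                        4, np.random.default_rng(42))
        np.testing.assert_array_equal(b1.images, b2.images)
        np.testing.assert_array_equal(b1.labels, b2.labels)
        assert b1.provenance == b2.provenance

    def test_retain_prob_sweep_lowers_positive_rate(self, small_phantom_store):
        """Raising background_retain_prob moves the accepted vessel-positive
        frequency toward the unconditioned rate."""
        rates = {}
        for retain in (0.1, 1.0):
            policy = SamplerPolicy(patch_shape=(32, 32, 32),
                                   vessel_fraction_threshold=0.01,
                                   background_retain_prob=retain)
            rng = np.random.default_rng(3)
            hits = 0
            for _ in range(150):
                _, origin = sample_origin([small_phantom_store], policy, rng)
                win = small_phantom_store.read_subvolume(
                    origin, (32, 32, 32), "labels")
                hits += win.mean() >= 0.01
            rates[retain] = hits / 150
        assert rates[0.1] > rates[1.0]
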