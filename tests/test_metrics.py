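import numpy as np
import pytest

from ronisteg import (
    AlignmentError,
    AttackSpec,
    EmbeddingKey,
    MedicalImage,
    MetricsReport,
    apply_attack,
    compute_mse,
    compute_psnr,
    robustness_trial,
)


def _img(arr, depth=16):
    return MedicalImage(np.asarray(arr, dtype=np.uint16), bit_depth=depth)


class TestMSE:
    def test_identical_images(self, rng):
        a = _img(rng.integers(0, 65536, (8, 8)))
        assert compute_mse(a, a) == 0.0

    def test_hand_evaluated(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        b[0, 0], b[0, 1] = 3, 4
        # (9 + 16) / 64
        assert compute_mse(_img(a), _img(b)) == pytest.approx(25 / 64)

    def test_symmetry(self, rng):
        a = _img(rng.integers(0, 65536, (8, 8)))
        b = _img(rng.integers(0, 65536, (8, 8)))
        assert compute_mse(a, b) == compute_mse(b, a)

    def test_shape_mismatch(self, rng):
        with pytest.raises(AlignmentError):
            compute_mse(_img(np.zeros((8, 8))), _img(np.zeros((8, 12))))


class TestPSNR:
    def test_identical_is_infinite(self):
        a = _img(np.zeros((8, 8)))
        assert np.isinf(compute_psnr(a, a))

    def test_unit_mse_closed_form(self):
        a = _img(np.zeros((8, 8)))
        b = _img(np.ones((8, 8)))
        assert compute_psnr(a, b) == pytest.approx(10 * np.log10(65535**2), abs=1e-9)
        assert round(compute_psnr(a, b), 2) == 96.33

    def test_doubling_error_costs_six_db(self):
        a = _img(np.zeros((8, 8)))
        b1 = _img(np.full((8, 8), 2))
        b2 = _img(np.full((8, 8), 4))
        drop = compute_psnr(a, b1) - compute_psnr(a, b2)
        assert drop == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_peak_uses_bit_depth(self):
        a12 = _img(np.zeros((8, 8)), depth=12)
        b12 = _img(np.ones((8, 8)), depth=12)
        assert compute_psnr(a12, b12) == pytest.approx(10 * np.log10(4095**2))

    def test_depth_mismatch(self):
        with pytest.raises(AlignmentError):
            compute_psnr(_img(np.zeros((8, 8)), 16), _img(np.zeros((8, 8)), 12))


class TestMetricsReport:
    def test_psnr_infinity_iff_zero_mse(self):
        MetricsReport(mse=0.0, psnr_db=float("inf"))
        MetricsReport(mse=1.0, psnr_db=96.33)
        with pytest.raises(ValueError):
            MetricsReport(mse=0.0, psnr_db=96.33)
        with pytest.raises(ValueError):
            MetricsReport(mse=1.0, psnr_db=float("inf"))


class TestAttacks:
    @pytest.mark.parametrize("spec", [
        AttackSpec("gaussian", {"sigma": 0.0}),
        AttackSpec("uniform", {"half_width": 0.0}),
        AttackSpec("salt_pepper", {"density": 0.0}),
    ])
    def test_null_attack_is_identity(self, rng, spec):
        img = _img(rng.integers(0, 65536, (16, 16)))
        np.testing.assert_array_equal(apply_attack(img, spec).pixels, img.pixels)

    def test_salt_pepper_full_density(self, rng):
        img = _img(rng.integers(1, 65535, (16, 16)))
        out = apply_attack(img, AttackSpec("salt_pepper", {"density": 1.0}, seed=3))
        assert set(np.unique(out.pixels)) <= {0, 65535}

    def test_gaussian_mse_matches_sigma_squared(self):
        img = _img(np.full((1024, 1024), 32768))
        sigma = 500.0
        out = apply_attack(img, AttackSpec("gaussian", {"sigma": sigma}, seed=9))
        mse = compute_mse(img, out)
        # rounding adds 1/12 variance; 5% tolerance on >=1e6 samples
        assert mse == pytest.approx(sigma**2, rel=0.05)

    def test_seeded_attack_is_reproducible(self, rng):
        img = _img(rng.integers(0, 65536, (32, 32)))
        spec = AttackSpec("uniform", {"half_width": 300.0}, seed=21)
        np.testing.assert_array_equal(apply_attack(img, spec).pixels,
                                      apply_attack(img, spec).pixels)

    def test_invalid_specs(self):
        with pytest.raises(Exception):
            AttackSpec("speckle", {})
        with pytest.raises(Exception):
            AttackSpec("salt_pepper", {"density": 1.5})


class TestRobustnessTrial:
    def test_null_attack_recovers_everything(self, mr_phantom, mr_mask,
                                             message_blocks):
        cover, _ = mr_phantom
        out = robustness_trial(cover, mr_mask, message_blocks, EmbeddingKey(),
                               AttackSpec("gaussian", {"sigma": 0.0}))
        assert out["ncc_message"] == pytest.approx(1.0, abs=1e-3)
        assert out["bit_accuracy"] == 1.0
        assert out["decoded"] is True
        assert np.isfinite(out["psnr_db"])

    def test_extreme_attack_destroys_message(self, mr_phantom, mr_mask,
                                             message_blocks):
        cover, _ = mr_phantom
        out = robustness_trial(cover, mr_mask, message_blocks, EmbeddingKey(),
                               AttackSpec("salt_pepper", {"density": 0.9}, seed=5))
        assert abs(out["ncc_message"]) < 0.2
        assert out["decoded"] is False

    def test_fixed_seed_reproducible(self, mr_phantom, mr_mask, message_blocks):
        cover, _ = mr_phantom
        spec = AttackSpec("gaussian", {"sigma": 100.0}, seed=77)
        a = robustness_trial(cover, mr_mask, message_blocks, EmbeddingKey(), spec)
        b = robustness_trial(cover, mr_mask, message_blocks, EmbeddingKey(), spec)
        assert a == b
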