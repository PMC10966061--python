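import numpy as np
import pytest

from ronisteg import (
    BinaryMask,
    CapacityError,
    EmbeddingKey,
    MedicalImage,
    MessageBlocks,
    ParameterError,
    adjust_message,
    blockify_message,
    capacity_report,
    dct2,
    embed,
    extract,
    idct2,
    iqun,
    plan_tiles,
    qr_to_text,
    qun,
    text_to_qr,
    threshold_mask,
    unblockify_and_decide,
)


def brute_force_dct2(block):
    """Independent O(N^4) evaluation of the orthonormal type-II 2D-DCT."""
    M, N = block.shape
    out = np.zeros((M, N))
    for u in range(M):
        for v in range(N):
            au = np.sqrt(1.0 / M) if u == 0 else np.sqrt(2.0 / M)
            av = np.sqrt(1.0 / N) if v == 0 else np.sqrt(2.0 / N)
            s = 0.0
            for m in range(M):
                for n in range(N):
                    s += (block[m, n]
                          * np.cos((2 * m + 1) * u * np.pi / (2 * M))
                          * np.cos((2 * n + 1) * v * np.pi / (2 * N)))
            out[u, v] = au * av * s
    return out


class TestTransforms:
    def test_matches_brute_force_double_sum(self, rng):
        for _ in range(50):
            b = rng.random((4, 4))
            np.testing.assert_allclose(dct2(b), brute_force_dct2(b), atol=1e-12)

    def test_constant_block_concentrates_in_dc(self):
        c = 0.7
        coeffs = dct2(np.full((4, 4), c))
        assert coeffs[0, 0] == pytest.approx(4 * c)
        assert np.abs(coeffs).sum() == pytest.approx(4 * c)

    def test_dc_only_inverts_to_constant(self):
        coeffs = np.zeros((4, 4))
        coeffs[0, 0] = 4.0
        np.testing.assert_allclose(idct2(coeffs), np.ones((4, 4)), atol=1e-12)

    def test_inverse_pair_and_parseval(self, rng):
        for _ in range(50):
            b = rng.random((4, 4))
            c = dct2(b)
            np.testing.assert_allclose(idct2(c), b, atol=1e-12)
            assert np.sum(b * b) == pytest.approx(np.sum(c * c))

    def test_zero_block(self):
        np.testing.assert_array_equal(dct2(np.zeros((4, 4))), np.zeros((4, 4)))


class TestQuantizer:
    def test_hand_evaluated_cells_beta8(self):
        # cell width 4/8 = 0.5; 0.6 lies in cell k=1 => base 0.5
        assert qun(0.6, 0.98, 8) == pytest.approx(0.99)
        assert qun(0.6, 0.02, 8) == pytest.approx(0.51)
        assert qun(-0.6, 0.98, 8) == pytest.approx(-0.99)

    def test_output_stays_inside_its_cell(self, rng):
        for _ in range(500):
            c = rng.uniform(-4, 4)
            beta = int(rng.integers(2, 2001))
            m = 0.02 if rng.random() < 0.5 else 0.98
            out = abs(qun(c, m, beta))
            k = min(int(abs(c) * beta / 4), beta - 1)
            assert 4 * k / beta < out < 4 * (k + 1) / beta

    def test_iqun_hand_cases(self):
        assert iqun(0.99, 8) == pytest.approx(0.98)
        assert iqun(0.51, 8) == pytest.approx(0.02)

    def test_iqun_inverts_qun(self, rng):
        c = rng.uniform(-4, 4, size=2000)
        for beta in (2, 3, 10, 100, 999, 2000):
            for m in (0.02, 0.98):
                np.testing.assert_allclose(iqun(qun(c, m, beta), beta), m, atol=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            qun(5.0, 0.5, 10)
        with pytest.raises(ParameterError):
            qun(0.5, 1.5, 10)
        with pytest.raises(ParameterError):
            qun(0.5, 0.5, 1)


class TestTilePlanning:
    def test_all_significant_gives_empty_plan(self):
        plan = plan_tiles(BinaryMask(np.ones((8, 8), dtype=np.uint8)))
        assert len(plan) == 0

    def test_all_background_8x8_row_major(self):
        plan = plan_tiles(BinaryMask(np.zeros((8, 8), dtype=np.uint8)))
        assert plan.tile_origins == [(0, 0), (0, 4), (4, 0), (4, 4)]

    def test_single_significant_pixel_excludes_its_tile(self):
        labels = np.zeros((8, 8), dtype=np.uint8)
        labels[0, 0] = 1
        plan = plan_tiles(BinaryMask(labels))
        assert plan.tile_origins == [(0, 4), (4, 0), (4, 4)]

    def test_seeded_permutation_is_deterministic(self):
        mask = BinaryMask(np.zeros((32, 32), dtype=np.uint8))
        key = EmbeddingKey(tile_order_seed=7)
        a = plan_tiles(mask, key=key)
        b = plan_tiles(mask, key=key)
        assert a.tile_origins == b.tile_origins
        assert sorted(a.tile_origins) == plan_tiles(mask).tile_origins


class TestCapacity:
    def test_all_background_is_one_bit_per_pixel(self):
        rep = capacity_report(BinaryMask(np.zeros((64, 64), dtype=np.uint8)))
        assert rep["capacity_bits"] == 64 * 64
        assert rep["capacity_bpp"] == 1.0
        assert rep["usable_fraction"] == 1.0

    def test_all_significant_is_zero(self):
        rep = capacity_report(BinaryMask(np.ones((64, 64), dtype=np.uint8)))
        assert rep["capacity_bits"] == 0

    def test_half_background_is_half_bpp(self):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[:, 32:] = 1
        rep = capacity_report(BinaryMask(labels))
        assert rep["capacity_bpp"] == 0.5


def _empty_message():
    return MessageBlocks(blocks=np.zeros((0, 4, 4)), original_shape=(0, 0))


class TestEmbedExtract:
    def test_zero_payload_is_pixel_identical(self, ct_phantom, ct_mask):
        cover, _ = ct_phantom
        res = embed(cover, ct_mask, _empty_message())
        assert res.verified
        np.testing.assert_array_equal(res.stego.pixels, cover.pixels)

    def test_untouched_pixels_bit_identical(self, ct_phantom, ct_mask, message_blocks):
        from ronisteg.stego import _select_tiles

        cover, _ = ct_phantom
        key = EmbeddingKey(beta=500)
        res = embed(cover, ct_mask, message_blocks, key, verify=False)
        plan = plan_tiles(ct_mask, key=key, margin_px=key.margin_px)
        touched = np.zeros(cover.shape, dtype=bool)
        for r, c in _select_tiles(plan, len(message_blocks), key.tile_spacing):
            touched[r: r + 4, c: c + 4] = True
        np.testing.assert_array_equal(res.stego.pixels[~touched],
                                      cover.pixels[~touched])

    def test_capacity_error_reports_required_vs_available(self, ct_phantom, ct_mask):
        cover, _ = ct_phantom
        huge = MessageBlocks(blocks=np.full((30000, 4, 4), 0.02),
                             original_shape=(600, 800))
        with pytest.raises(CapacityError) as err:
            embed(cover, ct_mask, huge)
        assert err.value.required == 30000
        assert err.value.available < 30000

    @pytest.mark.parametrize("beta", [10, 1000])
    def test_roundtrip_through_receiver_mask(self, mr_phantom, mr_mask, record,
                                             message_blocks, beta):
        cover, _ = mr_phantom
        res = embed(cover, mr_mask, message_blocks, EmbeddingKey(beta=beta),
                    verify=False)
        rx_mask = threshold_mask(res.stego)
        key = EmbeddingKey(beta=beta, message_shape=message_blocks.original_shape)
        rec = extract(res.stego, rx_mask, key,
                      (res.manifest["norm_min"], res.manifest["norm_max"]))
        np.testing.assert_array_equal(rec.blocks >= 0.5, message_blocks.blocks >= 0.5)
        assert qr_to_text(unblockify_and_decide(rec)) == record

    def test_self_verification_flag(self, mr_phantom, mr_mask, message_blocks):
        cover, _ = mr_phantom
        res = embed(cover, mr_mask, message_blocks, EmbeddingKey(beta=1000))
        assert res.verified
        assert res.manifest["tiles_used"] == len(message_blocks)

    def test_wrong_beta_fails_qr_decode(self, mr_phantom, mr_mask, message_blocks):
        from ronisteg import QRDecodeError

        cover, _ = mr_phantom
        res = embed(cover, mr_mask, message_blocks, EmbeddingKey(beta=1000),
                    verify=False)
        bad_key = EmbeddingKey(beta=777, message_shape=message_blocks.original_shape)
        rec = extract(res.stego, threshold_mask(res.stego), bad_key,
                      (res.manifest["norm_min"], res.manifest["norm_max"]))
        with pytest.raises(QRDecodeError):
            qr_to_text(unblockify_and_decide(rec))

    def test_imperceptibility_improves_with_beta(self, mr_phantom, mr_mask,
                                                 message_blocks):
        from ronisteg import compute_psnr

        cover, _ = mr_phantom
        psnrs = []
        for beta in (10, 100, 1000):
            res = embed(cover, mr_mask, message_blocks, EmbeddingKey(beta=beta),
                        verify=False)
            cover16 = MedicalImage(cover.pixels, bit_depth=res.stego.bit_depth)
            psnrs.append(compute_psnr(cover16, res.stego))
        assert psnrs == sorted(psnrs)
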