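"""Acquisition model: Fourier operators, mask generation, undersampling,
zero-filling and data consistency."""

import numpy as np
import pytest

from grdrn import kspace
from grdrn.containers import DynamicSequence, KSpaceSequence, SamplingMask

RNG = np.random.default_rng(11)


def naive_centered_dft(x):
    """O(n^2) centered orthonormal 2D DFT, written independently."""
    H, W = x.shape
    out = np.zeros((H, W), complex)
    r = np.arange(H)
    c = np.arange(W)
    # centered conventions: spatial origin at index n//2, DC at k = n//2
    for ku in range(H):
        for kv in range(W):
            u, v = ku - H // 2, kv - W // 2
            phase = np.exp(-2j * np.pi * (np.add.outer((r - H // 2) * u / H,
                                                       (c - W // 2) * v / W)))
            out[ku, kv] = (x * phase).sum()
    return out / np.sqrt(H * W)


class TestFourierPair:
    def test_unit_impulse_at_center_gives_flat_spectrum(self):
        x = np.zeros((8, 10), complex)
        x[4, 5] = 1.0
        k = kspace.forward_fft(x)
        np.testing.assert_allclose(k, np.full((8, 10), 1 / np.sqrt(80)),
                                   atol=1e-12)

    def test_round_trip_and_parseval(self):
        x = RNG.normal(size=(12, 16)) + 1j * RNG.normal(size=(12, 16))
        k = kspace.forward_fft(x)
        np.testing.assert_allclose(kspace.inverse_fft(k), x, atol=1e-10)
        assert np.isclose(np.linalg.norm(x), np.linalg.norm(k), rtol=1e-10)

    def test_matches_naive_centered_dft(self):
        x = RNG.normal(size=(8, 8)) + 1j * RNG.normal(size=(8, 8))
        np.testing.assert_allclose(kspace.forward_fft(x),
                                   naive_centered_dft(x), atol=1e-8)

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            kspace.forward_fft(np.ones(5))


class TestMaskGeneration:
    def test_acceleration_one_gives_all_ones(self):
        m = kspace.generate_mask(16, 12, 3, 1, rng_seed=0)
        assert np.all(m.masks == 1)

    def test_line_count_and_central_lines_at_paper_matrix(self):
        # 176 x 144 matrix, phase-encode size 144, 8x -> 18 lines
        m = kspace.generate_mask(144, 176, 4, 8, rng_seed=1)
        assert m.masks.shape == (4, 176, 144)
        np.testing.assert_array_equal(m.lines_per_frame(), [18] * 4)
        central = kspace.central_line_indices(144)
        np.testing.assert_array_equal(central, [70, 71, 72, 73, 74])
        assert np.all(m.masks[:, :, central] == 1)

    def test_columns_constant_along_frequency_encode(self):
        m = kspace.generate_mask(32, 24, 2, 4, rng_seed=2)
        assert np.all(m.masks == m.masks[:, :1, :])

    def test_frames_differ_and_seed_reproducible(self):
        a = kspace.generate_mask(64, 64, 6, 8, rng_seed=3)
        b = kspace.generate_mask(64, 64, 6, 8, rng_seed=3)
        c = kspace.generate_mask(64, 64, 6, 8, rng_seed=4)
        np.testing.assert_array_equal(a.masks, b.masks)
        assert not np.array_equal(a.masks, c.masks)
        assert any(not np.array_equal(a.masks[0], a.masks[t])
                   for t in range(1, 6))

    def test_shared_mask_mode(self):
        m = kspace.generate_mask(64, 64, 5, 8, rng_seed=5,
                                 shared_across_frames=True)
        for t in range(1, 5):
            np.testing.assert_array_equal(m.masks[0], m.masks[t])

    def test_too_high_acceleration_warns_and_keeps_central_lines(self):
        with pytest.warns(UserWarning):
            m = kspace.generate_mask(32, 16, 2, 16, rng_seed=6)
        np.testing.assert_array_equal(m.lines_per_frame(), [5, 5])

    def test_invalid_acceleration_rejected(self):
        with pytest.raises(ValueError):
            kspace.generate_mask(32, 32, 2, 0.5, rng_seed=0)

    @pytest.mark.parametrize("accel", [8, 12, 16])
    def test_supported_presets(self, accel):
        m = kspace.generate_mask(144, 176, 2, accel, rng_seed=7)
        assert m.lines_per_frame()[0] == round(144 / accel)


class TestUndersampleZeroFill:
    def test_all_ones_mask_is_identity(self):
        spec = RNG.normal(size=(2, 8, 8)) + 1j * RNG.normal(size=(2, 8, 8))
        full = KSpaceSequence(spectra=spec)
        mask = SamplingMask(masks=np.ones((2, 8, 8), np.uint8))
        out = kspace.undersample(full, mask)
        np.testing.assert_array_equal(out.spectra, spec)
        assert out.is_undersampled

    def test_masked_entries_exactly_zero(self):
        spec = RNG.normal(size=(1, 4, 4)) + 1j * RNG.normal(size=(1, 4, 4))
        masks = np.zeros((1, 4, 4), np.uint8)
        masks[:, :, 1] = 1
        masks[:, :, 3] = 1
        out = kspace.undersample(KSpaceSequence(spectra=spec),
                                 SamplingMask(masks=masks))
        assert np.all(out.spectra[:, :, [0, 2]] == 0)
        np.testing.assert_array_equal(out.spectra[:, :, [1, 3]],
                                      spec[:, :, [1, 3]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kspace.undersample(
                KSpaceSequence(spectra=np.zeros((1, 4, 4), complex)),
                SamplingMask(masks=np.ones((1, 4, 6), np.uint8)))

    def test_zero_fill_of_full_spectra_recovers_frames(self):
        frames = RNG.normal(size=(3, 8, 8)) + 1j * RNG.normal(size=(3, 8, 8))
        seq = DynamicSequence(frames=frames)
        back = kspace.zero_fill_recon(kspace.sequence_to_kspace(seq))
        np.testing.assert_allclose(back.frames, frames, atol=1e-10)

    def test_zero_fill_preserves_sampled_lines_under_aliasing(self):
        # a one-bright-pixel phantom at 8x: re-projecting the aliased image
        # must reproduce the acquired lines exactly
        frames = np.zeros((1, 32, 32), complex)
        frames[0, 10, 13] = 1.0
        full = kspace.sequence_to_kspace(DynamicSequence(frames=frames))
        with pytest.warns(UserWarning):
            mask = kspace.generate_mask(32, 32, 1, 8, rng_seed=9)
        under = kspace.undersample(full, mask)
        aliased = kspace.zero_fill_recon(under)
        reproj = kspace.forward_fft(aliased.frames)
        np.testing.assert_allclose(reproj * mask.masks, under.spectra,
                                   atol=1e-10)


class TestDataConsistency:
    def _toy(self):
        img = RNG.normal(size=(4, 4)) + 1j * RNG.normal(size=(4, 4))
        acq = RNG.normal(size=(4, 4)) + 1j * RNG.normal(size=(4, 4))
        mask = np.zeros((4, 4))
        mask[:, :2] = 1
        return img, acq, mask

    def test_matches_handwritten_formula(self):
        img, acq, mask = self._toy()
        out = kspace.data_consistency(img, acq, mask)
        expected = kspace.inverse_fft(mask * acq
                                      + (1 - mask) * kspace.forward_fft(img))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_sampled_coefficients_replaced_unsampled_kept(self):
        img, acq, mask = self._toy()
        out_k = kspace.forward_fft(kspace.data_consistency(img, acq, mask))
        in_k = kspace.forward_fft(img)
        np.testing.assert_allclose(out_k[mask == 1], acq[mask == 1],
                                   rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(out_k[mask == 0], in_k[mask == 0],
                                   rtol=1e-10, atol=1e-12)

    def test_idempotent(self):
        img, acq, mask = self._toy()
        once = kspace.data_consistency(img, acq, mask)
        twice = kspace.data_consistency(once, acq, mask)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_fixed_point_when_already_consistent(self):
        img, acq, mask = self._toy()
        consistent = kspace.data_consistency(img, acq, mask)
        np.testing.assert_allclose(
            kspace.data_consistency(consistent, acq, mask), consistent,
            atol=1e-10)

    def test_mask_all_ones_full_replacement(self):
        img, acq, _ = self._toy()
        out = kspace.data_consistency(img, acq, np.ones((4, 4)))
        np.testing.assert_allclose(out, kspace.inverse_fft(acq), atol=1e-10)

    def test_mask_all_zeros_no_replacement(self):
        img, acq, _ = self._toy()
        out = kspace.data_consistency(img, acq, np.zeros((4, 4)))
        np.testing.assert_allclose(out, img, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kspace.data_consistency(np.zeros((4, 4)), np.zeros((4, 6)),
                                    np.zeros((4, 4)))


def test_mask_density_non_increasing_from_center():
    """Sampling frequency of non-central lines decays with |offset| (1000
    seeded draws, binomial tolerance)."""
    n_pe, n_draws = 64, 1000
    counts = np.zeros(n_pe)
    for s in range(n_draws):
        m = kspace.generate_mask(n_pe, 4, 1, 8, rng_seed=s)
        counts += m.masks[0, 0, :]
    central = set(kspace.central_line_indices(n_pe).tolist())
    center = n_pe // 2
    offsets = sorted({abs(i - center) for i in range(n_pe)
                      if i not in central})
    freq_by_offset = []
    for off in offsets:
        idx = [i for i in range(n_pe)
               if abs(i - center) == off and i not in central]
        freq_by_offset.append(counts[idx].mean() / n_draws)
    # allow binomial noise: compare smoothed neighbours
    tol = 3 * np.sqrt(0.25 / n_draws)
    for a, b in zip(freq_by_offset[:-1], freq_by_offset[1:]):
        assert b <= a + tol
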