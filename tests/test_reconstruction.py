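"""Unrolled cascade: motion-augmented generation, residual dealiasing,
per-iteration data consistency, and the motion-free ablation."""

import numpy as np
import pytest

from grdrn import kspace
from grdrn.autodiff import Tensor
from grdrn.containers import DynamicSequence
from grdrn.phantom import PhantomConfig, generate_sequence
from grdrn.reconstruction import (DealiasingNetwork, ReconConfig,
                                  complex_to_channels, channels_to_complex,
                                  dealias_step, motion_augment,
                                  unrolled_forward)
from grdrn.registration import RegistrationConfig, RegistrationNetwork

RNG = np.random.default_rng(31)


def make_problem(n=4, size=16, accel=2, seed=0, noise=0.0):
    seq, vel = generate_sequence(PhantomConfig(
        height=size, width=size, n_frames=n, contraction_amplitude=1.5,
        noise_sd=noise, seed=seed))
    mask = kspace.generate_mask(size, size, n, accel, rng_seed=seed)
    under = kspace.undersample(kspace.sequence_to_kspace(seq), mask)
    return seq, under, mask


class TestMotionAugment:
    def test_all_ones_mask_full_replacement(self):
        acq = RNG.normal(size=(3, 8, 8)) + 1j * RNG.normal(size=(3, 8, 8))
        tpl = RNG.uniform(size=(8, 8)).astype(np.float32)
        G = motion_augment(tpl, np.zeros((3, 2, 8, 8), np.float32), acq,
                           np.ones((3, 8, 8)))
        np.testing.assert_allclose(channels_to_complex(G),
                                   kspace.inverse_fft(acq), atol=1e-5)

    def test_all_zero_mask_returns_lifted_template(self):
        acq = np.zeros((3, 8, 8), complex)
        tpl = RNG.uniform(size=(8, 8)).astype(np.float32)
        G = motion_augment(tpl, np.zeros((3, 2, 8, 8), np.float32), acq,
                           np.zeros((3, 8, 8)))
        out = channels_to_complex(G)
        for t in range(3):
            np.testing.assert_allclose(out[t].real, tpl, atol=1e-5)
            np.testing.assert_allclose(out[t].imag, 0.0, atol=1e-6)

    def test_half_sampled_spectral_bookkeeping_with_translation(self):
        tpl = RNG.uniform(size=(8, 8)).astype(np.float32)
        bwd = np.zeros((2, 2, 8, 8), np.float32)
        bwd[0, 1] = 1.0
        bwd[1, 1] = -1.0
        acq = RNG.normal(size=(2, 8, 8)) + 1j * RNG.normal(size=(2, 8, 8))
        mask = np.zeros((2, 8, 8))
        mask[:, :, ::2] = 1
        G = motion_augment(tpl, bwd, acq, mask)
        gk = kspace.forward_fft(channels_to_complex(G))
        # on support: acquired data; off support: spectrum of warped template
        np.testing.assert_allclose(gk[mask == 1], acq[mask == 1], atol=1e-5)
        from grdrn import diffeo
        warped = np.stack([diffeo.warp_image(tpl.astype(float), bwd[t])
                           for t in range(2)])
        wk = kspace.forward_fft(warped.astype(complex))
        np.testing.assert_allclose(gk[mask == 0], wk[mask == 0], atol=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            motion_augment(np.zeros((8, 8)), np.zeros((2, 2, 8, 8)),
                           np.zeros((2, 8, 9), complex), np.zeros((2, 8, 9)))


class TestDealiasStep:
    def test_zero_initialized_network_is_residual_identity(self):
        cfg = ReconConfig(channels=(4, 8, 4), iterations=1)
        net = DealiasingNetwork(cfg)
        x = Tensor(RNG.normal(size=(4, 2, 8, 8)).astype(np.float32))
        g = Tensor(RNG.normal(size=(4, 2, 8, 8)).astype(np.float32))
        z = dealias_step(net, g, g, x)
        np.testing.assert_array_equal(z.data, x.data)

    def test_deterministic(self):
        cfg = ReconConfig(channels=(4, 8, 4), zero_init_final_layer=False,
                          seed=5)
        net = DealiasingNetwork(cfg)
        x = Tensor(RNG.normal(size=(4, 2, 8, 8)).astype(np.float32))
        g = Tensor(RNG.normal(size=(4, 2, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(dealias_step(net, g, g, x).data,
                                      dealias_step(net, g, g, x).data)

    def test_motion_free_mode_takes_two_channels_only(self):
        cfg = ReconConfig(channels=(4, 8, 4), motion_mode="none",
                          zero_init_final_layer=False, seed=6)
        net = DealiasingNetwork(cfg)
        assert cfg.in_channels == 2
        x = Tensor(RNG.normal(size=(4, 2, 8, 8)).astype(np.float32))
        z = dealias_step(net, None, None, x)
        assert z.data.shape == (4, 2, 8, 8)
        with pytest.raises(ValueError):
            dealias_step(net, x, x, x)

    def test_full_mode_requires_motion_inputs(self):
        cfg = ReconConfig(channels=(4, 8, 4))
        net = DealiasingNetwork(cfg)
        x = Tensor(RNG.normal(size=(4, 2, 8, 8)).astype(np.float32))
        with pytest.raises(ValueError):
            dealias_step(net, None, None, x)


class TestUnrolledForward:
    def _nets(self, n_frames, motion="full", zero_init=True, seed=0):
        rc = ReconConfig(channels=(4, 8, 4), iterations=3, motion_mode=motion,
                         zero_init_final_layer=zero_init, seed=seed)
        reg = None
        if motion == "full":
            reg = RegistrationNetwork(RegistrationConfig(
                n_frames=n_frames, channels=(4, 8, 4),
                zero_init_final_layer=zero_init, seed=seed))
        return reg, DealiasingNetwork(rc), rc

    def test_identity_cascade_at_zero_initialization(self):
        seq, under, mask = make_problem()
        reg, net, rc = self._nets(4)
        states = unrolled_forward(reg, net, under, mask, rc)
        x0 = kspace.zero_fill_recon(under).frames
        for st in states:
            np.testing.assert_allclose(st.recon_complex, x0, atol=1e-5)

    def test_full_sampling_reproduces_ground_truth_each_iteration(self):
        seq, _, _ = make_problem()
        mask = kspace.generate_mask(16, 16, 4, 1, rng_seed=0)
        under = kspace.undersample(kspace.sequence_to_kspace(seq), mask)
        reg, net, rc = self._nets(4, zero_init=False, seed=3)
        states = unrolled_forward(reg, net, under, mask, rc)
        for st in states:
            np.testing.assert_allclose(st.recon_complex, seq.frames,
                                       atol=1e-4)

    @pytest.mark.parametrize("motion", ["full", "none"])
    def test_every_iteration_satisfies_data_consistency(self, motion):
        seq, under, mask = make_problem(seed=9)
        reg, net, rc = self._nets(4, motion=motion, zero_init=False, seed=7)
        states = unrolled_forward(reg, net, under, mask, rc)
        for st in states:
            k = kspace.forward_fft(st.recon_complex)
            np.testing.assert_allclose(k[mask.masks == 1],
                                       under.spectra[mask.masks == 1],
                                       atol=1e-5)

    def test_motion_free_mode_matches_shared_components(self):
        """Removing motion inputs must not change DC or FFT behaviour: with
        zero-initialized dealiasers both modes yield the zero-filled
        sequence at every iteration."""
        seq, under, mask = make_problem(seed=11)
        x0 = kspace.zero_fill_recon(under).frames
        for motion in ("full", "none"):
            reg, net, rc = self._nets(4, motion=motion)
            states = unrolled_forward(reg, net, under, mask, rc)
            np.testing.assert_allclose(states[-1].recon_complex, x0,
                                       atol=1e-5)

    def test_iteration_states_record_motion_artifacts(self):
        seq, under, mask = make_problem(seed=13)
        reg, net, rc = self._nets(4, zero_init=False, seed=13)
        states = unrolled_forward(reg, net, under, mask, rc)
        assert len(states) == rc.iterations
        for st in states:
            assert st.velocities.data.shape == (4, 2, 16, 16)
            assert st.forward.data.shape == (4, 2, 16, 16)
            assert st.template.data.shape == (16, 16)
            # generated frames match acquired data on support
            gk = kspace.forward_fft(channels_to_complex(st.generated))
            np.testing.assert_allclose(gk[mask.masks == 1],
                                       under.spectra[mask.masks == 1],
                                       atol=1e-5)

    def test_shape_mismatch_rejected(self):
        seq, under, mask = make_problem()
        reg, net, rc = self._nets(4)
        bad = kspace.generate_mask(16, 16, 5, 2, rng_seed=0)
        with pytest.raises(ValueError):
            unrolled_forward(reg, net, under, bad, rc)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(iterations=0)
        with pytest.raises(ValueError):
            ReconConfig(motion_mode="some")
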