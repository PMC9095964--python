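"""End-to-end training of the registration and reconstruction networks.

The composite loss sums, over the K unrolled iterations, an exponentially
increasing weight w_k = exp(k - K) times the per-iteration reconstruction
MSE against the fully sampled ground truth plus lambda times the
registration loss, the latter always evaluated on the ground-truth
magnitudes (motion can be learned from undersampled inputs when the loss
is built on clean images).  Undersampling masks are drawn on the fly from
a seeded stream, a fresh one per training step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kspace, metrics
from .autodiff import Tensor
from .containers import DynamicSequence
from .nn import Adam
from .reconstruction import (DealiasingNetwork, ReconConfig,
                             complex_to_channels, unrolled_forward)
from .registration import (RegistrationConfig, RegistrationNetwork,
                           registration_loss)

__all__ = ["TrainConfig", "TrainResult", "iteration_weights",
           "composite_loss", "train"]


@dataclass
class TrainConfig:
    alpha: float = 0.05
    lam: float = 1.0
    accelerations: tuple = (8,)
    epochs: int = 60
    batch_size: int = 1
    learning_rate: float = 1e-4
    lr_halve_every: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.lam < 0:
            raise ValueError("alpha and lambda must be >= 0")
        if any(a < 1 for a in self.accelerations):
            raise ValueError("accelerations must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only batch_size = 1 is supported")


def iteration_weights(n_iterations: int) -> np.ndarray:
    """w_k = exp(k - K) for k = 1..K (strictly increasing, w_K = 1)."""
    k = np.arange(1, n_iterations + 1)
    return np.exp(k - n_iterations).astype(float)


def learning_rate_at(config: TrainConfig, epoch: int) -> float:
    """Learning rate for a 1-based epoch (halved every `lr_halve_every`)."""
    return config.learning_rate * 0.5 ** ((epoch - 1) // config.lr_halve_every)


def composite_loss(states, gt: DynamicSequence, config: TrainConfig,
                   reg_config: RegistrationConfig | None = None):
    """Weighted per-iteration loss (Tensor scalar, plus logged components).

    Returns ``(loss, components)`` where components is a list of
    ``(w_k, rec_mse, reg_loss)`` floats per iteration.
    """
    if not states:
        raise ValueError("no iteration states")
    gtc = np.asarray(gt.frames)
    if gtc.shape != states[0].recon.data.shape[:1] + states[0].recon.data.shape[2:]:
        raise ValueError("ground truth and reconstruction shapes differ")
    gt_ch = complex_to_channels(gtc, dtype=states[0].recon.data.dtype)
    gt_mag = np.abs(gtc).astype(np.float32)
    weights = iteration_weights(len(states))
    mode = reg_config.mode if reg_config is not None else "groupwise"
    ref_idx = reg_config.reference_frame_index if reg_config is not None else 0

    total = None
    components = []
    for w, st in zip(weights, states):
        diff = st.recon - gt_ch
        rec = diff.square().sum(axis=1).mean()
        if st.velocities is not None and config.lam > 0:
            reg = registration_loss(Tensor(gt_mag), (st.forward, st.backward),
                                    st.velocities, config.alpha, mode=mode,
                                    reference_frame_index=ref_idx)
            term = rec + config.lam * reg
            reg_val = float(reg.data)
        else:
            term = rec
            reg_val = 0.0
        contrib = term * float(w)
        total = contrib if total is None else total + contrib
        components.append((float(w), float(rec.data), reg_val))
    return total, components


@dataclass
class TrainResult:
    reg_net: RegistrationNetwork | None
    recon_net: DealiasingNetwork
    history: list = field(default_factory=list)       # per-epoch mean loss
    val_psnr: list = field(default_factory=list)      # per-epoch mean PSNR
    best_epoch: int = 0


def _draw_mask(rng, shape, acceleration):
    n, h, w = shape
    seed = int(rng.integers(0, 2 ** 31 - 1))
    return kspace.generate_mask(n_pe=w, n_fe=h, n_frames=n,
                                acceleration=acceleration, rng_seed=seed)


def train(train_seqs, config: TrainConfig, recon_config: ReconConfig,
          reg_config: RegistrationConfig | None = None,
          val_seqs=None, verbose=False) -> TrainResult:
    """Jointly optimize both networks on ground-truth dynamic sequences.

    Per step: draw a sequence and a fresh mask, simulate undersampling of
    the ground-truth k-space, run the unrolled cascade and apply one Adam
    update to all parameters.  Fully reproducible for a fixed seed.
    Raises ``RuntimeError`` if the loss becomes non-finite.
    """
    if not train_seqs:
        raise ValueError("empty training set")
    use_motion = recon_config.motion_mode == "full"
    if use_motion and reg_config is None:
        raise ValueError("motion_mode 'full' requires a registration config")

    reg_net = RegistrationNetwork(reg_config) if use_motion else None
    recon_net = DealiasingNetwork(recon_config)
    params = list(recon_net.parameters())
    if reg_net is not None:
        params += list(reg_net.parameters())
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    result = TrainResult(reg_net=reg_net, recon_net=recon_net)
    best_psnr, best_state = -np.inf, None
    accels = list(config.accelerations)
    for epoch in range(1, config.epochs + 1):
        opt.lr = learning_rate_at(config, epoch)
        order = rng.permutation(len(train_seqs))
        losses = []
        for step, idx in enumerate(order):
            seq = train_seqs[idx]
            accel = accels[(epoch * len(order) + step) % len(accels)]
            mask = _draw_mask(rng, seq.frames.shape, accel)
            full_k = kspace.sequence_to_kspace(seq)
            under = kspace.undersample(full_k, mask)
            states = unrolled_forward(reg_net, recon_net, under, mask,
                                      recon_config)
            loss, _ = composite_loss(states, seq, config, reg_config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} step {step}: "
                    f"loss={float(loss.data)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        result.history.append(float(np.mean(losses)))
        if val_seqs:
            vp = validate_psnr(reg_net, recon_net, recon_config, val_seqs,
                               accels[0], seed=config.seed + 10_000 + epoch)
            result.val_psnr.append(vp)
            if vp > best_psnr:
                best_psnr, result.best_epoch = vp, epoch
                best_state = (reg_net.unet.state_dict() if reg_net else None,
                              recon_net.unet.state_dict())
        if verbose:
            msg = f"epoch {epoch:3d}  loss {result.history[-1]:.5f}"
            if val_seqs:
                msg += f"  val PSNR {result.val_psnr[-1]:.2f} dB"
            print(msg, flush=True)
    if best_state is not None:
        if reg_net is not None and best_state[0] is not None:
            reg_net.unet.load_state_dict(best_state[0])
        recon_net.unet.load_state_dict(best_state[1])
    return result


def save_checkpoint(path, reg_net, recon_net, recon_config: ReconConfig,
                    reg_config: RegistrationConfig | None = None,
                    train_config: TrainConfig | None = None) -> None:
    """Single-file checkpoint: parameters plus embedded configs."""
    import json
    from dataclasses import asdict

    meta = {"recon": asdict(recon_config),
            "reg": asdict(reg_config) if reg_config else None,
            "train": asdict(train_config) if train_config else None}
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), np.uint8)}
    for k, v in recon_net.unet.state_dict().items():
        arrays[f"recon_{k}"] = v
    if reg_net is not None:
        for k, v in reg_net.unet.state_dict().items():
            arrays[f"reg_{k}"] = v
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`.

    Returns ``(reg_net, recon_net, meta)`` with networks rebuilt from the
    embedded configs (reg_net is None for motion-free checkpoints).
    """
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        recon_cfg = ReconConfig(**{**meta["recon"],
                                   "channels": tuple(meta["recon"]["channels"])})
        recon_net = DealiasingNetwork(recon_cfg)
        recon_net.unet.load_state_dict(
            {k[len("recon_"):]: data[k] for k in data.files
             if k.startswith("recon_")})
        reg_net = None
        if meta["reg"] is not None:
            reg_cfg = RegistrationConfig(**{**meta["reg"],
                                            "channels": tuple(meta["reg"]["channels"])})
            reg_net = RegistrationNetwork(reg_cfg)
            reg_net.unet.load_state_dict(
                {k[len("reg_"):]: data[k] for k in data.files
                 if k.startswith("reg_")})
    return reg_net, recon_net, meta


def validate_psnr(reg_net, recon_net, recon_config, seqs, acceleration,
                  seed=0) -> float:
    """Mean final-iteration PSNR over sequences at one acceleration."""
    rng = np.random.default_rng(seed)
    vals = []
    for seq in seqs:
        mask = _draw_mask(rng, seq.frames.shape, acceleration)
        under = kspace.undersample(kspace.sequence_to_kspace(seq), mask)
        states = unrolled_forward(reg_net, recon_net, under, mask, recon_config)
        vals.append(metrics.psnr(np.abs(seq.frames),
                                 np.abs(states[-1].recon_complex)))
    return float(np.mean(vals))
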