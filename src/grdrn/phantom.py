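"""Synthetic dynamic cine phantom with known ground-truth motion.

Each sequence shows a bright annulus (a schematic myocardium) around a
dimmer blood-pool disk on a piecewise-smooth static background.  Motion is
prescribed as per-frame stationary velocity fields — a sinusoidally
modulated radial contraction of the annulus over the cycle plus an
optional bulk translation — so the ground-truth transforms are directly
comparable to the registration network's output: integrating +v_n warps
frame n onto the template scene, and the frames themselves are rendered by
warping the template with the integral of -v_n.  A smooth static phase map
turns the magnitude scene into complex frames; complex Gaussian noise is
optional.  The frame cycle is periodic, emulating cardiac cine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import dataio, diffeo
from .containers import DynamicSequence

__all__ = ["PhantomConfig", "generate_sequence", "template_scene",
           "motion_velocities", "render_frames", "build_dataset"]


@dataclass
class PhantomConfig:
    height: int = 64
    width: int = 64
    n_frames: int = 8
    contraction_amplitude: float = 3.0   # px, peak radial velocity of the annulus
    translation_amplitude: float = 0.0   # px, bulk cyclic translation
    outer_radius_frac: float = 0.30      # of min(height, width)
    inner_radius_frac: float = 0.17
    edge_width: float = 1.2              # px, soft edge of the analytic scene
    myocardium_intensity: float = 1.0
    blood_pool_intensity: float = 0.6
    background_level: float = 0.25       # amplitude of the static texture
    phase_scale: float = 0.5             # radians, low-frequency phase map
    noise_sd: float = 0.0                # complex Gaussian noise, per channel
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.contraction_amplitude < 0 or self.translation_amplitude < 0 \
                or self.noise_sd < 0:
            raise ValueError("amplitudes and noise sd must be >= 0")
        if self.inner_radius_frac >= self.outer_radius_frac:
            raise ValueError("degenerate geometry: inner radius >= outer radius")


def _soft(x, w):
    return 0.5 * (1.0 + np.tanh(x / w))


def _grid(cfg):
    r = np.arange(cfg.height, dtype=np.float64)[:, None]
    c = np.arange(cfg.width, dtype=np.float64)[None, :]
    cy, cx = (cfg.height - 1) / 2.0, (cfg.width - 1) / 2.0
    return r - cy, c - cx


def template_scene(cfg: PhantomConfig, rng=None) -> np.ndarray:
    """Static magnitude scene: annulus + blood pool + textured background."""
    rng = rng or np.random.default_rng(cfg.seed)
    dy, dx = _grid(cfg)
    d = np.hypot(dy, dx)
    rmin = min(cfg.height, cfg.width)
    r_out = cfg.outer_radius_frac * rmin
    r_in = cfg.inner_radius_frac * rmin
    annulus = _soft(d - r_in, cfg.edge_width) * _soft(r_out - d, cfg.edge_width)
    pool = _soft(r_in - d, cfg.edge_width)
    outside = _soft(d - r_out, cfg.edge_width)
    texture = gaussian_filter(rng.standard_normal((cfg.height, cfg.width)),
                              sigma=rmin / 10.0)
    span = np.ptp(texture)
    if span > 0:
        texture = (texture - texture.min()) / span
    background = cfg.background_level * (0.4 + 0.6 * texture) * outside
    return (cfg.myocardium_intensity * annulus
            + cfg.blood_pool_intensity * pool + background)


def motion_velocities(cfg: PhantomConfig) -> np.ndarray:
    """Prescribed stationary velocity fields (N, 2, H, W), summing to ~0.

    Frame n carries a radial contraction bump centered on the annulus with
    amplitude ``contraction_amplitude * sin(2 pi n / N)`` plus a constant
    translation rotating through the cycle with ``translation_amplitude``.
    The full-cycle sums of sin and cos vanish, so the set is centered.
    """
    dy, dx = _grid(cfg)
    d = np.hypot(dy, dx)
    rmin = min(cfg.height, cfg.width)
    r_mid = 0.5 * (cfg.outer_radius_frac + cfg.inner_radius_frac) * rmin
    width = max(0.5 * (cfg.outer_radius_frac - cfg.inner_radius_frac) * rmin, 1.0)
    bump = np.exp(-0.5 * ((d - r_mid) / width) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ur = np.where(d > 1e-9, dy / np.maximum(d, 1e-9), 0.0)
        uc = np.where(d > 1e-9, dx / np.maximum(d, 1e-9), 0.0)
    n = cfg.n_frames
    phases = 2.0 * np.pi * np.arange(n) / n
    v = np.zeros((n, 2, cfg.height, cfg.width))
    for i, ph in enumerate(phases):
        a = cfg.contraction_amplitude * np.sin(ph)
        v[i, 0] = -a * bump * ur + cfg.translation_amplitude * np.sin(ph)
        v[i, 1] = -a * bump * uc + cfg.translation_amplitude * np.cos(ph)
    return v


def render_frames(template: np.ndarray, velocities: np.ndarray,
                  n_steps: int = diffeo.DEFAULT_N_STEPS) -> np.ndarray:
    """Render frame n by warping the template with the integral of -v_n."""
    velocities = np.asarray(velocities)
    backward = diffeo.integrate_velocity(-velocities, n_steps)
    stack = np.broadcast_to(template, (velocities.shape[0],) + template.shape)
    return diffeo.warp_image(np.ascontiguousarray(stack), backward)


def generate_sequence(cfg: PhantomConfig):
    """Build one complex dynamic sequence and its ground-truth velocities.

    Returns ``(DynamicSequence, velocities)`` with frames of shape
    (N, H, W) complex64 and velocities (N, 2, H, W) float.  Bitwise
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    template = template_scene(cfg, rng)
    velocities = motion_velocities(cfg)
    mags = render_frames(template, velocities)
    phase = cfg.phase_scale * gaussian_filter(
        rng.standard_normal((cfg.height, cfg.width)),
        sigma=min(cfg.height, cfg.width) / 4.0)
    frames = mags * np.exp(1j * phase)[None]
    if cfg.noise_sd > 0:
        frames = frames + cfg.noise_sd * (
            rng.standard_normal(frames.shape)
            + 1j * rng.standard_normal(frames.shape))
    return DynamicSequence(frames=frames.astype(np.complex64)), velocities


def sample_config(base: PhantomConfig, seed: int,
                  contraction_range=(2.0, 4.0),
                  translation_range=(0.0, 1.0),
                  radius_jitter=0.03) -> PhantomConfig:
    """Randomize per-sequence geometry and motion amplitudes."""
    rng = np.random.default_rng(seed)
    outer = base.outer_radius_frac + rng.uniform(-radius_jitter, radius_jitter)
    inner = base.inner_radius_frac + rng.uniform(-radius_jitter / 2,
                                                 radius_jitter / 2)
    return replace(
        base,
        contraction_amplitude=float(rng.uniform(*contraction_range)),
        translation_amplitude=float(rng.uniform(*translation_range)),
        outer_radius_frac=float(outer),
        inner_radius_frac=float(min(inner, outer - 0.05)),
        seed=seed,
    )


def build_dataset(out_dir, n_train: int, n_val: int, n_test: int,
                  base_config: PhantomConfig | None = None, seed: int = 0,
                  contraction_range=(2.0, 4.0), translation_range=(0.0, 1.0),
                  overwrite: bool = False) -> dict:
    """Write disjoint seeded train/val/test HDF5 fixtures plus a manifest.

    Every sequence gets its own child seed; the manifest records them all,
    so regeneration from the manifest is byte-identical.
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be >= 0")
    base_config = base_config or PhantomConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    splits = {"train": n_train, "val": n_val, "test": n_test}
    ss = np.random.SeedSequence(seed)
    children = iter(ss.generate_state(sum(splits.values()) or 1) % (2 ** 31 - 1))
    manifest = {"seed": seed, "base_config": asdict(base_config),
                "contraction_range": list(contraction_range),
                "translation_range": list(translation_range), "splits": {}}
    for name, count in splits.items():
        path = out_dir / f"{name}.h5"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
        records = []
        split_seeds = []
        for i in range(count):
            child = int(next(children))
            cfg = sample_config(base_config, child, contraction_range,
                                translation_range)
            seq, vel = generate_sequence(cfg)
            records.append(dataio.SequenceRecord(
                seq_id=f"{name}_{i:04d}", sequence=seq,
                true_velocity=vel.astype(np.float32), seed=child))
            split_seeds.append(child)
        dataio.save_dataset(path, records)
        manifest["splits"][name] = {"path": path.name, "n": count,
                                    "seeds": split_seeds}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
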