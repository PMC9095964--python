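"""Core data containers shared by the acquisition, registration and
reconstruction modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DynamicSequence", "KSpaceSequence", "SamplingMask",
           "DeformationFieldSet"]


@dataclass
class DynamicSequence:
    """An ordered set of N complex (or real magnitude) 2D frames.

    By convention rows are the frequency-encode axis and columns the
    phase-encode axis.
    """

    frames: np.ndarray  # (N, H, W)
    ground_truth: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (N, H, W) with N >= 1")
        if not np.all(np.isfinite(self.frames.view(float) if
                                  np.iscomplexobj(self.frames) else self.frames)):
            raise ValueError("frames contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def magnitudes(self) -> np.ndarray:
        return np.abs(self.frames)


@dataclass
class KSpaceSequence:
    """Per-frame centered k-space spectra."""

    spectra: np.ndarray  # (N, H, W) complex
    is_undersampled: bool = False

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra)
        if self.spectra.ndim != 3:
            raise ValueError("spectra must be (N, H, W)")

    @property
    def n_frames(self) -> int:
        return self.spectra.shape[0]


@dataclass
class SamplingMask:
    """Per-frame binary Cartesian masks (1 = acquired line).

    Every sampled phase-encode line (a column) is fully sampled along the
    frequency-encode axis, so each mask column is constant.
    """

    masks: np.ndarray  # (N, H, W), {0, 1}
    acceleration: float = 1.0

    def __post_init__(self):
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (N, H, W)")
        vals = np.unique(self.masks)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask entries must be 0 or 1")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    def lines_per_frame(self) -> np.ndarray:
        """Number of sampled phase-encode lines in each frame."""
        return (self.masks[:, 0, :] > 0).sum(axis=1)


@dataclass
class DeformationFieldSet:
    """Forward (frame -> template) and backward displacement fields, in
    pixels, component order (row, col)."""

    forward: np.ndarray   # (N, 2, H, W)
    backward: np.ndarray  # (N, 2, H, W)

    def __post_init__(self):
        self.forward = np.asarray(self.forward)
        self.backward = np.asarray(self.backward)
        if self.forward.shape != self.backward.shape or \
                self.forward.ndim != 4 or self.forward.shape[1] != 2:
            raise ValueError("fields must be matching (N, 2, H, W) arrays")
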