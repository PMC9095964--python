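"""HDF5 dataset layout and NIfTI export.

Layout: groups ``/sequences/<id>`` with datasets ``image`` (N x H x W
complex64), ``kspace`` (N x H x W complex64), optional ``mask`` (N x H x W
uint8) and ``true_velocity`` (N x 2 x H x W float32, phantom only);
attributes ``acceleration`` and ``seed``.  Velocity and displacement
fields serialize as float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import kspace as ksp
from .containers import DynamicSequence, KSpaceSequence, SamplingMask

__all__ = ["SequenceRecord", "save_dataset", "load_dataset", "export_nifti"]


@dataclass
class SequenceRecord:
    seq_id: str
    sequence: DynamicSequence
    kspace: KSpaceSequence | None = None
    mask: SamplingMask | None = None
    true_velocity: np.ndarray | None = None
    displacement_fwd: np.ndarray | None = None
    displacement_bwd: np.ndarray | None = None
    seed: int | None = None
    acceleration: float | None = None
    extras: dict = field(default_factory=dict)


def save_dataset(path, records: list[SequenceRecord], mode: str = "w") -> None:
    path = Path(path)
    with h5py.File(path, mode) as fh:
        root = fh.require_group("sequences")
        for rec in records:
            g = root.create_group(rec.seq_id)
            g.create_dataset("image",
                             data=rec.sequence.frames.astype(np.complex64))
            k = rec.kspace or ksp.sequence_to_kspace(rec.sequence)
            g.create_dataset("kspace", data=k.spectra.astype(np.complex64))
            g.attrs["is_undersampled"] = bool(k.is_undersampled)
            if rec.mask is not None:
                g.create_dataset("mask",
                                 data=rec.mask.masks.astype(np.uint8))
                g.attrs["acceleration"] = float(rec.mask.acceleration)
            elif rec.acceleration is not None:
                g.attrs["acceleration"] = float(rec.acceleration)
            if rec.true_velocity is not None:
                g.create_dataset("true_velocity",
                                 data=np.asarray(rec.true_velocity,
                                                 dtype=np.float32))
            for name, arr in (("displacement_fwd", rec.displacement_fwd),
                              ("displacement_bwd", rec.displacement_bwd)):
                if arr is not None:
                    g.create_dataset(name,
                                     data=np.asarray(arr, dtype=np.float32))
            if rec.seed is not None:
                g.attrs["seed"] = int(rec.seed)
            for key, val in rec.extras.items():
                g.attrs[key] = val


def load_dataset(path) -> list[SequenceRecord]:
    records = []
    with h5py.File(path, "r") as fh:
        for seq_id in sorted(fh["sequences"]):
            g = fh["sequences"][seq_id]
            seq = DynamicSequence(frames=g["image"][()])
            k = KSpaceSequence(spectra=g["kspace"][()],
                               is_undersampled=bool(
                                   g.attrs.get("is_undersampled", False)))
            accel = g.attrs.get("acceleration")
            mask = None
            if "mask" in g:
                mask = SamplingMask(masks=g["mask"][()],
                                    acceleration=float(accel or 1.0))
            records.append(SequenceRecord(
                seq_id=seq_id, sequence=seq, kspace=k, mask=mask,
                true_velocity=g["true_velocity"][()]
                if "true_velocity" in g else None,
                displacement_fwd=g["displacement_fwd"][()]
                if "displacement_fwd" in g else None,
                displacement_bwd=g["displacement_bwd"][()]
                if "displacement_bwd" in g else None,
                seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
                acceleration=float(accel) if accel is not None else None))
    return records


def export_nifti(path, seq: DynamicSequence) -> None:
    """Write the magnitude series as a (H, W, 1, N) NIfTI volume."""
    import nibabel as nib

    mags = seq.magnitudes().astype(np.float32)      # (N, H, W)
    vol = np.transpose(mags, (1, 2, 0))[:, :, None, :]
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
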