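"""Diffusion-weighted datasets: shells, normalization, spherical means."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DwiDataset:
    """Multi-shell diffusion data on a voxel grid.

    signals : (X, Y, Z, N) array, arbitrary signal units.
    bvals : (N,) b-values in s/mm^2.
    bvecs : (N, 3) unit gradient directions (arbitrary for b = 0).
    """

    signals: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, self.bvals.size) and self.bvecs.shape[0] == 3:
            self.bvecs = self.bvecs.T
        if self.signals.shape[-1] != self.bvals.size:
            raise ValueError("volume count does not match bvals")
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (N, 3)")
        dw = self.bvals > 50
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("diffusion-weighted bvecs must be unit norm")
        if not np.any(self.shell_ids == 0):
            raise ValueError("at least one b = 0 volume required")
        if self.mask is None:
            self.mask = np.ones(self.signals.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)

    @property
    def shell_ids(self) -> np.ndarray:
        """b-values rounded to the nearest 50 s/mm^2 (b < 50 is b = 0)."""
        return (np.round(self.bvals / 50.0) * 50.0).astype(int)

    @property
    def shells(self) -> np.ndarray:
        """Sorted nonzero shell b-values present in the scheme."""
        ids = np.unique(self.shell_ids)
        return ids[ids > 0]

    def shell_selection(self, shells) -> "DwiDataset":
        """Subset to b = 0 plus the requested shell(s)."""
        shells = np.atleast_1d(shells).astype(int)
        keep = np.isin(self.shell_ids, np.concatenate([[0], shells]))
        return DwiDataset(
            signals=self.signals[..., keep],
            bvals=self.bvals[keep],
            bvecs=self.bvecs[keep],
            voxel_size=self.voxel_size,
            affine=self.affine,
            mask=self.mask,
        )

    def b0_mean(self) -> np.ndarray:
        return self.signals[..., self.shell_ids == 0].mean(axis=-1)


def spherical_mean(data: DwiDataset, min_directions: int = 6):
    """Per-voxel direction-averaged signal per shell, normalized to b = 0.

    The spherical mean is invariant to the fiber orientation distribution,
    which is what makes the multi-compartment spherical-mean decomposition
    orientation-free.  Returns ``(means, shells, valid)``: means has shape
    ``grid + (n_shells,)``, valid marks voxels with positive b = 0 signal.
    """
    ids = data.shell_ids
    shells = data.shells
    for b in shells:
        if (ids == b).sum() < min_directions:
            raise ValueError(f"shell b={b} has fewer than {min_directions} directions")
    s0 = data.b0_mean()
    valid = data.mask & (s0 > 0)
    n_dropped = int((data.mask & ~valid).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} masked voxel(s) with zero b=0 signal dropped")
    s0_safe = np.where(valid, s0, 1.0)
    means = np.stack(
        [data.signals[..., ids == b].mean(axis=-1) / s0_safe for b in shells],
        axis=-1,
    )
    return means, shells.astype(float), valid
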