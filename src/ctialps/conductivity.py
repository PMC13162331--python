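"""Low-frequency conductivity: scalar sigma_L and the tensor C_L.

Low-frequency (< 1 kHz) currents are confined to the extra-neurite space, so
the high-frequency conductivity sigma_H is down-scaled by the extra-neurite
share of the ion mobility:

    sigma_L = (1 - nu) * D_ext * sigma_H / (nu * beta * D_int + (1 - nu) * D_ext)

where beta is the apparent intra/extra ion-concentration ratio.  Anisotropy
is inherited from the water diffusion eigen-frame S_D with extra-neurite
eigenvalues

    d1 = d2 = (1 - nu) * D_int,     d3 = 3 * D_ext - 2 * (1 - nu) * D_int

(mean exactly D_ext), giving C_L = prefactor * S_D diag(d1, d2, d3) S_D^T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dti import DiffusionTensorField
from .smt import SMTParameterField

FLAG_DENOMINATOR = 1  # zero denominator in the sigma_L prefactor
FLAG_ORDERING = 2  # d3 < d1: oblate-inconsistent extra-neurite tensor


@dataclass
class CompartmentModel:
    """Scalar parameters linking compartment diffusivities to conductivity.

    beta : intra/extra apparent ion-concentration ratio (> 0, default 1).
    """

    beta: float = 1.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class ConductivityTensorField:
    """Per-voxel symmetric conductivity tensor C_L [S/m].

    Shares the eigen-frame of the water diffusion tensor; eigenvalues are the
    extra-neurite diffusivity eigenvalues scaled by the scalar prefactor.
    ``flags`` is a bitmask (1 = denominator failure, 2 = eigenvalue-ordering
    violation).
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    sigma_l: np.ndarray
    mask: np.ndarray
    flags: np.ndarray
    beta: float = 1.0

    def lower_triangular(self) -> np.ndarray:
        t = self.tensor
        return np.stack(
            [t[..., 0, 0], t[..., 0, 1], t[..., 1, 1],
             t[..., 0, 2], t[..., 1, 2], t[..., 2, 2]],
            axis=-1,
        )

    def summary(self) -> str:
        m = self.mask
        return "\n".join(
            [
                f"ConductivityTensorField (beta = {self.beta:g})",
                f"  voxels         : {int(m.sum())}",
                f"  sigma_L [S/m]  : median {np.median(self.sigma_l[m]):.4f}",
                f"  flagged voxels : {int((self.flags[m] != 0).sum())}",
            ]
        )


def low_frequency_sigma(sigma_h, nu_int, d_int, d_ext, beta: float = 1.0):
    """Scalar low-frequency conductivity sigma_L (elementwise).

    Returns sigma_L with the same shape as the inputs; voxels with a
    non-positive denominator yield NaN (callers mask and count them).
    """
    sigma_h = np.asarray(sigma_h, dtype=float)
    nu = np.asarray(nu_int, dtype=float)
    den = nu * beta * np.asarray(d_int, float) + (1.0 - nu) * np.asarray(d_ext, float)
    num = (1.0 - nu) * np.asarray(d_ext, float)
    # ratio-first form keeps the nu = 0 limit exact: num/den == 1.0 bitwise
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, sigma_h * (num / np.where(den > 0, den, 1.0)), np.nan)
    return out if out.ndim else float(out)


def extra_neurite_eigenvalues(nu_int, d_int, d_ext):
    """Extra-neurite tensor eigenvalues (d1, d2, d3); mean equals D_ext."""
    nu = np.asarray(nu_int, dtype=float)
    d1 = (1.0 - nu) * np.asarray(d_int, dtype=float)
    d3 = 3.0 * np.asarray(d_ext, dtype=float) - 2.0 * d1
    if d1.ndim:
        return d1, d1.copy(), d3
    return float(d1), float(d1), float(d3)


def build_cl(
    sigma_h: np.ndarray,
    smt: SMTParameterField,
    dti: DiffusionTensorField,
    model: CompartmentModel | None = None,
    mask: np.ndarray | None = None,
) -> ConductivityTensorField:
    """Assemble the low-frequency conductivity tensor field C_L.

    All inputs must live on one common grid (mixed grids are rejected, not
    resampled).  Ordering-violating voxels (3*D_ext < 3*(1-nu)*D_int) are
    kept but flagged so downstream ROI statistics can exclude them.
    """
    model = model or CompartmentModel()
    sigma_h = np.asarray(sigma_h, dtype=float)
    grid = sigma_h.shape
    if smt.nu_int.shape != grid or dti.tensor.shape[:3] != grid:
        raise ValueError("sigma_H, SMT and tensor fields must share one grid")
    if mask is None:
        mask = smt.mask & dti.mask
    sd = dti.eigenvectors
    ortho_err = np.abs(
        np.einsum("...ij,...kj->...ik", sd, sd) - np.eye(3)
    ).max(axis=(-2, -1))
    if np.any(ortho_err[mask] > 1e-6):
        raise ValueError("non-orthogonal water-tensor eigenvector matrix")

    nu, d_int, d_ext = smt.nu_int, smt.d_int, smt.d_ext
    d1, _, d3 = extra_neurite_eigenvalues(nu, d_int, d_ext)
    den = nu * model.beta * d_int + (1.0 - nu) * d_ext
    flags = np.zeros(grid, dtype=np.uint8)
    flags[mask & (den <= 0)] |= FLAG_DENOMINATOR
    flags[mask & (d3 < d1)] |= FLAG_ORDERING

    with np.errstate(invalid="ignore", divide="ignore"):
        pref = np.where(den > 0, (1.0 - nu) * sigma_h / np.where(den > 0, den, 1.0), 0.0)
    # eigen-frame order: water eigenvalues descend, so the fiber (axial)
    # direction is column 0 of S_D; it carries d3, the radial plane d1 = d2
    evals = np.zeros(grid + (3,))
    evals[..., 0] = pref * d3
    evals[..., 1] = pref * d1
    evals[..., 2] = pref * d1
    tensor = np.einsum("...ij,...j,...kj->...ik", sd, evals, sd, optimize=True)
    sigma_l = pref * d_ext
    out_mask = mask & (den > 0)
    return ConductivityTensorField(
        tensor=tensor,
        eigenvalues=evals,
        eigenvectors=sd.copy(),
        sigma_l=np.where(out_mask, sigma_l, np.nan),
        mask=out_mask,
        flags=flags,
        beta=model.beta,
    )


def apparent_ion_concentration(sigma_l, nu_int, d_ext):
    """Diagnostic apparent extra-neurite ion concentration (arbitrary units):
    c_ext = sigma_L / ((1 - nu) * D_ext)."""
    den = (1.0 - np.asarray(nu_int, float)) * np.asarray(d_ext, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, np.asarray(sigma_l, float) / np.where(den > 0, den, 1.0), np.nan)
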