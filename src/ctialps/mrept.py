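"""Phase-based MREPT: high-frequency conductivity from the transceive phase.

The measurable input is the transceive phase phi_tr = phi+ + phi- of the RF
(B1) field.  Under the assumption that conduction currents dominate
displacement currents (sigma_H >> omega*eps_H), the phase obeys

    grad(phi_tr) . grad(1/sigma_H) + lap(phi_tr) / sigma_H = 2 * omega * mu0

which this module solves for u = 1/sigma_H slice by slice with a 2-D
finite-difference method.  A small artificial diffusion term -c * lap(u)
(convection-reaction stabilization) regularizes the otherwise
convection-dominated transport of u along grad(phi_tr).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

MU0 = 4.0e-7 * math.pi  # magnetic permeability of free space [N/A^2]

#: proton Larmor angular frequency at 3 T [rad/s]
OMEGA_3T = 2.0 * math.pi * 127.74e6


@dataclass
class MultiEchoPhaseVolume:
    """Per-echo transceive phase and magnitude stacks.

    phase, magnitude : (X, Y, Z, NE) arrays, phase in radians.
    echo_times : (NE,) echo times in milliseconds.
    voxel_size : (3,) voxel edge lengths in millimetres.
    affine : (4, 4) voxel-to-world mapping.
    mask : optional (X, Y, Z) boolean array of valid voxels.
    """

    phase: np.ndarray
    magnitude: np.ndarray
    echo_times: np.ndarray
    voxel_size: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.phase.ndim == 3:
            self.phase = self.phase[..., None]
            self.magnitude = self.magnitude[..., None]
        if self.phase.shape != self.magnitude.shape:
            raise ValueError("phase and magnitude shapes differ")
        self.echo_times = np.atleast_1d(np.asarray(self.echo_times, dtype=float))
        if self.echo_times.size != self.phase.shape[-1]:
            raise ValueError("echo_times length does not match echo count")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be non-negative")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.phase.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)

    @property
    def n_echoes(self) -> int:
        return self.phase.shape[-1]


@dataclass
class ReconConfig:
    """Configuration of the convection-reaction reconstruction.

    omega : Larmor angular frequency [rad/s].
    c : regularization coefficient on the discrete Laplacian of u = 1/sigma.
        Interpreted in physical (SI metre) units by default, which is the
        scale at which c = 0.03 balances the convection and reaction terms
        of the operator; ``c_units='voxel'`` instead takes the Laplacian on
        the unit voxel lattice, making the term negligible at clinical
        field strengths (exposed for sensitivity checks).
    boundary_sigma : Dirichlet conductivity on the mask boundary ring [S/m].
        ``None`` seeds the boundary from the local Laplacian (Helmholtz)
        estimate smoothed along the ring.
    smooth_fwhm_vox : FWHM (in-plane voxels) of Gaussian pre-smoothing applied
        to phi_tr before differentiation; 0 disables (analytic phantoms).
    sigma_floor : floor for non-physical (<= 0) conductivity estimates [S/m].
    neg_fraction_max : hard-failure threshold on the fraction of interior
        voxels with u <= 0.
    residual_tol : relative residual ||Au - b|| / ||b|| above which a slice
        solve is considered failed.
    """

    omega: float = OMEGA_3T
    mu0: float = MU0
    c: float = 0.03
    c_units: str = "physical"
    boundary_sigma: float | np.ndarray | None = None
    smooth_fwhm_vox: float = 1.0
    sigma_floor: float = 0.01
    neg_fraction_max: float = 0.05
    residual_tol: float = 1e-8

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if not np.isclose(self.mu0, MU0, rtol=1e-12):
            raise ValueError("mu0 must be 4*pi*1e-7 N/A^2")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.c_units not in ("voxel", "physical"):
            raise ValueError("c_units must be 'voxel' or 'physical'")


@dataclass
class ConductivityMap:
    """Scalar conductivity field in S/m with validity mask and provenance."""

    sigma: np.ndarray
    mask: np.ndarray
    provenance: str
    report: dict = field(default_factory=dict)

    def summary(self) -> str:
        vals = self.sigma[self.mask]
        lines = [
            f"ConductivityMap ({self.provenance})",
            f"  valid voxels : {int(self.mask.sum())}",
            f"  sigma [S/m]  : median {np.median(vals):.4f}, "
            f"range [{vals.min():.4f}, {vals.max():.4f}]",
        ]
        for k, v in self.report.items():
            if np.isscalar(v):
                lines.append(f"  {k} : {v}")
        return "\n".join(lines)


def combine_echo_phase(vol: MultiEchoPhaseVolume) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared-weighted combination of per-echo phases.

    Weights w_k = |rho_k|^2 / sum_j |rho_j|^2 form a convex combination per
    voxel, down-weighting late (low-SNR) echoes.  Returns ``(phi_tr, mask)``
    where voxels with all-zero magnitude are removed from the mask.
    """
    mag2 = vol.magnitude**2
    denom = mag2.sum(axis=-1)
    bad = (denom <= 0) & vol.mask
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{n_bad} masked voxel(s) with all-zero magnitude excluded")
    safe = np.where(denom > 0, denom, 1.0)
    phi_tr = (mag2 * vol.phase).sum(axis=-1) / safe
    return phi_tr, vol.mask & ~bad


def echo_weights(magnitude: np.ndarray) -> np.ndarray:
    """Per-voxel echo weights w_k; sums to 1 where any magnitude is nonzero."""
    mag2 = np.asarray(magnitude, dtype=float) ** 2
    denom = mag2.sum(axis=-1, keepdims=True)
    return mag2 / np.where(denom > 0, denom, 1.0)


def _inplane_derivatives(phi: np.ndarray, hx: float, hy: float):
    """Central first derivatives and 5-point Laplacian of a 2-D slice."""
    gx = np.zeros_like(phi)
    gy = np.zeros_like(phi)
    lap = np.zeros_like(phi)
    gx[1:-1, :] = (phi[2:, :] - phi[:-2, :]) / (2 * hx)
    gy[:, 1:-1] = (phi[:, 2:] - phi[:, :-2]) / (2 * hy)
    lap[1:-1, :] += (phi[2:, :] - 2 * phi[1:-1, :] + phi[:-2, :]) / hx**2
    lap[:, 1:-1] += (phi[:, 2:] - 2 * phi[:, 1:-1] + phi[:, :-2]) / hy**2
    return gx, gy, lap


def _smooth_slice(phi: np.ndarray, fwhm_vox: float) -> np.ndarray:
    if fwhm_vox <= 0:
        return phi
    sd = fwhm_vox / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return ndi.gaussian_filter(phi, sd, mode="nearest")


def helmholtz_sigma(
    phi_tr: np.ndarray,
    cfg: ReconConfig,
    voxel_size_mm: np.ndarray,
    mask: np.ndarray | None = None,
) -> ConductivityMap:
    """Pointwise Laplacian-based conductivity estimate sigma = lap(phi)/(2 w mu0).

    The classic phase-only Helmholtz estimate: cheap and local, used here for
    initialization and Dirichlet boundary seeding of the full solve.
    Non-positive estimates are mapped to ``cfg.sigma_floor`` and flagged.
    """
    voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
    if voxel_size_mm.size < 2 or np.any(voxel_size_mm[:2] <= 0):
        raise ValueError("in-plane voxel spacing required")
    phi_tr = np.asarray(phi_tr, dtype=float)
    if mask is None:
        mask = np.ones(phi_tr.shape, dtype=bool)
    hx, hy = voxel_size_mm[0] * 1e-3, voxel_size_mm[1] * 1e-3
    sigma = np.zeros(phi_tr.shape)
    work = phi_tr if phi_tr.ndim == 3 else phi_tr[..., None]
    out = sigma if sigma.ndim == 3 else sigma[..., None]
    for k in range(work.shape[2]):
        sl = _smooth_slice(work[:, :, k], cfg.smooth_fwhm_vox)
        _, _, lap = _inplane_derivatives(sl, hx, hy)
        out[:, :, k] = lap / (2.0 * cfg.omega * cfg.mu0)
    flagged = (sigma <= 0) & mask
    sigma = np.where(flagged, cfg.sigma_floor, sigma)
    return ConductivityMap(
        sigma=sigma,
        mask=mask.copy(),
        provenance="helmholtz",
        report={"n_floored": int(flagged.sum())},
    )


def _interior_boundary(mask2d: np.ndarray):
    """Split a 2-D mask into interior voxels (all 4 neighbours in-mask) and
    the boundary ring."""
    interior = mask2d.copy()
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    inner = np.zeros_like(interior)
    inner[1:-1, 1:-1] = (
        mask2d[1:-1, 1:-1]
        & mask2d[2:, 1:-1]
        & mask2d[:-2, 1:-1]
        & mask2d[1:-1, 2:]
        & mask2d[1:-1, :-2]
    )
    interior &= inner
    boundary = mask2d & ~interior
    return interior, boundary


def assemble_cr_system(
    phi_slice: np.ndarray,
    mask_slice: np.ndarray,
    cfg: ReconConfig,
    voxel_size_mm: np.ndarray,
    boundary_u: np.ndarray,
):
    """Assemble the sparse convection-reaction system for one slice.

    Discretizes  -c*lap(u) + grad(phi).grad(u) + lap(phi)*u = 2*omega*mu0
    over the interior of ``mask_slice`` (central differences, physical
    spacing in metres for the phi terms).  Dirichlet values ``boundary_u``
    (u = 1/sigma on the mask boundary ring) are eliminated into the RHS.

    Returns ``(A, b, interior_idx)`` where ``interior_idx`` is the (i, j)
    index arrays of the interior unknowns in row order.
    """
    hx = float(voxel_size_mm[0]) * 1e-3
    hy = float(voxel_size_mm[1]) * 1e-3
    interior, _ = _interior_boundary(mask_slice)
    n = int(interior.sum())
    if n == 0:
        return None, None, None
    gx, gy, lap = _inplane_derivatives(phi_slice, hx, hy)
    if not (
        np.all(np.isfinite(gx[interior]))
        and np.all(np.isfinite(gy[interior]))
        and np.all(np.isfinite(lap[interior]))
    ):
        ii, jj = np.nonzero(interior & ~np.isfinite(gx + gy + lap))
        raise ValueError(
            f"non-finite phase derivative inside mask at voxel ({ii[0]}, {jj[0]})"
        )
    # diffusion scaling: voxel-lattice Laplacian (dimensionless c) or physical
    if cfg.c_units == "voxel":
        dx2 = dy2 = 1.0
    else:
        dx2, dy2 = hx**2, hy**2

    idx = -np.ones(mask_slice.shape, dtype=int)
    ii, jj = np.nonzero(interior)
    idx[ii, jj] = np.arange(n)

    rows, cols, vals = [], [], []
    b = np.full(n, 2.0 * cfg.omega * cfg.mu0)

    diag = lap[ii, jj] + 2.0 * cfg.c / dx2 + 2.0 * cfg.c / dy2
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)

    # neighbour couplings: (di, dj, coefficient)
    for di, dj, coef in (
        (1, 0, gx[ii, jj] / (2 * hx) - cfg.c / dx2),
        (-1, 0, -gx[ii, jj] / (2 * hx) - cfg.c / dx2),
        (0, 1, gy[ii, jj] / (2 * hy) - cfg.c / dy2),
        (0, -1, -gy[ii, jj] / (2 * hy) - cfg.c / dy2),
    ):
        ni, nj = ii + di, jj + dj
        nidx = idx[ni, nj]
        free = nidx >= 0
        rows.append(np.arange(n)[free])
        cols.append(nidx[free])
        vals.append(coef[free])
        # Dirichlet neighbours move to the RHS
        fixed = ~free
        b[fixed] -= coef[fixed] * boundary_u[ni[fixed], nj[fixed]]

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, b, (ii, jj)


def _boundary_u_from_helmholtz(
    phi_slice, mask_slice, cfg, voxel_size_mm
) -> np.ndarray:
    """Dirichlet u = 1/sigma on the boundary ring, seeded from the Helmholtz
    estimate of the nearest interior voxel and smoothed along the ring.

    The pointwise Laplacian estimate is undefined on the ring itself (grid
    edge / mask border), so each ring voxel inherits the nearest valid
    interior estimate before smoothing.
    """
    est = helmholtz_sigma(phi_slice, cfg, voxel_size_mm, mask_slice)
    interior, boundary = _interior_boundary(mask_slice)
    valid = interior & (est.sigma > cfg.sigma_floor)
    sig = est.sigma.copy()
    if valid.any():
        _, (ni, nj) = ndi.distance_transform_edt(~valid, return_indices=True)
        sig = sig[ni, nj]
    sig = np.clip(ndi.gaussian_filter(sig, 1.0, mode="nearest"),
                  cfg.sigma_floor, None)
    u = np.zeros_like(sig)
    u[boundary] = 1.0 / sig[boundary]
    return u


def solve_hfc(
    vol: MultiEchoPhaseVolume, cfg: ReconConfig | None = None
) -> ConductivityMap:
    """Reconstruct sigma_H from a multi-echo phase volume.

    Combines echoes, then per slice assembles and directly factorizes the
    convection-reaction system for u = 1/sigma_H.  Voxels with u <= 0 are
    masked out and counted; per-slice relative residuals are reported.
    """
    cfg = cfg or ReconConfig()
    phi_tr, mask = combine_echo_phase(vol)
    return solve_hfc_from_phase(phi_tr, mask, cfg, vol.voxel_size)


def solve_hfc_from_phase(
    phi_tr: np.ndarray,
    mask: np.ndarray,
    cfg: ReconConfig,
    voxel_size_mm: np.ndarray,
) -> ConductivityMap:
    """Slice-wise convection-reaction solve given a combined phase field."""
    phi_tr = np.asarray(phi_tr, dtype=float)
    if phi_tr.ndim == 2:
        phi_tr = phi_tr[..., None]
        mask = np.asarray(mask, dtype=bool)[..., None]
    mask = np.asarray(mask, dtype=bool)
    sigma = np.zeros(phi_tr.shape)
    out_mask = np.zeros(phi_tr.shape, dtype=bool)
    residuals, skipped, n_nonpos_total, n_interior_total = {}, [], 0, 0

    for k in range(phi_tr.shape[2]):
        msk = mask[:, :, k]
        phi = _smooth_slice(phi_tr[:, :, k], cfg.smooth_fwhm_vox)
        interior, boundary = _interior_boundary(msk)
        if interior.sum() == 0:
            if msk.any():
                skipped.append(k)
            continue
        if cfg.boundary_sigma is None:
            bu = _boundary_u_from_helmholtz(phi, msk, cfg, voxel_size_mm)
        else:
            bs = cfg.boundary_sigma
            bsl = bs[:, :, k] if isinstance(bs, np.ndarray) and bs.ndim == 3 else bs
            bu = np.zeros_like(phi)
            bu[boundary] = 1.0 / np.asarray(bsl, dtype=float)[boundary] \
                if isinstance(bsl, np.ndarray) else 1.0 / float(bsl)
        A, b, (ii, jj) = assemble_cr_system(phi, msk, cfg, voxel_size_mm, bu)
        u = spla.spsolve(A.tocsc(), b)
        res = float(np.linalg.norm(A @ u - b) / np.linalg.norm(b))
        if not np.all(np.isfinite(u)) or res > cfg.residual_tol:
            raise RuntimeError(
                f"slice {k}: solver failed (relative residual {res:.3e})"
            )
        residuals[k] = res
        nonpos = u <= 0
        n_nonpos_total += int(nonpos.sum())
        n_interior_total += u.size
        sig_sl = np.zeros(phi.shape)
        sig_sl[ii[~nonpos], jj[~nonpos]] = 1.0 / u[~nonpos]
        sigma[:, :, k] = sig_sl
        ok = np.zeros(phi.shape, dtype=bool)
        ok[ii[~nonpos], jj[~nonpos]] = True
        # boundary ring keeps its Dirichlet value so the map is defined there
        sigma[:, :, k][boundary] = np.where(
            bu[boundary] > 0, 1.0 / np.where(bu[boundary] > 0, bu[boundary], 1.0), 0.0
        )
        ok |= boundary & (bu > 0)
        out_mask[:, :, k] = ok

    if n_interior_total and n_nonpos_total / n_interior_total > cfg.neg_fraction_max:
        raise RuntimeError(
            f"{n_nonpos_total}/{n_interior_total} interior voxels with u <= 0 "
            f"exceeds threshold {cfg.neg_fraction_max}"
        )
    return ConductivityMap(
        sigma=sigma,
        mask=out_mask,
        provenance="convection_reaction",
        report={
            "per_slice_residual": residuals,
            "skipped_slices": skipped,
            "n_nonpositive_u": n_nonpos_total,
            "n_interior": n_interior_total,
        },
    )
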