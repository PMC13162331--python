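"""Diffusion tensor model: weighted log-linear fit and scalar maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi import DwiDataset

# lower-triangular storage order used for 6-volume tensor files
LOWER_TRIANGULAR_ORDER = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")


@dataclass
class DiffusionTensorField:
    """Fitted symmetric 3x3 tensors with eigen-system and scalar maps.

    tensor : (X, Y, Z, 3, 3) in mm^2/s.
    eigenvalues : (X, Y, Z, 3), sorted descending (lambda1 >= 2 >= 3).
    eigenvectors : (X, Y, Z, 3, 3), columns are the eigenvectors (S_D).
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0
    b_shell: float | None = None
    flags: np.ndarray | None = None

    @property
    def md(self) -> np.ndarray:
        return self.eigenvalues.mean(axis=-1)

    @property
    def ad(self) -> np.ndarray:
        return self.eigenvalues[..., 0]

    @property
    def rd(self) -> np.ndarray:
        return self.eigenvalues[..., 1:].mean(axis=-1)

    @property
    def fa(self) -> np.ndarray:
        ev = self.eigenvalues
        md = self.md[..., None]
        num = np.sqrt(1.5 * ((ev - md) ** 2).sum(axis=-1))
        den = np.sqrt((ev**2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return np.clip(fa, 0.0, 1.0)

    def lower_triangular(self) -> np.ndarray:
        """(X, Y, Z, 6) in the order Dxx Dxy Dyy Dxz Dyz Dzz."""
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
                "DiffusionTensorField"
                + (f" (b = {self.b_shell:g})" if self.b_shell else ""),
                f"  voxels fitted  : {int(m.sum())}",
                f"  MD [mm^2/s]    : median {np.median(self.md[m]):.3e}",
                f"  FA             : median {np.median(self.fa[m]):.3f}",
                f"  clamped voxels : {self.n_clamped}",
            ]
        )


class DiffusionTensorModel:
    """Weighted log-linear least-squares diffusion tensor fit.

    The log-signal is linear in the six unique tensor elements; weights
    proportional to the squared signal make the log-domain fit
    approximately maximum-likelihood for Gaussian signal noise.

    Parameters
    ----------
    data : DwiDataset
    shell : optional b-value (or list) restricting the fit to b = 0 plus
        that shell; tensors can then be fitted per shell as needed.
    weighted : apply signal-squared weights (True) or plain OLS.
    """

    def __init__(self, data: DwiDataset, shell=None, weighted: bool = True):
        self.data = data.shell_selection(shell) if shell is not None else data
        self.shell = shell
        self.weighted = weighted
        b = self.data.bvals
        g = self.data.bvecs
        n_dirs = np.unique(
            np.round(g[self.data.shell_ids > 0], 6), axis=0
        ).shape[0]
        if n_dirs < 6:
            raise ValueError("at least 6 unique gradient directions required")
        # design matrix for ln S = ln S0 - b g^T D g
        self._design = np.column_stack(
            [
                np.ones_like(b),
                -b * g[:, 0] ** 2,
                -b * g[:, 1] ** 2,
                -b * g[:, 2] ** 2,
                -2.0 * b * g[:, 0] * g[:, 1],
                -2.0 * b * g[:, 0] * g[:, 2],
                -2.0 * b * g[:, 1] * g[:, 2],
            ]
        )

    def fit(self) -> DiffusionTensorField:
        d = self.data
        grid = d.signals.shape[:3]
        sig = d.signals.reshape(-1, d.bvals.size)
        mask = d.mask.reshape(-1) & np.all(sig > 0, axis=1)
        s = sig[mask]
        y = np.log(s)
        X = self._design
        if self.weighted:
            # per-voxel weights: solve (X^T W X) beta = X^T W y, W = diag(s^2)
            beta = np.empty((s.shape[0], 7))
            XtX = np.einsum("vi,ij,ik->vjk", s**2, X, X, optimize=True)
            Xty = np.einsum("vi,ij,vi->vj", s**2, X, y, optimize=True)
            beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        else:
            beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T
        tensors = np.zeros((s.shape[0], 3, 3))
        dxx, dyy, dzz = beta[:, 1], beta[:, 2], beta[:, 3]
        dxy, dxz, dyz = beta[:, 4], beta[:, 5], beta[:, 6]
        tensors[:, 0, 0] = dxx
        tensors[:, 1, 1] = dyy
        tensors[:, 2, 2] = dzz
        tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
        tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
        tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
        evals, evecs = np.linalg.eigh(tensors)
        order = np.argsort(evals, axis=1)[:, ::-1]
        evals = np.take_along_axis(evals, order, axis=1)
        evecs = np.stack(
            [np.take_along_axis(evecs[:, i, :], order, axis=1) for i in range(3)],
            axis=1,
        )
        n_clamped = int(np.any(evals < 0, axis=1).sum())
        evals = np.clip(evals, 0.0, None)

        full_t = np.zeros(grid + (3, 3))
        full_ev = np.zeros(grid + (3,))
        full_vec = np.zeros(grid + (3, 3))
        full_vec[..., :, :] = np.eye(3)
        full_t.reshape(-1, 3, 3)[mask] = tensors
        full_ev.reshape(-1, 3)[mask] = evals
        full_vec.reshape(-1, 3, 3)[mask] = evecs
        shell_val = None
        if self.shell is not None and np.isscalar(self.shell):
            shell_val = float(self.shell)
        return DiffusionTensorField(
            tensor=full_t,
            eigenvalues=full_ev,
            eigenvectors=full_vec,
            mask=mask.reshape(grid),
            n_clamped=n_clamped,
            b_shell=shell_val,
        )


def fit_dti(data: DwiDataset, shell=None, weighted: bool = True) -> DiffusionTensorField:
    """Convenience wrapper: ``DiffusionTensorModel(data, shell).fit()``."""
    return DiffusionTensorModel(data, shell=shell, weighted=weighted).fit()
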