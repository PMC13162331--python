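"""NIfTI and FSL bval/bvec input/output helpers (nibabel-backed)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .dwi import DwiDataset
from .mrept import MultiEchoPhaseVolume


def load_nifti(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (data, affine, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return data, img.affine, np.asarray(img.header.get_zooms()[:3])


def save_nifti(path, data, affine) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    # zero the timestamp-like fields so identical inputs give identical bytes
    img.header["cal_min"] = 0
    img.header["cal_max"] = 0
    nib.save(img, str(path))


def load_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL-format whitespace-separated 1xN bvals and 3xN bvecs."""
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is 3xN rows, transpose
        bvecs = bvecs.T
    return bvals, bvecs


def save_bvals_bvecs(bval_path, bvec_path, bvals, bvecs) -> None:
    np.savetxt(str(bval_path), np.atleast_2d(np.asarray(bvals)), fmt="%.1f")
    np.savetxt(str(bvec_path), np.asarray(bvecs).T, fmt="%.8f")


def load_dwi(dwi_path, bval_path, bvec_path, mask_path=None) -> DwiDataset:
    data, affine, vox = load_nifti(dwi_path)
    bvals, bvecs = load_bvals_bvecs(bval_path, bvec_path)
    mask = None
    if mask_path is not None:
        mask = load_nifti(mask_path)[0] > 0
    return DwiDataset(
        signals=data, bvals=bvals, bvecs=bvecs,
        voxel_size=vox, affine=affine, mask=mask,
    )


def load_multi_echo_phase(
    phase_path, magnitude_path, echo_times_ms, mask_path=None
) -> MultiEchoPhaseVolume:
    """Load a 4-D phase + magnitude pair (echo on the 4th axis).

    ``echo_times_ms`` may be a sequence, a comma-separated string, or the
    path of a JSON sidecar with an ``echo_times_ms`` entry.
    """
    phase, affine, vox = load_nifti(phase_path)
    mag = load_nifti(magnitude_path)[0]
    if isinstance(echo_times_ms, (str, Path)):
        p = Path(echo_times_ms)
        if p.exists():
            echo_times_ms = json.loads(p.read_text())["echo_times_ms"]
        else:
            echo_times_ms = [float(x) for x in str(echo_times_ms).split(",")]
    mask = None
    if mask_path is not None:
        mask = load_nifti(mask_path)[0] > 0
    return MultiEchoPhaseVolume(
        phase=phase, magnitude=mag,
        echo_times=np.asarray(echo_times_ms, dtype=float),
        voxel_size=vox, affine=affine, mask=mask,
    )
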