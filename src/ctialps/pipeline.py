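"""Subject-level orchestration: phase + DWI in, ALPS table out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .alps import (
    cti_alps,
    cti_alps_closed_form_from_rois,
    default_roi_specs,
    dti_alps,
    laterality,
    place_rois,
)
from .conductivity import CompartmentModel, build_cl
from .dti import DiffusionTensorModel
from .dwi import DwiDataset
from .mrept import MultiEchoPhaseVolume, ReconConfig, solve_hfc
from .smt import MCSMTModel


@dataclass
class SubjectResult:
    """All per-subject outputs of the CTI-ALPS pipeline."""

    sigma_h: object
    smt: object
    dti: dict
    cl: object
    alps: pd.DataFrame
    rois: dict = field(repr=False, default=None)

    def summary(self) -> str:
        lines = ["CTI-ALPS subject result", self.sigma_h.summary(), self.smt.summary()]
        for shell, f in self.dti.items():
            lines.append(f.summary())
        lines.append(self.cl.summary())
        lines.append(self.alps.to_string(index=False))
        return "\n".join(lines)


def run_subject(
    phase_vol: MultiEchoPhaseVolume,
    dwi: DwiDataset,
    recon_cfg: ReconConfig | None = None,
    model: CompartmentModel | None = None,
    roi_specs=None,
    shells=(800, 2000),
    subject_id: str = "subject",
    fit_mask: np.ndarray | str | None = "roi",
) -> SubjectResult:
    """Run the full pipeline on co-registered phase and DWI volumes.

    ``fit_mask`` restricts the voxel-wise fits: an explicit boolean array,
    ``"roi"`` (default; ROI spheres dilated by 2 voxels — the index uses
    only ROI voxels), or ``None`` for the whole DWI mask.
    """
    recon_cfg = recon_cfg or ReconConfig()
    model = model or CompartmentModel()
    roi_specs = roi_specs or default_roi_specs()
    rois = place_rois(roi_specs, dwi.affine, dwi.signals.shape[:3])

    if isinstance(fit_mask, str) and fit_mask == "roi":
        union = np.zeros(dwi.signals.shape[:3], dtype=bool)
        for m in rois.values():
            union |= m
        fit_mask = ndi.binary_dilation(union, iterations=2) & dwi.mask
    elif fit_mask is None:
        fit_mask = dwi.mask
    dwi_fit = DwiDataset(
        signals=dwi.signals, bvals=dwi.bvals, bvecs=dwi.bvecs,
        voxel_size=dwi.voxel_size, affine=dwi.affine, mask=fit_mask,
    )

    sigma_h = solve_hfc(phase_vol, recon_cfg)
    smt = MCSMTModel(dwi_fit).fit()
    dti_fields = {int(b): DiffusionTensorModel(dwi_fit, shell=b).fit() for b in shells}

    cl = build_cl(
        sigma_h.sigma, smt, dti_fields[max(shells)], model,
        mask=smt.mask & dti_fields[max(shells)].mask & sigma_h.mask,
    )

    rows = []
    cti9 = cti_alps(cl, rois, affine=dwi.affine)
    cti11 = {s: cti_alps_closed_form_from_rois(smt, rois, s) for s in ("L", "R")}
    dti_res = {b: dti_alps(dti_fields[b], rois, affine=dwi.affine) for b in dti_fields}
    delta9 = laterality(cti9)
    for side in ("L", "R"):
        row = dict(
            subject_id=subject_id,
            side=side,
            cti_alps=cti9[side].value,
            cti_alps_closed_form=cti11[side].value,
            delta_cti_alps=delta9,
            roi_voxels_projection=cti9[side].roi_voxel_counts["projection"],
            roi_voxels_association=cti9[side].roi_voxel_counts["association"],
        )
        for b, res in dti_res.items():
            row[f"dti_alps_b{b}"] = res[side].value
            row[f"delta_dti_alps_b{b}"] = laterality(res)
        rows.append(row)
    table = pd.DataFrame(rows)
    return SubjectResult(
        sigma_h=sigma_h, smt=smt, dti=dti_fields, cl=cl, alps=table, rois=rois
    )
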