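"""ALPS indices from tensor fields and template-space spherical ROIs.

The ALPS (analysis aLong the Perivascular Space) index compares diffusivity
(or conductivity) along the left-right x-axis — the direction of the deep
medullary veins and their perivascular spaces — against the fiber-transverse
diffusivities in two white-matter sites at the lateral-ventricle level:
a projection-fiber ROI (p) and an association-fiber ROI (a):

    ALPS = (Dxx(p) + Dxx(a)) / (Dyy(p) + Dzz(a))

The conductivity variant (CTI-ALPS) substitutes the low-frequency
conductivity tensor components C_L for D.  Besides the component-ratio form,
a coordinate-free form over per-ROI direction cosines and a closed form in
the spherical-mean compartment parameters are provided as cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

#: template-space ROI set as shipped: 5-mm spheres on bilateral projection
#: and association fiber sites
DEFAULT_ROI_SPECS = [
    dict(name="projection_R", center_mm=(24.0, -12.0, 24.0), diameter_mm=5.0),
    dict(name="projection_L", center_mm=(-28.0, -12.0, 24.0), diameter_mm=5.0),
    dict(name="association_R", center_mm=(36.0, -12.0, 24.0), diameter_mm=5.0),
    dict(name="association_L", center_mm=(-40.0, -12.0, 24.0), diameter_mm=5.0),
]


@dataclass
class RoiSpec:
    """A spherical ROI in template (world) coordinates."""

    name: str
    center_mm: tuple
    diameter_mm: float

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")


@dataclass
class AlpsResult:
    """Per-hemisphere ALPS value with the ROI component means behind it."""

    side: str
    value: float
    variant: str
    components: dict = field(default_factory=dict)
    roi_voxel_counts: dict = field(default_factory=dict)
    b_value: float | None = None

    def summary(self) -> str:
        comp = ", ".join(f"{k}={v:.4g}" for k, v in self.components.items())
        return (
            f"ALPS[{self.variant}] side={self.side}"
            + (f" b={self.b_value:g}" if self.b_value else "")
            + f": {self.value:.4f}  ({comp})"
        )


def default_roi_specs() -> list[RoiSpec]:
    return [RoiSpec(**s) for s in DEFAULT_ROI_SPECS]


def place_rois(
    specs: list[RoiSpec], affine: np.ndarray, shape: tuple
) -> dict[str, np.ndarray]:
    """Voxelize spherical ROIs: a voxel belongs to an ROI iff its center's
    world distance to the ROI center is <= diameter/2."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    xyz = (vox @ affine.T)[..., :3]
    masks = {}
    for s in specs:
        c = np.asarray(s.center_mm, dtype=float)
        m = np.linalg.norm(xyz - c, axis=-1) <= s.diameter_mm / 2.0
        if not m.any():
            raise ValueError(f"ROI {s.name!r} contains no voxels")
        masks[s.name] = m
    return masks


def _assert_ras(affine: np.ndarray):
    """Require template (RAS) orientation: x left-right, y anterior-posterior,
    z inferior-superior, each axis-aligned."""
    R = np.asarray(affine, dtype=float)[:3, :3]
    off = R - np.diag(np.diag(R))
    if np.any(np.abs(off) > 1e-6) or np.any(np.diag(R) <= 0):
        raise ValueError(
            "tensor field must be in axis-aligned RAS template orientation; "
            "reorient upstream rather than relying on silent flips"
        )


def _roi_component_means(
    diag_field: np.ndarray,
    rois: dict[str, np.ndarray],
    side: str,
    valid: np.ndarray,
) -> tuple[dict, dict]:
    comps, counts = {}, {}
    for site, comp_keys in (("projection", ("xx", "yy", "zz")),
                            ("association", ("xx", "yy", "zz"))):
        m = rois[f"{site}_{side}"] & valid
        if not m.any():
            raise ValueError(f"all voxels of ROI {site}_{side} are flagged/invalid")
        counts[site] = int(m.sum())
        for ax, key in enumerate(comp_keys):
            comps[f"{key}_{site[0]}"] = float(diag_field[..., ax][m].mean())
    return comps, counts


def _alps_from_diag(diag_field, rois, valid, variant, b_value=None):
    results = {}
    for side in ("L", "R"):
        comps, counts = _roi_component_means(diag_field, rois, side, valid)
        value = (comps["xx_p"] + comps["xx_a"]) / (comps["yy_p"] + comps["zz_a"])
        results[side] = AlpsResult(
            side=side,
            value=float(value),
            variant=variant,
            components=comps,
            roi_voxel_counts=counts,
            b_value=b_value,
        )
    return results


def dti_alps(tensors, rois: dict[str, np.ndarray], affine=None) -> dict[str, AlpsResult]:
    """DTI-ALPS (mALPS) per hemisphere from water-tensor diagonals.

    ``tensors`` is a DiffusionTensorField; flagged/unfitted voxels are
    excluded from the ROI means.
    """
    if affine is not None:
        _assert_ras(affine)
    diag = np.stack(
        [tensors.tensor[..., 0, 0], tensors.tensor[..., 1, 1], tensors.tensor[..., 2, 2]],
        axis=-1,
    )
    return _alps_from_diag(diag, rois, tensors.mask, "dti", b_value=tensors.b_shell)


def cti_alps(cl, rois: dict[str, np.ndarray], affine=None,
                 exclude_flagged: bool = True) -> dict[str, AlpsResult]:
    """CTI-ALPS per hemisphere as the C_L component ratio (canonical form)."""
    if affine is not None:
        _assert_ras(affine)
    valid = cl.mask.copy()
    if exclude_flagged:
        valid &= cl.flags == 0
    diag = np.stack(
        [cl.tensor[..., 0, 0], cl.tensor[..., 1, 1], cl.tensor[..., 2, 2]],
        axis=-1,
    )
    return _alps_from_diag(diag, rois, valid, "cti")


def cti_alps_direction_cosine(sd_p: np.ndarray, d_p, sd_a: np.ndarray, d_a) -> float:
    """Coordinate-free CTI-ALPS from per-ROI direction cosines.

    ``sd_p``/``sd_a`` are the per-ROI eigenvector matrices (columns =
    eigenvectors, column i paired with eigenvalue d[i]); ``d_p``/``d_a`` the
    extra-neurite eigenvalues.  With S_D = I this reduces exactly to the
    axis-aligned component composition.
    """
    for sd in (sd_p, sd_a):
        if np.abs(sd @ sd.T - np.eye(3)).max() > 1e-8:
            raise ValueError("direction-cosine matrix is not orthogonal")
    d_p = np.asarray(d_p, dtype=float)
    d_a = np.asarray(d_a, dtype=float)
    num = (sd_p[0, :] ** 2 * d_p).sum() + (sd_a[0, :] ** 2 * d_a).sum()
    den = (sd_p[1, :] ** 2 * d_p).sum() + (sd_a[2, :] ** 2 * d_a).sum()
    return float(num / den)


def cti_alps_closed_form(nu_ip, d_ip, nu_ia, d_ia, d_ea) -> float:
    """Closed-form CTI-ALPS from per-ROI spherical-mean parameters.

    Assumes axis alignment (projection fibers transverse to x and y,
    association fibers axial along z) and a common scalar prefactor:

        [(1-nu_ia) D_ia + (1-nu_ip) D_ip]
        / [(1-nu_ip) D_ip + (3 D_ea - 2 (1-nu_ia) D_ia)]
    """
    num = (1.0 - nu_ia) * d_ia + (1.0 - nu_ip) * d_ip
    den = (1.0 - nu_ip) * d_ip + (3.0 * d_ea - 2.0 * (1.0 - nu_ia) * d_ia)
    if den <= 0:
        raise ValueError("non-positive denominator in closed-form index")
    return float(num / den)


def cti_alps_closed_form_from_rois(smt, rois: dict[str, np.ndarray],
                            side: str) -> AlpsResult:
    """Closed-form index from ROI means of the voxel-wise MC-SMT maps."""
    comps, counts = {}, {}
    vals = {}
    for site in ("projection", "association"):
        m = rois[f"{site}_{side}"] & smt.mask
        if not m.any():
            raise ValueError(f"all voxels of ROI {site}_{side} are invalid")
        counts[site] = int(m.sum())
        vals[site] = {
            "nu": float(smt.nu_int[m].mean()),
            "d_int": float(smt.d_int[m].mean()),
            "d_ext": float(smt.d_ext[m].mean()),
        }
    value = cti_alps_closed_form(
        nu_ip=vals["projection"]["nu"], d_ip=vals["projection"]["d_int"],
        nu_ia=vals["association"]["nu"], d_ia=vals["association"]["d_int"],
        d_ea=vals["association"]["d_ext"],
    )
    comps = {f"{k}_{s[0]}": v for s, d in vals.items() for k, v in d.items()}
    return AlpsResult(side=side, value=value, variant="cti_closed_form",
                      components=comps, roi_voxel_counts=counts)


def check_prefactor_cancellation(component_ratio: float, closed_form: float, tol: float = 0.05) -> bool:
    """Warn when the component-ratio and closed-form indices disagree beyond
    ``tol`` — the signature of ROI-specific scalar prefactors."""
    rel = abs(closed_form - component_ratio) / abs(component_ratio)
    if rel > tol:
        warnings.warn(
            f"closed-form vs component-ratio CTI-ALPS differ by {rel:.1%}: "
            "scalar prefactor likely differs between ROIs"
        )
        return False
    return True


def laterality(results: dict[str, AlpsResult]) -> float:
    """Within-subject laterality Delta = right - left of one index variant."""
    if "L" not in results or "R" not in results:
        raise ValueError("both sides required for laterality")
    return float(results["R"].value - results["L"].value)
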