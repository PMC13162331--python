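"""ROI placement and the ALPS index variants."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ctialps.alps import (
    RoiSpec,
    cti_alps,
    cti_alps_direction_cosine,
    cti_alps_closed_form,
    default_roi_specs,
    dti_alps,
    laterality,
    place_rois,
)
from ctialps.conductivity import ConductivityTensorField
from ctialps.dti import DiffusionTensorField


def _grid(shape=(21, 21, 21), vox=2.0):
    aff = np.diag([vox, vox, vox, 1.0])
    aff[:3, 3] = -(np.array(shape) - 1) / 2.0 * vox
    return aff, shape


def brute_force_sphere_count(center, diameter, affine, shape):
    """Independent enumeration of voxels within the sphere radius."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                xyz = (affine @ np.array([i, j, k, 1.0]))[:3]
                if np.linalg.norm(xyz - np.asarray(center)) <= diameter / 2.0:
                    count += 1
    return count


def _tensor_field(shape, tensor_by_mask):
    """tensor_by_mask: list of (mask or None, 3x3); None = everywhere."""
    t = np.zeros(shape + (3, 3))
    for m, tens in tensor_by_mask:
        if m is None:
            t[...] = tens
        else:
            t[m] = tens
    evals, evecs = np.linalg.eigh(t)
    order = np.argsort(evals, axis=-1)[..., ::-1]
    evals = np.take_along_axis(evals, order, axis=-1)
    evecs = np.take_along_axis(evecs, order[..., None, :], axis=-1)
    return DiffusionTensorField(
        tensor=t, eigenvalues=evals, eigenvectors=evecs, mask=np.ones(shape, bool)
    )


def _roi_masks(affine, shape):
    return place_rois(default_roi_specs(), affine, shape)


def _alps_grid():
    # grid that covers the template ROI centers with voxel centers on them
    shape = (54, 14, 10)
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = (-54.0, -26.0, 14.0)
    return aff, shape


class TestRoiPlacement:
    def test_5mm_sphere_on_2mm_grid_has_7_voxels(self):
        aff, shape = _grid()
        spec = RoiSpec(name="projection_R", center_mm=(0, 0, 0), diameter_mm=5.0)
        masks = place_rois([spec], aff, shape)
        assert masks["projection_R"].sum() == 7
        assert masks["projection_R"].sum() == brute_force_sphere_count(
            (0, 0, 0), 5.0, aff, shape
        )

    def test_tiny_sphere_is_single_voxel(self):
        aff, shape = _grid()
        masks = place_rois(
            [RoiSpec(name="projection_L", center_mm=(0, 0, 0), diameter_mm=0.1)],
            aff, shape,
        )
        assert masks["projection_L"].sum() == 1

    def test_translation_by_voxel_pitch_shifts_mask(self):
        aff, shape = _grid()
        m0 = place_rois(
            [RoiSpec(name="a", center_mm=(0, 0, 0), diameter_mm=5.0)], aff, shape
        )["a"]
        m1 = place_rois(
            [RoiSpec(name="a", center_mm=(2.0, 0, 0), diameter_mm=5.0)], aff, shape
        )["a"]
        assert m0.sum() == m1.sum()
        np.testing.assert_array_equal(np.roll(m0, 1, axis=0), m1)

    def test_default_specs_are_the_template_set(self):
        names = {s.name for s in default_roi_specs()}
        assert names == {"projection_L", "projection_R",
                         "association_L", "association_R"}
        proj_r = next(s for s in default_roi_specs() if s.name == "projection_R")
        assert proj_r.center_mm == (24.0, -12.0, 24.0)
        assert proj_r.diameter_mm == 5.0

    def test_empty_roi_rejected(self):
        aff, shape = _grid()
        with pytest.raises(ValueError, match="no voxels"):
            place_rois(
                [RoiSpec(name="a", center_mm=(500, 0, 0), diameter_mm=5.0)],
                aff, shape,
            )


class TestDtiAlps:
    def test_isotropic_tensors_give_unity(self):
        aff, shape = _alps_grid()
        field = _tensor_field(shape, [(None, np.eye(3) * 0.7e-3)])
        res = dti_alps(field, _roi_masks(aff, shape), affine=aff)
        for side in ("L", "R"):
            assert res[side].value == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_ratio(self):
        aff, shape = _alps_grid()
        rois = _roi_masks(aff, shape)
        proj = np.diag([1.2e-3, 0.4e-3, 0.8e-3])
        asso = np.diag([1.1e-3, 0.7e-3, 0.3e-3])
        field = _tensor_field(
            shape,
            [(None, np.eye(3) * 1e-3),
             (rois["projection_L"] | rois["projection_R"], proj),
             (rois["association_L"] | rois["association_R"], asso)],
        )
        res = dti_alps(field, rois, affine=aff)
        expected = (1.2 + 1.1) / (0.4 + 0.3)
        assert res["L"].value == pytest.approx(expected, rel=1e-12)
        assert res["R"].value == pytest.approx(expected, rel=1e-12)
        assert res["L"].components["xx_p"] == pytest.approx(1.2e-3)

    def test_swapping_transverse_diffusivities_changes_denominator_only(self):
        aff, shape = _alps_grid()
        rois = _roi_masks(aff, shape)
        proj = np.diag([1.2e-3, 0.4e-3, 0.8e-3])
        asso = np.diag([1.1e-3, 0.7e-3, 0.3e-3])
        proj_sw = np.diag([1.2e-3, 0.8e-3, 0.4e-3])
        asso_sw = np.diag([1.1e-3, 0.3e-3, 0.7e-3])
        f1 = _tensor_field(shape, [(None, np.eye(3) * 1e-3),
                                   (rois["projection_L"], proj),
                                   (rois["association_L"], asso)])
        f2 = _tensor_field(shape, [(None, np.eye(3) * 1e-3),
                                   (rois["projection_L"], proj_sw),
                                   (rois["association_L"], asso_sw)])
        r1 = dti_alps(f1, rois, affine=aff)["L"].value
        r2 = dti_alps(f2, rois, affine=aff)["L"].value
        assert r1 == pytest.approx((1.2 + 1.1) / (0.4 + 0.3), rel=1e-12)
        assert r2 == pytest.approx((1.2 + 1.1) / (0.8 + 0.7), rel=1e-12)

    def test_non_ras_affine_rejected(self):
        aff, shape = _alps_grid()
        bad = aff.copy()
        bad[0, 0] = -2.0
        field = _tensor_field(shape, [(None, np.eye(3) * 1e-3)])
        with pytest.raises(ValueError, match="RAS"):
            dti_alps(field, _roi_masks(aff, shape), affine=bad)


def _cl_from_tensor_field(field, scale=1.0):
    t = field.tensor * scale
    return ConductivityTensorField(
        tensor=t, eigenvalues=field.eigenvalues * scale,
        eigenvectors=field.eigenvectors,
        sigma_l=np.trace(t, axis1=-2, axis2=-1) / 3.0,
        mask=field.mask, flags=np.zeros(field.mask.shape, np.uint8),
    )


class TestCtiAlps:
    def test_isotropic_cl_gives_unity_and_scale_invariance(self):
        aff, shape = _alps_grid()
        rois = _roi_masks(aff, shape)
        field = _tensor_field(shape, [(None, np.eye(3) * 0.42)])
        for scale in (1.0, 17.3):
            res = cti_alps(_cl_from_tensor_field(field, scale), rois, affine=aff)
            assert res["L"].value == pytest.approx(1.0, abs=1e-12)

    def test_global_scaling_leaves_index_unchanged(self):
        aff, shape = _alps_grid()
        rois = _roi_masks(aff, shape)
        proj = np.diag([0.3, 0.1, 0.25])
        asso = np.diag([0.28, 0.2, 0.08])
        field = _tensor_field(shape, [(None, np.eye(3) * 0.2),
                                      (rois["projection_L"], proj),
                                      (rois["association_L"], asso)])
        v1 = cti_alps(_cl_from_tensor_field(field, 1.0), rois, affine=aff)["L"].value
        v2 = cti_alps(_cl_from_tensor_field(field, 5.5), rois, affine=aff)["L"].value
        assert v1 == pytest.approx(v2, rel=1e-14)

    def test_direction_cosine_form_reduces_to_closed_form_with_identity_frame(self):
        nu_p, d_p = 0.6, 1.7e-3
        nu_a, d_a = 0.5, 2.0e-3
        d_ea = 1.4e-3
        d1p = (1 - nu_p) * d_p
        d_ep = d_p * (1 + 2 * (1 - nu_p)) / 3
        d3p = 3 * d_ep - 2 * d1p
        d1a = (1 - nu_a) * d_a
        d3a = 3 * d_ea - 2 * d1a
        # axis alignment of the closed form: fibers along z in both ROIs
        sd = np.eye(3)[:, [2, 0, 1]]
        v10 = cti_alps_direction_cosine(sd, [d3p, d1p, d1p], sd, [d3a, d1a, d1a])
        v11 = cti_alps_closed_form(nu_p, d_p, nu_a, d_a, d_ea)
        assert v10 == v11

    def test_direction_cosine_form_matches_component_ratio_under_rotations(self):
        """20 seeded random per-ROI rotations: the direction-cosine form
        equals the component ratio of the rotated tensors to 1e-10."""
        d_p = np.array([1.5e-3, 0.6e-3, 0.6e-3])
        d_a = np.array([1.8e-3, 0.4e-3, 0.4e-3])
        for i in range(20):
            rp = Rotation.random(random_state=np.random.RandomState(100 + i)).as_matrix()
            ra = Rotation.random(random_state=np.random.RandomState(200 + i)).as_matrix()
            cp = rp @ np.diag(d_p) @ rp.T
            ca = ra @ np.diag(d_a) @ ra.T
            component_ratio = (cp[0, 0] + ca[0, 0]) / (cp[1, 1] + ca[2, 2])
            dircos = cti_alps_direction_cosine(rp, d_p, ra, d_a)
            assert dircos == pytest.approx(component_ratio, abs=1e-10)

    def test_degenerate_isotropic_eigenvalues_give_unity(self):
        d = np.full(3, 1.1e-3)
        for i in range(5):
            r = Rotation.random(random_state=np.random.RandomState(i)).as_matrix()
            assert cti_alps_direction_cosine(r, d, r, d) == pytest.approx(1.0, abs=1e-12)

    def test_direction_cosine_form_requires_orthogonal_frame(self):
        bad = np.eye(3)
        bad[0, 1] = 0.2
        with pytest.raises(ValueError, match="orthogonal"):
            cti_alps_direction_cosine(bad, np.ones(3), np.eye(3), np.ones(3))

    def test_closed_form_worked_example(self):
        v = cti_alps_closed_form(0.5, 1.2e-3, 0.5, 1.2e-3, 0.8e-3)
        assert v == pytest.approx(1.2e-3 / 1.8e-3, rel=1e-12)

    def test_closed_form_equal_rois_isotropic_gives_unity(self):
        # d3 = d1 requires 3*d_ea = 3*(1-nu)*d_int
        nu, d = 0.4, 1.5e-3
        d_ea = (1 - nu) * d
        assert cti_alps_closed_form(nu, d, nu, d, d_ea) == pytest.approx(1.0)

    def test_closed_form_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            cti_alps_closed_form(0.1, 2.5e-3, 0.1, 2.8e-3, 0.1e-3)


class TestLaterality:
    def test_signed_difference_and_antisymmetry(self):
        from ctialps.alps import AlpsResult

        res = {
            "L": AlpsResult(side="L", value=1.33, variant="dti"),
            "R": AlpsResult(side="R", value=1.35, variant="dti"),
        }
        assert laterality(res) == pytest.approx(0.02)
        swapped = {"L": res["R"], "R": res["L"]}
        assert laterality(swapped) == pytest.approx(-0.02)
        assert laterality({"L": res["L"], "R": res["L"]}) == 0.0

    def test_missing_side_rejected(self):
        from ctialps.alps import AlpsResult

        with pytest.raises(ValueError, match="both sides"):
            laterality({"L": AlpsResult(side="L", value=1.0, variant="dti")})
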