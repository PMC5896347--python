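"""Strain estimation, principal angle, NSDI and the lesion ROI metrics."""

import numpy as np
import pytest

from nsdielast import phantom_fem
from nsdielast.fields import DisplacementField, StrainTensorField
from nsdielast.strain_nsdi import (
    LesionROI,
    estimate_strains,
    make_outside_band,
    nsdi,
    nsdi_from_strain,
    principal_angle,
    roi_stats,
    size_ratio,
)

QP = np.pi / 4


def strain_of(exx, eyy, exy, sp=(0.2, 0.2)):
    return StrainTensorField(
        np.atleast_2d(np.asarray(exx, float)),
        np.atleast_2d(np.asarray(eyy, float)),
        np.atleast_2d(np.asarray(exy, float)),
        sp,
    )


def eigen_oracle_angle(exx, eyy, exy):
    """Angle to the principal axis nearest the lateral direction, by
    brute-force eigen-decomposition of [[exx, exy], [exy, eyy]]."""
    w, v = np.linalg.eigh(np.array([[exx, exy], [exy, eyy]]))
    angles = []
    for k in (0, 1):
        ang = np.arctan2(v[1, k], v[0, k])  # angle to lateral (x) axis
        # fold direction ambiguity and axis periodicity into (-pi/2, pi/2]
        while ang > np.pi / 2:
            ang -= np.pi
        while ang <= -np.pi / 2:
            ang += np.pi
        angles.append(ang)
    return min(angles, key=abs)


class TestEstimateStrains:
    def test_linear_axial_profile_recovered_exactly(self):
        ny = nx = 31
        sp = 0.2
        Y, X = np.meshgrid(np.arange(ny) * sp, np.arange(nx) * sp, indexing="ij")
        f = DisplacementField(-0.01 * Y, 0.005 * X, (sp, sp))
        st = estimate_strains(f, window_mm=1.8)
        m = st.valid_mask
        assert np.allclose(st.eyy[m], -0.01, atol=1e-12)
        assert np.allclose(st.exx[m], 0.005, atol=1e-12)
        assert np.allclose(st.exy[m], 0.0, atol=1e-12)

    def test_rigid_rotation_gives_zero_shear(self):
        """The symmetric strain combination cancels rigid-body rotation,
        unlike the axial-shear component alone."""
        ny = nx = 31
        sp = 0.2
        Y, X = np.meshgrid(np.arange(ny) * sp, np.arange(nx) * sp, indexing="ij")
        omega = 1e-3
        f = DisplacementField(omega * X, -omega * Y, (sp, sp))
        st = estimate_strains(f, window_mm=1.8)
        m = st.valid_mask
        assert np.max(np.abs(st.exy[m])) < 1e-12
        # the axial-shear component alone would be omega, not zero
        assert omega > 1e-12

    def test_window_shorter_than_three_steps_rejected(self):
        f = DisplacementField(np.zeros((20, 20)), np.zeros((20, 20)), (1.0, 1.0))
        with pytest.raises(ValueError):
            estimate_strains(f, window_mm=1.8)

    def test_fe_phantom_strains_match_element_strains(self, case1_coarse):
        """Windowed estimation on the sampled FE field reproduces the FE
        shape-function strains to a few percent of the peak strain."""
        spec, mesh, sol = case1_coarse
        fld = phantom_fem.sample_displacement(sol, mesh, 0.2)
        st = estimate_strains(fld, window_mm=1.8)
        exx, eyy, exy, mask, _, _ = phantom_fem.sample_strain(sol, mesh, 0.2)
        m = st.valid_mask & mask
        peak = np.max(np.abs(eyy[m]))
        rmse = np.sqrt(np.mean((st.eyy[m] - eyy[m]) ** 2))
        assert rmse < 0.05 * peak


class TestPrincipalAngle:
    def test_zero_shear_gives_zero_angle(self):
        st = strain_of(0.002, -0.01, 0.0)
        assert principal_angle(st)[0, 0] == 0.0

    def test_pure_shear_gives_quarter_pi(self):
        st = strain_of(0.0, 0.0, 1e-3)
        assert principal_angle(st)[0, 0] == pytest.approx(QP, abs=1e-15)

    def test_equal_arguments_give_pi_over_eight(self):
        st = strain_of(1e-3, -1e-3, 1e-3)  # exx - eyy = 2e-3 = 2 exy
        assert principal_angle(st)[0, 0] == pytest.approx(np.pi / 8, abs=1e-15)

    def test_fold_rule_near_negative_axis(self):
        st = strain_of(-1e-3, 1e-3, 1e-5)  # exx - eyy = -2e-3, tiny shear
        th = principal_angle(st)[0, 0]
        assert th == pytest.approx(-0.0050, abs=1e-4)
        assert th == pytest.approx(eigen_oracle_angle(-1e-3, 1e-3, 1e-5), abs=1e-12)

    def test_isotropic_strain_returns_zero(self):
        st = strain_of(1e-3, 1e-3, 0.0)
        assert principal_angle(st)[0, 0] == 0.0

    def test_matches_eigen_decomposition_on_random_tensors(self):
        """Folded angle equals the brute-force nearest-eigenvector angle."""
        rng = np.random.default_rng(12)
        n = 10_000
        exx, eyy, exy = rng.standard_normal((3, n)) * 0.01
        st = strain_of(exx[None, :], eyy[None, :], exy[None, :])
        th = principal_angle(st)[0]
        for i in range(0, n, 37):  # dense spot-check against the slow oracle
            assert th[i] == pytest.approx(eigen_oracle_angle(exx[i], eyy[i], exy[i]), abs=1e-9)
        assert np.all(np.abs(th) <= QP + 1e-15)


class TestNSDI:
    @pytest.mark.parametrize("theta, value", [(0.0, 0.0), (QP, 1.0), (np.pi / 8, 0.5)])
    def test_linear_normalization(self, theta, value):
        img = nsdi(np.full((4, 4), theta), (0.2, 0.2))
        assert np.allclose(img.values, value)

    def test_unfolded_input_rejected(self):
        with pytest.raises(ValueError):
            nsdi(np.full((4, 4), 1.0), (0.2, 0.2))

    def test_rotation_exclusion(self, case1_coarse):
        """Adding a linearized rigid rotation leaves NSDI untouched."""
        spec, mesh, sol = case1_coarse
        fld = phantom_fem.sample_displacement(sol, mesh, 0.4)
        base = nsdi_from_strain(estimate_strains(fld, 1.8))
        Y, X = np.meshgrid(fld.axial_coords_mm(), fld.lateral_coords_mm(), indexing="ij")
        omega = 5e-3
        rot = DisplacementField(
            fld.u_axial + omega * X, fld.v_lateral - omega * Y,
            fld.grid_spacing_mm, fld.origin_mm, fld.valid_mask,
            state="ground_truth",
        )
        rotated = nsdi_from_strain(estimate_strains(rot, 1.8))
        m = base.valid_mask & rotated.valid_mask
        assert np.max(np.abs(base.values[m] - rotated.values[m])) < 1e-9

    def test_axis_swap_invariance(self):
        rng = np.random.default_rng(3)
        exx, eyy, exy = rng.standard_normal((3, 5, 5)) * 0.01
        a = nsdi_from_strain(strain_of(exx, eyy, exy))
        b = nsdi_from_strain(strain_of(eyy, exx, exy))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_phantom_nsdi_quadrant_symmetric(self, case1_coarse):
        """Centered circular inclusion: the NSDI image mirrors about both
        centerlines (windowed image chain; sampled displacement is
        continuous, so the symmetry is exact to solver tolerance)."""
        spec, mesh, sol = case1_coarse
        from nsdielast.pipeline import truth_nsdi

        img, _, _ = truth_nsdi(spec, 0.4, strain_source="window")
        v = np.where(img.valid_mask, img.values, 0.0)
        assert np.allclose(v, v[:, ::-1], atol=1e-7)
        assert np.allclose(v, v[::-1, :], atol=1e-7)


class TestROI:
    def disc_roi(self, r=5.0, c=(20.0, 20.0), n=64):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return LesionROI(np.column_stack([c[1] + r * np.cos(t), c[0] + r * np.sin(t)]))

    def test_constant_image_means(self):
        img = nsdi(np.full((201, 201), np.pi / 8), (0.2, 0.2))
        inside, outside = roi_stats(img, self.disc_roi())
        assert inside == pytest.approx(0.5)
        assert outside == pytest.approx(0.5)

    def test_piecewise_image_means(self):
        roi = self.disc_roi()
        shape, sp = (201, 201), (0.2, 0.2)
        inside_mask = roi.inside_mask(shape, sp)
        theta = np.where(inside_mask, 0.8, 0.2) * QP
        img = nsdi(theta, sp)
        inside, outside = roi_stats(img, roi)
        assert inside == pytest.approx(0.8)
        assert outside == pytest.approx(0.2)

    def test_outside_band_has_equal_area(self):
        mask = self.disc_roi().inside_mask((201, 201), (0.2, 0.2))
        band = make_outside_band(mask)
        assert abs(int(band.sum()) - int(mask.sum())) <= 1
        assert not (band & mask).any()

    def test_band_physical_area_consistent_across_resolutions(self):
        areas = []
        for sp, shape in [((0.2, 0.2), (201, 201)), ((0.4, 0.4), (101, 101))]:
            mask = self.disc_roi().inside_mask(shape, sp)
            band = make_outside_band(mask)
            areas.append(band.sum() * sp[0] * sp[1])
        # center-sampled rasterization limits agreement to ~1% of the area
        assert abs(areas[0] - areas[1]) <= 0.01 * areas[0]

    def test_lesion_touching_border_rejected(self):
        roi = self.disc_roi(r=5.0, c=(3.0, 20.0))
        mask = roi.inside_mask((201, 201), (0.2, 0.2))
        with pytest.raises(ValueError):
            make_outside_band(mask)

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(ValueError):
            LesionROI(bowtie)


class TestSizeRatio:
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)

    def test_identical_contours(self):
        assert size_ratio(self.square, self.square) == pytest.approx(1.0)

    def test_scaled_contour_gives_squared_ratio(self):
        assert size_ratio(2 * self.square, self.square) == pytest.approx(4.0)

    def test_rectangle_vs_square(self):
        rect = self.square * np.array([1.0, 2.0])
        assert size_ratio(self.square, rect) == pytest.approx(0.5)

    def test_length_method_uses_caliper(self):
        assert size_ratio(2 * self.square, self.square, method="length") == pytest.approx(2.0)

    def test_degenerate_bmode_contour_rejected(self):
        line = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            size_ratio(self.square, line)
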