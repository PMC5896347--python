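"""Finite-element phantom solver: closed-form oracles and mesh contracts."""

import numpy as np
import pytest

from nsdielast import phantom_fem
from nsdielast.phantom_fem import (
    GeometryError,
    PhantomSpec,
    ResolutionError,
    build_mesh,
    random_sub_inclusions,
    sample_displacement,
    solve,
)

NU = 0.495


def homogeneous_spec(**kw):
    kw.setdefault("modulus_ratio", 1.0)
    kw.setdefault("applied_compression", 0.01)
    kw.setdefault("mesh_resolution_mm", 1.0)
    return PhantomSpec(**kw)


class TestSpecValidation:
    def test_inclusion_must_be_inside_domain(self):
        with pytest.raises(GeometryError):
            PhantomSpec(inclusion_center_mm=(20.0, 36.0), inclusion_diameter_mm=10.0)

    @pytest.mark.parametrize("nu", [0.0, 0.5, 0.6])
    def test_poisson_ratio_bounds(self, nu):
        with pytest.raises(ValueError):
            PhantomSpec(poisson_ratio=nu)

    def test_slip_requires_friction(self):
        with pytest.raises(ValueError):
            PhantomSpec(interface="slip")

    def test_compression_must_be_positive(self):
        with pytest.raises(ValueError):
            PhantomSpec(applied_compression=0.0)


class TestBuildMesh:
    def test_bonded_mesh_has_two_materials_and_no_interface_pairs(self):
        mesh = build_mesh(PhantomSpec(modulus_ratio=4.0, mesh_resolution_mm=0.5))
        assert set(np.unique(mesh.material_id)) == {0, 1}
        assert mesh.interface_node_pairs.shape[0] == 0

    def test_inclusion_tagging_by_centroid(self):
        spec = PhantomSpec(modulus_ratio=4.0, mesh_resolution_mm=0.5)
        mesh = build_mesh(spec)
        p = mesh.node_coordinates_mm[mesh.elements]
        cent = p.mean(axis=1)
        cy, cx = spec.inclusion_center_mm
        r = np.hypot(cent[:, 0] - cx, cent[:, 1] - cy)
        assert np.all(r[mesh.material_id == 1] < spec.inclusion_diameter_mm / 2)
        assert np.all(r[mesh.material_id == 0] >= spec.inclusion_diameter_mm / 2)

    def test_case2_sub_inclusions_are_five_disjoint_regions(self):
        subs = random_sub_inclusions((20.0, 20.0), 10.0, seed=4)
        spec = PhantomSpec(modulus_ratio=5.0, sub_inclusions=subs, mesh_resolution_mm=0.25)
        mesh = build_mesh(spec)
        sub_ids = set(np.unique(mesh.material_id)) - {0, 1}
        assert sub_ids == {2, 3, 4, 5, 6}
        # each sub-inclusion is a separate connected tag with >= some elements
        for sid in sub_ids:
            assert np.count_nonzero(mesh.material_id == sid) >= 10

    def test_sub_inclusion_separation_constraints(self):
        subs = random_sub_inclusions((20.0, 20.0), 10.0, seed=0)
        centers = np.array([c for c, _d, _r in subs])
        d = 1.5
        for i in range(len(centers)):
            assert np.hypot(*(centers[i] - np.array([20.0, 20.0]))) <= 5.0 - d / 2 - 1.0 + 1e-9
            for j in range(i + 1, len(centers)):
                assert np.linalg.norm(centers[i] - centers[j]) >= d + 1.0 - 1e-9

    def test_resolution_error_for_coarse_mesh_under_sub_inclusions(self):
        subs = [((20.0, 20.0), 1.5, 2.0)]
        spec = PhantomSpec(modulus_ratio=5.0, sub_inclusions=subs, mesh_resolution_mm=1.0)
        with pytest.raises(ResolutionError):
            build_mesh(spec)

    def test_slip_mesh_duplicates_interface_nodes(self):
        spec = PhantomSpec(
            modulus_ratio=4.0, interface="slip", friction_coefficient=0.1,
            mesh_resolution_mm=0.5,
        )
        mesh = build_mesh(spec)
        pairs = mesh.interface_node_pairs
        assert pairs.shape[0] > 0
        # duplicated nodes coincide geometrically
        assert np.allclose(
            mesh.node_coordinates_mm[pairs[:, 0]], mesh.node_coordinates_mm[pairs[:, 1]]
        )
        # normals are unit radial vectors
        assert np.allclose(np.linalg.norm(mesh.interface_normals, axis=1), 1.0)


class TestSolve:
    def test_homogeneous_plane_strain_oracle(self):
        """Uniaxial compression with free sides: exx = nu/(1-nu) * |eyy|."""
        spec = homogeneous_spec()
        mesh = build_mesh(spec)
        sol = solve(spec, mesh)
        exx, eyy, exy = sol.element_strains.T
        expected_exx = NU / (1 - NU) * 0.01
        assert np.allclose(eyy, -0.01, atol=1e-6)
        assert np.max(np.abs(exx - expected_exx)) < 0.01 * 0.01
        assert np.max(np.abs(exy)) < 1e-10

    def test_zero_load_limit(self):
        spec = homogeneous_spec(applied_compression=1e-12)
        mesh = build_mesh(spec)
        sol = solve(spec, mesh)
        assert np.max(np.abs(sol.nodal_displacements_mm)) < 1e-10

    def test_unit_modulus_ratio_matches_homogeneous(self):
        """An inclusion with modulus ratio 1 is materially invisible."""
        spec = homogeneous_spec(mesh_resolution_mm=0.5)
        mesh = build_mesh(spec)
        sol = solve(spec, mesh)
        assert np.allclose(sol.element_strains[:, 1], -0.01, atol=1e-8)

    def test_prescribed_boundary_displacements(self):
        spec = PhantomSpec(modulus_ratio=4.0, mesh_resolution_mm=0.5)
        mesh = build_mesh(spec)
        sol = solve(spec, mesh)
        y = mesh.node_coordinates_mm[:, 1]
        top = np.isclose(y, 0.0)
        bottom = np.isclose(y, spec.domain_height_mm)
        assert np.allclose(sol.nodal_displacements_mm[top, 1], 0.01 * 40.0)
        assert np.allclose(sol.nodal_displacements_mm[bottom, 1], 0.0)

    def test_mirror_symmetry_about_vertical_centerline(self, case1_coarse):
        spec, mesh, sol = case1_coarse
        fld = sample_displacement(sol, mesh, 0.5)
        u = fld.u_axial
        v = fld.v_lateral
        # axial displacement mirror-even, lateral mirror-odd
        assert np.allclose(u, u[:, ::-1], atol=1e-8)
        assert np.allclose(v, -v[:, ::-1], atol=1e-8)

    def test_refinement_convergence_of_inclusion_core_strain(self):
        """Halving the mesh size changes the inclusion-core strain by < 2%.

        Guards against volumetric locking at nu = 0.495, which would make
        coarse-mesh strains grossly stiff.
        """
        means = []
        for h in (0.5, 0.25):
            spec = PhantomSpec(modulus_ratio=4.0, mesh_resolution_mm=h)
            mesh = build_mesh(spec)
            sol = solve(spec, mesh)
            p = mesh.node_coordinates_mm[mesh.elements].mean(axis=1)
            core = np.hypot(p[:, 0] - 20.0, p[:, 1] - 20.0) < 3.0
            means.append(sol.element_strains[core, 1].mean())
        assert abs(means[1] - means[0]) / abs(means[1]) < 0.02

    def test_inclusion_strain_decreases_with_modulus_ratio(self):
        prev = None
        for ratio in (2.0, 4.0, 8.0):
            spec = PhantomSpec(modulus_ratio=ratio, mesh_resolution_mm=0.5)
            mesh = build_mesh(spec)
            sol = solve(spec, mesh)
            inc = mesh.material_id == 1
            mean_abs = abs(sol.element_strains[inc, 1].mean())
            if prev is not None:
                assert mean_abs < prev
            prev = mean_abs

    def test_slip_inclusion_carries_less_strain_than_bonded(self):
        vals = {}
        for iface, f in (("bonded", None), ("slip", 0.1)):
            spec = PhantomSpec(
                modulus_ratio=4.0, interface=iface, friction_coefficient=f,
                mesh_resolution_mm=0.5,
            )
            mesh = build_mesh(spec)
            sol = solve(spec, mesh)
            inc = mesh.material_id == 1
            vals[iface] = abs(sol.element_strains[inc, 1].mean())
        assert vals["slip"] < vals["bonded"]

    def test_high_friction_approaches_bonded(self):
        spec_b = PhantomSpec(modulus_ratio=4.0, mesh_resolution_mm=0.5)
        sol_b = solve(spec_b, build_mesh(spec_b))
        spec_s = PhantomSpec(
            modulus_ratio=4.0, interface="slip", friction_coefficient=1000.0,
            mesh_resolution_mm=0.5,
        )
        mesh_s = build_mesh(spec_s)
        sol_s = solve(spec_s, mesh_s)
        inc_b = build_mesh(spec_b).material_id == 1
        inc_s = mesh_s.material_id == 1
        mb = sol_b.element_strains[inc_b, 1].mean()
        ms = sol_s.element_strains[inc_s, 1].mean()
        assert abs(ms - mb) / abs(mb) < 0.02


class TestSampleDisplacement:
    def test_reproduces_nodal_values(self, case1_coarse):
        spec, mesh, sol = case1_coarse
        fld = sample_displacement(sol, mesh, 0.5)  # grid falls on nodes
        # node (j, i) of the structured grid maps to pixel (j, i)
        nn = (mesh.ny + 1) * (mesh.nx + 1)
        grid_u = sol.nodal_displacements_mm[:nn, 1].reshape(mesh.ny + 1, mesh.nx + 1)
        interior = np.s_[1:-1, 1:-1]
        assert np.allclose(fld.u_axial[interior], grid_u[interior], atol=1e-10)

    def test_homogeneous_axial_profile_linear_in_depth(self):
        spec = homogeneous_spec()
        mesh = build_mesh(spec)
        sol = solve(spec, mesh)
        fld = sample_displacement(sol, mesh, 0.2)
        ys = fld.axial_coords_mm()
        col = fld.u_axial[:, fld.shape[1] // 2]
        slope = np.polyfit(ys, col, 1)[0]
        assert abs(slope - (-0.01)) < 1e-6

    def test_outside_grid_points_masked_not_extrapolated(self, case1_coarse):
        spec, mesh, sol = case1_coarse
        fld = sample_displacement(sol, mesh, 1.0, origin_mm=(-2.0, -2.0), shape=(45, 45))
        assert not fld.valid_mask[0, :].any()  # row above the domain
        assert not fld.valid_mask[:, 0].any()  # column left of the domain
        assert fld.valid_mask[5:40, 5:40].all()
        assert np.all(fld.u_axial[~fld.valid_mask] == 0.0)
        assert fld.state == "ground_truth"
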