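"""SPFD solver: assembly structure, closed-form oracle, conservation."""

import numpy as np
import pytest

from conftest import uniform_bz_vector_potential
from pemfdose import phantom as ph
from pemfdose import solver as sv
from pemfdose.errors import ConfigurationError
from pemfdose.tissues import TissueProperties


def _sphere_phantom(radius_mm, voxel_mm, sigma=0.1, eps_r=0.0):
    props = TissueProperties("conductor", np.array([50.0, 7500.0]),
                             np.array([sigma, sigma]),
                             np.array([eps_r, eps_r]))
    return ph.build_layered_head(radius_mm=radius_mm, layers=(),
                                 core="conductor", voxel_size_mm=voxel_mm,
                                 tissue_table={7: props}, name="sphere")


def sphere_eddy_current_error(phantom, frequency=1000.0, B0=1e-3,
                              sigma=0.1, config=None, margin_mm=4.0):
    """Relative |J| error vs. the closed-form eddy-current profile.

    A homogeneous sphere in a uniform axial B has the exact quasistatic
    solution J_phi = sigma * pi * f * B * rho (rho = cylindrical
    radius); the comparison excludes a fixed surface layer
    (``margin_mm``, where the voxel staircase dominates) and voxels
    with |J| below 20% of the maximum, where the 1/rho normalization
    blows up.  Returns (max_rel_error, rms_rel_error, solution).
    """
    a_field = uniform_bz_vector_potential(B0, center_mm=(13.0, -7.0, 5.0))
    system = sv.assemble_spfd(phantom, a_field, frequency,
                              include_displacement=False)
    phi, stats = sv.solve(system, config)
    sol = sv.fields_from_potential(phi, system, stats)
    mags = np.linalg.norm(sol.J_volume, axis=-1)
    conducting = phantom.conducting_mask()
    idx = np.argwhere(conducting)
    world = phantom.voxel_to_world(idx)
    rho = np.sqrt(world[:, 0] ** 2 + world[:, 1] ** 2) * 1e-3
    radius_mm = np.linalg.norm(world, axis=1)
    oracle = sigma * np.pi * frequency * B0 * rho
    got = np.abs(mags[idx[:, 0], idx[:, 1], idx[:, 2]])
    interior = radius_mm <= radius_mm.max() - margin_mm
    strong = oracle > 0.2 * oracle.max()
    sel = interior & strong
    rel = np.abs(got[sel] - oracle[sel]) / oracle[sel]
    return float(np.max(rel)), float(np.sqrt(np.mean(rel ** 2))), sol


class TestAssembly:
    def test_interior_row_sums_vanish(self, uniform_sphere_phantom):
        a_field = uniform_bz_vector_potential(1e-3)
        system = sv.assemble_spfd(uniform_sphere_phantom, a_field, 1000.0,
                                  include_displacement=False)
        row_sums = np.asarray(system.matrix.sum(axis=1)).ravel()
        assert np.max(np.abs(row_sums)) < 1e-12 * np.abs(
            system.matrix.diagonal()).max()

    def test_conductivity_scaling_leaves_potential_invariant(self):
        p1 = _sphere_phantom(25.0, 2.5, sigma=0.1)
        p2 = _sphere_phantom(25.0, 2.5, sigma=0.2)
        a_field = uniform_bz_vector_potential(1e-3, center_mm=(5.0, 3.0, 0.0))
        s1 = sv.assemble_spfd(p1, a_field, 1000.0, include_displacement=False)
        s2 = sv.assemble_spfd(p2, a_field, 1000.0, include_displacement=False)
        phi1, _ = sv.solve(s1)
        phi2, _ = sv.solve(s2)
        scale = np.max(np.abs(phi1))
        np.testing.assert_allclose(phi1 / scale, phi2 / scale, atol=1e-7)
        J1 = sv.fields_from_potential(phi1, s1).J_volume
        J2 = sv.fields_from_potential(phi2, s2).J_volume
        np.testing.assert_allclose(2.0 * J1, J2, atol=1e-8 * np.abs(J2).max())

    def test_zero_frequency_gives_zero_rhs_and_fields(self):
        p = _sphere_phantom(25.0, 2.5)
        a_field = uniform_bz_vector_potential(1e-3)
        system = sv.assemble_spfd(p, a_field, 0.0)
        assert np.all(system.rhs == 0)
        phi, stats = sv.solve(system)
        assert stats.iterations == 0
        sol = sv.fields_from_potential(phi, system, stats)
        assert np.all(sol.J_volume == 0)

    def test_no_conductor_rejected(self):
        props = TissueProperties("vacuum", np.array([50.0, 7500.0]),
                                 np.array([0.0, 0.0]), np.array([0.0, 0.0]))
        p = ph.build_layered_head(radius_mm=25.0, layers=(), core="vacuum",
                                  voxel_size_mm=2.5, tissue_table={7: props})
        with pytest.raises(ConfigurationError):
            sv.assemble_spfd(p, uniform_bz_vector_potential(1e-3), 1000.0)


class TestSphereOracle:
    def test_eddy_currents_match_closed_form(self, uniform_sphere_phantom):
        err, _, sol = sphere_eddy_current_error(uniform_sphere_phantom)
        assert err <= 0.05
        assert sol.solver_stats.final_residual <= 1e-9

    def test_grid_convergence_monotone(self):
        errors = []
        for voxel in (4.0, 2.0, 1.0):
            p = _sphere_phantom(25.0, voxel)
            _, rms, _ = sphere_eddy_current_error(p, margin_mm=5.0)
            errors.append(rms)
        assert errors[0] > errors[1] > errors[2]

    def test_air_carries_no_current(self, uniform_sphere_phantom):
        _, _, sol = sphere_eddy_current_error(uniform_sphere_phantom)
        air = ~uniform_sphere_phantom.conducting_mask()
        assert np.all(sol.J_volume[air] == 0)

    def test_current_reversal_negates_fields(self):
        p = _sphere_phantom(25.0, 2.5)
        a_field = uniform_bz_vector_potential(1e-3, center_mm=(5.0, 0.0, 0.0))
        s_pos = sv.assemble_spfd(p, a_field, 1000.0,
                                 include_displacement=False, current=1.0)
        s_neg = sv.assemble_spfd(p, a_field, 1000.0,
                                 include_displacement=False, current=-1.0)
        phi_p, _ = sv.solve(s_pos)
        phi_n, _ = sv.solve(s_neg)
        Jp = sv.fields_from_potential(phi_p, s_pos).J_volume
        Jn = sv.fields_from_potential(phi_n, s_neg).J_volume
        np.testing.assert_allclose(Jn, -Jp, atol=1e-9 * np.abs(Jp).max())


class TestConservationAndSolve:
    def test_divergence_residual_below_tolerance(self, uniform_sphere_phantom):
        _, _, sol = sphere_eddy_current_error(uniform_sphere_phantom)
        assert sol.divergence_ratio <= 1e-8

    def test_node_current_balance_brute_force(self):
        # Independent check: recompute the net current into every node
        # from edge conductances and potentials, without the matrix.
        p = _sphere_phantom(15.0, 2.5)
        a_field = uniform_bz_vector_potential(1e-3, center_mm=(4.0, 2.0, 1.0))
        system = sv.assemble_spfd(p, a_field, 1000.0,
                                  include_displacement=False)
        phi, _ = sv.solve(system)
        omega = system.omega
        h = system.h_m
        net = np.zeros(system.node_shape, dtype=complex)
        sigma = system.sigma_star
        for axis in range(3):
            s = sv._edge_conductance(sigma, axis, h)
            edge_idx = np.argwhere(s != 0)
            s_e = s[tuple(edge_idx.T)]
            mid = sv._edge_midpoints_voxel_coords(edge_idx, axis)
            a_e = np.asarray(a_field(p.voxel_to_world(mid)))[:, axis]
            n1 = tuple(edge_idx.T)
            step = edge_idx.copy()
            step[:, axis] += 1
            n2 = tuple(step.T)
            # Current flowing from n1 to n2 along the edge:
            # I = s * integral(E . dl) = s * (phi1 - phi2 - j w A h).
            current = s_e * (phi[n1] - phi[n2] - 1j * omega * a_e * h)
            np.add.at(net, n1, current)
            np.add.at(net, n2, -current)
        J = sv.fields_from_potential(phi, system).J_volume
        scale = np.abs(J).max() * h ** 2
        assert np.max(np.abs(net)) <= 1e-8 * scale

    def test_zero_rhs_solves_immediately(self):
        p = _sphere_phantom(15.0, 2.5)
        system = sv.assemble_spfd(p, uniform_bz_vector_potential(0.0), 1000.0,
                                  include_displacement=False)
        phi, stats = sv.solve(system)
        assert stats.iterations == 0
        assert np.all(phi == 0)

    def test_tighter_tolerance_never_worse(self):
        p = _sphere_phantom(20.0, 2.5)
        a_field = uniform_bz_vector_potential(1e-3, center_mm=(5.0, 0.0, 0.0))
        system = sv.assemble_spfd(p, a_field, 1000.0,
                                  include_displacement=False)
        residuals = []
        for tol in (1e-6, 1e-9, 1e-12):
            _, stats = sv.solve(system, sv.SolverConfig(tolerance=tol))
            residuals.append(stats.final_residual)
        assert residuals[0] >= residuals[1] >= residuals[2]


class TestSolveBand:
    def test_one_solution_per_frequency(self):
        p = _sphere_phantom(15.0, 2.5)
        a_field = uniform_bz_vector_potential(1e-3)
        freqs = np.array([75.0, 150.0, 225.0])
        sols = sv.solve_band(p, a_field, freqs, include_displacement=False)
        assert [s.frequency for s in sols] == list(freqs)

    def test_empty_band_rejected(self):
        p = _sphere_phantom(15.0, 2.5)
        with pytest.raises(ConfigurationError):
            sv.solve_band(p, uniform_bz_vector_potential(1e-3), [])

    def test_fast_mode_matches_full_on_nondispersive_phantom(self):
        p = _sphere_phantom(20.0, 2.5)
        a_field = uniform_bz_vector_potential(1e-3, center_mm=(6.0, -2.0, 0.0))
        freqs = np.array([500.0, 1000.0, 2000.0])
        full = sv.solve_band(p, a_field, freqs, include_displacement=False)
        fast = sv.solve_band(p, a_field, freqs, include_displacement=False,
                             fast_mode=True)
        for a, b in zip(full, fast):
            denom = np.abs(a.J_volume).max()
            assert np.max(np.abs(a.J_volume - b.J_volume)) / denom <= 1e-6

    def test_fast_mode_refused_for_dispersive_phantom(self, small_head):
        with pytest.raises(ConfigurationError):
            sv.solve_band(small_head, uniform_bz_vector_potential(1e-3),
                          [500.0, 1000.0], include_displacement=False,
                          fast_mode=True)

    def test_displacement_currents_are_small_correction(self):
        # Permittivity adds a modest out-of-phase term at these
        # frequencies: keeping sigma* complex changes |J| by < 10%.
        p_real = _sphere_phantom(20.0, 2.5, sigma=0.1, eps_r=0.0)
        p_disp = _sphere_phantom(20.0, 2.5, sigma=0.1, eps_r=1e5)
        a_field = uniform_bz_vector_potential(1e-3, center_mm=(5.0, 0.0, 0.0))
        sols = {}
        for name, p, disp in [("real", p_real, False), ("disp", p_disp, True)]:
            system = sv.assemble_spfd(p, a_field, 1000.0,
                                      include_displacement=disp)
            phi, _ = sv.solve(system)
            sols[name] = sv.fields_from_potential(phi, system).J_volume
        denom = np.abs(sols["real"]).max()
        rel = np.max(np.abs(np.abs(sols["disp"]) - np.abs(sols["real"]))) / denom
        assert 0 < rel < 0.10
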