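import math

import numpy as np
import pytest

from membpka.constants import PhysicalConstants
from membpka.environment_model import MembraneGeometry
from membpka.pb_solver import (
    GridSpec,
    build_dielectric_map,
    build_grid,
    build_screening_map,
    coulomb_energy,
    electrostatic_free_energy,
    focused_solve,
    linearization_error_report,
    solve_linearized_pb,
    spread_charges,
)
from membpka.structure_io import StructureFrame
from conftest import make_atom

ORIGIN = np.zeros((1, 3))
UNIT = np.array([1.0])


def solve_uniform(const, spacing=0.5, padding=14.0, eps=80.0, charge=1.0,
                  screened=True):
    frame = StructureFrame([make_atom("Q", radius=0.0)])
    grid = build_grid(frame, spacing, padding)
    diel = build_dielectric_map(frame, grid, None, {"solvent": eps})
    kap = build_screening_map(diel, const)
    if not screened:
        kap.kappa_sq[:] = 0.0
    return solve_linearized_pb(ORIGIN, [charge], diel, kap, const)


class TestGrid:
    def test_single_atom_dims(self):
        frame = StructureFrame([make_atom("Q", radius=0.0)])
        grid = build_grid(frame, 0.5, 10.0)
        assert grid.dims == (41, 41, 41)

    def test_two_pass_default_spacings_supported(self):
        frame = StructureFrame([make_atom("Q", radius=0.0)])
        for spacing in (1.5, 0.5):
            g = build_grid(frame, spacing, 10.0)
            assert g.spacing == spacing

    def test_doubling_padding_grows_dims(self):
        frame = StructureFrame([make_atom("Q", radius=0.0)])
        g1 = build_grid(frame, 0.5, 10.0)
        g2 = build_grid(frame, 0.5, 20.0)
        assert g2.dims == tuple(d + 40 for d in g1.dims)


class TestDielectricMap:
    def test_region_values(self):
        atoms = [make_atom("CA2", "C", "PRO", 1, "A", pos=(0, 0, 30.0), radius=2.0)]
        frame = StructureFrame(atoms)
        grid = GridSpec(origin=np.array([-10.0, -10.0, -10.0]), spacing=1.0,
                        dims=(21, 21, 51))
        membrane = MembraneGeometry(midplane_z=0.0, core_half_thickness=17.0,
                                    total_thickness=38.0)
        diel = build_dielectric_map(frame, grid, membrane)
        # far solvent voxel (above membrane and away from protein)
        assert diel.epsilon[0, 0, -1] == 80.0
        # membrane midplane, outside protein
        iz0 = 10  # z = 0
        assert diel.epsilon[0, 0, iz0] == 4.0
        # headgroup shell at z = 18
        iz_hg = 28
        assert diel.epsilon[0, 0, iz_hg] == 8.0
        # protein voxel at atom center (z = 30 -> index 40)
        assert diel.epsilon[10, 10, 40] == 8.0

    def test_zero_radius_atoms_make_no_protein_voxels(self):
        frame = StructureFrame([make_atom("Q", radius=0.0)])
        grid = build_grid(frame, 1.0, 5.0)
        diel = build_dielectric_map(frame, grid, None)
        assert (diel.epsilon == 80.0).all()


class TestLinearizedSolve:
    def test_zero_charge_gives_zero_potential(self, const_ambient):
        frame = StructureFrame([make_atom("Q", radius=0.0)])
        grid = build_grid(frame, 1.0, 8.0)
        diel = build_dielectric_map(frame, grid, None)
        kap = build_screening_map(diel, const_ambient)
        phi = solve_linearized_pb(np.zeros((0, 3)), [], diel, kap, const_ambient)
        assert np.allclose(phi.phi, 0.0)

    def test_matches_coulomb_within_5pct(self, const_ambient):
        phi = solve_uniform(const_ambient, screened=False)
        rs = np.arange(3.0, 10.01, 0.5)
        pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
        ana = const_ambient.coulomb_constant / (80.0 * rs)
        rel = np.abs(phi.interpolate(pts) - ana) / ana
        assert rel.max() < 0.05

    def test_matches_screened_coulomb_within_7pct(self, const_saline):
        phi = solve_uniform(const_saline)
        rs = np.arange(3.0, 10.01, 0.5)
        pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
        kappa = const_saline.debye_kappa(80.0)
        ana = const_saline.coulomb_constant * np.exp(-kappa * rs) / (80.0 * rs)
        rel = np.abs(phi.interpolate(pts) - ana) / ana
        assert rel.max() < 0.07

    def test_screening_reduces_far_potential(self, const_ambient, const_saline):
        phi0 = solve_uniform(const_ambient, spacing=1.0, screened=False)
        phi1 = solve_uniform(const_saline, spacing=1.0)
        pt = np.array([[10.0, 0.0, 0.0]])
        assert abs(phi1.interpolate(pt)[0]) < abs(phi0.interpolate(pt)[0])

    def test_linearity_in_source(self, const_ambient):
        phi1 = solve_uniform(const_ambient, spacing=1.0, charge=1.0, screened=False)
        phi3 = solve_uniform(const_ambient, spacing=1.0, charge=3.0, screened=False)
        assert np.allclose(phi3.phi, 3.0 * phi1.phi, rtol=1e-5, atol=1e-8)

    def test_mirror_symmetry(self, const_ambient):
        # charge offset along +x with a dielectric slab symmetric in x
        frame = StructureFrame([make_atom("Q", pos=(2.0, 0, 0), radius=1.5)])
        grid = GridSpec(origin=np.array([-10.0, -10.0, -10.0]), spacing=1.0,
                        dims=(21, 21, 21))
        diel = build_dielectric_map(frame, grid, None)
        kap = build_screening_map(diel, const_ambient)
        phi = solve_linearized_pb(np.array([[2.0, 0, 0]]), UNIT, diel, kap, const_ambient)

        frame_m = StructureFrame([make_atom("Q", pos=(-2.0, 0, 0), radius=1.5)])
        diel_m = build_dielectric_map(frame_m, grid, None)
        kap_m = build_screening_map(diel_m, const_ambient)
        phi_m = solve_linearized_pb(np.array([[-2.0, 0, 0]]), UNIT, diel_m, kap_m,
                                    const_ambient)
        dev = np.abs(phi.phi - phi_m.phi[::-1, :, :]).max()
        assert dev < 1e-6 * np.abs(phi.phi).max()


class TestFocusing:
    def test_equal_spacing_equals_single_solve(self, const_ambient):
        frame = StructureFrame([make_atom("Q", radius=0.0)])
        fine, coarse = focused_solve(
            ORIGIN, UNIT, frame, None, const_ambient,
            coarse_spacing=1.0, fine_spacing=1.0, padding=8.0,
            focus_center=np.zeros(3), focus_half_extent=50.0,
        )
        assert fine is coarse

    def test_focused_matches_direct_fine_solve(self, const_ambient):
        frame = StructureFrame([make_atom("Q", radius=0.0)])
        fine, _ = focused_solve(
            ORIGIN, UNIT, frame, None, const_ambient,
            coarse_spacing=1.5, fine_spacing=0.5, padding=12.0,
            focus_center=np.zeros(3), focus_half_extent=6.0,
        )
        rs = np.arange(2.0, 5.51, 0.5)
        pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
        direct = solve_uniform(const_ambient, spacing=0.5, padding=12.0, screened=True)
        rel = np.abs(fine.interpolate(pts) - direct.interpolate(pts)) / np.abs(
            direct.interpolate(pts)
        )
        assert rel.max() < 0.02


def born_energy(const, spacing, R=2.0):
    frame = StructureFrame([make_atom("Q", radius=R)])
    grid = build_grid(frame, spacing, 12.0)
    kap_zero = None
    diel_s = build_dielectric_map(frame, grid, None, {"protein": 1.0, "solvent": 80.0})
    kap = build_screening_map(diel_s, const)
    kap.kappa_sq[:] = 0.0
    phi_s = solve_linearized_pb(ORIGIN, UNIT, diel_s, kap, const)
    diel_v = build_dielectric_map(frame, grid, None, {"protein": 1.0, "solvent": 1.0})
    phi_v = solve_linearized_pb(ORIGIN, UNIT, diel_v, kap, const)
    return (electrostatic_free_energy(phi_s, ORIGIN, UNIT)
            - electrostatic_free_energy(phi_v, ORIGIN, UNIT))


class TestEnergies:
    def test_zero_charges_zero_energy(self, const_ambient):
        phi = solve_uniform(const_ambient, spacing=1.0, screened=False)
        assert electrostatic_free_energy(phi, np.zeros((0, 3)), []) == 0.0

    def test_born_ion_within_10pct(self, const_ambient):
        R = 2.0
        expected = -const_ambient.coulomb_constant / (2 * R) * (1 - 1 / 80.0)
        got = born_energy(const_ambient, 0.5, R)
        assert abs(got - expected) / abs(expected) < 0.10

    def test_born_error_decreases_with_refinement(self, const_ambient):
        R = 2.0
        expected = -const_ambient.coulomb_constant / (2 * R) * (1 - 1 / 80.0)
        errs = [abs(born_energy(const_ambient, h, R) - expected) for h in (2.0, 1.0, 0.5)]
        assert errs[0] > errs[1] > errs[2]

    def test_doubling_charges_quadruples_energy(self, const_ambient):
        phi1 = solve_uniform(const_ambient, spacing=1.0, charge=1.0, screened=False)
        phi2 = solve_uniform(const_ambient, spacing=1.0, charge=2.0, screened=False)
        e1 = electrostatic_free_energy(phi1, ORIGIN, [1.0])
        e2 = electrostatic_free_energy(phi2, ORIGIN, [2.0])
        assert e2 == pytest.approx(4.0 * e1, rel=1e-6)


class TestCoulombEnergy:
    def test_zero_valence(self):
        assert coulomb_energy(0.0, 1.0, 5.0, 78.0) == 0.0

    def test_salt_bridge_worked_value(self):
        # opposite unit charges at 5 Å in eps_r = 78
        e = coulomb_energy(-1.0, 1.0, 5.0, 78.0)
        assert e == pytest.approx(-0.852, abs=0.002)

    def test_halving_distance_doubles_magnitude(self):
        e5 = coulomb_energy(1.0, 1.0, 5.0, 78.0)
        e25 = coulomb_energy(1.0, 1.0, 2.5, 78.0)
        assert e25 == pytest.approx(2.0 * e5)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            coulomb_energy(1.0, 1.0, 0.0, 78.0)


class TestLinearizationReport:
    def test_worked_salt_bridge_example(self):
        rep = linearization_error_report(-0.852, 0.593, max_order=3)
        assert rep.exact == pytest.approx(4.207, abs=0.002)
        approx = rep.table["approximation"].to_numpy()
        assert approx[0] == pytest.approx(2.437, abs=0.002)
        assert approx[1] == pytest.approx(3.469, abs=0.002)
        assert approx[2] == pytest.approx(3.964, abs=0.002)
        rel = rep.table["relative_error"].to_numpy() * 100
        assert round(rel[0]) == 42 and round(rel[1]) == 18 and round(rel[2]) == 6
        assert rep.table["pka_error"].iloc[0] == pytest.approx(0.24, abs=0.005)

    def test_zero_energy_degenerate(self):
        rep = linearization_error_report(0.0, 0.593, max_order=4)
        assert rep.exact == 1.0
        assert np.allclose(rep.table["approximation"], 1.0)
        assert np.allclose(rep.table["relative_error"], 0.0)
        assert np.allclose(rep.table["pka_error"], 0.0)

    def test_series_converges_to_exponential(self):
        rep = linearization_error_report(-0.852, 0.593, max_order=10)
        assert abs(rep.table["approximation"].iloc[-1] - rep.exact) / rep.exact < 1e-6


class TestSpreadCharges:
    def test_on_node_charge_is_exact(self):
        grid = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(5, 5, 5))
        rho = spread_charges(grid, np.array([[2.0, 2.0, 2.0]]), [1.5])
        assert rho[2, 2, 2] == pytest.approx(1.5)
        assert rho.sum() == pytest.approx(1.5)

    def test_total_charge_conserved_off_node(self):
        grid = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(5, 5, 5))
        rho = spread_charges(grid, np.array([[1.3, 2.7, 0.2]]), [-2.0])
        assert rho.sum() == pytest.approx(-2.0)

    def test_outside_grid_rejected(self):
        grid = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(5, 5, 5))
        with pytest.raises(ValueError):
            spread_charges(grid, np.array([[10.0, 0.0, 0.0]]), [1.0])
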