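"""Finite-difference PB solver against closed-form electrostatics."""

import warnings

import numpy as np
import pytest

from oligovar.electrostatics import (
    isopotential_surfaces,
    map_to_surface,
    potential_at,
    solvation_energy,
    solve_potential,
    write_dx,
    write_ply,
)
from oligovar.forcefield import COULOMB_CONSTANT, KT_298_KCAL
from oligovar.synthetic import make_point_charge_cluster

POINT = [[0.0, 0.0, 0.0]]


@pytest.fixture(scope="module")
def plus_one():
    asm, _ = make_point_charge_cluster([1.0], POINT)
    return asm


def test_uniform_dielectric_matches_screened_coulomb(plus_one):
    g = solve_potential(plus_one, spacing=0.8, extension=16.0, radii=[1.5],
                        uniform_dielectric=80.0)
    for r in (8.0, 10.0, 15.0):
        pts = np.array([[r, 0, 0], [0, -r, 0], [0, 0, r]])
        expected = COULOMB_CONSTANT / (80.0 * r) / KT_298_KCAL
        got = potential_at(g, pts).mean()
        assert got == pytest.approx(expected, rel=0.02)


def test_zero_charges_give_zero_potential():
    asm, _ = make_point_charge_cluster([0.0, 0.0], [[0, 0, 0], [4, 0, 0]])
    g = solve_potential(asm, spacing=0.8, extension=6.0, radii=[1.5, 1.5])
    assert np.all(g.values == 0.0)


def test_born_ion_solvation_energy(plus_one):
    """Reaction-field energy of a 2 A / +1 e ion vs the Born closed form."""
    E = solvation_energy(plus_one, spacing=0.3, extension=6.0, radii=[2.0])
    born = -COULOMB_CONSTANT / 2.0 * (1.0 - 1.0 / 80.0) / 2.0
    assert E == pytest.approx(born, rel=0.05)


def test_solver_linearity():
    """Potential of q1+q2 equals the sum of the single-charge solutions."""
    pos = [[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]]
    asm, _ = make_point_charge_cluster([1.0, -0.5], pos)
    kw = dict(spacing=0.6, extension=6.0, radii=[1.6, 1.6])
    g_both = solve_potential(asm, **kw)
    g_1 = solve_potential(asm, charges=[1.0, 0.0], **kw)
    g_2 = solve_potential(asm, charges=[0.0, -0.5], **kw)
    assert np.allclose(g_both.values, g_1.values + g_2.values, atol=1e-6)


def test_antisymmetry_under_charge_negation(plus_one):
    minus, _ = make_point_charge_cluster([-1.0], POINT)
    kw = dict(spacing=0.8, extension=8.0, radii=[1.5])
    ga = solve_potential(plus_one, **kw)
    gb = solve_potential(minus, **kw)
    assert np.allclose(ga.values, -gb.values, atol=0.0)


def test_grid_refinement_convergence(plus_one):
    """Halving the spacing changes the far-field potential by < 5%."""
    pts = np.array([[6.0, 0, 0], [0, 6.0, 0], [0, 0, -6.0]])
    vals = []
    for h in (0.8, 0.4):
        g = solve_potential(plus_one, spacing=h, extension=8.0, radii=[1.5],
                            uniform_dielectric=80.0)
        vals.append(potential_at(g, pts).mean())
    assert abs(vals[1] - vals[0]) / abs(vals[1]) < 0.05


class TestIsopotential:
    def test_point_charge_isosurface_is_spherical(self, plus_one):
        # +1 e in uniform dielectric 10: 10 kT/e falls at r = k/(10*10*kT)
        g = solve_potential(plus_one, spacing=0.4, extension=10.0, radii=[1.5],
                            uniform_dielectric=10.0)
        mesh = isopotential_surfaces(g, levels=(10.0,))[10.0]
        r = np.linalg.norm(mesh.vertices, axis=1)
        r_expected = COULOMB_CONSTANT / (10.0 * 10.0 * KT_298_KCAL)
        assert r.min() / r.max() > 0.95
        assert np.median(r) == pytest.approx(r_expected, rel=0.05)

    def test_negative_system_has_no_positive_isosurface(self):
        minus, _ = make_point_charge_cluster([-1.0], POINT)
        g = solve_potential(minus, spacing=0.8, extension=8.0, radii=[1.5])
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            mesh = isopotential_surfaces(g, levels=(10.0,))[10.0]
        assert len(mesh.vertices) == 0
        assert any("outside" in str(w.message) for w in rec)

    def test_dipole_nodal_plane(self):
        asm, _ = make_point_charge_cluster([1.0, -1.0],
                                           [[-3.0, 0, 0], [3.0, 0, 0]])
        g = solve_potential(asm, spacing=0.5, extension=8.0, radii=[1.5, 1.5],
                            uniform_dielectric=20.0)
        mesh = isopotential_surfaces(g, levels=(0.0,))[0.0]
        # the 0 kT/e surface is the plane bisecting the charges (x = 0)
        assert len(mesh.vertices) > 0
        assert np.max(np.abs(mesh.vertices[:, 0])) < g.spacing


class TestSurfaceMap:
    def test_sphere_ses_area(self, plus_one):
        g = solve_potential(plus_one, spacing=0.8, extension=6.0, radii=[2.0])
        mesh = map_to_surface(g, plus_one, radii=[2.0], mesh_spacing=0.25)
        assert mesh.area() == pytest.approx(4 * np.pi * 2.0 ** 2, rel=0.05)

    def test_mesh_is_closed(self, plus_one):
        g = solve_potential(plus_one, spacing=0.8, extension=6.0, radii=[2.0])
        mesh = map_to_surface(g, plus_one, radii=[2.0], mesh_spacing=0.4)
        edges: dict[tuple[int, int], int] = {}
        for f in mesh.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                e = (min(a, b), max(a, b))
                edges[e] = edges.get(e, 0) + 1
        assert set(edges.values()) == {2}

    def test_positive_solute_has_positive_surface_potential(self, plus_one):
        g = solve_potential(plus_one, spacing=0.5, extension=6.0, radii=[2.0])
        mesh = map_to_surface(g, plus_one, radii=[2.0], mesh_spacing=0.4)
        assert np.all(mesh.vertex_potential > 0)
        assert mesh.scale_bounds == (-0.3, 0.3)
        assert np.all(np.abs(mesh.clamped()) <= 0.3)


def test_artifact_export_round_trip(plus_one, tmp_path):
    g = solve_potential(plus_one, spacing=0.8, extension=6.0, radii=[1.5])
    dx = tmp_path / "g.dx"
    write_dx(g, dx)
    text = dx.read_text()
    assert "gridpositions counts" in text and "%d %d %d" % g.dims in text
    mesh = map_to_surface(g, plus_one, radii=[1.5], mesh_spacing=0.5)
    ply = tmp_path / "m.ply"
    write_ply(mesh, ply)
    head = ply.read_text().splitlines()
    assert head[0] == "ply" and f"element vertex {len(mesh.vertices)}" in head
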