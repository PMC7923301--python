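"""PDB round-trips, biological-unit reconstruction and rigid superposition."""

import io

import numpy as np
import pytest

from oligovar.geometry import rotation_about_axis
from oligovar.structure import (
    Assembly,
    AssemblyArityError,
    ClashError,
    EmptyStructureError,
    PdbParseError,
    SymmetryOperator,
    build_biological_unit,
    build_head_to_head,
    read_structure,
    superpose,
    write_structure,
)
from oligovar.synthetic import FixtureSpec, make_c3_trimer, make_head_to_head_template


def test_pdb_round_trip_preserves_everything(c3_trimer, tmp_path):
    trimer, _ = c3_trimer
    p1 = tmp_path / "a.pdb"
    write_structure(trimer, p1)
    again, _ops = read_structure(p1)
    assert again.n_atoms == trimer.n_atoms
    a1 = list(trimer.atoms())
    a2 = list(again.atoms())
    for x, y in zip(a1, a2):
        assert x.name == y.name
        assert x.residue_name == y.residue_name
        assert x.residue_number == y.residue_number
        assert np.allclose(x.coordinates, y.coordinates, atol=1.1e-3)
    # second round trip is exact (coordinates already quantized to 3 decimals)
    p2 = tmp_path / "b.pdb"
    write_structure(again, p2)
    third, _ = read_structure(p2)
    assert np.allclose(
        np.concatenate([p.coords() for p in again.protomers]),
        np.concatenate([p.coords() for p in third.protomers]), atol=1e-9)


def test_biomt_operators_round_trip(c3_trimer, tmp_path):
    trimer, meta = c3_trimer
    path = tmp_path / "ops.pdb"
    write_structure(trimer, path, operators=meta["operators"])
    _asm, ops = read_structure(path)
    assert len(ops) == 3
    assert ops[0].is_identity()
    for op, ref in zip(ops, meta["operators"]):
        assert np.allclose(op.rotation, ref.rotation, atol=1e-5)
        assert np.allclose(op.translation, ref.translation, atol=1e-4)


def test_malformed_coordinate_line_names_line_number(tmp_path):
    bad = tmp_path / "bad.pdb"
    bad.write_text(
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.0xx  -5.147  1.00  0.00           C\n")
    with pytest.raises(PdbParseError, match="line 2"):
        read_structure(bad)


def test_waters_only_is_an_empty_structure(tmp_path):
    p = tmp_path / "w.pdb"
    p.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n")
    with pytest.raises(EmptyStructureError):
        read_structure(p)


def test_symmetry_operator_validation():
    with pytest.raises(ValueError):
        SymmetryOperator(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # improper
    with pytest.raises(ValueError):
        SymmetryOperator(2 * np.eye(3), np.zeros(3))  # not orthonormal


class TestBiologicalUnit:
    def test_wrong_operator_count_is_an_arity_error(self, c3_trimer):
        trimer, _ = c3_trimer
        asym = Assembly([trimer.protomers[0].copy()])
        with pytest.raises(AssemblyArityError):
            build_biological_unit(asym, [SymmetryOperator.identity()])

    def test_c3_reconstruction_centers_on_the_axis(self, c3_trimer, fixture_spec):
        trimer, meta = c3_trimer
        centroids = np.array([p.coords().mean(axis=0) for p in trimer.protomers])
        center = centroids.mean(axis=0)
        assert abs(center[0]) < 1e-6 and abs(center[1]) < 1e-6
        assert trimer.kind == "trimer"
        assert [p.chain_id for p in trimer.protomers] == ["A", "B", "C"]

    def test_copies_are_exact_symmetry_images(self, c3_trimer):
        trimer, _ = c3_trimer
        _op, r01 = superpose(trimer.protomers[0], trimer.protomers[1])
        _op, r02 = superpose(trimer.protomers[0], trimer.protomers[2])
        assert r01 < 1e-3 and r02 < 1e-3

    def test_internal_geometry_identical_across_copies(self, c3_trimer):
        trimer, _ = c3_trimer
        rng = np.random.default_rng(0)
        n = len(trimer.protomers[0].atoms)
        pairs = rng.integers(0, n, size=(50, 2))
        dists = []
        for p in trimer.protomers:
            xyz = p.coords()
            dists.append(np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1))
        assert np.allclose(dists[0], dists[1], atol=1e-6)
        assert np.allclose(dists[0], dists[2], atol=1e-6)

    def test_operator_set_is_idempotent(self, c3_trimer):
        trimer, meta = c3_trimer
        asym = Assembly([trimer.protomers[0].copy()])
        again = build_biological_unit(asym, meta["operators"])
        for p, q in zip(trimer.protomers, again.protomers):
            assert np.allclose(p.coords(), q.coords(), atol=1e-9)


class TestSuperpose:
    def test_self_superposition_is_identity(self, c3_trimer):
        trimer, _ = c3_trimer
        op, r = superpose(trimer.protomers[0], trimer.protomers[0])
        assert r < 1e-9
        assert np.allclose(op.rotation, np.eye(3), atol=1e-9)

    def test_translation_recovery(self, c3_trimer):
        trimer, _ = c3_trimer
        mob = trimer.protomers[0].transformed(np.eye(3), np.array([1.0, 2.0, 3.0]))
        op, r = superpose(mob, trimer.protomers[0])
        assert r < 1e-9
        assert np.allclose(op.translation, [-1.0, -2.0, -3.0], atol=1e-9)

    def test_rotation_recovery_under_noise(self, c3_trimer):
        trimer, _ = c3_trimer
        R = rotation_about_axis([1.0, 0.0, 0.0], 90.0)
        mob = trimer.protomers[0].transformed(R, np.zeros(3))
        rng = np.random.default_rng(1)
        mob.set_coords(mob.coords() + rng.normal(scale=0.1, size=mob.coords().shape))
        op, r = superpose(mob, trimer.protomers[0], atom_selection="all")
        assert 0.05 <= r <= 0.2
        # recovered rotation within 1 degree of the inverse of the planted one
        resid = op.rotation @ R
        ang = np.degrees(np.arccos(np.clip((np.trace(resid) - 1) / 2, -1, 1)))
        assert ang < 1.0

    def test_rmsd_is_symmetric_and_rotation_proper(self, c3_trimer):
        trimer, _ = c3_trimer
        a, b = trimer.protomers[0], trimer.protomers[1]
        op_ab, r_ab = superpose(a, b)
        op_ba, r_ba = superpose(b, a)
        assert abs(r_ab - r_ba) < 1e-9
        for op in (op_ab, op_ba):
            assert abs(np.linalg.det(op.rotation) - 1.0) < 1e-6

    def test_underdetermined_selection(self, c3_trimer):
        trimer, _ = c3_trimer
        with pytest.raises(ValueError, match="underdetermined"):
            superpose(trimer.protomers[0], trimer.protomers[1],
                      atom_selection=lambda a: a.name == "SG")


class TestHeadToHead:
    def test_planted_separation_recovered(self, fixture_spec):
        spec = FixtureSpec(seed=fixture_spec.seed, separation=40.0)
        trimer, _ = make_c3_trimer(spec)
        template = make_head_to_head_template(spec, reference=trimer.protomers[0])
        hexamer = build_head_to_head(trimer, template)
        assert len(hexamer.protomers) == 6
        c1 = np.mean([p.coords().mean(axis=0) for p in hexamer.protomers[:3]], axis=0)
        c2 = np.mean([p.coords().mean(axis=0) for p in hexamer.protomers[3:]], axis=0)
        assert abs(np.linalg.norm(c1 - c2) - 40.0) < 0.01
        assert hexamer.trimer_groups() == ([0, 1, 2], [3, 4, 5])

    def test_degenerate_template_clashes(self, c3_trimer):
        trimer, _ = c3_trimer
        u = trimer.protomers[0].copy()
        v = trimer.protomers[0].copy()
        v.chain_id = "B"
        template = Assembly([u, v])
        with pytest.raises(ClashError, match=":"):
            build_head_to_head(trimer, template)
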