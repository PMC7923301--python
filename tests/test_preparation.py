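"""Water pruning, pH 7.5 protonation rules and the capped minimizer."""

import numpy as np
import pytest

from oligovar.builder import build_peptide
from oligovar.energetics import EnergyModel
from oligovar.preparation import (
    assign_protonation,
    minimize_capped,
    net_formal_charge,
    prune_waters,
)
from oligovar.structure import Assembly, AtomRecord, Protomer
from oligovar.synthetic import make_water_probe


def _water(i, xyz):
    return AtomRecord(serial=900 + i, name="O", element="O", residue_name="HOH",
                      chain_id="W", residue_number=i, insertion_code="",
                      coordinates=np.array(xyz, float), is_hetero=True)


class TestWaterPruning:
    def test_water_near_protein_is_kept_isolated_and_chained_are_deleted(self):
        asm, meta = make_water_probe()
        pruned, n = prune_waters(asm, cutoff=3.5)
        survivors = {(p.chain_id, a.residue_number) for p in pruned.protomers
                     for a in p.atoms if a.is_water}
        assert survivors == set(meta["kept"])
        assert n == len(meta["pruned"])

    def test_water_chain_pruned_as_a_block(self):
        """Waters 2.8 A apart support each other but not past the 3.5 A rule."""
        pep = build_peptide(["ALA"], chain_id="A")
        base = pep.coords().mean(axis=0) + np.array([0.0, 20.0, 0.0])
        waters = [_water(i + 1, base + [2.8 * i, 0, 0]) for i in range(3)]
        asm = Assembly([pep, Protomer("W", waters)])
        _pruned, n = prune_waters(asm)
        assert n == 3

    def test_no_waters_is_a_no_op(self, c3_trimer):
        trimer, _ = c3_trimer
        pruned, n = prune_waters(trimer)
        assert n == 0 and pruned.n_atoms == trimer.n_atoms

    def test_order_independence(self):
        asm, _ = make_water_probe()
        flipped = asm.copy()
        flipped.protomers = flipped.protomers[::-1]
        for p in flipped.protomers:
            p.atoms = p.atoms[::-1]
        s1 = {(p.chain_id, a.residue_number) for p in prune_waters(asm)[0].protomers
              for a in p.atoms if a.is_water}
        s2 = {(p.chain_id, a.residue_number) for p in prune_waters(flipped)[0].protomers
              for a in p.atoms if a.is_water}
        assert s1 == s2


class TestProtonation:
    def test_glu_deprotonated_lys_arg_protonated(self):
        pep = build_peptide(["ALA", "GLU", "LYS", "ARG", "ASP", "ALA"], chain_id="A")
        asm = Assembly([pep])
        _out, rep = assign_protonation(asm, ph=7.5)
        labels = rep.protonation_assignments
        assert labels["A:2"] == "GLU(-)"
        assert labels["A:3"] == "LYS(+)"
        assert labels["A:4"] == "ARG(+)"
        assert labels["A:5"] == "ASP(-)"
        # net formal charge = (#Arg + #Lys) - (#Asp + #Glu)
        assert net_formal_charge(rep) == 2 - 2

    def test_disulfide_cysteines_get_no_thiol_hydrogen(self):
        pep1 = build_peptide(["ALA", "CYS", "ALA"], chain_id="A")
        pep2 = build_peptide(["ALA", "CYS", "ALA"], chain_id="B")
        sg1 = pep1.atom(2, "SG")
        sg2 = pep2.atom(2, "SG")
        shift = sg1.coordinates + np.array([2.05, 0.0, 0.0]) - sg2.coordinates
        pep2.set_coords(pep2.coords() + shift)
        asm = Assembly([pep1, pep2])
        out, rep = assign_protonation(asm)
        assert rep.protonation_assignments["A:2"] == "CYS(SS)"
        assert rep.protonation_assignments["B:2"] == "CYS(SS)"
        for p in out.protomers:
            assert not any(a.name == "HG" for a in p.residue(2))

    def test_free_cysteine_keeps_its_thiol(self):
        pep = build_peptide(["ALA", "CYS", "ALA"], chain_id="A")
        out, rep = assign_protonation(Assembly([pep]))
        assert rep.protonation_assignments["A:2"] == "CYS(SH)"
        assert any(a.name == "HG" for a in out.protomers[0].residue(2))

    def test_his_tautomer_donates_to_a_nearby_carbonyl(self):
        """An acceptor (carbonyl O) near Nd1 makes Nd1-H the H-bond-maximizing
        tautomer; with no neighbors the common epsilon tautomer wins the tie."""
        pep = build_peptide(["ALA", "HIS", "ALA"], chain_id="A")
        lone, rep_lone = assign_protonation(Assembly([pep.copy()]))
        assert rep_lone.protonation_assignments["A:2"] == "HIE"
        nd1 = pep.atom(2, "ND1")
        probe = Protomer("X", [AtomRecord(
            serial=500, name="O", element="O", residue_name="GLY", chain_id="X",
            residue_number=1, insertion_code="",
            coordinates=nd1.coordinates + np.array([0.0, 0.0, 2.9]))])
        out, rep = assign_protonation(Assembly([pep.copy(), probe]))
        assert rep.protonation_assignments["A:2"] == "HID"
        his = out.protomers[0].residue(2)
        assert any(a.name == "HD1" for a in his)
        assert not any(a.name == "HE2" for a in his)

    def test_hydrogen_count_is_reported(self):
        pep = build_peptide(["ALA", "ALA", "ALA"], chain_id="A")
        # strip all hydrogens, then let preparation re-add the amide ones
        pep.atoms = [a for a in pep.atoms if a.element != "H"]
        _out, rep = assign_protonation(Assembly([pep]))
        assert rep.added_hydrogens == 2  # amide H of residues 2 and 3


class TestCappedMinimization:
    def test_already_minimized_structure_is_a_fixed_point(self):
        from oligovar.energetics import minimize_mm

        model = EnergyModel()
        pep = build_peptide(["ALA", "ALA"], chain_id="A")
        # reach an actual local minimum first (uncapped), then cap it
        relaxed, _info = minimize_mm(model, Assembly([pep]), rmsd_cap=None,
                                     max_steps=2000)
        again, rep = minimize_capped(relaxed, rmsd_cap=0.3, model=model, max_steps=400)
        e0 = model.energy(relaxed)
        e1 = model.energy(again)
        assert abs(e1.bonded + e1.vdw + e1.coulomb - (e0.bonded + e0.vdw + e0.coulomb)) < 1e-4
        assert rep.final_heavy_atom_rmsd <= 0.3 + 1e-6

    def test_stretched_bond_relaxes_within_the_cap(self):
        model = EnergyModel()
        pep = build_peptide(["ALA", "ALA"], chain_id="A")
        cb = pep.atom(1, "CB")
        ca = pep.atom(1, "CA")
        cb.coordinates = ca.coordinates + 1.25 * (cb.coordinates - ca.coordinates)
        asm = Assembly([pep])
        e_start = model.energy(asm)
        relaxed, rep = minimize_capped(asm, rmsd_cap=0.3, model=model)
        e_end = model.energy(relaxed)
        mm = lambda e: e.bonded + e.vdw + e.coulomb  # noqa: E731
        assert mm(e_end) < mm(e_start)
        assert rep.final_heavy_atom_rmsd <= 0.3 + 1e-6

    def test_zero_cap_returns_input_unchanged(self, c3_trimer):
        trimer, _ = c3_trimer
        out, rep = minimize_capped(trimer, rmsd_cap=0.0)
        assert np.allclose(out.coords(), trimer.coords(), atol=0.0)
        assert rep.minimization_steps == 0
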