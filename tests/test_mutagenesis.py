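"""Side-chain replacement, rotamer selection and local relaxation."""

import numpy as np
import pytest

from oligovar.combinatorics import CompositionVector
from oligovar.energetics import EnergyModel, folding_energy
from oligovar.mutagenesis import (
    MutationSpec,
    MutationValidationError,
    apply_mutation,
    measure_chis,
    relax_environment,
)


def side_names(protomer, resnum):
    return {a.name for a in protomer.residue(resnum)
            if a.name not in ("N", "CA", "C", "O", "H")}


def test_spec_parsing_and_validation():
    spec = MutationSpec.parse("A:180:Q>E")
    assert (spec.chain_id, spec.residue_number) == ("A", 180)
    assert spec.wt_three == "GLN" and spec.mut_three == "GLU"
    with pytest.raises(ValueError):
        MutationSpec.parse("garbage")
    with pytest.raises(ValueError):
        MutationSpec("A", 180, "Q", "Q")


def test_all_false_composition_is_identity(c3_trimer, qe_spec):
    trimer, _ = c3_trimer
    out, choices = apply_mutation(trimer, CompositionVector((False,) * 3), qe_spec)
    assert choices == {}
    assert np.allclose(out.coords(), trimer.coords(), atol=0.0)
    assert [a.name for a in out.atoms()] == [a.name for a in trimer.atoms()]


def test_gln_to_glu_changes_exactly_the_flagged_residue(c3_trimer, qe_spec):
    trimer, _ = c3_trimer
    out, choices = apply_mutation(trimer, CompositionVector((True, False, False)), qe_spec)
    assert set(choices) == {0}
    # amide tip atoms replaced by the carboxylate pair
    old = side_names(trimer.protomers[0], 180)
    new = side_names(out.protomers[0], 180)
    assert "NE2" in old and "OE2" not in old
    assert new - old == {"OE2"} and "NE2" not in new
    # backbone of the mutated residue untouched
    for name in ("N", "CA", "C", "O"):
        assert np.allclose(trimer.protomers[0].atom(180, name).coordinates,
                           out.protomers[0].atom(180, name).coordinates, atol=0.0)
    # the two unflagged protomers are bitwise identical
    for i in (1, 2):
        assert np.allclose(trimer.protomers[i].coords(),
                           out.protomers[i].coords(), atol=0.0)


def test_symmetric_environment_gives_identical_rotamers(c3_trimer, qe_spec):
    trimer, _ = c3_trimer
    _out, choices = apply_mutation(trimer, CompositionVector((True,) * 3), qe_spec)
    chis = {c.chi_angles for c in choices.values()}
    assert len(chis) == 1
    assert all(c.clash_free for c in choices.values())


def test_wt_mismatch_guards_numbering_drift(c3_trimer):
    trimer, _ = c3_trimer
    bad = MutationSpec("A", 180, "N", "D")  # site actually holds Gln
    with pytest.raises(MutationValidationError, match="GLN|numbering"):
        apply_mutation(trimer, CompositionVector((True, False, False)), bad)


def test_mutate_then_revert_restores_side_chain(qe_spec):
    # jitter-free fixture: the WT side chain is exactly template-built, so
    # rebuilding it at the measured chi angles must reproduce it atom for atom
    from oligovar.synthetic import FixtureSpec, make_c3_trimer

    trimer, _ = make_c3_trimer(FixtureSpec(seed=0, jitter=0.0))
    original = {a.name: a.coordinates.copy()
                for a in trimer.protomers[0].residue(180) if a.is_heavy}
    wt_chis = measure_chis(trimer.protomers[0], 180)
    cv = CompositionVector((True, False, False))
    mutated, _ = apply_mutation(trimer, cv, qe_spec)
    back = MutationSpec("A", 180, "E", "Q")
    with pytest.warns(UserWarning, match="rotamer"):
        # the override re-creates the WT's tight packing, which the clash
        # filter flags; the fallback still places it at the requested chis
        reverted, _ = apply_mutation(mutated, cv, back, rotamer_override=wt_chis)
    for a in reverted.protomers[0].residue(180):
        if a.is_heavy and a.name in original:
            assert np.allclose(a.coordinates, original[a.name], atol=1e-6), a.name


def test_composition_symmetry_of_energies(c3_trimer, qe_spec, mm_model):
    """Compositions related by the C3 symmetry score equal within tolerance."""
    trimer, _ = c3_trimer
    vals = []
    for flags in ((True, False, False), (False, True, False), (False, False, True)):
        mut, _ = apply_mutation(trimer, CompositionVector(flags), qe_spec)
        vals.append(folding_energy(mm_model, mut, ["GLU", "GLN", "GLN"]).total)
    assert max(vals) - min(vals) < 0.1


class TestRelaxation:
    def test_radius_zero_moves_only_the_target_side_chain(self, c3_trimer, qe_spec, mm_model):
        trimer, _ = c3_trimer
        mut, _ = apply_mutation(trimer, CompositionVector((True, False, False)), qe_spec)
        relaxed = relax_environment(mut, ("A", 180), radius=0.0, model=mm_model,
                                    max_steps=30)
        moved = ~np.all(np.isclose(relaxed.coords(), mut.coords(), atol=1e-12), axis=1)
        atoms = list(mut.atoms())
        for i in np.nonzero(moved)[0]:
            a = atoms[i]
            assert a.chain_id == "A" and a.residue_number == 180
            assert a.name not in ("N", "CA", "C", "O", "H")

    def test_relaxation_is_nearly_idempotent(self, c3_trimer, qe_spec, mm_model):
        from oligovar.forcefield import parameterize

        trimer, _ = c3_trimer
        mut, _ = apply_mutation(trimer, CompositionVector((True, False, False)), qe_spec)
        once = relax_environment(mut, ("A", 180), radius=3.0, model=mm_model,
                                 max_steps=2000)
        twice = relax_environment(once, ("A", 180), radius=3.0, model=mm_model,
                                  max_steps=2000)
        e1, _g = mm_model._mm_energy_grad(once.coords(), parameterize(once))
        e2, _g = mm_model._mm_energy_grad(twice.coords(), parameterize(twice))
        assert abs(e2 - e1) < 1e-4

    def test_relaxation_never_increases_mm_energy(self, c3_trimer, qe_spec, mm_model):
        from oligovar.forcefield import parameterize

        trimer, _ = c3_trimer
        mut, _ = apply_mutation(trimer, CompositionVector((True, True, True)), qe_spec)
        e0, _ = mm_model._mm_energy_grad(mut.coords(), parameterize(mut))
        relaxed = relax_environment(mut, ("A", 180), radius=4.0, model=mm_model,
                                    max_steps=60)
        e1, _ = mm_model._mm_energy_grad(relaxed.coords(), parameterize(relaxed))
        assert e1 <= e0 + 1e-9
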