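"""Energy decomposition and the MM/GBSA thermodynamic cycle.

The quantitative anchors are point-charge toy systems whose interaction
energies have a closed form; the protein-level checks are structural
(decomposition identities, cycle closure, all-WT zeros) and ordinal
(interface charge swaps destabilize more, and more mutated protomers
destabilize more).
"""

import numpy as np
import pytest

from oligovar.combinatorics import (
    CompositionVector,
    EvaluationPairing,
    enumerate_compositions,
    protomer_pairings,
)
from oligovar.energetics import (
    DdgRecord,
    EnergyModel,
    bind_records,
    binding_energy,
    fold_records,
    folding_energy,
    pool,
    scan,
)
from oligovar.synthetic import (
    coulomb_interaction,
    make_mutation_trend_pair,
    make_point_charge_cluster,
)


class TestToyCoulomb:
    def test_dipole_energy_matches_closed_form(self, dipole_cluster, toy_model):
        asm, _ = dipole_cluster
        e = toy_model.energy(asm)
        assert e.coulomb == pytest.approx(332.0637 * (1 * -1) / 10.0, abs=1e-9)
        assert e.bonded == e.vdw == e.gb_polar == e.sa_nonpolar == 0.0

    def test_single_neutral_atom_scores_zero(self, toy_model):
        asm, _ = make_point_charge_cluster([0.0], [[0, 0, 0]])
        e = toy_model.energy(asm)
        assert e.total == 0.0

    def test_energy_is_chain_order_invariant(self, toy_model):
        rng = np.random.default_rng(5)
        q = rng.normal(size=5)
        x = rng.normal(scale=6, size=(5, 3))
        asm, _ = make_point_charge_cluster(q, x)
        flipped = asm.copy()
        flipped.protomers = flipped.protomers[::-1]
        assert toy_model.energy(asm).coulomb == pytest.approx(
            toy_model.energy(flipped).coulomb, abs=1e-9)


class TestThermodynamicCycle:
    def _wt_mut(self):
        rng = np.random.default_rng(9)
        x = rng.normal(scale=7.0, size=(6, 3))
        q_wt = np.ones(6)
        q_mut = q_wt.copy()
        q_mut[0] = -1.0  # planted charge swap in the first protomer
        wt, wt_table = make_point_charge_cluster(q_wt, x)
        mut, mut_table = make_point_charge_cluster(q_mut, x)
        return wt, wt_table, mut, mut_table

    def test_ddg_bind_matches_brute_force_pairwise_oracle(self, toy_model):
        wt, wt_table, mut, mut_table = self._wt_mut()
        cv = CompositionVector((True,) + (False,) * 5)
        pairing = EvaluationPairing(cv, (0, 1, 2), (3, 4, 5), "trimer_vs_trimer")
        dg_mut = binding_energy(toy_model, mut, pairing)
        wt_pairing = EvaluationPairing(CompositionVector((False,) * 6),
                                       (0, 1, 2), (3, 4, 5), "trimer_vs_trimer")
        dg_wt = binding_energy(toy_model, wt, wt_pairing)
        oracle = (coulomb_interaction(mut_table, (0, 1, 2), (3, 4, 5))
                  - coulomb_interaction(wt_table, (0, 1, 2), (3, 4, 5)))
        assert (dg_mut - dg_wt).total == pytest.approx(oracle, abs=1e-9)
        assert (dg_mut - dg_wt).coulomb == pytest.approx(oracle, abs=1e-9)

    def test_all_wt_composition_scores_exactly_zero(self, toy_model):
        wt, _t, _m, _mt = self._wt_mut()
        pairing = EvaluationPairing(CompositionVector((False,) * 6),
                                    (0, 1, 2), (3, 4, 5), "trimer_vs_trimer")
        d = binding_energy(toy_model, wt, pairing) - binding_energy(toy_model, wt, pairing)
        assert d.total == 0.0 and d.coulomb == 0.0

    def test_cycle_closure_identity(self, toy_model):
        """(dG_mut - dG_wt) equals the alternate leg dE(complex) - sum dE(units)."""
        wt, _wt_t, mut, _mut_t = self._wt_mut()
        cv = CompositionVector((True,) + (False,) * 5)
        pairing = EvaluationPairing(cv, (0, 1, 2), (3, 4, 5), "trimer_vs_trimer")
        left = np.arange(3)
        right = np.arange(3, 6)
        leg1 = (binding_energy(toy_model, mut, pairing)
                - binding_energy(toy_model, wt, pairing)).total
        dE_complex = toy_model.energy(mut).total - toy_model.energy(wt).total
        dE_left = (toy_model.energy(mut, indices=left).total
                   - toy_model.energy(wt, indices=left).total)
        dE_right = (toy_model.energy(mut, indices=right).total
                    - toy_model.energy(wt, indices=right).total)
        assert leg1 == pytest.approx(dE_complex - dE_left - dE_right, abs=1e-9)

    def test_unit_swap_symmetry(self, toy_model):
        """Same mutation in both units of a symmetric pairing: swap-invariant."""
        rng = np.random.default_rng(13)
        half = rng.normal(scale=6.0, size=(3, 3))
        x = np.vstack([half, half + np.array([0.0, 0.0, 25.0])])
        q = np.ones(6)
        q[0] = q[3] = -1.0
        asm, _ = make_point_charge_cluster(q, x)
        cv = CompositionVector((True, False, False, True, False, False))
        p1 = EvaluationPairing(cv, (0, 1, 2), (3, 4, 5), "trimer_vs_trimer")
        p2 = EvaluationPairing(cv, (3, 4, 5), (0, 1, 2), "trimer_vs_trimer")
        assert binding_energy(toy_model, asm, p1).total == pytest.approx(
            binding_energy(toy_model, asm, p2).total, abs=1e-9)


def test_decomposition_components_sum_to_total(c3_trimer, mm_model):
    trimer, _ = c3_trimer
    e = mm_model.energy(trimer)
    assert e.total == pytest.approx(
        e.bonded + e.vdw + e.coulomb + e.gb_polar + e.sa_nonpolar, abs=1e-6)
    assert e.solvation == pytest.approx(e.gb_polar + e.sa_nonpolar, abs=1e-12)


@pytest.fixture(scope="module")
def trimer_scan(qe_spec, mm_model):
    from oligovar.synthetic import FixtureSpec, make_c3_trimer

    trimer, _ = make_c3_trimer(FixtureSpec(seed=7))
    comps = enumerate_compositions(3)
    pairings = protomer_pairings(comps)
    return scan(trimer, comps, pairings, qe_spec, model=mm_model,
                relax_radius=4.0, relax_steps=300)


class TestScanTrends:
    def test_record_counts(self, trimer_scan):
        assert len(bind_records(trimer_scan)) == 21
        assert len(fold_records(trimer_scan)) == 7

    def test_decomposition_conservation_per_record(self, trimer_scan):
        for r in trimer_scan:
            if r.pairing is None:
                assert r.ddg_f_app == pytest.approx(
                    r.ddg_f_coulomb + r.ddg_f_solv + r.ddg_f_residual, abs=1e-6)
            else:
                assert r.ddg_b_app == pytest.approx(
                    r.ddg_b_coulomb + r.ddg_b_solv + r.ddg_b_residual, abs=1e-6)

    def test_interface_charge_swap_destabilizes_monotonically(self, trimer_scan):
        folds = pool(fold_records(trimer_scan))
        means_f = [ps.mean["ddg_f_app"] for ps in folds]
        assert all(m > 0 for m in means_f)
        assert means_f == sorted(means_f)
        binds = pool(bind_records(trimer_scan))
        means_b = [ps.mean["ddg_b_app"] for ps in binds]
        assert all(m > 0 for m in means_b)
        assert means_b == sorted(means_b)
        assert [ps.n for ps in binds] == [9, 9, 3]

    def test_surface_site_is_milder_than_interface(self, qe_spec, mm_model):
        """Homozygous charge swap at the three-fold interface vs the same swap
        rotated to face bulk solvent: the interface effect dominates."""
        (ti, _mi), (ts, _ms) = make_mutation_trend_pair(seed=7)
        cv = [CompositionVector((True, True, True))]
        r_int = scan(ti, cv, [], qe_spec, model=mm_model,
                     relax_radius=4.0, relax_steps=300)
        r_surf = scan(ts, cv, [], qe_spec, model=mm_model,
                      relax_radius=4.0, relax_steps=300)
        assert abs(r_surf[0].ddg_f_app) < abs(r_int[0].ddg_f_app)


class TestPooling:
    def _records(self, values, n=3):
        comps = enumerate_compositions(n)
        recs = []
        for cv, v in zip([c for c in comps if c.mutation_count == 1], values):
            recs.append(DdgRecord(composition=cv, ddg_f_app=v, ddg_f_coulomb=0.0,
                                  ddg_f_solv=0.0, ddg_f_residual=v))
        return recs

    def test_mean_and_sample_sd(self):
        stats = pool(self._records([1.0, 2.0, 3.0]))
        assert stats[0].mean["ddg_f_app"] == pytest.approx(2.0)
        assert stats[0].sd["ddg_f_app"] == pytest.approx(1.0)  # n-1 denominator
        assert stats[0].n == 3

    def test_single_member_group_has_absent_sd(self):
        cv = CompositionVector((True, True, True))
        stats = pool([DdgRecord(composition=cv, ddg_f_app=5.0)])
        assert stats[0].n == 1 and stats[0].sd is None

    def test_pooling_is_order_invariant(self):
        recs = self._records([3.0, 1.0, 2.0])
        s1 = pool(recs)
        s2 = pool(recs[::-1])
        assert s1[0].mean == s2[0].mean and s1[0].sd == s2[0].sd

    def test_mixed_record_types_rejected(self):
        cv = CompositionVector((True, False, False))
        fold = DdgRecord(composition=cv, ddg_f_app=1.0)
        bind = DdgRecord(composition=cv,
                         pairing=EvaluationPairing(cv, (0,), (1, 2), "protomer_vs_rest"),
                         ddg_b_app=1.0)
        with pytest.raises(ValueError):
            pool([fold, bind])
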