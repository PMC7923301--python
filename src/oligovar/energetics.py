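"""MM/GBSA-style energies and apparent ddG of binding and folding.

The model is a single-structure (one-trajectory) thermodynamic cycle:
separated binding partners keep their complex-geometry coordinates, the
unfolded reference of each chain is an extended Gly-X-Gly tripeptide at the
scanned position (every other residue cancels in the WT-vs-mutant
difference), and no conformational-ensemble or entropy terms are included.
Quantities are therefore *apparent* ddG values - comparative indexes, not
calibrated free energies.

Energy components: harmonic bonds/angles (bonded), Lennard-Jones (vdw),
vacuum Coulomb with 332.0637 kcal*A/(mol*e^2), HCT pairwise-descreening
generalized Born polar solvation (solute dielectric 1, solvent 80), and a
linear-SASA nonpolar term. Minimization acts on the MM terms (bonded + LJ +
Coulomb) with an optional heavy-atom displacement cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from scipy.optimize import minimize as _scipy_minimize

from . import combinatorics as comb
from .builder import build_peptide
from .forcefield import (
    COULOMB_CONSTANT,
    GB_OFFSET,
    ParamSet,
    parameterize,
)
from .structure import Assembly

__all__ = [
    "EnergyBreakdown",
    "DdgRecord",
    "PooledStats",
    "EnergyModel",
    "minimize_mm",
    "binding_energy",
    "folding_energy",
    "ddg_bind",
    "ddg_fold",
    "scan",
    "pool",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Additive decomposition of a conformation's energy (kcal/mol)."""

    bonded: float = 0.0
    vdw: float = 0.0
    coulomb: float = 0.0
    gb_polar: float = 0.0
    sa_nonpolar: float = 0.0

    @property
    def total(self) -> float:
        return self.bonded + self.vdw + self.coulomb + self.gb_polar + self.sa_nonpolar

    @property
    def solvation(self) -> float:
        return self.gb_polar + self.sa_nonpolar

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(*(a - b for a, b in zip(self._tuple(), other._tuple())))

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(*(a + b for a, b in zip(self._tuple(), other._tuple())))

    def _tuple(self):
        return (self.bonded, self.vdw, self.coulomb, self.gb_polar, self.sa_nonpolar)


@dataclass
class DdgRecord:
    """Apparent ddG (binding and/or folding) of one composition."""

    composition: comb.CompositionVector
    pairing: comb.EvaluationPairing | None = None
    ddg_b_app: float | None = None
    ddg_b_coulomb: float | None = None
    ddg_b_solv: float | None = None
    ddg_b_residual: float | None = None
    ddg_f_app: float | None = None
    ddg_f_coulomb: float | None = None
    ddg_f_solv: float | None = None
    ddg_f_residual: float | None = None

    COLUMNS = ("ddg_b_app", "ddg_b_coulomb", "ddg_b_solv", "ddg_b_residual",
               "ddg_f_app", "ddg_f_coulomb", "ddg_f_solv", "ddg_f_residual")


@dataclass
class PooledStats:
    """Mean +- sample SD of ddG columns for one mutation-count group."""

    mutation_count: int
    n: int
    mean: dict[str, float]
    sd: dict[str, float] | None  # absent (None) when n == 1


def _delta_record(mut: EnergyBreakdown, wt: EnergyBreakdown) -> dict[str, float]:
    d = mut - wt
    return {
        "app": d.total,
        "coulomb": d.coulomb,
        "solv": d.solvation,
        "residual": d.bonded + d.vdw,
    }


class EnergyModel:
    """Force-field evaluation engine with switchable components."""

    def __init__(
        self,
        use_bonded: bool = True,
        use_vdw: bool = True,
        use_coulomb: bool = True,
        use_gb: bool = True,
        use_sa: bool = True,
        solute_dielectric: float = 1.0,
        solvent_dielectric: float = 80.0,
        sa_gamma: float = 0.0054,
        sasa_probe: float = 1.4,
        sasa_points: int = 300,
    ):
        self.use_bonded = use_bonded
        self.use_vdw = use_vdw
        self.use_coulomb = use_coulomb
        self.use_gb = use_gb
        self.use_sa = use_sa
        self.eps_in = solute_dielectric
        self.eps_out = solvent_dielectric
        self.sa_gamma = sa_gamma
        self.sasa_probe = sasa_probe
        self.sasa_points = sasa_points
        self._ref_cache: dict[str, EnergyBreakdown] = {}

    @classmethod
    def toy(cls) -> "EnergyModel":
        """Coulomb-only evaluation for point-charge oracle systems."""
        return cls(use_bonded=False, use_vdw=False, use_gb=False, use_sa=False)

    def provenance(self) -> dict:
        return {
            "terms": {k: getattr(self, f"use_{k}") for k in
                      ("bonded", "vdw", "coulomb", "gb", "sa")},
            "solute_dielectric": self.eps_in,
            "solvent_dielectric": self.eps_out,
            "coulomb_constant": COULOMB_CONSTANT,
            "sa_gamma_kcal_per_A2": self.sa_gamma,
            "gb_model": "HCT pairwise descreening",
        }

    # ---- component evaluations -------------------------------------------

    def _bonded(self, xyz: np.ndarray, p: ParamSet, sub: np.ndarray | None):
        e = 0.0
        if len(p.bonds):
            mask = np.ones(len(p.bonds), bool) if sub is None else (
                sub[p.bonds[:, 0]] & sub[p.bonds[:, 1]])
            b = p.bonds[mask]
            r0 = p.bond_r0[mask]
            if len(b):
                d = np.linalg.norm(xyz[b[:, 0]] - xyz[b[:, 1]], axis=1)
                e += float(np.sum(300.0 * (d - r0) ** 2))
        if len(p.angles):
            mask = np.ones(len(p.angles), bool) if sub is None else (
                sub[p.angles[:, 0]] & sub[p.angles[:, 1]] & sub[p.angles[:, 2]])
            a = p.angles[mask]
            t0 = p.angle_theta0[mask]
            if len(a):
                u = xyz[a[:, 0]] - xyz[a[:, 1]]
                v = xyz[a[:, 2]] - xyz[a[:, 1]]
                cos = np.sum(u * v, axis=1) / (
                    np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
                th = np.arccos(np.clip(cos, -1.0, 1.0))
                e += float(np.sum(60.0 * (th - t0) ** 2))
        return e

    def _pair_distances(self, xyz: np.ndarray):
        diff = xyz[:, None, :] - xyz[None, :, :]
        r = np.sqrt(np.maximum(np.sum(diff * diff, axis=-1), 1e-12))
        return r

    def _nonbonded(self, xyz, p: ParamSet, idx: np.ndarray):
        q = p.charges[idx]
        rm = p.lj_rmin2[idx]
        ep = p.lj_eps[idx]
        scale = p.scale_matrix[np.ix_(idx, idx)]
        r = self._pair_distances(xyz[idx])
        np.fill_diagonal(r, 1.0)
        e_coul = 0.0
        e_vdw = 0.0
        if self.use_coulomb:
            mat = COULOMB_CONSTANT / self.eps_in * np.outer(q, q) / r * scale
            e_coul = 0.5 * float(mat.sum())
        if self.use_vdw:
            rmin = rm[:, None] + rm[None, :]
            eij = np.sqrt(np.outer(ep, ep))
            x6 = (rmin / r) ** 6
            mat = eij * (x6 * x6 - 2.0 * x6) * scale
            e_vdw = 0.5 * float(mat.sum())
        return e_vdw, e_coul

    def born_radii(self, xyz, p: ParamSet, idx: np.ndarray) -> np.ndarray:
        rho = p.gb_radii[idx] - GB_OFFSET
        srho = p.gb_scale[idx] * rho
        r = self._pair_distances(xyz[idx])
        n = len(idx)
        np.fill_diagonal(r, np.inf)
        sj = srho[None, :].repeat(n, axis=0)
        rhoi = rho[:, None].repeat(n, axis=1)
        U = r + sj
        L = np.maximum(rhoi, np.abs(r - sj))
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (1.0 / L - 1.0 / U) \
                + (r / 4.0) * (1.0 / U**2 - 1.0 / L**2) \
                + (1.0 / (2.0 * r)) * np.log(L / U) \
                + (sj**2 / (4.0 * r)) * (1.0 / L**2 - 1.0 / U**2)
            inside = rhoi < (sj - r)
            term = term + np.where(inside, 2.0 * (1.0 / rhoi - 1.0 / L), 0.0)
        term[~np.isfinite(term)] = 0.0
        term[rhoi >= U] = 0.0
        inv = 1.0 / rho - 0.5 * np.sum(term, axis=1)
        inv = np.maximum(inv, 1.0 / 1000.0)
        return 1.0 / inv

    def _gb_energy(self, xyz, p: ParamSet, idx: np.ndarray) -> float:
        q = p.charges[idx]
        if not np.any(q):
            return 0.0
        R = self.born_radii(xyz, p, idx)
        r = self._pair_distances(xyz[idx])
        np.fill_diagonal(r, 0.0)
        RR = np.outer(R, R)
        f = np.sqrt(r * r + RR * np.exp(-r * r / (4.0 * RR)))
        pref = -0.5 * COULOMB_CONSTANT * (1.0 / self.eps_in - 1.0 / self.eps_out)
        return pref * float((np.outer(q, q) / f).sum())

    def _sa_energy(self, assembly: Assembly, p: ParamSet, idx: np.ndarray) -> float:
        atoms = list(assembly.atoms())
        sel = [atoms[i] for i in idx]
        arr = bst.AtomArray(len(sel))
        arr.coord = np.array([a.coordinates for a in sel], dtype=np.float32)
        arr.element = np.array([a.element.upper() for a in sel])
        arr.res_id = np.arange(len(sel))
        arr.res_name = np.array([a.residue_name for a in sel])
        arr.atom_name = np.array([a.name for a in sel])
        arr.chain_id = np.array([a.chain_id[:1] or "A" for a in sel])
        radii = np.maximum(p.lj_rmin2[idx], 0.8).astype(float)
        sasa = bst.sasa(arr, probe_radius=self.sasa_probe, vdw_radii=radii,
                        point_number=self.sasa_points)
        return self.sa_gamma * float(np.nansum(sasa))

    # ---- public API -------------------------------------------------------

    def energy(
        self,
        assembly: Assembly,
        indices: np.ndarray | None = None,
        params: ParamSet | None = None,
    ) -> EnergyBreakdown:
        """Energy of the assembly (or of an atom subset in place)."""
        p = params if params is not None else parameterize(assembly)
        xyz = assembly.coords()
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")
        idx = np.arange(p.n_atoms) if indices is None else np.asarray(indices, int)
        sub = None
        if indices is not None:
            sub = np.zeros(p.n_atoms, bool)
            sub[idx] = True
        bonded = self._bonded(xyz, p, sub) if self.use_bonded else 0.0
        vdw, coul = self._nonbonded(xyz, p, idx) if (self.use_vdw or self.use_coulomb) \
            else (0.0, 0.0)
        if not self.use_vdw:
            vdw = 0.0
        if not self.use_coulomb:
            coul = 0.0
        gb = self._gb_energy(xyz, p, idx) if self.use_gb else 0.0
        sa = self._sa_energy(assembly, p, idx) if self.use_sa else 0.0
        return EnergyBreakdown(bonded=bonded, vdw=vdw, coulomb=coul,
                               gb_polar=gb, sa_nonpolar=sa)

    # ---- MM energy + gradient for minimization ---------------------------

    def _mm_energy_grad(self, xyz: np.ndarray, p: ParamSet):
        n = p.n_atoms
        e = 0.0
        g = np.zeros((n, 3))
        if self.use_bonded and len(p.bonds):
            d = xyz[p.bonds[:, 0]] - xyz[p.bonds[:, 1]]
            r = np.linalg.norm(d, axis=1)
            dr = r - p.bond_r0
            e += float(np.sum(300.0 * dr**2))
            f = (2.0 * 300.0 * dr / r)[:, None] * d
            np.add.at(g, p.bonds[:, 0], f)
            np.add.at(g, p.bonds[:, 1], -f)
        if self.use_bonded and len(p.angles):
            i, j, k = p.angles[:, 0], p.angles[:, 1], p.angles[:, 2]
            u = xyz[i] - xyz[j]
            v = xyz[k] - xyz[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos = np.sum(u * v, axis=1) / (nu * nv)
            cos = np.clip(cos, -1.0 + 1e-10, 1.0 - 1e-10)
            th = np.arccos(cos)
            sin = np.sqrt(1.0 - cos * cos)
            dE = 2.0 * 60.0 * (th - p.angle_theta0)
            e += float(np.sum(60.0 * (th - p.angle_theta0) ** 2))
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            dth_di = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
            dth_dk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
            np.add.at(g, i, dE[:, None] * dth_di)
            np.add.at(g, k, dE[:, None] * dth_dk)
            np.add.at(g, j, -dE[:, None] * (dth_di + dth_dk))
        if self.use_coulomb or self.use_vdw:
            diff = xyz[:, None, :] - xyz[None, :, :]
            r2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(r2, 1.0)
            r = np.sqrt(r2)
            scale = p.scale_matrix
            if self.use_coulomb:
                qq = COULOMB_CONSTANT / self.eps_in * np.outer(p.charges, p.charges) * scale
                e += 0.5 * float((qq / r).sum())
                coef = -qq / (r2 * r)
                g += np.sum(coef[:, :, None] * diff, axis=1)
            if self.use_vdw:
                rmin = p.lj_rmin2[:, None] + p.lj_rmin2[None, :]
                eij = np.sqrt(np.outer(p.lj_eps, p.lj_eps)) * scale
                x6 = (rmin / r) ** 6
                e += 0.5 * float((eij * (x6 * x6 - 2.0 * x6)).sum())
                coef = eij * 12.0 * (x6 - x6 * x6) / r2
                g += np.sum(coef[:, :, None] * diff, axis=1)
        return e, g


def minimize_mm(
    model: EnergyModel,
    assembly: Assembly,
    rmsd_cap: float | None = None,
    max_steps: int = 200,
    free_mask: np.ndarray | None = None,
    chunk: int = 10,
    params: ParamSet | None = None,
):
    """Displacement-capped MM minimization.

    Runs L-BFGS in small chunks; after each chunk the heavy-atom RMSD from
    the starting coordinates is checked and the last iterate within the cap
    is kept, so the result never drifts more than one chunk's movement past
    the cap. Energy is non-increasing by construction. ``rmsd_cap=0``
    returns the input unchanged.
    """
    p = params if params is not None else parameterize(assembly)
    out = assembly.copy()
    if rmsd_cap is not None and rmsd_cap <= 0.0:
        return out, {"minimization_steps": 0, "final_heavy_atom_rmsd": 0.0}
    x0 = assembly.coords()
    if not np.all(np.isfinite(x0)):
        raise ValueError("non-finite starting coordinates")
    e0, _ = model._mm_energy_grad(x0, p)
    if not math.isfinite(e0):
        raise ValueError("non-finite starting energy")
    free = np.ones(p.n_atoms, bool) if free_mask is None else np.asarray(free_mask, bool)
    heavy = p.heavy_mask

    def heavy_rmsd(x):
        d = x[heavy] - x0[heavy]
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    def fun(z):
        x = x0.copy()
        x[free] = z.reshape(-1, 3)
        e, g = model._mm_energy_grad(x, p)
        return e, g[free].ravel()

    best = x0.copy()
    best_e = e0
    steps = 0
    cur = x0[free].ravel().copy()
    if rmsd_cap is None:
        # no displacement cap: one uninterrupted L-BFGS run converges best
        res = _scipy_minimize(fun, cur, jac=True, method="L-BFGS-B",
                              options={"maxiter": max_steps, "ftol": 1e-12,
                                       "gtol": 1e-8})
        if res.fun <= best_e:
            best = x0.copy()
            best[free] = res.x.reshape(-1, 3)
            best_e = res.fun
        out.set_coords(best)
        return out, {
            "minimization_steps": res.nit,
            "final_heavy_atom_rmsd": heavy_rmsd(best),
            "initial_energy": e0,
            "final_energy": best_e,
        }
    while steps < max_steps:
        res = _scipy_minimize(fun, cur, jac=True, method="L-BFGS-B",
                              options={"maxiter": chunk, "ftol": 1e-10, "gtol": 1e-8})
        steps += max(res.nit, 1)
        x = x0.copy()
        x[free] = res.x.reshape(-1, 3)
        r = heavy_rmsd(x)
        if rmsd_cap is not None and r > rmsd_cap:
            break
        if res.fun <= best_e:
            best = x
            best_e = res.fun
        if res.nit < chunk:  # converged inside the chunk
            break
        cur = res.x
    out.set_coords(best)
    return out, {
        "minimization_steps": steps,
        "final_heavy_atom_rmsd": heavy_rmsd(best),
        "initial_energy": e0,
        "final_energy": best_e,
    }


# ---- thermodynamic cycle --------------------------------------------------

def protomer_atom_indices(assembly: Assembly) -> list[np.ndarray]:
    out = []
    i = 0
    for p in assembly.protomers:
        out.append(np.arange(i, i + len(p.atoms)))
        i += len(p.atoms)
    return out


def binding_energy(
    model: EnergyModel,
    assembly: Assembly,
    pairing: comb.EvaluationPairing,
    params: ParamSet | None = None,
) -> EnergyBreakdown:
    """dG_bind = E(complex) - E(left) - E(right), units in complex geometry."""
    if len(pairing.left_unit) + len(pairing.right_unit) != len(assembly.protomers):
        raise ValueError("pairing does not partition this assembly")
    p = params if params is not None else parameterize(assembly)
    prot_idx = protomer_atom_indices(assembly)
    left = np.concatenate([prot_idx[i] for i in pairing.left_unit])
    right = np.concatenate([prot_idx[i] for i in pairing.right_unit])
    e_all = model.energy(assembly, params=p)
    e_l = model.energy(assembly, indices=left, params=p)
    e_r = model.energy(assembly, indices=right, params=p)
    return e_all - e_l - e_r


def _unfolded_reference(model: EnergyModel, res_name: str) -> EnergyBreakdown:
    key = f"GXG:{res_name}"
    if key not in model._ref_cache:
        pep = build_peptide(["GLY", res_name, "GLY"], phi=180.0, psi=180.0, chain_id="X")
        ref = Assembly([pep], kind="protomer")
        model._ref_cache[key] = model.energy(ref)
    return model._ref_cache[key]


def folding_energy(
    model: EnergyModel,
    assembly: Assembly,
    site_residues: list[str],
    params: ParamSet | None = None,
) -> EnergyBreakdown:
    """dG_fold = E(assembly) - sum of extended Gly-X-Gly references.

    ``site_residues`` lists the residue type at the scanned site in each
    protomer (the only residues whose unfolded reference does not cancel in
    WT-vs-mutant differences).
    """
    e = model.energy(assembly, params=params)
    for res in site_residues:
        e = e - _unfolded_reference(model, res)
    return e


def ddg_bind(
    model: EnergyModel,
    mutant: Assembly,
    pairing: comb.EvaluationPairing,
    wt_reference: EnergyBreakdown,
) -> dict[str, float]:
    """ddG_b^app of a mutant composition vs the WT dG_b for the same pairing."""
    return _delta_record(binding_energy(model, mutant, pairing), wt_reference)


def ddg_fold(
    model: EnergyModel,
    mutant: Assembly,
    site_residues: list[str],
    wt_reference: EnergyBreakdown,
) -> dict[str, float]:
    """ddG_f^app of a mutant composition vs the WT dG_f."""
    return _delta_record(folding_energy(model, mutant, site_residues), wt_reference)


def scan(
    assembly: Assembly,
    compositions,
    pairings,
    spec,
    model: EnergyModel | None = None,
    relax_radius: float | None = 4.0,
    relax_steps: int = 300,
    relax_cap: float | None = 0.3,
) -> list[DdgRecord]:
    """Evaluate ddG of folding per composition and of binding per pairing.

    Every composition (including the all-WT reference) receives identical
    treatment: the variant side chains are placed with the most probable
    clash-free rotamer, then side chains within ``relax_radius`` of the
    scanned site in *all* protomers are MM-relaxed (set ``relax_radius`` to
    None to skip relaxation). One structure per composition is reused across
    its pairings.
    """
    from .mutagenesis import apply_mutation, relax_sites  # local import: avoids cycle

    if model is None:
        model = EnergyModel()
    compositions = list(compositions)
    pairings = list(pairings)
    wt_name, mut_name = spec.wt_three, spec.mut_three

    def prepared(composition: comb.CompositionVector) -> Assembly:
        asm, _ = apply_mutation(assembly, composition, spec)
        if relax_radius is not None:
            asm = relax_sites(asm, spec, model, radius=relax_radius,
                              max_steps=relax_steps, rmsd_cap=relax_cap)
        return asm

    structures: dict[tuple, Assembly] = {}
    params_cache: dict[tuple, ParamSet] = {}

    def get(composition):
        key = composition.flags
        if key not in structures:
            asm = prepared(composition)
            structures[key] = asm
            params_cache[key] = parameterize(asm)
        return structures[key], params_cache[key]

    n = len(assembly.protomers)
    wt_comp = comb.CompositionVector((False,) * n)
    wt_asm, wt_params = get(wt_comp)

    wt_bind: dict[tuple, EnergyBreakdown] = {}
    records: list[DdgRecord] = []

    def site_residues(composition):
        return [mut_name if f else wt_name for f in composition.flags]

    wt_fold = folding_energy(model, wt_asm, site_residues(wt_comp), params=wt_params)
    for cv in compositions:
        asm, prm = get(cv)
        d = _delta_record(folding_energy(model, asm, site_residues(cv), params=prm), wt_fold)
        records.append(DdgRecord(
            composition=cv, pairing=None,
            ddg_f_app=d["app"], ddg_f_coulomb=d["coulomb"],
            ddg_f_solv=d["solv"], ddg_f_residual=d["residual"]))
    for pr in pairings:
        ukey = (pr.left_unit, pr.right_unit)
        if ukey not in wt_bind:
            wt_bind[ukey] = binding_energy(model, wt_asm, comb.EvaluationPairing(
                wt_comp, pr.left_unit, pr.right_unit, pr.mode), params=wt_params)
        asm, prm = get(pr.composition)
        d = _delta_record(binding_energy(model, asm, pr, params=prm), wt_bind[ukey])
        records.append(DdgRecord(
            composition=pr.composition, pairing=pr,
            ddg_b_app=d["app"], ddg_b_coulomb=d["coulomb"],
            ddg_b_solv=d["solv"], ddg_b_residual=d["residual"]))
    return records


def fold_records(records) -> list[DdgRecord]:
    return [r for r in records if r.pairing is None]


def bind_records(records) -> list[DdgRecord]:
    return [r for r in records if r.pairing is not None]


def pool(records) -> list[PooledStats]:
    """Group records by mutation count; mean and sample SD per ddG column.

    Records must be homogeneous (all folding or all binding) so that the
    reported n matches the combinatorial group size.
    """
    records = list(records)
    modes = {r.pairing.mode if r.pairing is not None else "fold" for r in records}
    if len(modes) > 1:
        raise ValueError(f"pool() needs homogeneous records, got {sorted(modes)}")
    groups = comb.group_by_mutation_count(records)
    out = []
    for k, recs in groups.items():
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        any_sd = False
        for col in DdgRecord.COLUMNS:
            vals = [getattr(r, col) for r in recs if getattr(r, col) is not None]
            if not vals:
                continue
            means[col] = float(np.mean(vals))
            if len(vals) > 1:
                sds[col] = float(np.std(vals, ddof=1))
                any_sd = True
        out.append(PooledStats(mutation_count=k, n=len(recs), mean=means,
                               sd=sds if any_sd else None))
    return out
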