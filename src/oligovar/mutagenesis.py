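"""Point mutagenesis by side-chain replacement with rotamer selection.

A substitution (e.g. Gln→Glu at position 180) is introduced into the
flagged protomers of a composition by stripping the side chain, rebuilding
the target residue's side chain from its internal-coordinate template at
each library rotamer, and keeping the most probable clash-free rotamer
(clash: heavy-atom pair closer than 0.7x the sum of vdW radii). Backbone
atoms never move. A local MM relaxation of surrounding side chains is
available separately so that placement stays deterministic.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .builder import ROTAMER_LIBRARY, SIDECHAIN_TEMPLATES, build_side_chain
from .forcefield import ONE_TO_THREE, THREE_TO_ONE, VDW_RADII
from .structure import Assembly, AtomRecord, Protomer

__all__ = [
    "MutationSpec",
    "RotamerChoice",
    "MutationValidationError",
    "apply_mutation",
    "relax_environment",
    "relax_sites",
    "measure_chis",
]

BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "OXT"}


class MutationValidationError(ValueError):
    """WT residue at the addressed position does not match the spec."""


@dataclass(frozen=True)
class MutationSpec:
    """chain:resnum:WT>MUT in one-letter codes, e.g. A:180:Q>E."""

    chain_id: str
    residue_number: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in ONE_TO_THREE:
                raise ValueError(f"unknown amino acid code {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValueError("wt and mutant amino acids must differ")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        m = re.fullmatch(r"(\w+):(\d+):([A-Z])>([A-Z])", text.strip())
        if not m:
            raise ValueError(f"cannot parse mutation spec {text!r} (expected A:180:Q>E)")
        return cls(m.group(1), int(m.group(2)), m.group(3), m.group(4))

    @property
    def wt_three(self) -> str:
        return ONE_TO_THREE[self.wt_aa]

    @property
    def mut_three(self) -> str:
        return ONE_TO_THREE[self.mut_aa]

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_number}:{self.wt_aa}>{self.mut_aa}"


@dataclass
class RotamerChoice:
    chi_angles: tuple[float, ...]
    library_probability: float
    post_min_energy: float = math.nan
    clash_free: bool = True

    def __post_init__(self):
        # normalize chi angles into (-180, 180]
        self.chi_angles = tuple(
            180.0 if c == 180.0 else ((c + 180.0) % 360.0) - 180.0 for c in self.chi_angles
        )


def _chi_chain_atoms(res_name: str) -> list[tuple[str, str, str, str]]:
    """Atom-name quadruples defining chi_1..chi_n for a residue."""
    chains = []
    for name, (a, b, c), _r, _t, tors in SIDECHAIN_TEMPLATES.get(res_name, []):
        if isinstance(tors, tuple) and tors[2] == 0.0:
            chains.append((tors[1], (a, b, c, name)))
    chains.sort(key=lambda e: e[0])
    return [atoms for _k, atoms in chains]


def measure_chis(protomer: Protomer, residue_number: int, icode: str = "") -> tuple[float, ...]:
    """Measure the chi angles of a residue as built (degrees)."""
    from .geometry import dihedral

    atoms = {a.name: a.coordinates for a in protomer.residue(residue_number, icode)}
    if not atoms:
        raise KeyError(f"residue {residue_number}{icode} not found")
    res_name = protomer.residue(residue_number, icode)[0].residue_name
    chis = []
    for a, b, c, d in _chi_chain_atoms(res_name):
        if d not in atoms:
            break
        chis.append(dihedral(atoms[a], atoms[b], atoms[c], atoms[d]))
    return tuple(chis)


def _clash_score(side_xyz, side_el, env_xyz, env_radii) -> tuple[int, float]:
    if len(env_xyz) == 0 or len(side_xyz) == 0:
        return 0, 0.0
    tree = cKDTree(env_xyz)
    n_clash = 0
    overlap = 0.0
    for xyz, el in zip(side_xyz, side_el):
        r_self = VDW_RADII.get(el, VDW_RADII["C"])
        cutoff = 0.7 * (r_self + max(env_radii))
        for j in tree.query_ball_point(xyz, cutoff):
            thresh = 0.7 * (r_self + env_radii[j])
            d = float(np.linalg.norm(xyz - env_xyz[j]))
            if d < thresh:
                n_clash += 1
                overlap += thresh - d
    return n_clash, overlap


def apply_mutation(
    assembly: Assembly,
    composition,
    spec: MutationSpec,
    rotamer_override: tuple[float, ...] | None = None,
):
    """Introduce the substitution into every flagged protomer.

    Returns ``(new_assembly, {protomer_index: RotamerChoice})``. Unflagged
    protomers (and every backbone atom) are untouched; an all-false
    composition returns an identical copy.
    """
    flags = list(composition.flags)
    if len(flags) != len(assembly.protomers):
        raise ValueError("composition length does not match protomer count")
    if spec.mut_three not in SIDECHAIN_TEMPLATES:
        raise ValueError(f"no building template for target residue {spec.mut_three}")
    out = assembly.copy()
    choices: dict[int, RotamerChoice] = {}
    if not any(flags):
        return out, choices

    # Placements are independent: every flagged protomer is clash-checked
    # against the *original* structure with all flagged side chains removed,
    # so symmetry-equivalent compositions choose symmetry-equivalent rotamers.
    flagged = {i for i, f in enumerate(flags) if f}
    env_all: list[AtomRecord] = []
    for qi, qprot in enumerate(assembly.protomers):
        target = qprot.residue(spec.residue_number)
        tkey = target[0].residue_key if target else None
        for a in qprot.atoms:
            if qi in flagged and tkey is not None and a.residue_key == tkey \
                    and a.name not in ("N", "CA", "C", "O", "H"):
                continue
            if a.is_heavy:
                env_all.append((qi, a))

    for pi, flag in enumerate(flags):
        if not flag:
            continue
        prot = out.protomers[pi]
        res_atoms = prot.residue(spec.residue_number)
        if not res_atoms:
            raise MutationValidationError(
                f"protomer {pi} ({prot.chain_id}): no residue {spec.residue_number}")
        found = res_atoms[0].residue_name
        if found != spec.wt_three:
            raise MutationValidationError(
                f"protomer {pi} ({prot.chain_id}): residue {spec.residue_number} is "
                f"{found}, expected {spec.wt_three} - author numbering may have drifted")
        backbone = {a.name: a.coordinates for a in res_atoms if a.name in BACKBONE_NAMES}
        for key in ("N", "CA", "C"):
            if key not in backbone:
                raise MutationValidationError(
                    f"protomer {pi}: residue {spec.residue_number} lacks backbone atom {key}")

        env = [a for qi, a in env_all
               if not (qi == pi and a.residue_key == res_atoms[0].residue_key)]
        env_xyz = np.array([a.coordinates for a in env]) if env else np.zeros((0, 3))
        env_radii = [VDW_RADII.get(a.element.upper(), VDW_RADII["C"]) for a in env]

        if rotamer_override is not None:
            candidates = [(tuple(rotamer_override), 1.0)]
        else:
            candidates = sorted(ROTAMER_LIBRARY.get(spec.mut_three, [((), 1.0)]),
                                key=lambda e: (-e[1], e[0]))
        scored = []
        for chis, prob in candidates:
            side = build_side_chain(spec.mut_three, backbone, chis)
            heavy = [(n, x, e) for n, x, e in side if e != "H"]
            n_clash, overlap = _clash_score(
                np.array([x for _n, x, _e in heavy]).reshape(-1, 3),
                [e for _n, _x, e in heavy], env_xyz, env_radii)
            scored.append((n_clash, overlap, chis, prob, side))
            if n_clash == 0:
                break
        n_clash, overlap, chis, prob, side = min(
            scored, key=lambda s: (s[0] > 0, -s[3], s[1], s[2]))
        if n_clash > 0:
            warnings.warn(
                f"no clash-free rotamer for {spec.mut_three} at protomer {pi} "
                f"residue {spec.residue_number}; using lowest-clash rotamer "
                f"({n_clash} contacts)", stacklevel=2)
        # rebuild the residue: backbone atoms kept verbatim, new side chain appended
        kept = [a for a in res_atoms if a.name in BACKBONE_NAMES]
        new_atoms: list[AtomRecord] = []
        for a in kept:
            b = a.copy()
            b.residue_name = spec.mut_three
            new_atoms.append(b)
        serial = max(a.serial for a in prot.atoms)
        for name, xyz, el in side:
            serial += 1
            new_atoms.append(AtomRecord(
                serial=serial, name=name, element=el, residue_name=spec.mut_three,
                chain_id=prot.chain_id, residue_number=spec.residue_number,
                insertion_code=res_atoms[0].insertion_code, coordinates=np.array(xyz)))
        rebuilt = []
        inserted = False
        for a in prot.atoms:
            if a.residue_key == res_atoms[0].residue_key:
                if not inserted:
                    rebuilt.extend(new_atoms)
                    inserted = True
                continue
            rebuilt.append(a)
        prot.atoms = rebuilt
        choices[pi] = RotamerChoice(tuple(chis), prob, clash_free=(n_clash == 0))
    return out, choices


def _free_sidechain_mask(assembly: Assembly, centers_xyz: np.ndarray, radius: float):
    """Side-chain atoms of residues with any atom within ``radius`` of a center."""
    atoms = list(assembly.atoms())
    xyz = np.array([a.coordinates for a in atoms])
    tree = cKDTree(xyz)
    near = set()
    for c in centers_xyz:
        near.update(tree.query_ball_point(c, radius))
    near_res = {(atoms[i].chain_id, atoms[i].residue_key) for i in near}
    mask = np.zeros(len(atoms), bool)
    for i, a in enumerate(atoms):
        if (a.chain_id, a.residue_key) in near_res and a.name not in BACKBONE_NAMES:
            mask[i] = True
    return mask


def relax_environment(
    assembly: Assembly,
    center: tuple[str, int],
    radius: float = 5.0,
    model=None,
    max_steps: int = 100,
) -> Assembly:
    """MM-relax side chains within ``radius`` of the addressed residue.

    ``center`` is (chain_id, residue_number). Atoms outside the radius are
    fixed; backbone atoms are always fixed; radius 0 relaxes only the
    addressed residue's own side chain. Energy is non-increasing.
    """
    from .energetics import EnergyModel, minimize_mm

    if model is None:
        model = EnergyModel()
    chain_id, resnum = center
    prot = next((p for p in assembly.protomers if p.chain_id == chain_id), None)
    if prot is None:
        raise KeyError(f"no protomer with chain id {chain_id}")
    res_atoms = prot.residue(resnum)
    if not res_atoms:
        raise KeyError(f"no residue {resnum} in chain {chain_id}")
    centers = np.array([a.coordinates for a in res_atoms])
    mask = _free_sidechain_mask(assembly, centers, radius)
    # the addressed residue's own side chain is always free
    for i, a in enumerate(assembly.atoms()):
        if a.chain_id == chain_id and a.residue_key == res_atoms[0].residue_key \
                and a.name not in BACKBONE_NAMES:
            mask[i] = True
    if not mask.any():
        return assembly.copy()
    relaxed, _info = minimize_mm(model, assembly, rmsd_cap=None, max_steps=max_steps,
                                 free_mask=mask)
    return relaxed


def relax_sites(
    assembly: Assembly,
    spec: MutationSpec,
    model,
    radius: float = 4.0,
    max_steps: int = 300,
    rmsd_cap: float | None = 0.3,
) -> Assembly:
    """Relax side chains around the scanned position in every protomer at once.

    Used by the composition scan so that every composition (all-WT included)
    gets the identical relaxation treatment. The heavy-atom displacement cap
    (default 0.3 A, the same threshold used when refining the reference
    structure) keeps every composition near its placed geometry instead of
    wandering to unrelated local minima.
    """
    from .energetics import minimize_mm

    centers = []
    for prot in assembly.protomers:
        centers.extend(a.coordinates for a in prot.residue(spec.residue_number))
    if not centers:
        return assembly.copy()
    mask = _free_sidechain_mask(assembly, np.array(centers), radius)
    if not mask.any():
        return assembly.copy()
    relaxed, _info = minimize_mm(model, assembly, rmsd_cap=rmsd_cap,
                                 max_steps=max_steps, free_mask=mask)
    return relaxed
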