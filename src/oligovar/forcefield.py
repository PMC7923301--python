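"""Compact polar-hydrogen protein force field.

A transparent fixed-charge parameter set written for this package: apolar
hydrogens are implicit (united into their carbons), polar hydrogens are
explicit, and per-residue side-chain charges sum exactly to the residue's
formal charge at pH 7.5. Lennard-Jones parameters are element-based,
generalized-Born intrinsic radii follow the usual mbondi-style element
values, and bonded terms are harmonic bonds and angles with ideal values
taken from standard peptide geometry. The set is intentionally small and
auditable; it is an approximate comparative index generator, not a
quantitative free-energy force field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Assembly

__all__ = [
    "ParamSet",
    "ParameterizationError",
    "parameterize",
    "COULOMB_CONSTANT",
    "KT_298_KCAL",
    "VDW_RADII",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

# electrostatic constant in kcal*A/(mol*e^2) and kT at 298 K in kcal/mol
COULOMB_CONSTANT = 332.0637
KT_298_KCAL = 0.0019872041 * 298.0


class ParameterizationError(ValueError):
    """A residue has no parameters; message names the residue."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Lennard-Jones: rmin/2 (A) and epsilon (kcal/mol) per element
VDW_RADII = {"C": 1.908, "N": 1.824, "O": 1.661, "S": 2.000, "H": 0.600, "X": 0.000}
VDW_EPS = {"C": 0.086, "N": 0.170, "O": 0.210, "S": 0.250, "H": 0.0157, "X": 0.000}

# GB intrinsic radii (A), dielectric offset and HCT descreening scales
GB_RADII = {"C": 1.70, "N": 1.55, "O": 1.50, "S": 1.80, "H": 1.30, "X": 1.50}
GB_OFFSET = 0.09
GB_SCALE = {"C": 0.72, "N": 0.79, "O": 0.85, "S": 0.80, "H": 0.85, "X": 0.80}

BACKBONE_CHARGES = {"N": -0.40, "H": 0.25, "CA": 0.10, "C": 0.55, "O": -0.50, "OXT": 0.0}

# Side-chain partial charges; each residue's side chain sums to its formal charge.
SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "GLY": {},
    "ALA": {"CB": 0.0},
    "VAL": {"CB": 0.0, "CG1": 0.0, "CG2": 0.0},
    "LEU": {"CB": 0.0, "CG": 0.0, "CD1": 0.0, "CD2": 0.0},
    "ILE": {"CB": 0.0, "CG1": 0.0, "CG2": 0.0, "CD1": 0.0},
    "PRO": {"CB": 0.0, "CG": 0.0, "CD": 0.10},
    "MET": {"CB": 0.0, "CG": 0.10, "SD": -0.20, "CE": 0.10},
    "PHE": {"CB": 0.0, "CG": 0.0, "CD1": 0.0, "CD2": 0.0, "CE1": 0.0, "CE2": 0.0, "CZ": 0.0},
    "SER": {"CB": 0.20, "OG": -0.60, "HG": 0.40},
    "THR": {"CB": 0.20, "OG1": -0.60, "HG1": 0.40, "CG2": 0.0},
    "CYS": {"CB": 0.10, "SG": -0.40, "HG": 0.30},
    "TYR": {"CB": 0.0, "CG": 0.0, "CD1": 0.0, "CD2": 0.0, "CE1": 0.0, "CE2": 0.0,
            "CZ": 0.15, "OH": -0.55, "HH": 0.40},
    "TRP": {"CB": 0.0, "CG": 0.0, "CD1": 0.0, "CD2": 0.0, "NE1": -0.35, "HE1": 0.35,
            "CE2": 0.0, "CE3": 0.0, "CZ2": 0.0, "CZ3": 0.0, "CH2": 0.0},
    "ASN": {"CB": 0.0, "CG": 0.55, "OD1": -0.55, "ND2": -0.60, "HD21": 0.30, "HD22": 0.30},
    "GLN": {"CB": 0.0, "CG": 0.0, "CD": 0.55, "OE1": -0.55, "NE2": -0.60,
            "HE21": 0.30, "HE22": 0.30},
    "ASP": {"CB": 0.0, "CG": 0.30, "OD1": -0.65, "OD2": -0.65},
    "GLU": {"CB": 0.0, "CG": 0.0, "CD": 0.30, "OE1": -0.65, "OE2": -0.65},
    "LYS": {"CB": 0.0, "CG": 0.0, "CD": 0.0, "CE": 0.20, "NZ": -0.30,
            "HZ1": 1.1 / 3, "HZ2": 1.1 / 3, "HZ3": 1.1 / 3},
    "ARG": {"CB": 0.0, "CG": 0.0, "CD": 0.10, "NE": -0.40, "HE": 0.30, "CZ": 0.50,
            "NH1": -0.45, "NH2": -0.45, "HH11": 0.35, "HH12": 0.35, "HH21": 0.35, "HH22": 0.35},
    "HIS": {"CB": 0.0, "CG": 0.10, "ND1": -0.40, "HD1": 0.30, "CD2": 0.10,
            "CE1": 0.30, "NE2": -0.40, "HE2": 0.30},
    "HOH": {"O": -0.834, "H1": 0.417, "H2": 0.417},
    "WAT": {"O": -0.834, "H1": 0.417, "H2": 0.417},
}

_CC = 1.525
# Side-chain bonds with ideal lengths (A); polar-H bonds included.
SIDECHAIN_BONDS: dict[str, list[tuple[str, str, float]]] = {
    "GLY": [],
    "ALA": [("CA", "CB", 1.53)],
    "VAL": [("CA", "CB", 1.54), ("CB", "CG1", _CC), ("CB", "CG2", _CC)],
    "LEU": [("CA", "CB", 1.53), ("CB", "CG", _CC), ("CG", "CD1", _CC), ("CG", "CD2", _CC)],
    "ILE": [("CA", "CB", 1.54), ("CB", "CG1", _CC), ("CB", "CG2", _CC), ("CG1", "CD1", _CC)],
    "PRO": [("CA", "CB", 1.53), ("CB", "CG", _CC), ("CG", "CD", _CC), ("CD", "N", 1.47)],
    "MET": [("CA", "CB", 1.53), ("CB", "CG", _CC), ("CG", "SD", 1.81), ("SD", "CE", 1.79)],
    "PHE": [("CA", "CB", 1.53), ("CB", "CG", 1.51), ("CG", "CD1", 1.39), ("CG", "CD2", 1.39),
            ("CD1", "CE1", 1.39), ("CD2", "CE2", 1.39), ("CE1", "CZ", 1.39), ("CE2", "CZ", 1.39)],
    "SER": [("CA", "CB", 1.53), ("CB", "OG", 1.41), ("OG", "HG", 0.96)],
    "THR": [("CA", "CB", 1.54), ("CB", "OG1", 1.41), ("OG1", "HG1", 0.96), ("CB", "CG2", _CC)],
    "CYS": [("CA", "CB", 1.53), ("CB", "SG", 1.81), ("SG", "HG", 1.34)],
    "TYR": [("CA", "CB", 1.53), ("CB", "CG", 1.51), ("CG", "CD1", 1.39), ("CG", "CD2", 1.39),
            ("CD1", "CE1", 1.39), ("CD2", "CE2", 1.39), ("CE1", "CZ", 1.39), ("CE2", "CZ", 1.39),
            ("CZ", "OH", 1.36), ("OH", "HH", 0.96)],
    "TRP": [("CA", "CB", 1.53), ("CB", "CG", 1.50), ("CG", "CD1", 1.37), ("CG", "CD2", 1.43),
            ("CD1", "NE1", 1.38), ("NE1", "HE1", 1.01), ("NE1", "CE2", 1.37),
            ("CD2", "CE2", 1.41), ("CD2", "CE3", 1.40), ("CE3", "CZ3", 1.39),
            ("CZ3", "CH2", 1.39), ("CH2", "CZ2", 1.39), ("CZ2", "CE2", 1.39)],
    "ASN": [("CA", "CB", 1.53), ("CB", "CG", 1.52), ("CG", "OD1", 1.23), ("CG", "ND2", 1.33),
            ("ND2", "HD21", 1.01), ("ND2", "HD22", 1.01)],
    "GLN": [("CA", "CB", 1.53), ("CB", "CG", _CC), ("CG", "CD", 1.52), ("CD", "OE1", 1.23),
            ("CD", "NE2", 1.33), ("NE2", "HE21", 1.01), ("NE2", "HE22", 1.01)],
    "ASP": [("CA", "CB", 1.53), ("CB", "CG", 1.52), ("CG", "OD1", 1.25), ("CG", "OD2", 1.25)],
    "GLU": [("CA", "CB", 1.53), ("CB", "CG", _CC), ("CG", "CD", 1.52), ("CD", "OE1", 1.25),
            ("CD", "OE2", 1.25)],
    "LYS": [("CA", "CB", 1.53), ("CB", "CG", _CC), ("CG", "CD", _CC), ("CD", "CE", _CC),
            ("CE", "NZ", 1.49), ("NZ", "HZ1", 1.01), ("NZ", "HZ2", 1.01), ("NZ", "HZ3", 1.01)],
    "ARG": [("CA", "CB", 1.53), ("CB", "CG", _CC), ("CG", "CD", _CC), ("CD", "NE", 1.46),
            ("NE", "HE", 1.01), ("NE", "CZ", 1.33), ("CZ", "NH1", 1.33), ("CZ", "NH2", 1.33),
            ("NH1", "HH11", 1.01), ("NH1", "HH12", 1.01), ("NH2", "HH21", 1.01),
            ("NH2", "HH22", 1.01)],
    "HIS": [("CA", "CB", 1.53), ("CB", "CG", 1.50), ("CG", "ND1", 1.38), ("ND1", "CE1", 1.32),
            ("CE1", "NE2", 1.32), ("NE2", "CD2", 1.37), ("CD2", "CG", 1.36),
            ("ND1", "HD1", 1.01), ("NE2", "HE2", 1.01)],
    "HOH": [("O", "H1", 0.96), ("O", "H2", 0.96)],
    "WAT": [("O", "H1", 0.96), ("O", "H2", 0.96)],
}

BACKBONE_BONDS = [("N", "H", 1.01), ("N", "CA", 1.458), ("CA", "C", 1.524), ("C", "O", 1.229)]
PEPTIDE_BOND_LENGTH = 1.335

# atoms treated as sp2 centers (ideal angle 120 deg); everything else 109.47
_SP2_BACKBONE = {"C", "N"}
SP2_SIDECHAIN: dict[str, set[str]] = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "ASP": {"CG"},
    "GLU": {"CD"},
    "ASN": {"CG", "ND2"},
    "GLN": {"CD", "NE2"},
    "ARG": {"NE", "CZ", "NH1", "NH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

BOND_K = 300.0     # kcal/mol/A^2
ANGLE_K = 60.0     # kcal/mol/rad^2
SCALE_14 = 0.5

TOY_RESIDUE = "CHG"  # bare point-charge residues (toy systems / PQR-style input)


@dataclass
class ParamSet:
    """Flattened per-atom and bonded parameters for one assembly."""

    charges: np.ndarray          # (n,) e
    lj_rmin2: np.ndarray         # (n,) A, rmin/2
    lj_eps: np.ndarray           # (n,) kcal/mol
    gb_radii: np.ndarray         # (n,) A, intrinsic
    gb_scale: np.ndarray         # (n,)
    bonds: np.ndarray            # (nb, 2) int indices
    bond_r0: np.ndarray          # (nb,)
    angles: np.ndarray           # (na, 3) int indices (i, center, k)
    angle_theta0: np.ndarray     # (na,) rad
    exclusions: np.ndarray       # (n, n) bool: fully excluded pairs (1-2, 1-3, self)
    scale_matrix: np.ndarray     # (n, n) float: 0 excluded, SCALE_14, or 1
    heavy_mask: np.ndarray       # (n,) bool
    provenance: dict | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


def _residue_charge(res_name: str, atom_name: str, atom_names: set[str], explicit) -> float:
    if explicit is not None:
        return float(explicit)
    if atom_name in BACKBONE_CHARGES and res_name not in ("HOH", "WAT"):
        if res_name == "PRO" and atom_name == "N":
            return -0.25  # no amide H on proline; CD(+0.10) closes the ring charge
        return BACKBONE_CHARGES[atom_name]
    side = SIDECHAIN_CHARGES.get(res_name)
    if side is None:
        raise ParameterizationError(f"no parameters for residue {res_name}")
    q = side.get(atom_name, 0.0)
    # protonation-state adjustments read off the atoms actually present
    if res_name == "CYS" and atom_name == "SG" and "HG" not in atom_names:
        return -0.10  # disulfide / deprotonated templates stay neutral with CB
    if res_name == "HIS" and atom_name in ("ND1", "NE2"):
        if "HD1" in atom_names and "HE2" in atom_names:
            return -0.05  # doubly protonated His: +1 overall
    return q


def parameterize(assembly: Assembly) -> ParamSet:
    """Assign charges, LJ, GB and bonded parameters for every atom.

    Unknown residues raise :class:`ParameterizationError`. Atoms with an
    explicit ``charge`` attribute (toy systems, PQR input) keep it verbatim
    and get no bonded terms.
    """
    atoms = list(assembly.atoms())
    n = len(atoms)
    q = np.zeros(n)
    rmin2 = np.zeros(n)
    eps = np.zeros(n)
    gbr = np.zeros(n)
    gbs = np.zeros(n)
    heavy = np.zeros(n, dtype=bool)

    # group atoms by (protomer, residue) preserving order
    index_of = {}
    residues: list[tuple[str, list[int]]] = []
    offset = 0
    for prot in assembly.protomers:
        current_key = None
        for a in prot.atoms:
            i = offset
            offset += 1
            index_of[id(a)] = i
            rkey = (prot.chain_id, a.residue_key)
            if rkey != current_key:
                residues.append((a.residue_name, []))
                current_key = rkey
            residues[-1][1].append(i)

    flat = atoms
    for res_name, idxs in residues:
        names = {flat[i].name for i in idxs}
        for i in idxs:
            a = flat[i]
            el = a.element.upper()
            if a.charge is not None or res_name == TOY_RESIDUE:
                q[i] = a.charge if a.charge is not None else 0.0
                el = el if el in VDW_RADII else "X"
            else:
                if res_name not in SIDECHAIN_CHARGES:
                    raise ParameterizationError(f"no parameters for residue {res_name}")
                q[i] = _residue_charge(res_name, a.name, names, None)
                if el not in VDW_RADII:
                    el = "C"
            rmin2[i] = VDW_RADII.get(el, VDW_RADII["C"])
            eps[i] = VDW_EPS.get(el, VDW_EPS["C"])
            gbr[i] = GB_RADII.get(el, GB_RADII["C"])
            gbs[i] = GB_SCALE.get(el, GB_SCALE["C"])
            heavy[i] = el != "H"

    # bonded terms
    bonds: list[tuple[int, int, float]] = []
    offset = 0
    for prot in assembly.protomers:
        # index atoms of this protomer by (residue_key, name)
        lookup: dict[tuple[tuple[int, str], str], int] = {}
        order: list[tuple[int, str]] = []
        for k, a in enumerate(prot.atoms):
            lookup[(a.residue_key, a.name)] = offset + k
            if not order or order[-1] != a.residue_key:
                order.append(a.residue_key)
        res_names = {a.residue_key: a.residue_name for a in prot.atoms}
        for rkey in order:
            rname = res_names[rkey]
            if rname == TOY_RESIDUE:
                continue
            templ = []
            if rname not in ("HOH", "WAT"):
                templ += BACKBONE_BONDS
            templ += SIDECHAIN_BONDS.get(rname, [])
            for a1, a2, r0 in templ:
                i = lookup.get((rkey, a1))
                j = lookup.get((rkey, a2))
                if i is not None and j is not None:
                    bonds.append((i, j, r0))
        # peptide bonds between consecutive residues (by geometry: C-N < 1.8 A)
        for r1, r2 in zip(order[:-1], order[1:]):
            i = lookup.get((r1, "C"))
            j = lookup.get((r2, "N"))
            if i is not None and j is not None:
                d = np.linalg.norm(flat[i].coordinates - flat[j].coordinates)
                if d < 1.8:
                    bonds.append((i, j, PEPTIDE_BOND_LENGTH))
        offset += len(prot.atoms)

    # disulfides: SG-SG < 2.5 A anywhere in the assembly
    sgs = [i for i, a in enumerate(flat) if a.residue_name == "CYS" and a.name == "SG"]
    for ii in range(len(sgs)):
        for jj in range(ii + 1, len(sgs)):
            i, j = sgs[ii], sgs[jj]
            if np.linalg.norm(flat[i].coordinates - flat[j].coordinates) < 2.5:
                bonds.append((i, j, 2.04))

    bond_idx = np.array([(i, j) for i, j, _ in bonds], dtype=int).reshape(-1, 2)
    bond_r0 = np.array([r0 for _, _, r0 in bonds], dtype=float)

    # angle list from the bond graph
    neigh: dict[int, list[int]] = {}
    for i, j in bond_idx:
        neigh.setdefault(int(i), []).append(int(j))
        neigh.setdefault(int(j), []).append(int(i))
    angles = []
    theta0 = []
    for c, nbrs in neigh.items():
        ac = flat[c]
        sp2 = (ac.name in _SP2_BACKBONE and ac.residue_name not in ("HOH", "WAT")) or (
            ac.name in SP2_SIDECHAIN.get(ac.residue_name, set())
        )
        t0 = np.deg2rad(120.0 if sp2 else 109.47)
        if ac.residue_name in ("HOH", "WAT"):
            t0 = np.deg2rad(104.5)
        nbrs_sorted = sorted(nbrs)
        for x in range(len(nbrs_sorted)):
            for y in range(x + 1, len(nbrs_sorted)):
                angles.append((nbrs_sorted[x], c, nbrs_sorted[y]))
                theta0.append(t0)
    angle_idx = np.array(angles, dtype=int).reshape(-1, 3)
    angle_t0 = np.array(theta0, dtype=float)

    # exclusion / scaling matrices
    excl = np.eye(n, dtype=bool)
    scale = np.ones((n, n))
    np.fill_diagonal(scale, 0.0)
    for i, j in bond_idx:
        excl[i, j] = excl[j, i] = True
        scale[i, j] = scale[j, i] = 0.0
    for i, c, k in angle_idx:
        excl[i, k] = excl[k, i] = True
        scale[i, k] = scale[k, i] = 0.0
    # 1-4: neighbors of angle ends through one more bond
    for i, c, k in angle_idx:
        for end, other in ((i, k), (k, i)):
            for m in neigh.get(int(other), []):
                if m != int(c) and m != int(end) and not excl[int(end), m]:
                    scale[int(end), m] = scale[m, int(end)] = SCALE_14

    return ParamSet(
        charges=q, lj_rmin2=rmin2, lj_eps=eps, gb_radii=gbr, gb_scale=gbs,
        bonds=bond_idx, bond_r0=bond_r0, angles=angle_idx, angle_theta0=angle_t0,
        exclusions=excl, scale_matrix=scale, heavy_mask=heavy,
        provenance={"force_field": "oligovar polar-hydrogen set v1",
                    "gb_model": "HCT pairwise descreening", "coulomb_constant": COULOMB_CONSTANT},
    )
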