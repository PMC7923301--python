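"""Internal-coordinate construction of peptides and side chains.

Backbones are grown by NeRF from ideal peptide geometry (bond lengths and
angles of the trans peptide unit); side chains are grown from per-residue
internal-coordinate templates whose rotatable torsions are the familiar
chi angles. The same machinery serves three purposes: generating synthetic
test assemblies, replacing side chains during point mutagenesis, and
building the extended Gly-X-Gly unfolded-state reference peptides.

The rotamer library is a compact backbone-independent table of canonical
gauche/trans chi combinations with approximate population frequencies;
"most probable rotamer" selection only needs the frequency ordering, not
calibrated probabilities.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom
from .structure import AtomRecord, Protomer

__all__ = [
    "SIDECHAIN_TEMPLATES",
    "ROTAMER_LIBRARY",
    "BUILDABLE_RESIDUES",
    "build_peptide",
    "build_side_chain",
    "default_chis",
]

# torsion spec: float = fixed torsion (deg); ("chi", k, offset) = chi_k + offset
_C = "chi"
SIDECHAIN_TEMPLATES: dict[str, list] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.41, 110.5, (_C, 1, 0.0)),
            ("HG", ("CA", "CB", "OG"), 0.96, 109.5, (_C, 2, 0.0))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 114.0, (_C, 1, 0.0)),
            ("HG", ("CA", "CB", "SG"), 1.34, 96.0, (_C, 2, 0.0))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.525, 110.5, (_C, 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.525, 110.5, (_C, 1, 122.6))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.41, 109.5, (_C, 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.525, 110.5, (_C, 1, -120.0)),
            ("HG1", ("CA", "CB", "OG1"), 0.96, 109.5, 180.0)],
    "LEU": [("CG", ("N", "CA", "CB"), 1.53, 116.3, (_C, 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.525, 110.5, (_C, 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.525, 110.5, (_C, 2, 122.6))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.53, 110.5, (_C, 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.525, 110.5, (_C, 1, -122.6)),
            ("CD1", ("CA", "CB", "CG1"), 1.525, 113.0, (_C, 2, 0.0))],
    "MET": [("CG", ("N", "CA", "CB"), 1.53, 114.0, (_C, 1, 0.0)),
            ("SD", ("CA", "CB", "CG"), 1.81, 112.7, (_C, 2, 0.0)),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.2, (_C, 3, 0.0))],
    "ASP": [("CG", ("N", "CA", "CB"), 1.52, 112.6, (_C, 1, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, (_C, 2, 0.0)),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, (_C, 2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.52, 112.6, (_C, 1, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, (_C, 2, 0.0)),
            ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, (_C, 2, 180.0)),
            ("HD21", ("CB", "CG", "ND2"), 1.01, 120.0, 0.0),
            ("HD22", ("CB", "CG", "ND2"), 1.01, 120.0, 180.0)],
    "GLU": [("CG", ("N", "CA", "CB"), 1.525, 114.0, (_C, 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, (_C, 2, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, (_C, 3, 0.0)),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, (_C, 3, 180.0))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.525, 114.0, (_C, 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, (_C, 2, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, (_C, 3, 0.0)),
            ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, (_C, 3, 180.0)),
            ("HE21", ("CG", "CD", "NE2"), 1.01, 120.0, 0.0),
            ("HE22", ("CG", "CD", "NE2"), 1.01, 120.0, 180.0)],
    "LYS": [("CG", ("N", "CA", "CB"), 1.525, 114.0, (_C, 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.525, 111.3, (_C, 2, 0.0)),
            ("CE", ("CB", "CG", "CD"), 1.525, 111.3, (_C, 3, 0.0)),
            ("NZ", ("CG", "CD", "CE"), 1.49, 111.0, (_C, 4, 0.0)),
            ("HZ1", ("CD", "CE", "NZ"), 1.01, 109.5, 60.0),
            ("HZ2", ("CD", "CE", "NZ"), 1.01, 109.5, 180.0),
            ("HZ3", ("CD", "CE", "NZ"), 1.01, 109.5, -60.0)],
    "ARG": [("CG", ("N", "CA", "CB"), 1.525, 114.0, (_C, 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.525, 111.3, (_C, 2, 0.0)),
            ("NE", ("CB", "CG", "CD"), 1.46, 112.0, (_C, 3, 0.0)),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, (_C, 4, 0.0)),
            ("HE", ("CG", "CD", "NE"), 1.01, 118.0, (_C, 4, 180.0)),
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
            ("HH11", ("NE", "CZ", "NH1"), 1.01, 120.0, 0.0),
            ("HH12", ("NE", "CZ", "NH1"), 1.01, 120.0, 180.0),
            ("HH21", ("NE", "CZ", "NH2"), 1.01, 120.0, 0.0),
            ("HH22", ("NE", "CZ", "NH2"), 1.01, 120.0, 180.0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.50, 113.8, (_C, 1, 0.0)),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, (_C, 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.36, 129.7, (_C, 2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 109.3, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0),
            ("HE2", ("CG", "CD2", "NE2"), 1.01, 125.5, 180.0)],
    "PHE": [("CG", ("N", "CA", "CB"), 1.51, 113.8, (_C, 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, (_C, 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, (_C, 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.51, 113.8, (_C, 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, (_C, 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, (_C, 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.36, 120.0, 180.0),
            ("HH", ("CE1", "CZ", "OH"), 0.96, 109.0, 180.0)],
}

BUILDABLE_RESIDUES = frozenset(SIDECHAIN_TEMPLATES)

# (chi tuple, frequency); most frequent first is not required, selection sorts.
ROTAMER_LIBRARY: dict[str, list[tuple[tuple[float, ...], float]]] = {
    "GLY": [((), 1.0)],
    "ALA": [((), 1.0)],
    "SER": [((-60.0, 180.0), 0.45), ((60.0, 180.0), 0.30), ((180.0, 180.0), 0.25)],
    "CYS": [((-60.0, 180.0), 0.50), ((180.0, 180.0), 0.30), ((60.0, 180.0), 0.20)],
    "VAL": [((180.0,), 0.73), ((-60.0,), 0.20), ((60.0,), 0.07)],
    "THR": [((60.0,), 0.49), ((-60.0,), 0.43), ((180.0,), 0.08)],
    "LEU": [((-60.0, 180.0), 0.59), ((180.0, 60.0), 0.29), ((-60.0, 60.0), 0.07),
            ((180.0, 180.0), 0.05)],
    "ILE": [((-60.0, 180.0), 0.60), ((-60.0, -60.0), 0.15), ((180.0, 180.0), 0.15),
            ((60.0, 180.0), 0.10)],
    "MET": [((-60.0, 180.0, 180.0), 0.30), ((-60.0, -60.0, -60.0), 0.20),
            ((180.0, 180.0, 180.0), 0.25), ((-60.0, 180.0, -60.0), 0.15),
            ((180.0, 60.0, 180.0), 0.10)],
    "ASP": [((-60.0, -15.0), 0.45), ((180.0, 15.0), 0.35), ((60.0, -15.0), 0.20)],
    "ASN": [((-60.0, -20.0), 0.45), ((180.0, 30.0), 0.35), ((60.0, -20.0), 0.20)],
    "GLU": [((-60.0, 180.0, -10.0), 0.26), ((180.0, 180.0, -10.0), 0.22),
            ((-60.0, -60.0, -10.0), 0.17), ((180.0, 60.0, 0.0), 0.12),
            ((-60.0, 60.0, -10.0), 0.13), ((60.0, 180.0, 0.0), 0.10)],
    "GLN": [((-60.0, 180.0, 0.0), 0.25), ((180.0, 180.0, 0.0), 0.20),
            ((-60.0, -60.0, -40.0), 0.17), ((180.0, 60.0, 0.0), 0.13),
            ((-60.0, 60.0, 30.0), 0.14), ((60.0, 180.0, 0.0), 0.11)],
    "LYS": [((-60.0, 180.0, 180.0, 180.0), 0.35), ((180.0, 180.0, 180.0, 180.0), 0.30),
            ((-60.0, -60.0, 180.0, 180.0), 0.15), ((180.0, 60.0, 180.0, 180.0), 0.10),
            ((60.0, 180.0, 180.0, 180.0), 0.10)],
    "ARG": [((-60.0, 180.0, 180.0, 180.0), 0.30), ((180.0, 180.0, 180.0, 180.0), 0.25),
            ((-60.0, -60.0, 180.0, 180.0), 0.18), ((180.0, 60.0, 180.0, 180.0), 0.14),
            ((60.0, 180.0, 180.0, 180.0), 0.13)],
    "HIS": [((-60.0, -75.0), 0.35), ((180.0, -75.0), 0.30), ((-60.0, 75.0), 0.20),
            ((60.0, 75.0), 0.15)],
    "PHE": [((-60.0, 90.0), 0.44), ((180.0, 80.0), 0.33), ((60.0, 90.0), 0.23)],
    "TYR": [((-60.0, 90.0), 0.44), ((180.0, 80.0), 0.33), ((60.0, 90.0), 0.23)],
}

# ideal trans-peptide geometry
_B = {"N-CA": 1.458, "CA-C": 1.524, "C-N": 1.335, "C-O": 1.229, "N-H": 1.01, "CA-CB": 1.53}
_A = {"N-CA-C": 111.1, "CA-C-N": 116.6, "C-N-CA": 121.9, "CA-C-O": 120.5,
      "C-N-H": 119.0, "N-CA-CB": 110.5}
_CB_TORSION = 122.68  # dihedral C-N-CA-CB for an L-amino acid


def default_chis(res_name: str) -> tuple[float, ...]:
    lib = ROTAMER_LIBRARY.get(res_name)
    if not lib:
        return ()
    return max(lib, key=lambda e: e[1])[0]


def _chi_value(spec, chis: tuple[float, ...]) -> float:
    if isinstance(spec, tuple):
        _, k, off = spec
        base = chis[k - 1] if k - 1 < len(chis) else 180.0
        return base + off
    return float(spec)


def build_side_chain(
    res_name: str,
    backbone: dict[str, np.ndarray],
    chis: tuple[float, ...] | None = None,
) -> list[tuple[str, np.ndarray, str]]:
    """Construct side-chain atoms (name, xyz, element) from N/CA/C positions.

    ``backbone`` must contain N, CA and C. Returns CB plus template atoms;
    GLY returns an empty list.
    """
    if res_name not in SIDECHAIN_TEMPLATES:
        raise ValueError(f"no side-chain template for residue {res_name}")
    if res_name == "GLY":
        return []
    if chis is None:
        chis = default_chis(res_name)
    pos = dict(backbone)
    out = []
    cb = place_atom(pos["C"], pos["N"], pos["CA"], _B["CA-CB"], _A["N-CA-CB"], _CB_TORSION)
    pos["CB"] = cb
    out.append(("CB", cb, "C"))
    for name, (a, b, c), r, theta, tors in SIDECHAIN_TEMPLATES[res_name]:
        xyz = place_atom(pos[a], pos[b], pos[c], r, theta, _chi_value(tors, chis))
        pos[name] = xyz
        out.append((name, xyz, name.lstrip("0123456789")[0]))
    return out


def build_peptide(
    sequence: list[str],
    phi: float = -57.0,
    psi: float = -47.0,
    omega: float = 180.0,
    chain_id: str = "A",
    first_residue_number: int = 1,
    chis: dict[int, tuple[float, ...]] | None = None,
    origin: np.ndarray | None = None,
) -> Protomer:
    """Build an ideal-geometry peptide (3-letter code sequence) with side chains.

    ``chis`` optionally overrides chi angles per residue index (0-based);
    otherwise each residue gets its most probable rotamer. Backbone amide
    hydrogens are included from the second residue on.
    """
    seq = list(sequence)
    n_res = len(seq)
    bb: list[dict[str, np.ndarray]] = []
    # seed frame
    N0 = np.zeros(3)
    CA0 = np.array([_B["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_A["N-CA-C"])
    C0 = CA0 + _B["CA-C"] * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    bb.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n_res):
        prev = bb[-1]
        N = place_atom(prev["N"], prev["CA"], prev["C"], _B["C-N"], _A["CA-C-N"], psi)
        CA = place_atom(prev["CA"], prev["C"], N, _B["N-CA"], _A["C-N-CA"], omega)
        C = place_atom(prev["C"], N, CA, _B["CA-C"], _A["N-CA-C"], phi)
        bb.append({"N": N, "CA": CA, "C": C})
    atoms: list[AtomRecord] = []
    serial = 0
    for i, res in enumerate(seq):
        frame = bb[i]
        res_atoms: list[tuple[str, np.ndarray, str]] = [
            ("N", frame["N"], "N"), ("CA", frame["CA"], "C"), ("C", frame["C"], "C")]
        # carbonyl O anti to the next N (or from psi for the last residue)
        if i + 1 < n_res:
            nxt = bb[i + 1]["N"]
            v1 = frame["CA"] - frame["C"]
            v2 = nxt - frame["C"]
            bisec = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
            O = frame["C"] - _B["C-O"] * bisec / np.linalg.norm(bisec)
        else:
            O = place_atom(frame["N"], frame["CA"], frame["C"], _B["C-O"], _A["CA-C-O"],
                           psi + 180.0)
        res_atoms.append(("O", O, "O"))
        if i > 0 and res != "PRO":
            prev = bb[i - 1]
            H = place_atom(prev["CA"], prev["C"], frame["N"], _B["N-H"], _A["C-N-H"], 0.0)
            res_atoms.append(("H", H, "H"))
        chi = (chis or {}).get(i)
        res_atoms.extend(build_side_chain(res, frame, chi))
        for name, xyz, el in res_atoms:
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=name, element=el, residue_name=res,
                chain_id=chain_id, residue_number=first_residue_number + i,
                insertion_code="", coordinates=np.array(xyz, float)))
    prot = Protomer(chain_id, atoms)
    if origin is not None:
        xyz = prot.coords()
        prot.set_coords(xyz - xyz.mean(axis=0) + np.asarray(origin, float))
    return prot
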