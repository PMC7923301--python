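"""Structure model and PDB I/O for oligomeric assemblies.

The in-memory model is deliberately small: an :class:`Assembly` is an ordered
list of :class:`Protomer` objects (one chain each), every atom keeping its
author numbering so that a residue printed as "Q180" in the literature stays
addressable as chain + 180. Biological units are rebuilt from REMARK 350
BIOMT operators (or operators supplied explicitly), and head-to-head
double-trimer assemblies are built by rigid superposition onto a template.

Coordinate parsing is delegated to gemmi; a fixed-column validation pass runs
first so malformed coordinate lines are reported with their line number
(gemmi itself tolerates them silently). Writing uses an exact fixed-column
formatter so round-trips preserve author numbering and 3-decimal coordinates.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .geometry import kabsch, rmsd

__all__ = [
    "AtomRecord",
    "Protomer",
    "SymmetryOperator",
    "Assembly",
    "PdbParseError",
    "EmptyStructureError",
    "AssemblyArityError",
    "ClashError",
    "read_structure",
    "write_structure",
    "build_biological_unit",
    "superpose",
    "build_head_to_head",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}


class PdbParseError(ValueError):
    """A coordinate line could not be parsed; carries the 1-based line number."""


class EmptyStructureError(ValueError):
    """No protein atoms found in the file."""


class AssemblyArityError(ValueError):
    """Wrong number of symmetry operators / protomers for the requested assembly."""


class ClashError(ValueError):
    """Two placed units overlap; message names the offending atom pair."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    coordinates: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    charge: float | None = None  # explicit point charge (PQR / toy systems)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol must be non-empty")

    def copy(self) -> "AtomRecord":
        return dataclasses.replace(self, coordinates=self.coordinates.copy())

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def residue_key(self) -> tuple[int, str]:
        return (self.residue_number, self.insertion_code)


@dataclass
class Protomer:
    chain_id: str
    atoms: list[AtomRecord]
    source: str = "asymmetric unit"  # | "symmetry copy" | "superposed copy"

    def coords(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        for a, x in zip(self.atoms, np.asarray(xyz, float)):
            a.coordinates = np.array(x, dtype=float)

    def copy(self) -> "Protomer":
        return Protomer(self.chain_id, [a.copy() for a in self.atoms], self.source)

    def residues(self) -> dict[tuple[int, str], list[AtomRecord]]:
        out: dict[tuple[int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def residue(self, number: int, icode: str = "") -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue_key == (number, icode)]

    def atom(self, number: int, name: str, icode: str = "") -> AtomRecord:
        for a in self.atoms:
            if a.residue_key == (number, icode) and a.name == name:
                return a
        raise KeyError(f"{self.chain_id}:{number}{icode}:{name} not found")

    def relabel(self, chain_id: str) -> "Protomer":
        """Set the chain id on the protomer and every atom (in place)."""
        self.chain_id = chain_id
        for a in self.atoms:
            a.chain_id = chain_id
        return self

    def transformed(self, R: np.ndarray, t: np.ndarray, source: str | None = None) -> "Protomer":
        p = self.copy()
        p.set_coords(p.coords() @ np.asarray(R, float).T + np.asarray(t, float))
        if source is not None:
            p.source = source
        return p


@dataclass
class SymmetryOperator:
    rotation: np.ndarray
    translation: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("operator needs a 3x3 rotation and a 3-vector translation")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError(f"operator {self.label}: rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError(f"operator {self.label}: determinant must be +1 (proper rotation)")

    @classmethod
    def identity(cls, label: str = "identity") -> "SymmetryOperator":
        return cls(np.eye(3), np.zeros(3), label)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation

    def is_identity(self, atol: float = 1e-6) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=atol) and np.allclose(
            self.translation, 0.0, atol=atol
        )


@dataclass
class Assembly:
    protomers: list[Protomer]
    kind: str = "protomer"  # protomer | trimer | hexamer
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if self.kind == "trimer" and len(self.protomers) != 3:
            raise AssemblyArityError(f"trimer must have 3 protomers, got {len(self.protomers)}")
        if self.kind == "hexamer" and len(self.protomers) != 6:
            raise AssemblyArityError(f"hexamer must have 6 protomers, got {len(self.protomers)}")

    def copy(self) -> "Assembly":
        return Assembly([p.copy() for p in self.protomers], self.kind, list(self.provenance))

    def atoms(self):
        for p in self.protomers:
            yield from p.atoms

    def coords(self) -> np.ndarray:
        return np.concatenate([p.coords() for p in self.protomers], axis=0)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, float)
        i = 0
        for p in self.protomers:
            n = len(p.atoms)
            p.set_coords(xyz[i : i + n])
            i += n

    @property
    def n_atoms(self) -> int:
        return sum(len(p.atoms) for p in self.protomers)

    def subset(self, protomer_indices) -> "Assembly":
        """Sub-assembly of the given protomers, coordinates copied as-is."""
        prots = [self.protomers[i].copy() for i in protomer_indices]
        return Assembly(prots, kind="protomer", provenance=list(self.provenance))

    def trimer_groups(self) -> tuple[list[int], list[int]]:
        if self.kind != "hexamer":
            raise ValueError("trimer_groups is defined for hexamers only")
        return [0, 1, 2], [3, 4, 5]


def _infer_kind(n_chains: int) -> str:
    return {3: "trimer", 6: "hexamer"}.get(n_chains, "protomer")


def _validate_pdb_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PdbParseError(f"line {i}: coordinate record too short")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PdbParseError(
                        f"line {i}: malformed {what} coordinate field {line[lo:hi]!r}"
                    ) from None


def _parse_biomt(text: str) -> list[SymmetryOperator]:
    rows: dict[str, list[tuple[int, list[float]]]] = {}
    for line in text.splitlines():
        if line.startswith("REMARK 350") and "BIOMT" in line:
            tok = line.split()
            # REMARK 350 BIOMTn  opid  r1 r2 r3 t
            tag = tok[2]
            rownum = int(tag[-1])
            opid = tok[3]
            vals = [float(v) for v in tok[4:8]]
            rows.setdefault(opid, []).append((rownum, vals))
    ops = []
    for opid in sorted(rows, key=lambda s: int(s)):
        mat = np.zeros((3, 3))
        vec = np.zeros(3)
        for rownum, vals in rows[opid]:
            mat[rownum - 1] = vals[:3]
            vec[rownum - 1] = vals[3]
        ops.append(SymmetryOperator(mat, vec, label=f"BIOMT {opid}"))
    return ops


def read_structure(path) -> tuple[Assembly, list[SymmetryOperator]]:
    """Read a PDB file into an Assembly (one protomer per chain) + BIOMT operators.

    Author residue numbering, insertion codes, occupancies and B-factors are
    preserved. All ATOM and HETATM records of the first model are kept.
    """
    with open(path) as fh:
        text = fh.read()
    _validate_pdb_lines(text)
    ops = _parse_biomt(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model found")
    model = st[0]
    protomers: list[Protomer] = []
    for ch in model:
        atoms: list[AtomRecord] = []
        for res in ch:
            het = res.het_flag == "H"
            for at in res:
                atoms.append(
                    AtomRecord(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        chain_id=ch.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        coordinates=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                        is_hetero=het,
                    )
                )
        if atoms:
            protomers.append(Protomer(ch.name, atoms))
    n_protein = sum(1 for p in protomers for a in p.atoms if not a.is_water)
    if n_protein == 0:
        raise EmptyStructureError(f"{path}: no protein atoms")
    return Assembly(protomers, kind=_infer_kind(len(protomers))), ops


def write_structure(assembly: Assembly, path, operators: list[SymmetryOperator] | None = None) -> None:
    """Write an assembly as PDB (ATOM/HETATM/TER), optional REMARK 350 BIOMT."""
    buf = io.StringIO()
    if operators:
        buf.write("REMARK 350 BIOMOLECULE: 1\n")
        for k, op in enumerate(operators, start=1):
            for r in range(3):
                buf.write(
                    "REMARK 350   BIOMT%d %3d%10.6f%10.6f%10.6f     %10.5f\n"
                    % (r + 1, k, *op.rotation[r], op.translation[r])
                )
    serial = 0
    for prot in assembly.protomers:
        for a in prot.atoms:
            serial += 1
            rec = "HETATM" if a.is_hetero else "ATOM  "
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            buf.write(
                "%6s%5d %4s %-3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f          %2s\n"
                % (
                    rec,
                    serial % 100000,
                    name,
                    a.residue_name[:3],
                    prot.chain_id[:1] or "A",
                    a.residue_number,
                    a.insertion_code[:1] or " ",
                    a.coordinates[0],
                    a.coordinates[1],
                    a.coordinates[2],
                    a.occupancy,
                    a.b_factor,
                    a.element[:2].rjust(2),
                )
            )
        serial += 1
        buf.write("TER   %5d      %-3s %1s%4d\n" % (
            serial % 100000, prot.atoms[-1].residue_name[:3],
            prot.chain_id[:1] or "A", prot.atoms[-1].residue_number))
    buf.write("END\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


TRIMER_CHAINS = ("A", "B", "C")
HEXAMER_CHAINS = ("A", "B", "C", "D", "E", "F")


def build_biological_unit(asymmetric: Assembly, ops) -> Assembly:
    """Apply 3 symmetry operators to the asymmetric chain, producing a trimer.

    The identity must be counted among the operators. Copies are relabeled
    A, B, C and tagged as symmetry copies.
    """
    ops = list(ops)
    if len(ops) != 3:
        raise AssemblyArityError(
            f"trimer reconstruction needs exactly 3 operators (identity included), got {len(ops)}"
        )
    base = asymmetric.protomers[0]
    protomers = []
    for chain, op in zip(TRIMER_CHAINS, ops):
        p = base.transformed(op.rotation, op.translation,
                             source="asymmetric unit" if op.is_identity() else "symmetry copy")
        protomers.append(p.relabel(chain))
    return Assembly(protomers, kind="trimer", provenance=list(ops))


def _paired_coords(mobile: Protomer, reference: Protomer, atom_selection) -> tuple[np.ndarray, np.ndarray]:
    if atom_selection is None:
        atom_selection = lambda a: a.name == "CA"  # noqa: E731
    elif isinstance(atom_selection, str):
        name = atom_selection
        atom_selection = (lambda a: True) if name == "all" else (lambda a: a.name == name)
    mob = {(a.residue_key, a.name): a for a in mobile.atoms if atom_selection(a)}
    ref = {(a.residue_key, a.name): a for a in reference.atoms if atom_selection(a)}
    keys = sorted(set(mob) & set(ref))
    if len(keys) < 3:
        raise ValueError(f"underdetermined superposition: only {len(keys)} paired atoms")
    P = np.array([mob[k].coordinates for k in keys])
    Q = np.array([ref[k].coordinates for k in keys])
    return P, Q


def superpose(mobile: Protomer, reference: Protomer, atom_selection=None):
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Atoms are paired by (residue number, insertion code, atom name); default
    selection is C-alpha. Returns ``(SymmetryOperator, rmsd)``.
    """
    P, Q = _paired_coords(mobile, reference, atom_selection)
    R, t, r = kabsch(P, Q)
    return SymmetryOperator(R, t, label="superposition"), r


def build_head_to_head(
    trimer: Assembly,
    template: Assembly,
    atom_selection=None,
    clash_cutoff: float = 1.5,
) -> Assembly:
    """Build a hexamer by superposing the trimer onto each of two template units.

    ``template`` holds two protomers that define the relative head-to-head
    placement (the first protomer of the trimer is fitted to each). The two
    placed trimer copies are checked for inter-trimer heavy-atom clashes.
    """
    if len(template.protomers) < 2:
        raise ValueError("template must contain two units defining the relative placement")
    placed: list[list[Protomer]] = []
    for unit_idx in (0, 1):
        op, r = superpose(trimer.protomers[0], template.protomers[unit_idx], atom_selection)
        copy = [p.transformed(op.rotation, op.translation, source="superposed copy")
                for p in trimer.protomers]
        placed.append(copy)
    a = np.concatenate([p.coords() for p in placed[0]])
    b = np.concatenate([p.coords() for p in placed[1]])
    heavy_a = [at for p in placed[0] for at in p.atoms]
    heavy_b = [at for p in placed[1] for at in p.atoms]
    ia = [i for i, at in enumerate(heavy_a) if at.is_heavy]
    ib = [i for i, at in enumerate(heavy_b) if at.is_heavy]
    tree = cKDTree(b[ib])
    dist, j = tree.query(a[ia], k=1)
    if np.min(dist) < clash_cutoff:
        k = int(np.argmin(dist))
        at1 = heavy_a[ia[k]]
        at2 = heavy_b[ib[int(j[k])]]
        raise ClashError(
            f"inter-trimer clash: {at1.chain_id}:{at1.residue_number}:{at1.name} vs "
            f"{at2.chain_id}:{at2.residue_number}:{at2.name} at {np.min(dist):.2f} A"
        )
    protomers = []
    for chain, p in zip(HEXAMER_CHAINS, placed[0] + placed[1]):
        protomers.append(p.relabel(chain))
    return Assembly(protomers, kind="hexamer", provenance=list(trimer.provenance) + ["head-to-head superposition"])
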