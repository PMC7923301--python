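"""Synthetic assemblies with planted, analytically known structure.

Every pipeline stage is testable offline with these generators:

* ``make_c3_trimer`` - three identical poly-Ala helices in exact C3
  symmetry with one glutamine planted so its side chain points at the
  three-fold axis (a buried-polar-interface analog of a disease-linked
  oligomer interface residue). The generator verifies its own plant
  (inter-protomer contact distance) and returns the symmetry operators it
  used, so biological-unit reconstruction can be checked for closure.
* ``make_head_to_head_template`` - two protomer placements related by a
  180-degree flip and an axial separation, the template for building a
  double-trimer (head-to-head hexamer).
* ``make_point_charge_cluster`` - bare point charges with a brute-force
  pairwise Coulomb table, the oracle for the thermodynamic cycle.
* ``make_mutation_trend_pair`` - the same trimer with the planted residue
  facing the interface vs facing bulk solvent, for effect-size ordering
  checks.

Protomers are ideal helices rather than beta-sandwich mimics: the
contracts exercised downstream are topological and chemical, not
fold-specific. A single integer seed controls all randomness (coordinate
jitter), applied to the protomer *before* symmetry replication so the
trimer stays exactly C3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .builder import build_peptide
from .forcefield import COULOMB_CONSTANT
from .geometry import rotation_about_axis
from .structure import Assembly, AtomRecord, Protomer, SymmetryOperator, build_biological_unit

__all__ = [
    "FixtureSpec",
    "GenerationError",
    "make_c3_trimer",
    "make_head_to_head_template",
    "make_hexamer",
    "make_point_charge_cluster",
    "make_mutation_trend_pair",
    "make_water_probe",
    "coulomb_interaction",
]


class GenerationError(ValueError):
    """Requested fixture geometry is inconsistent (clashes or broken plant)."""


@dataclass
class FixtureSpec:
    kind: str = "c3_trimer"  # c3_trimer | head_to_head_hexamer | point_charge_cluster
    n_residues: int = 12
    interface_residue_number: int = 180
    interface_residue_name: str = "GLN"
    first_residue_number: int = 174
    radius: float = 7.5          # helix-axis distance from the C3 axis, A
    separation: float = 24.0     # trimer-trimer centroid separation, A
    jitter: float = 0.02         # per-coordinate sigma, A
    acidic_shoulder: bool = True  # Glu one turn below the plant (see _helix_protomer)
    seed: int = 0
    contact_cutoff: float = 4.5


def _plant_index(spec: FixtureSpec) -> int:
    idx = spec.interface_residue_number - spec.first_residue_number
    if not (0 <= idx < spec.n_residues):
        raise GenerationError("interface residue number outside the protomer")
    return idx


def _helix_protomer(spec: FixtureSpec, face_interface: bool = True) -> Protomer:
    """One helix along +z with the planted side chain's azimuth at 180 deg."""
    if spec.n_residues < 8:
        raise GenerationError("need at least 8 residues per protomer")
    idx = _plant_index(spec)
    seq = ["ALA"] * spec.n_residues
    seq[idx] = spec.interface_residue_name
    if spec.acidic_shoulder and idx >= 4:
        # a glutamate one helix turn below the plant, facing the same azimuth:
        # the interface already carries negative charge, so a planted charge
        # swap is repulsive from the first mutated protomer on
        seq[idx - 4] = "GLU"
    prot = build_peptide(seq, phi=-57.0, psi=-47.0, chain_id="A",
                         first_residue_number=spec.first_residue_number)
    xyz = prot.coords()
    xyz -= xyz.mean(axis=0)
    # align the helix axis (first->last CA direction) with +z
    ca = np.array([a.coordinates - prot.coords().mean(axis=0)
                   for a in prot.atoms if a.name == "CA"])
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s > 1e-12:
        ang = np.degrees(np.arctan2(s, np.dot(axis, z)))
        R = rotation_about_axis(v, ang)
        xyz = xyz @ R.T
    prot.set_coords(xyz)
    # rotate about z so the planted side-chain tip faces azimuth 180 (toward -x)
    res = prot.residue(spec.interface_residue_number)
    side = [a for a in res if a.name not in ("N", "CA", "C", "O", "H")]
    heavy_side = [a for a in side if a.is_heavy]
    tip = np.mean([a.coordinates for a in heavy_side[-2:]], axis=0) if heavy_side \
        else res[0].coordinates
    # align the tip *position* (coordinates are helix-centered here) so that
    # after radial placement it sits as close to the symmetry axis as possible
    az = np.degrees(np.arctan2(tip[1], tip[0]))
    target = 180.0 if face_interface else 0.0
    Rz = rotation_about_axis(z, target - az)
    prot.set_coords(prot.coords() @ Rz.T)
    # seeded jitter before replication keeps the trimer exactly C3
    rng = np.random.default_rng(spec.seed)
    if spec.jitter > 0:
        prot.set_coords(prot.coords() + rng.normal(scale=spec.jitter,
                                                   size=prot.coords().shape))
    # place at (radius, 0, 0)
    prot.set_coords(prot.coords() + np.array([spec.radius, 0.0, 0.0]))
    return prot


def c3_operators() -> list[SymmetryOperator]:
    z = np.array([0.0, 0.0, 1.0])
    return [
        SymmetryOperator.identity(),
        SymmetryOperator(rotation_about_axis(z, 120.0), np.zeros(3), "Rz(120)"),
        SymmetryOperator(rotation_about_axis(z, 240.0), np.zeros(3), "Rz(240)"),
    ]


def _interprotomer_stats(assembly: Assembly, residue_number: int):
    """(global min heavy-atom inter-protomer distance, planted-residue min, contacts)."""
    heavy = []
    planted = []
    for pi, prot in enumerate(assembly.protomers):
        for a in prot.atoms:
            if a.is_heavy:
                heavy.append((pi, a))
                if a.residue_number == residue_number and a.name not in ("N", "CA", "C", "O"):
                    planted.append((pi, a))
    global_min = np.inf
    plant_min = np.inf
    contacts = 0
    xyz = {pi: [] for pi in range(len(assembly.protomers))}
    for pi, a in heavy:
        xyz[pi].append(a.coordinates)
    trees = {pi: cKDTree(np.array(v)) for pi, v in xyz.items() if v}
    for pi in trees:
        for pj in trees:
            if pj <= pi:
                continue
            d, _ = trees[pj].query(np.array(xyz[pi]), k=1)
            global_min = min(global_min, float(np.min(d)))
    for pi, a in planted:
        for pj in trees:
            if pj == pi:
                continue
            d, _ = trees[pj].query(a.coordinates, k=1)
            plant_min = min(plant_min, float(d))
            if d < 4.5:
                contacts += 1
    return global_min, plant_min, contacts


def make_c3_trimer(spec: FixtureSpec | None = None, face_interface: bool = True):
    """Exact-C3 trimer with a planted interface residue; returns (Assembly, metadata).

    Raises :class:`GenerationError` when the requested geometry clashes or,
    for interface-facing plants, when the planted residue fails to touch
    both neighboring protomers within the contact cutoff.
    """
    spec = spec or FixtureSpec()
    prot = _helix_protomer(spec, face_interface=face_interface)
    ops = c3_operators()
    asym = Assembly([prot], kind="protomer")
    trimer = build_biological_unit(asym, ops)
    gmin, plant_min, contacts = _interprotomer_stats(trimer, spec.interface_residue_number)
    if gmin < 1.9:
        raise GenerationError(f"protomer clash: min inter-protomer distance {gmin:.2f} A")
    if face_interface and plant_min > spec.contact_cutoff:
        raise GenerationError(
            f"planted residue does not reach the interface ({plant_min:.2f} A)")
    meta = {
        "operators": ops,
        "planted_residue": ("A", spec.interface_residue_number, spec.interface_residue_name),
        "plant_min_interprotomer_distance": plant_min,
        "plant_contact_count": contacts,
        "min_interprotomer_distance": gmin,
        "seed": spec.seed,
        "face_interface": face_interface,
    }
    return trimer, meta


def make_head_to_head_template(spec: FixtureSpec | None = None,
                               reference: Protomer | None = None) -> Assembly:
    """Two protomer placements related by an x-flip and a z-separation.

    The template's two units define where each trimer of a head-to-head
    hexamer goes: unit 1 in place, unit 2 flipped 180 degrees about x and
    shifted ``separation`` along z.
    """
    spec = spec or FixtureSpec()
    base = reference if reference is not None else _helix_protomer(spec)
    u1 = base.copy().relabel("A")
    flip = rotation_about_axis(np.array([1.0, 0.0, 0.0]), 180.0)
    u2 = base.transformed(flip, np.array([0.0, 0.0, spec.separation])).relabel("B")
    return Assembly([u1, u2], kind="protomer", provenance=["head-to-head template"])


def make_hexamer(spec: FixtureSpec | None = None):
    """Convenience: trimer + template -> head-to-head hexamer (Assembly, metadata)."""
    from .structure import build_head_to_head

    spec = spec or FixtureSpec()
    trimer, meta = make_c3_trimer(spec)
    template = make_head_to_head_template(spec, reference=trimer.protomers[0])
    hexamer = build_head_to_head(trimer, template)
    meta = dict(meta)
    meta["separation"] = spec.separation
    return hexamer, meta


def make_point_charge_cluster(charges, positions) -> tuple[Assembly, np.ndarray]:
    """Point-charge toy system: one single-atom protomer per charge.

    Returns the assembly plus the brute-force pairwise Coulomb energy matrix
    (kcal/mol, zero diagonal); ``coulomb_interaction`` sums it across any
    partition. Coincident positions raise a singularity error.
    """
    charges = np.asarray(charges, float)
    positions = np.asarray(positions, float).reshape(-1, 3)
    if len(charges) != len(positions):
        raise ValueError("one position per charge required")
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    off = ~np.eye(len(charges), dtype=bool)
    if np.any(d[off] < 1e-9):
        raise ValueError("coincident charge positions (Coulomb singularity)")
    protomers = []
    for i, (q, x) in enumerate(zip(charges, positions)):
        atom = AtomRecord(serial=i + 1, name="Q", element="X", residue_name="CHG",
                          chain_id=chr(ord("A") + i % 26), residue_number=1,
                          insertion_code="", coordinates=np.array(x), charge=float(q))
        protomers.append(Protomer(atom.chain_id, [atom]))
    kind = {3: "trimer", 6: "hexamer"}.get(len(protomers), "protomer")
    with np.errstate(divide="ignore"):
        e = np.where(off, COULOMB_CONSTANT * np.outer(charges, charges) / np.where(off, d, 1.0), 0.0)
    return Assembly(protomers, kind=kind), e


def coulomb_interaction(pair_energies: np.ndarray, left, right) -> float:
    """Brute-force cross-partition Coulomb interaction from the pair table."""
    left = np.asarray(list(left), int)
    right = np.asarray(list(right), int)
    return float(pair_energies[np.ix_(left, right)].sum())


def make_mutation_trend_pair(seed: int = 0):
    """Interface-facing vs solvent-facing plants of the same protomer sequence.

    Returns ``((interface_trimer, meta), (surface_trimer, meta))``; the two
    assemblies differ only in the planted residue's orientation relative to
    the three-fold axis.
    """
    spec = FixtureSpec(seed=seed)
    interface = make_c3_trimer(spec, face_interface=True)
    surface = make_c3_trimer(spec, face_interface=False)
    if interface[1]["plant_contact_count"] < 1:
        raise GenerationError("interface plant lost its contacts")
    return interface, surface


def make_water_probe():
    """Tiny dipeptide plus waters exercising the 3.5 A water-pruning rule.

    Ground truth in the metadata: the water near the protein survives, the
    isolated water and the water-only chain are pruned.
    """
    pep = build_peptide(["GLY", "ALA"], chain_id="A")
    o_xyz = next(a.coordinates for a in pep.atoms if a.name == "O")
    waters = []

    def water(i, xyz):
        return AtomRecord(serial=100 + i, name="O", element="O", residue_name="HOH",
                          chain_id="W", residue_number=i + 1, insertion_code="",
                          coordinates=np.array(xyz, float), is_hetero=True)

    waters.append(water(0, o_xyz + np.array([3.0, 0.0, 0.0])))      # kept
    waters.append(water(1, o_xyz + np.array([20.0, 0.0, 0.0])))     # isolated, pruned
    base = o_xyz + np.array([0.0, 15.0, 0.0])
    for k in range(3):                                               # chain, pruned
        waters.append(water(2 + k, base + np.array([2.8 * k, 0.0, 0.0])))
    asm = Assembly([pep, Protomer("W", waters)], kind="protomer")
    meta = {"kept": [("W", 1)], "pruned": [("W", 2), ("W", 3), ("W", 4), ("W", 5)]}
    return asm, meta
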