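"""Enumeration of WT/mutant compositions of an oligomeric assembly.

A dominant missense variant produces a mixed pool of WT and mutant chains,
so a trimer has 2^3 - 1 = 7 non-WT compositions and a double-trimer 2^6 - 1
= 63. Each trimer composition is evaluated three times (each protomer
against the complementary dimer), giving 21 protomer-vs-rest pairings.
Grouping by mutation count yields binomial-coefficient group sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "CompositionVector",
    "EvaluationPairing",
    "enumerate_compositions",
    "protomer_pairings",
    "group_by_mutation_count",
    "symmetry_reduce",
]

_KIND_BY_LEN = {3: "trimer", 6: "hexamer"}


@dataclass(frozen=True)
class CompositionVector:
    """Per-protomer mutation flags; True = that protomer carries the variant."""

    flags: tuple[bool, ...]
    assembly_kind: str = ""

    def __post_init__(self):
        kind = self.assembly_kind or _KIND_BY_LEN.get(len(self.flags), "protomer")
        object.__setattr__(self, "flags", tuple(bool(f) for f in self.flags))
        object.__setattr__(self, "assembly_kind", kind)
        if kind == "trimer" and len(self.flags) != 3:
            raise ValueError("trimer composition needs 3 flags")
        if kind == "hexamer" and len(self.flags) != 6:
            raise ValueError("hexamer composition needs 6 flags")

    @property
    def mutation_count(self) -> int:
        return sum(self.flags)

    @property
    def is_all_wt(self) -> bool:
        return not any(self.flags)

    def bitstring(self) -> str:
        s = "".join("M" if f else "W" for f in self.flags)
        if len(s) == 6:
            return s[:3] + "-" + s[3:]
        return s

    def permuted(self, perm: tuple[int, ...]) -> "CompositionVector":
        return CompositionVector(tuple(self.flags[p] for p in perm), self.assembly_kind)


@dataclass(frozen=True)
class EvaluationPairing:
    """A binding evaluation: left unit vs right unit of one composition."""

    composition: CompositionVector
    left_unit: tuple[int, ...]
    right_unit: tuple[int, ...]
    mode: str  # protomer_vs_rest | trimer_vs_trimer

    def __post_init__(self):
        left, right = set(self.left_unit), set(self.right_unit)
        n = len(self.composition.flags)
        if left & right:
            raise ValueError("pairing units must be disjoint")
        if left | right != set(range(n)):
            raise ValueError("pairing units must cover every protomer")


def enumerate_compositions(n_protomers: int, include_all_wt: bool = False) -> list[CompositionVector]:
    """All 2^n WT/mutant assignments in lexicographic order (optionally minus all-WT)."""
    if n_protomers <= 0:
        raise ValueError("n_protomers must be positive")
    out = []
    for flags in itertools.product((False, True), repeat=n_protomers):
        cv = CompositionVector(flags)
        if cv.is_all_wt and not include_all_wt:
            continue
        out.append(cv)
    return out


def protomer_pairings(compositions) -> list[EvaluationPairing]:
    """Each protomer of each trimer composition vs the complementary dimer."""
    out = []
    for cv in compositions:
        if len(cv.flags) != 3:
            raise ValueError("protomer pairings are defined on trimer compositions")
        if cv.is_all_wt:
            raise ValueError("all-WT composition must be excluded upstream")
        for i in range(3):
            rest = tuple(j for j in range(3) if j != i)
            out.append(EvaluationPairing(cv, (i,), rest, "protomer_vs_rest"))
    return out


def trimer_pairing(composition: CompositionVector) -> EvaluationPairing:
    """The single head-to-head pairing of a hexamer composition."""
    if len(composition.flags) != 6:
        raise ValueError("trimer-vs-trimer pairing needs a hexamer composition")
    return EvaluationPairing(composition, (0, 1, 2), (3, 4, 5), "trimer_vs_trimer")


def group_by_mutation_count(records) -> dict[int, list]:
    """Partition (CompositionVector, value) pairs (or records with .composition)."""
    records = list(records)
    kinds = set()
    out: dict[int, list] = {}
    for rec in records:
        cv = rec[0] if isinstance(rec, tuple) else rec.composition
        kinds.add(cv.assembly_kind)
        out.setdefault(cv.mutation_count, []).append(rec)
    if len(kinds) > 1:
        raise ValueError(f"mixed assembly kinds in grouping: {sorted(kinds)}")
    return dict(sorted(out.items()))


def _is_group(perms: list[tuple[int, ...]]) -> bool:
    s = set(perms)
    n = len(perms[0])
    if tuple(range(n)) not in s:
        return False
    for p in perms:
        for q in perms:
            if tuple(p[i] for i in q) not in s:
                return False
    return True


def symmetry_reduce(compositions, symmetry_group):
    """Orbit representatives and multiplicities under a permutation group.

    The group acts on protomer indices. Returns ``[(representative,
    multiplicity), ...]``; multiplicities sum to the input count.
    """
    perms = [tuple(p) for p in symmetry_group]
    if not perms or not _is_group(perms):
        raise ValueError("symmetry_group must be a permutation group (closed, with identity)")
    remaining = list(compositions)
    seen: set[tuple[bool, ...]] = set()
    out = []
    pool = {cv.flags for cv in remaining}
    for cv in remaining:
        if cv.flags in seen:
            continue
        orbit = {cv.permuted(p).flags for p in perms}
        orbit &= pool
        seen |= orbit
        out.append((cv, len(orbit)))
    return out
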