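"""Explicit pedigrees for gene-dropping simulation.

A pedigree is a DAG of members; founders have no parents, every non-founder
has exactly two (one male, one female).  Builders are provided for the
parent-pair structures the consanguinity statistic is validated against:
unrelated (kinship 0), second cousins (1/64, e.g. parents who share a
great-grandparent couple), first cousins (1/16) and full siblings (1/4).
The exact kinship coefficient is computed from the graph by the standard
recursion, so a builder's declared ``kinship_label`` is verifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

from .errors import PedigreeError


@dataclass(frozen=True)
class Member:
    id: str
    sex: str  # "M" or "F"
    father: Optional[str] = None
    mother: Optional[str] = None

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise PedigreeError(f"sex must be M or F, got {self.sex!r}")
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(f"member {self.id}: need both parents or neither")

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class PedigreeSpec:
    """Founder/offspring graph plus the samples to emit.

    ``target_samples`` maps role (child/mother/father) to member id;
    ``kinship_label`` declares the expected kinship between the emitted
    mother and father, checked against the graph on construction.
    """

    members: Mapping[str, Member]
    target_samples: Mapping[str, str]
    kinship_label: float = 0.0

    def __post_init__(self):
        for m in self.members.values():
            for pid, psex in ((m.father, "M"), (m.mother, "F")):
                if pid is None:
                    continue
                if pid not in self.members:
                    raise PedigreeError(f"member {m.id}: unknown parent {pid}")
                if self.members[pid].sex != psex:
                    raise PedigreeError(
                        f"member {m.id}: parent {pid} has inconsistent sex"
                    )
        for role, mid in self.target_samples.items():
            if mid not in self.members:
                raise PedigreeError(f"target {role}={mid} not in pedigree")
        self.topological_order()  # raises on cycles
        fa = self.target_samples.get("father")
        mo = self.target_samples.get("mother")
        if fa and mo:
            phi = kinship(self, fa, mo)
            if abs(phi - self.kinship_label) > 1e-12:
                raise PedigreeError(
                    f"declared kinship_label {self.kinship_label} != computed "
                    f"kinship {phi} for pair ({fa}, {mo})"
                )

    @property
    def founders(self) -> list:
        return [m.id for m in self.members.values() if m.is_founder]

    def topological_order(self) -> list:
        """Members ordered founders-first; raises PedigreeError on a cycle."""
        order, state = [], {}

        def visit(mid, stack):
            if state.get(mid) == 2:
                return
            if mid in stack:
                raise PedigreeError(f"pedigree cycle involving {mid}")
            stack = stack | {mid}
            m = self.members[mid]
            if not m.is_founder:
                visit(m.father, stack)
                visit(m.mother, stack)
            state[mid] = 2
            order.append(mid)

        for mid in self.members:
            visit(mid, frozenset())
        return order

    def generation(self, mid: str) -> int:
        m = self.members[mid]
        if m.is_founder:
            return 0
        return 1 + max(self.generation(m.father), self.generation(m.mother))


def kinship(ped: PedigreeSpec, a: str, b: str) -> float:
    """Kinship coefficient phi(a, b) by the standard recursion."""
    memo: dict = {}

    def phi(x: str, y: str) -> float:
        if (x, y) in memo:
            return memo[(x, y)]
        mx, my = ped.members[x], ped.members[y]
        if x == y:
            val = 0.5 if mx.is_founder else 0.5 * (1.0 + phi(mx.father, mx.mother))
        else:
            # recurse on the member further from the founders
            if ped.generation(x) < ped.generation(y):
                x, y, mx, my = y, x, my, mx
            if mx.is_founder:
                val = 0.0  # founders are mutually unrelated
            else:
                val = 0.5 * (phi(mx.father, y) + phi(mx.mother, y))
        memo[(x, y)] = memo[(y, x)] = val
        return val

    return phi(a, b)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _trio_targets(father: str, mother: str, child: Optional[str]) -> dict:
    t = {"father": father, "mother": mother}
    if child:
        t["child"] = child
    return t


def unrelated_parents(child: bool = True, child_sex: str = "F") -> PedigreeSpec:
    """phi = 0: two founder parents."""
    members = {
        "FA": Member("FA", "M"),
        "MO": Member("MO", "F"),
    }
    if child:
        members["CH"] = Member("CH", child_sex, father="FA", mother="MO")
    return PedigreeSpec(members=members,
                        target_samples=_trio_targets("FA", "MO", "CH" if child else None),
                        kinship_label=0.0)


def sibling_parents(child: bool = True, child_sex: str = "F") -> PedigreeSpec:
    """phi = 1/4: the emitted parents are full siblings."""
    members = {
        "GF": Member("GF", "M"), "GM": Member("GM", "F"),
        "FA": Member("FA", "M", father="GF", mother="GM"),
        "MO": Member("MO", "F", father="GF", mother="GM"),
    }
    if child:
        members["CH"] = Member("CH", child_sex, father="FA", mother="MO")
    return PedigreeSpec(members=members,
                        target_samples=_trio_targets("FA", "MO", "CH" if child else None),
                        kinship_label=0.25)


def cousin_parents(degree: int = 1, child: bool = True,
                   child_sex: str = "F") -> PedigreeSpec:
    """phi = 1/16 for first cousins (degree=1), 1/64 for second cousins
    (degree=2; parents share a great-grandparent couple), 4**-(degree+1) in
    general."""
    if degree < 1:
        raise PedigreeError("degree must be >= 1")
    members = {
        "A0": Member("A0", "M"), "B0": Member("B0", "F"),
        "S1": Member("S1", "M", father="A0", mother="B0"),
        "S2": Member("S2", "F", father="A0", mother="B0"),
    }
    # marry each sibling line to unrelated founders for degree-1 generations,
    # then the final offspring are degree-th cousins
    left, right = "S1", "S2"
    for g in range(degree):
        lsp = f"LSP{g}"
        rsp = f"RSP{g}"
        members[lsp] = Member(lsp, "F")
        members[rsp] = Member(rsp, "M")
        lchild = f"L{g + 1}"
        rchild = f"R{g + 1}"
        # left line stays male, right line stays female so the final pair is
        # a father and a mother
        members[lchild] = Member(lchild, "M", father=left, mother=lsp)
        members[rchild] = Member(rchild, "F", father=rsp, mother=right)
        left, right = lchild, rchild
    targets_child = None
    if child:
        members["CH"] = Member("CH", child_sex, father=left, mother=right)
        targets_child = "CH"
    return PedigreeSpec(members=members,
                        target_samples=_trio_targets(left, right, targets_child),
                        kinship_label=0.25 ** (degree + 1))


def pedigree_for_kinship(phi: float, child: bool = True,
                         child_sex: str = "F") -> PedigreeSpec:
    """Builder lookup for the kinship levels used in validation."""
    if phi == 0.0:
        return unrelated_parents(child, child_sex)
    if abs(phi - 0.25) < 1e-12:
        return sibling_parents(child, child_sex)
    if abs(phi - 1 / 16) < 1e-12:
        return cousin_parents(1, child, child_sex)
    if abs(phi - 1 / 64) < 1e-12:
        return cousin_parents(2, child, child_sex)
    raise PedigreeError(f"no builder for kinship {phi}")
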