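"""Pedigree structures for extended-family genetic analysis.

A :class:`Pedigree` is a loop-free directed family graph.  Individuals are
either founders (no parents) or nonfounders (exactly two parents).  All
likelihood code in this package assumes the topological ordering guaranteed
here: parents always precede their children.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["Individual", "Pedigree", "PedigreeError", "kinship_matrix"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None  # None for founders
    mother: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    family_id: str = "1"

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """An ordered, validated family graph.

    ``members`` is stored in topological order (parents before children);
    construction validates the zero-or-both-parents rule and rejects
    marriage loops and cycles.
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = _toposort(self.members, self.family_id)
        self._index = {ind.iid: i for i, ind in enumerate(self.members)}
        _reject_loops(self)

    # -- basic queries ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def index(self, iid: str) -> int:
        return self._index[iid]

    def __getitem__(self, iid: str) -> Individual:
        return self.members[self._index[iid]]

    @property
    def ids(self) -> list[str]:
        return [m.iid for m in self.members]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    @property
    def n_meioses(self) -> int:
        """Number of parent-to-child transmissions (2 per nonfounder)."""
        return 2 * len(self.nonfounders)

    def children_of(self, iid: str) -> list[Individual]:
        return [m for m in self.members if iid in (m.father, m.mother)]

    def couples(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for m in self.members:
            if m.father is not None:
                seen.setdefault((m.father, m.mother), None)
        return list(seen)

    def n_generations(self) -> int:
        depth: dict[str, int] = {}
        for m in self.members:
            if m.is_founder:
                depth[m.iid] = 1
            else:
                depth[m.iid] = 1 + max(depth[m.father], depth[m.mother])
        return max(depth.values()) if depth else 0


def _toposort(members: Iterable[Individual], family_id: str) -> list[Individual]:
    members = list(members)
    ids = {m.iid for m in members}
    if len(ids) != len(members):
        raise PedigreeError(f"family {family_id}: duplicated individual IDs")
    for m in members:
        if (m.father is None) != (m.mother is None):
            raise PedigreeError(
                f"family {family_id}: individual {m.iid} has exactly one parent "
                "specified; pedigree members need zero or both parents"
            )
        for p in (m.father, m.mother):
            if p is not None and p not in ids:
                raise PedigreeError(
                    f"family {family_id}: parent {p} of {m.iid} is not in the pedigree"
                )
    # Kahn's algorithm; cycle => error.
    placed: dict[str, Individual] = {}
    out: list[Individual] = []
    pending = list(members)
    while pending:
        progress = False
        rest = []
        for m in pending:
            if m.is_founder or (m.father in placed and m.mother in placed):
                placed[m.iid] = m
                out.append(m)
                progress = True
            else:
                rest.append(m)
        if not progress:
            raise PedigreeError(f"family {family_id}: pedigree contains a cycle")
        pending = rest
    return out


def _reject_loops(ped: Pedigree) -> None:
    """Reject pedigrees with loops (inbreeding or marriage loops).

    The marriage graph has one node per individual plus one per couple;
    each couple connects to both partners and to each child.  The pedigree
    is loop-free iff this graph is a forest.
    """
    edges = 0
    nodes = set(ped.ids)
    parent: dict[str, str] = {x: x for x in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> bool:
        ra, rb = find(a), find(b)
        if ra == rb:
            return False
        parent[ra] = rb
        return True

    for fa, mo in ped.couples():
        cnode = f"\0couple:{fa}+{mo}"
        parent[cnode] = cnode
        for end in (fa, mo):
            edges += 1
            if not union(cnode, end):
                raise PedigreeError(
                    f"family {ped.family_id}: pedigree contains a loop "
                    "(inbreeding or intermarriage); loops are not supported"
                )
        for ch in ped.members:
            if ch.father == fa and ch.mother == mo:
                edges += 1
                if not union(cnode, ch.iid):
                    raise PedigreeError(
                        f"family {ped.family_id}: pedigree contains a loop "
                        "(inbreeding or intermarriage); loops are not supported"
                    )


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Kinship coefficients phi_ij for all pairs in a pedigree.

    Computed by the standard recursion in topological order:
    phi(i,i) = (1 + phi(f_i, m_i)) / 2 and, for i not an ancestor of j,
    phi(i,j) = (phi(f_i, j) + phi(m_i, j)) / 2.  Founders are assumed
    unrelated and non-inbred.  Rows/columns follow ``ped.members`` order.
    """
    n = len(ped)
    phi = np.zeros((n, n))
    for i, ind in enumerate(ped.members):
        if ind.is_founder:
            phi[i, i] = 0.5
        else:
            fi, mi = ped.index(ind.father), ped.index(ind.mother)
            phi[i, i] = 0.5 * (1.0 + phi[fi, mi])
            for j in range(i):
                phi[i, j] = phi[j, i] = 0.5 * (phi[fi, j] + phi[mi, j])
        # founders: phi with everyone earlier is 0 unless that person
        # descends from them -- impossible in topological order.
    return phi
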