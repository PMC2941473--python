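"""Molecular graph model: atoms, bonds, connectivity helpers."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

#: sentinel bond order for aromatic bonds (counts 1.5 toward valence sums)
AROMATIC = "ar"

SUPPORTED_ELEMENTS = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "H"}

#: allowed valence states, smallest first; implicit-H uses the smallest
#: valence >= the (rounded-up) bond-order sum
DEFAULT_VALENCES = {
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
    "H": (1,),
}

_ORDER_VALUE = {1: 1.0, 2: 2.0, 3: 3.0, AROMATIC: 1.5}


@dataclass
class AtomNode:
    element: str
    formal_charge: int = 0
    aromatic: bool = False
    implicit_h: int = 0

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element: {self.element!r}")
        if not -2 <= self.formal_charge <= 2:
            raise ValueError(f"formal charge out of range: {self.formal_charge}")
        if self.implicit_h < 0:
            raise ValueError("implicit_h must be non-negative")


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: object  # 1 | 2 | 3 | AROMATIC

    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


class MolecularGraph:
    """Ordered atoms plus an undirected bond set (no duplicate pairs)."""

    def __init__(self) -> None:
        self.atoms: list[AtomNode] = []
        self.bonds: list[Bond] = []
        self._adj: dict[int, dict[int, object]] = {}

    def add_atom(self, atom: AtomNode) -> int:
        self.atoms.append(atom)
        idx = len(self.atoms) - 1
        self._adj[idx] = {}
        return idx

    def add_bond(self, a: int, b: int, order: object = 1) -> None:
        n = len(self.atoms)
        if not (0 <= a < n and 0 <= b < n):
            raise ValueError(f"bond references missing atom: ({a},{b})")
        if a == b:
            raise ValueError("self-bond not allowed")
        if order not in _ORDER_VALUE:
            raise ValueError(f"unknown bond order: {order!r}")
        if b in self._adj[a]:
            raise ValueError(f"duplicate bond between atoms {a} and {b}")
        self.bonds.append(Bond(a, b, order))
        self._adj[a][b] = order
        self._adj[b][a] = order

    # -- connectivity ------------------------------------------------------

    def neighbors(self, i: int) -> dict[int, object]:
        return self._adj[i]

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def bond_order_sum(self, i: int) -> float:
        return sum(_ORDER_VALUE[o] for o in self._adj[i].values())

    def components(self) -> list[list[int]]:
        """Connected components as sorted atom-index lists, ordered by minimum index."""
        seen: set[int] = set()
        comps: list[list[int]] = []
        for start in range(len(self.atoms)):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                i = stack.pop()
                comp.append(i)
                for j in self._adj[i]:
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
            comps.append(sorted(comp))
        return comps

    @property
    def n_components(self) -> int:
        return len(self.components())

    def permuted(self, order: list[int]) -> "MolecularGraph":
        """Return a copy with atoms re-indexed so new index k holds old atom order[k]."""
        if sorted(order) != list(range(len(self.atoms))):
            raise ValueError("order must be a permutation of atom indices")
        inv = {old: new for new, old in enumerate(order)}
        g = MolecularGraph()
        for old in order:
            a = self.atoms[old]
            g.add_atom(AtomNode(a.element, a.formal_charge, a.aromatic, a.implicit_h))
        for b in self.bonds:
            g.add_bond(inv[b.a], inv[b.b], b.order)
        return g

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomNode]:
        return iter(self.atoms)


def implicit_h_for(element: str, bond_order_sum: float, charge: int = 0) -> int:
    """Implicit hydrogens for a bare (non-bracket) organic-subset atom.

    Aromatic bonds contribute 1.5 each; the total is rounded up before the
    smallest admissible default valence is chosen.
    """
    s = math.ceil(bond_order_sum - 1e-9)
    for v in DEFAULT_VALENCES[element]:
        if v >= s:
            return v - s
    return 0
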