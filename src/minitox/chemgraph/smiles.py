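"""SMILES-subset parser.

Grammar: organic-subset atoms B,C,N,O,P,S,F,Cl,Br,I; aromatic lowercase
b,c,n,o,p,s; bracket atoms with an optional H count and charge (+,-,+2,-2);
bonds - = # : ; branches; ring-closure digits (and %nn); '.' component
separator. No stereo descriptors, isotopes or wildcards.
"""

from __future__ import annotations

import re

from minitox.chemgraph.graph import (
    AROMATIC,
    AtomNode,
    MolecularGraph,
    implicit_h_for,
)

_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_AROMATIC_ORGANIC = {"b", "c", "n", "o", "p", "s"}
_BOND_SYMBOLS = {"-": 1, "=": 2, "#": 3, ":": AROMATIC}

_BRACKET_RE = re.compile(
    r"\[(?P<el>[A-Za-z][a-z]?)(?P<h>H\d*)?(?P<chg>\+2|-2|\+\+|--|\+|-)?\]"
)


class SmilesParseError(ValueError):
    """Parse failure; carries the 0-based offending position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _charge_value(token: str | None) -> int:
    if not token:
        return 0
    return {"+": 1, "-": -1, "+2": 2, "-2": -2, "++": 2, "--": -2}[token]


def parse_smiles(text: str) -> MolecularGraph:
    if not text:
        raise SmilesParseError("empty SMILES", 0)
    g = MolecularGraph()
    prev: int | None = None           # atom awaiting the next bond
    stack: list[int | None] = []      # branch return points
    pending: object | None = None     # explicit bond symbol waiting for an atom
    rings: dict[str, tuple[int, object | None, int]] = {}  # digit -> (atom, bond, pos)
    bracket_h: dict[int, int] = {}    # atoms whose H count is explicit

    def attach(idx: int, pos: int) -> None:
        nonlocal prev, pending
        if prev is not None:
            order = pending
            if order is None:
                order = (
                    AROMATIC
                    if g.atoms[prev].aromatic and g.atoms[idx].aromatic
                    else 1
                )
            try:
                g.add_bond(prev, idx, order)
            except ValueError as exc:
                raise SmilesParseError(str(exc), pos) from exc
        pending = None
        prev = idx

    def close_ring(digit: str, pos: int) -> None:
        nonlocal pending
        if prev is None:
            raise SmilesParseError("ring-closure digit before any atom", pos)
        if digit in rings:
            other, other_bond, _ = rings.pop(digit)
            order = pending if pending is not None else other_bond
            if order is None:
                order = (
                    AROMATIC
                    if g.atoms[prev].aromatic and g.atoms[other].aromatic
                    else 1
                )
            try:
                g.add_bond(prev, other, order)
            except ValueError as exc:
                raise SmilesParseError(str(exc), pos) from exc
        else:
            rings[digit] = (prev, pending, pos)
        pending = None

    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "(":
            if prev is None:
                raise SmilesParseError("branch opens before any atom", i)
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise SmilesParseError("unbalanced parenthesis", i)
            if pending is not None:
                raise SmilesParseError("bond symbol with no following atom", i)
            prev = stack.pop()
            i += 1
        elif ch == ".":
            if pending is not None:
                raise SmilesParseError("bond symbol before component separator", i)
            prev = None
            i += 1
        elif ch in _BOND_SYMBOLS:
            if prev is None:
                raise SmilesParseError("bond symbol with no preceding atom", i)
            pending = _BOND_SYMBOLS[ch]
            i += 1
        elif ch.isdigit():
            close_ring(ch, i)
            i += 1
        elif ch == "%":
            m = re.match(r"%(\d\d)", text[i:])
            if not m:
                raise SmilesParseError("malformed %nn ring closure", i)
            close_ring(m.group(1), i)
            i += 3
        elif ch == "[":
            m = _BRACKET_RE.match(text, i)
            if not m:
                raise SmilesParseError("malformed bracket atom", i)
            el = m.group("el")
            aromatic = el[0].islower()
            element = el.capitalize() if aromatic else el
            if aromatic and el not in _AROMATIC_ORGANIC:
                raise SmilesParseError(f"unknown aromatic atom symbol {el!r}", i)
            h = m.group("h")
            hcount = 0 if h is None else (1 if h == "H" else int(h[1:]))
            try:
                atom = AtomNode(
                    element,
                    formal_charge=_charge_value(m.group("chg")),
                    aromatic=aromatic,
                    implicit_h=hcount,
                )
            except ValueError as exc:
                raise SmilesParseError(str(exc), i) from exc
            idx = g.add_atom(atom)
            bracket_h[idx] = hcount
            attach(idx, i)
            i = m.end()
        else:
            # organic-subset atom: try two-letter halogens first
            sym = None
            if text[i : i + 2] in ("Cl", "Br"):
                sym = text[i : i + 2]
            elif ch in _ORGANIC:
                sym = ch
            elif ch in _AROMATIC_ORGANIC:
                sym = ch
            if sym is None:
                raise SmilesParseError(f"unknown atom symbol {ch!r}", i)
            aromatic = sym.islower()
            element = sym.capitalize() if aromatic else sym
            idx = g.add_atom(AtomNode(element, aromatic=aromatic))
            attach(idx, i)
            i += len(sym)

    if stack:
        raise SmilesParseError("unbalanced parenthesis", n)
    if pending is not None:
        raise SmilesParseError("bond symbol with no following atom", n)
    if rings:
        digit, (_, _, pos) = sorted(rings.items())[0]
        raise SmilesParseError(f"unclosed ring-closure digit {digit}", pos)

    # implicit hydrogens: bare atoms only; bracket atoms keep explicit count
    for idx, atom in enumerate(g.atoms):
        if idx not in bracket_h:
            atom.implicit_h = implicit_h_for(atom.element, g.bond_order_sum(idx))
    g._explicit_h_atoms = set(bracket_h)  # consumed by the writer
    return g
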