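"""Canonical SMILES writer.

Atom ranking uses iterative neighborhood refinement seeded by
(element, aromatic, charge, degree, implicit_h); residual ties are resolved
by branching on each tied atom and keeping the lexicographically smallest
output string, so the result depends only on graph structure, never on atom
input order. The string is implementation-canonical — deterministic within
this package, not aligned with any external toolkit.
"""

from __future__ import annotations

from minitox.chemgraph.graph import AROMATIC, MolecularGraph, implicit_h_for

_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_AROMATIC_ORGANIC = {"b", "c", "n", "o", "p", "s"}
_CHARGE_TOKEN = {0: "", 1: "+", -1: "-", 2: "+2", -2: "-2"}


def canonical_smiles(g: MolecularGraph) -> str:
    """Deterministic canonical SMILES; components sorted and dot-joined."""
    if not g.atoms:
        return ""
    parts = [_canon_component(g, comp) for comp in g.components()]
    return ".".join(sorted(parts))


# -- ranking ---------------------------------------------------------------


def _refine(g: MolecularGraph, comp: list[int], seed: dict[int, object]) -> dict[int, int]:
    """Iterated neighborhood refinement; returns dense integer ranks."""
    ranks = _dense(seed, comp)
    while True:
        keys = {
            i: (ranks[i], tuple(sorted(ranks[j] for j in g.neighbors(i))))
            for i in comp
        }
        new = _dense(keys, comp)
        if len(set(new.values())) == len(set(ranks.values())):
            return new
        ranks = new


def _dense(keys: dict[int, object], comp: list[int]) -> dict[int, int]:
    order = sorted(set(keys[i] for i in comp))
    pos = {k: r for r, k in enumerate(order)}
    return {i: pos[keys[i]] for i in comp}


def _initial_keys(g: MolecularGraph, comp: list[int]) -> dict[int, object]:
    out = {}
    for i in comp:
        a = g.atoms[i]
        out[i] = (a.element, a.aromatic, a.formal_charge, g.degree(i), a.implicit_h)
    return out


def _canon_component(g: MolecularGraph, comp: list[int]) -> str:
    ranks = _refine(g, comp, _initial_keys(g, comp))
    return _search(g, comp, ranks)


def _search(g: MolecularGraph, comp: list[int], ranks: dict[int, int]) -> str:
    by_rank: dict[int, list[int]] = {}
    for i in comp:
        by_rank.setdefault(ranks[i], []).append(i)
    tied = [atoms for _, atoms in sorted(by_rank.items()) if len(atoms) > 1]
    if not tied:
        return _write(g, comp, ranks)
    best: str | None = None
    for pick in tied[0]:
        seed = {i: (ranks[i], 0 if i == pick else 1) for i in comp}
        candidate = _search(g, comp, _refine(g, comp, seed))
        if best is None or candidate < best:
            best = candidate
    assert best is not None
    return best


# -- writing ---------------------------------------------------------------


def _atom_token(g: MolecularGraph, i: int) -> str:
    a = g.atoms[i]
    sym = a.element.lower() if a.aromatic else a.element
    bare_ok = (
        a.formal_charge == 0
        and a.element in _ORGANIC
        and (not a.aromatic or sym in _AROMATIC_ORGANIC)
        and a.implicit_h == implicit_h_for(a.element, g.bond_order_sum(i))
    )
    if bare_ok:
        return sym
    h = "" if a.implicit_h == 0 else ("H" if a.implicit_h == 1 else f"H{a.implicit_h}")
    return f"[{sym}{h}{_CHARGE_TOKEN[a.formal_charge]}]"


def _bond_token(g: MolecularGraph, i: int, j: int) -> str:
    order = g.neighbors(i)[j]
    both_aromatic = g.atoms[i].aromatic and g.atoms[j].aromatic
    if order == 1:
        return "-" if both_aromatic else ""
    if order == 2:
        return "="
    if order == 3:
        return "#"
    if order == AROMATIC:
        return "" if both_aromatic else ":"
    raise AssertionError(order)


def _ring_digit(n: int) -> str:
    return str(n) if n <= 9 else f"%{n:02d}"


def _write(g: MolecularGraph, comp: list[int], ranks: dict[int, int]) -> str:
    root = min(comp, key=lambda i: ranks[i])

    # pass 1: classify tree vs ring-closure edges in deterministic DFS order
    tree_children: dict[int, list[int]] = {i: [] for i in comp}
    opens: dict[int, list[tuple[int, int]]] = {i: [] for i in comp}   # ancestor side
    closes: dict[int, list[tuple[int, int]]] = {i: [] for i in comp}  # descendant side
    counter = 0
    visited: set[int] = set()
    stack: list[tuple[int, int | None]] = [(root, None)]
    # recursive formulation keeps child order identical in both passes
    def dfs(i: int, parent: int | None) -> None:
        nonlocal counter
        visited.add(i)
        for j in sorted(g.neighbors(i), key=lambda j: ranks[j]):
            if j == parent:
                continue
            if j in visited:
                if any(n == i for n, _ in opens[j]) or any(n == i for n, _ in closes[j]):
                    continue
                counter += 1
                opens[j].append((i, counter))
                closes[i].append((j, counter))
            else:
                tree_children[i].append(j)
                dfs(j, i)

    dfs(root, None)

    def render(i: int) -> str:
        out = [_atom_token(g, i)]
        for _, num in sorted(opens[i], key=lambda t: t[1]):
            out.append(_ring_digit(num))
        for j, num in sorted(closes[i], key=lambda t: t[1]):
            out.append(_bond_token(g, i, j) + _ring_digit(num))
        kids = tree_children[i]
        for j in kids[:-1]:
            out.append("(" + _bond_token(g, i, j) + render(j) + ")")
        if kids:
            j = kids[-1]
            out.append(_bond_token(g, i, j) + render(j))
        return "".join(out)

    return render(root)
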