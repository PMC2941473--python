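"""Linear path fingerprints and Tanimoto similarity.

Every simple path of 1..max_path_atoms atoms contributes one label (read in
its lexicographically smaller direction); labels hash to bits with 64-bit
FNV-1a, which is deterministic and platform-independent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from minitox.chemgraph.graph import AROMATIC, MolecularGraph

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_BOND_CHAR = {1: "-", 2: "=", 3: "#", AROMATIC: ":"}
_CHARGE_MARK = {0: "", 1: "+", -1: "-", 2: "++", -2: "--"}


def fnv1a64(data: str) -> int:
    h = _FNV_OFFSET
    for byte in data.encode("utf-8"):
        h ^= byte
        h = (h * _FNV_PRIME) & 0xFFFFFFFFFFFFFFFF
    return h


@dataclass
class Fingerprint:
    length: int = 1024
    bits: set[int] = field(default_factory=set)
    labels: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("fingerprint length must be positive")
        bad = [b for b in self.bits if not 0 <= b < self.length]
        if bad:
            raise ValueError(f"bit indices out of range: {bad}")


def _atom_label(g: MolecularGraph, i: int) -> str:
    a = g.atoms[i]
    sym = a.element.lower() if a.aromatic else a.element
    return sym + _CHARGE_MARK[a.formal_charge]


def _path_label(g: MolecularGraph, path: list[int]) -> str:
    def read(seq: list[int]) -> str:
        parts = [_atom_label(g, seq[0])]
        for a, b in zip(seq, seq[1:]):
            parts.append(_BOND_CHAR[g.neighbors(a)[b]])
            parts.append(_atom_label(g, b))
        return "".join(parts)

    return min(read(path), read(path[::-1]))


def iter_simple_paths(g: MolecularGraph, max_atoms: int):
    """Yield each undirected simple path of 1..max_atoms atoms exactly once."""
    for start in range(len(g.atoms)):
        yield [start]
        stack = [[start]]
        while stack:
            path = stack.pop()
            if len(path) == max_atoms:
                continue
            for j in sorted(g.neighbors(path[-1])):
                if j in path:
                    continue
                nxt = path + [j]
                # count undirected paths once: keep endpoint-ordered direction
                if nxt[0] < nxt[-1]:
                    yield nxt
                stack.append(nxt)


def path_fingerprint(
    g: MolecularGraph, max_path_atoms: int = 7, length: int = 1024
) -> Fingerprint:
    if max_path_atoms < 1:
        raise ValueError("max_path_atoms must be >= 1")
    if length < 64:
        raise ValueError("fingerprint length must be >= 64")
    labels = Counter()
    for path in iter_simple_paths(g, max_path_atoms):
        labels[_path_label(g, path)] += 1
    bits = {fnv1a64(label) % length for label in labels}
    return Fingerprint(length=length, bits=bits, labels=labels)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B| over bit sets; two empty fingerprints compare as 1.0."""
    if a.length != b.length:
        raise ValueError(f"fingerprint length mismatch: {a.length} != {b.length}")
    union = a.bits | b.bits
    if not union:
        return 1.0
    return len(a.bits & b.bits) / len(union)
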