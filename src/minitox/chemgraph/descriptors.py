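"""Structure checking and physico-chemical descriptors."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from minitox.chemgraph.graph import DEFAULT_VALENCES, MolecularGraph

#: fixed table of standard atomic weights (3 decimals) for reproducibility
ATOMIC_MASSES = {
    "H": 1.008,
    "B": 10.811,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.060,
    "Cl": 35.453,
    "Br": 79.904,
    "I": 126.904,
}

#: fixed external descriptor names, in canonical order
DESCRIPTOR_NAMES = ("MW", "HeavyAtoms", "Rings", "AromaticAtoms", "HBD", "HBA")


@dataclass
class DescriptorVector:
    molecular_weight: float
    heavy_atom_count: int
    ring_count: int
    aromatic_atom_count: int
    hbond_donors: int
    hbond_acceptors: int

    def as_dict(self) -> dict[str, float]:
        return {
            "MW": self.molecular_weight,
            "HeavyAtoms": self.heavy_atom_count,
            "Rings": self.ring_count,
            "AromaticAtoms": self.aromatic_atom_count,
            "HBD": self.hbond_donors,
            "HBA": self.hbond_acceptors,
        }


@dataclass
class StructureReport:
    n_components: int
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


def check_structure(g: MolecularGraph) -> StructureReport:
    """Graph-level correctness check: valences, charges, component count.

    Findings are warnings, never errors — callers decide whether to continue.
    """
    if not g.atoms:
        return StructureReport(0, ["empty structure"])
    report = StructureReport(g.n_components)
    if report.n_components > 1:
        report.warnings.append(
            f"structure contains {report.n_components} disconnected molecules"
        )
    for i, atom in enumerate(g.atoms):
        allowed = max(DEFAULT_VALENCES[atom.element]) + max(atom.formal_charge, 0)
        total = math.ceil(g.bond_order_sum(i) - 1e-9) + atom.implicit_h
        if total > allowed:
            report.warnings.append(
                f"atom {i} ({atom.element}): bond-order sum {total} exceeds "
                f"allowed valence {allowed}"
            )
    return report


def molecular_descriptors(g: MolecularGraph) -> DescriptorVector:
    if not g.atoms:
        raise ValueError("cannot compute descriptors of an empty graph")
    mw = 0.0
    heavy = aromatic = hbd = hba = 0
    for i, atom in enumerate(g.atoms):
        mw += ATOMIC_MASSES[atom.element] + atom.implicit_h * ATOMIC_MASSES["H"]
        if atom.element != "H":
            heavy += 1
        if atom.aromatic:
            aromatic += 1
        if atom.element in ("N", "O"):
            hba += 1
            explicit_h = sum(
                1 for j in g.neighbors(i) if g.atoms[j].element == "H"
            )
            if atom.implicit_h + explicit_h >= 1:
                hbd += 1
    rings = len(g.bonds) - len(g.atoms) + g.n_components
    return DescriptorVector(
        molecular_weight=round(mw, 3),
        heavy_atom_count=heavy,
        ring_count=rings,
        aromatic_atom_count=aromatic,
        hbond_donors=hbd,
        hbond_acceptors=hba,
    )
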