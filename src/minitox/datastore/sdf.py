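"""Minimal SDF V2000 reader: structures plus data items, coordinates ignored."""

from __future__ import annotations

import pathlib

from minitox.chemgraph import canonical_smiles
from minitox.chemgraph.graph import (
    AROMATIC,
    AtomNode,
    MolecularGraph,
    implicit_h_for,
)
from minitox.datastore.resources import Compound, Dataset, Feature, NUMERIC, STRING


class SdfError(ValueError):
    pass


_BOND_ORDER = {1: 1, 2: 2, 3: 3, 4: AROMATIC}


def _parse_molblock(lines: list[str], record_no: int) -> tuple[MolecularGraph, str]:
    if len(lines) < 4:
        raise SdfError(f"record {record_no}: truncated molblock")
    name = lines[0].strip()
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise SdfError(f"record {record_no}: malformed counts line {counts!r}") from None
    atom_lines = lines[4 : 4 + n_atoms]
    bond_lines = lines[4 + n_atoms : 4 + n_atoms + n_bonds]
    truncated = any(
        ln.strip() == "M  END" for ln in atom_lines + bond_lines
    )
    if truncated or len(atom_lines) < n_atoms or len(bond_lines) < n_bonds:
        raise SdfError(
            f"record {record_no}: counts line declares {n_atoms} atoms / "
            f"{n_bonds} bonds but block is shorter"
        )
    g = MolecularGraph()
    for ln in atom_lines:
        fields = ln.split()
        if len(fields) < 4:
            raise SdfError(f"record {record_no}: malformed atom line {ln!r}")
        try:
            g.add_atom(AtomNode(fields[3]))
        except ValueError as exc:
            raise SdfError(f"record {record_no}: {exc}") from exc
    aromatic_atoms = set()
    for ln in bond_lines:
        try:
            a, b, order = int(ln[0:3]) - 1, int(ln[3:6]) - 1, int(ln[6:9])
        except (ValueError, IndexError):
            raise SdfError(f"record {record_no}: malformed bond line {ln!r}") from None
        if order not in _BOND_ORDER:
            raise SdfError(f"record {record_no}: unsupported bond type {order}")
        try:
            g.add_bond(a, b, _BOND_ORDER[order])
        except ValueError as exc:
            raise SdfError(f"record {record_no}: {exc}") from exc
        if order == 4:
            aromatic_atoms.update((a, b))
    for i in aromatic_atoms:
        g.atoms[i].aromatic = True
    for ln in lines[4 + n_atoms + n_bonds :]:
        if ln.startswith("M  CHG"):
            fields = ln.split()
            n = int(fields[2])
            for k in range(n):
                idx = int(fields[3 + 2 * k]) - 1
                g.atoms[idx].formal_charge = int(fields[4 + 2 * k])
    for i, atom in enumerate(g.atoms):
        atom.implicit_h = implicit_h_for(atom.element, g.bond_order_sum(i))
    return g, name


def read_sdf_v2000_minimal(
    source: str | pathlib.Path, dataset_uri: str = "urn:minitox:dataset/sdf"
) -> Dataset:
    text = pathlib.Path(source).read_text(encoding="utf-8")
    records = [r for r in text.split("$$$$") if r.strip()]
    dataset = Dataset(uri=dataset_uri, title=pathlib.Path(source).name)
    raw_items: dict[str, dict[str, str]] = {}  # compound uri -> tag -> value
    seen: dict[str, str] = {}
    counter = 0
    for rec_no, record in enumerate(records, start=1):
        lines = record.lstrip("\n").split("\n")
        end = next(
            (i for i, ln in enumerate(lines) if ln.strip() == "M  END"), len(lines)
        )
        g, name = _parse_molblock(lines[: end + 1], rec_no)
        canon = canonical_smiles(g)
        # data items
        items: dict[str, str] = {}
        tag = None
        buf: list[str] = []
        for ln in lines[end + 1 :]:
            if ln.startswith(">"):
                if tag is not None:
                    items[tag] = "\n".join(buf).strip()
                lo, hi = ln.find("<"), ln.rfind(">")
                if lo == -1 or hi <= lo:
                    raise SdfError(f"record {rec_no}: malformed data header {ln!r}")
                tag, buf = ln[lo + 1 : hi], []
            elif tag is not None:
                buf.append(ln)
        if tag is not None:
            items[tag] = "\n".join(buf).strip()
        if canon in seen:  # duplicate structure: merge, first record wins per tag
            curi = seen[canon]
            for k, v in items.items():
                raw_items[curi].setdefault(k, v)
            if name and name not in dataset.compounds[curi].names:
                dataset.compounds[curi].names.append(name)
            continue
        counter += 1
        curi = f"{dataset_uri}/compound/{counter}"
        dataset.add_compound(
            Compound(uri=curi, canonical_smiles=canon, names=[name] if name else [])
        )
        seen[canon] = curi
        raw_items[curi] = items
    tags = sorted({t for items in raw_items.values() for t in items})
    for tag in tags:
        values = [items[tag] for items in raw_items.values() if tag in items]
        numeric = all(_is_number(v) for v in values) and values
        f = Feature(
            uri=f"{dataset_uri}/feature/{tag}",
            name=tag,
            value_kind=NUMERIC if numeric else STRING,
            has_source=dataset_uri,
        )
        dataset.add_feature(f)
        for curi, items in raw_items.items():
            if tag in items:
                v = float(items[tag]) if numeric else items[tag]
                dataset.set_value(curi, f.uri, v)
    return dataset


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
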