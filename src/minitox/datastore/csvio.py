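"""Training-table CSV exchange (``smiles,activity`` format).

Comma-separated, double-quote quoting, UTF-8, header row required. Rows with
unparsable SMILES are reported and skipped; duplicate structures are merged
by canonical form, and conflicting activity labels become missing values
with a logged conflict (inconsistent data flagged for manual inspection).
"""

from __future__ import annotations

import csv
import io
import pathlib
from dataclasses import dataclass, field

from minitox.chemgraph import canonical_smiles, parse_smiles, SmilesParseError
from minitox.datastore.resources import Compound, Dataset, Feature, NOMINAL


@dataclass
class IngestResult:
    dataset: Dataset
    activity_feature_uri: str
    rejected_rows: list[tuple[int, str, str]] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)


def ingest_training_csv(
    source: str | pathlib.Path | io.TextIOBase,
    dataset_uri: str = "urn:minitox:dataset/csv",
    title: str = "",
) -> IngestResult:
    if isinstance(source, (str, pathlib.Path)):
        fh = open(source, newline="", encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    try:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError("empty CSV: missing header row") from None
        if [h.strip().lower() for h in header[:2]] != ["smiles", "activity"]:
            raise ValueError(
                f"expected header 'smiles,activity', got {','.join(header)!r}"
            )
        rows = [(i, r) for i, r in enumerate(reader, start=2) if any(x.strip() for x in r)]
    finally:
        if close:
            fh.close()

    levels = sorted({r[1].strip() for _, r in rows if len(r) >= 2})
    if len(levels) > 2:
        raise ValueError(f"activity must have at most 2 levels, got {levels}")
    if not levels:
        raise ValueError("CSV contains no data rows")
    domain = tuple(levels)

    feature_uri = dataset_uri + "/feature/activity"
    dataset = Dataset(uri=dataset_uri, title=title)
    dataset.add_feature(
        Feature(
            uri=feature_uri,
            name="activity",
            value_kind=NOMINAL,
            has_source=dataset_uri,
            nominal_domain=domain,
        )
    )
    result = IngestResult(dataset=dataset, activity_feature_uri=feature_uri)
    seen: dict[str, str] = {}  # canonical smiles -> compound uri
    conflicted: set[str] = set()
    counter = 0
    for lineno, row in rows:
        smiles = row[0].strip()
        label = row[1].strip() if len(row) >= 2 else ""
        try:
            canon = canonical_smiles(parse_smiles(smiles))
        except SmilesParseError as exc:
            result.rejected_rows.append((lineno, smiles, str(exc)))
            continue
        if canon in seen:
            curi = seen[canon]
            prev = dataset.get_value(curi, feature_uri)
            if curi in conflicted:
                continue
            if prev is not None and prev != label:
                del dataset.entries[curi][feature_uri]
                conflicted.add(curi)
                result.conflicts.append(
                    f"{canon}: conflicting labels {prev!r} vs {label!r}; value dropped"
                )
            continue
        counter += 1
        curi = f"{dataset_uri}/compound/{counter}"
        dataset.add_compound(Compound(uri=curi, canonical_smiles=canon))
        dataset.set_value(curi, feature_uri, label)
        seen[canon] = curi
    return result


def write_training_csv(
    dataset: Dataset, feature_uri: str, path: str | pathlib.Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        w.writerow(["smiles", "activity"])
        for curi, c in dataset.compounds.items():
            value = dataset.get_value(curi, feature_uri)
            if value is None:
                continue
            w.writerow([c.canonical_smiles, value])
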