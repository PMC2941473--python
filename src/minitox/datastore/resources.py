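"""Core resource types: Compound, Feature, Dataset."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field


NUMERIC = "numeric"
NOMINAL = "nominal"
STRING = "string"
VALUE_KINDS = (NUMERIC, NOMINAL, STRING)


@dataclass
class Compound:
    uri: str
    canonical_smiles: str
    names: list[str] = field(default_factory=list)
    inchi: str | None = None  # opaque identifier, stored not computed
    origin_inventory: str = ""

    def __post_init__(self) -> None:
        self.names = sorted(self.names)  # treated as a set; kept sorted

    def to_dict(self) -> dict:
        return {
            "uri": self.uri,
            "canonical_smiles": self.canonical_smiles,
            "names": list(self.names),
            "inchi": self.inchi,
            "origin_inventory": self.origin_inventory,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Compound":
        return cls(
            uri=d["uri"],
            canonical_smiles=d["canonical_smiles"],
            names=list(d.get("names", [])),
            inchi=d.get("inchi"),
            origin_inventory=d.get("origin_inventory", ""),
        )


@dataclass
class Feature:
    """A property of a compound; always carries hasSource provenance."""

    uri: str
    name: str
    value_kind: str
    has_source: str
    nominal_domain: tuple[str, ...] | None = None
    endpoint_ref: str | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind: {self.value_kind!r}")
        if not self.has_source:
            raise ValueError(f"feature {self.uri} lacks hasSource provenance")
        if self.nominal_domain is not None:
            self.nominal_domain = tuple(sorted(self.nominal_domain))
        if self.value_kind == NOMINAL and not self.nominal_domain:
            raise ValueError(f"nominal feature {self.uri} needs a nominal_domain")

    def accepts(self, value) -> bool:
        if self.value_kind == NUMERIC:
            return isinstance(value, (int, float)) and not isinstance(value, bool)
        if self.value_kind == NOMINAL:
            return value in (self.nominal_domain or ())
        return isinstance(value, str)

    def to_dict(self) -> dict:
        return {
            "uri": self.uri,
            "name": self.name,
            "value_kind": self.value_kind,
            "has_source": self.has_source,
            "nominal_domain": list(self.nominal_domain) if self.nominal_domain else None,
            "endpoint_ref": self.endpoint_ref,
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Feature":
        dom = d.get("nominal_domain")
        return cls(
            uri=d["uri"],
            name=d["name"],
            value_kind=d["value_kind"],
            has_source=d["has_source"],
            nominal_domain=tuple(dom) if dom else None,
            endpoint_ref=d.get("endpoint_ref"),
            units=d.get("units"),
        )


class Dataset:
    """Ordered data entries (compounds with feature values) plus a feature list.

    Missing values are simply absent from an entry's mapping — never sentinel
    numbers.
    """

    def __init__(
        self,
        uri: str,
        title: str = "",
        created: str = "",
        features: list[Feature] | None = None,
        compounds: list[Compound] | None = None,
        entries: dict[str, dict[str, object]] | None = None,
    ) -> None:
        self.uri = uri
        self.title = title
        self.created = created
        self.features: list[Feature] = list(features or [])
        self.compounds: dict[str, Compound] = {}
        self.entries: dict[str, dict[str, object]] = {}
        for c in compounds or []:
            self.add_compound(c)
        for curi, vals in (entries or {}).items():
            self.entries[curi] = dict(vals)

    # -- construction ------------------------------------------------------

    def add_compound(self, c: Compound) -> None:
        if c.uri in self.compounds:
            raise ValueError(f"duplicate compound uri in dataset: {c.uri}")
        self.compounds[c.uri] = c
        self.entries.setdefault(c.uri, {})

    def add_feature(self, f: Feature) -> None:
        if any(f2.uri == f.uri for f2 in self.features):
            raise ValueError(f"duplicate feature uri in dataset: {f.uri}")
        self.features.append(f)

    def feature(self, uri: str) -> Feature:
        for f in self.features:
            if f.uri == uri:
                return f
        raise KeyError(uri)

    def has_feature(self, uri: str) -> bool:
        return any(f.uri == uri for f in self.features)

    def set_value(self, compound_uri: str, feature_uri: str, value) -> None:
        f = self.feature(feature_uri)
        if not f.accepts(value):
            raise ValueError(
                f"value {value!r} violates {f.value_kind} feature {feature_uri}"
            )
        if compound_uri not in self.compounds:
            raise KeyError(compound_uri)
        self.entries[compound_uri][feature_uri] = value

    def get_value(self, compound_uri: str, feature_uri: str, default=None):
        return self.entries.get(compound_uri, {}).get(feature_uri, default)

    def validate(self) -> None:
        feature_uris = {f.uri for f in self.features}
        for curi, vals in self.entries.items():
            if curi not in self.compounds:
                raise ValueError(f"entry for unknown compound {curi}")
            for furi, v in vals.items():
                if furi not in feature_uris:
                    raise ValueError(f"value for unknown feature {furi}")
                if not self.feature(furi).accepts(v):
                    raise ValueError(
                        f"value {v!r} violates feature {furi} in entry {curi}"
                    )

    # -- derived -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.compounds)

    def subset(self, compound_uris: list[str], uri: str) -> "Dataset":
        """New dataset restricted to the given compounds (order as given)."""
        return Dataset(
            uri=uri,
            title=self.title,
            created=self.created,
            features=list(self.features),
            compounds=[self.compounds[c] for c in compound_uris],
            entries={c: dict(self.entries[c]) for c in compound_uris},
        )

    def to_dict(self) -> dict:
        return {
            "uri": self.uri,
            "title": self.title,
            "created": self.created,
            "features": [f.to_dict() for f in self.features],
            "compounds": [c.to_dict() for c in self.compounds.values()],
            "entries": {c: dict(v) for c, v in self.entries.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Dataset":
        return cls(
            uri=d["uri"],
            title=d.get("title", ""),
            created=d.get("created", ""),
            features=[Feature.from_dict(x) for x in d["features"]],
            compounds=[Compound.from_dict(x) for x in d["compounds"]],
            entries=d.get("entries", {}),
        )

    @property
    def snapshot_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.uri == other.uri
            and self.title == other.title
            and self.created == other.created
            and self.features == other.features
            and list(self.compounds.values()) == list(other.compounds.values())
            and self.entries == other.entries
        )
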