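"""In-memory resource store with optional directory persistence.

URIs are minted from a configurable base plus resource kind and a stable
counter, emulating web-addressable resources without a network.
"""

from __future__ import annotations

import json
import pathlib
from typing import Callable

from minitox.chemgraph import canonical_smiles, parse_smiles, SmilesParseError
from minitox.datastore.resources import Compound, Dataset


class NotFoundError(KeyError):
    pass


class DataStore:
    def __init__(self, base_uri: str = "urn:minitox:", root: str | None = None) -> None:
        self.base_uri = base_uri
        self.datasets: dict[str, Dataset] = {}
        self.models: dict[str, object] = {}
        self.validation_records: dict[str, object] = {}
        self.ad_models: dict[str, object] = {}
        self.log: list[str] = []
        self._counters: dict[str, int] = {}
        self.root = pathlib.Path(root) if root else None
        if self.root and self.root.exists():
            self._load()

    def mint_uri(self, kind: str) -> str:
        self._counters[kind] = self._counters.get(kind, 0) + 1
        return f"{self.base_uri}{kind}/{self._counters[kind]}"

    # -- dataset CRUD ------------------------------------------------------

    def store_dataset(self, d: Dataset) -> str:
        d.validate()
        if not d.uri:
            d.uri = self.mint_uri("dataset")
        self.datasets[d.uri] = d
        self.log.append(f"store dataset {d.uri} ({len(d)} entries)")
        self._persist()
        return d.uri

    def fetch_dataset(self, uri: str) -> Dataset:
        try:
            return self.datasets[uri]
        except KeyError:
            raise NotFoundError(f"no such dataset: {uri}") from None

    def update_dataset(self, uri: str, d: Dataset) -> None:
        if uri not in self.datasets:
            raise NotFoundError(f"no such dataset: {uri}")
        d.validate()
        d.uri = uri
        self.datasets[uri] = d
        self.log.append(f"update dataset {uri}")
        self._persist()

    def delete_dataset(self, uri: str) -> None:
        if uri not in self.datasets:
            raise NotFoundError(f"no such dataset: {uri}")
        del self.datasets[uri]
        self.log.append(f"delete dataset {uri}")
        self._persist()

    # -- model / record storage -------------------------------------------

    def store_model(self, model) -> str:
        if not model.uri:
            model.uri = self.mint_uri("model")
        self.models[model.uri] = model
        self.log.append(f"store model {model.uri}")
        self._persist()
        return model.uri

    def fetch_model(self, uri: str):
        try:
            return self.models[uri]
        except KeyError:
            raise NotFoundError(f"no such model: {uri}") from None

    def store_validation_record(self, record) -> str:
        if not record.uri:
            record.uri = self.mint_uri("validation")
        self.validation_records[record.uri] = record
        self.log.append(f"store validation record {record.uri}")
        self._persist()
        return record.uri

    def fetch_validation_record(self, uri: str):
        try:
            return self.validation_records[uri]
        except KeyError:
            raise NotFoundError(f"no such validation record: {uri}") from None

    def store_ad_model(self, ad) -> str:
        if not ad.uri:
            ad.uri = self.mint_uri("addomain")
        self.ad_models[ad.uri] = ad
        self.log.append(f"store AD model {ad.uri}")
        self._persist()
        return ad.uri

    # -- search / query ----------------------------------------------------

    def query_datasets(
        self,
        compound: str | None = None,
        endpoint: str | None = None,
        endpoint_descendants: Callable[[str], set] | None = None,
    ) -> list[tuple[str, list[tuple[str, str, object]]]]:
        """Datasets holding the compound (and optionally a matching endpoint).

        ``endpoint_descendants`` maps an endpoint class URI to its subclass
        closure (self included); without it the endpoint filter is exact.
        Returns ``(dataset_uri, [(compound_uri, feature_uri, value), ...])``.
        """
        accept: set | None = None
        if endpoint is not None:
            accept = (
                set(endpoint_descendants(endpoint))
                if endpoint_descendants
                else {endpoint}
            )
        out = []
        for uri in sorted(self.datasets):
            d = self.datasets[uri]
            compound_uris = list(d.compounds)
            if compound is not None:
                compound_uris = [c for c in compound_uris if c == compound]
                if not compound_uris:
                    continue
            hits = []
            for curi in compound_uris:
                for furi, value in sorted(d.entries.get(curi, {}).items()):
                    f = d.feature(furi)
                    if accept is not None and f.endpoint_ref not in accept:
                        continue
                    hits.append((curi, furi, value))
            if accept is not None and not hits:
                continue
            out.append((uri, hits))
        return out

    def search_compounds(self, query: str) -> list[Compound]:
        """Free-text search: name substring, canonical-SMILES or InChI match."""
        matches: dict[str, Compound] = {}
        canon = None
        try:
            canon = canonical_smiles(parse_smiles(query))
        except SmilesParseError:
            pass
        q = query.lower()
        for d in self.datasets.values():
            for c in d.compounds.values():
                if any(q in name.lower() for name in c.names):
                    matches[c.uri] = c
                elif canon is not None and c.canonical_smiles == canon:
                    matches[c.uri] = c
                elif c.inchi is not None and c.inchi == query:
                    matches[c.uri] = c
        return [matches[u] for u in sorted(matches)]

    # -- persistence -------------------------------------------------------

    def _persist(self) -> None:
        if self.root is None:
            return
        self.root.mkdir(parents=True, exist_ok=True)
        state = {
            "base_uri": self.base_uri,
            "counters": self._counters,
            "datasets": {u: d.to_dict() for u, d in self.datasets.items()},
            "models": {u: m.to_dict() for u, m in self.models.items()},
            "validation_records": {
                u: r.to_dict() for u, r in self.validation_records.items()
            },
            "ad_models": {u: a.to_dict() for u, a in self.ad_models.items()},
        }
        (self.root / "store.json").write_text(
            json.dumps(state, sort_keys=True, indent=1)
        )

    def _load(self) -> None:
        path = self.root / "store.json"
        if not path.exists():
            return
        # local imports avoid a cycle: algorithms/validation depend on datastore
        from minitox.algorithms import Model
        from minitox.addomain import ADModel
        from minitox.validation import ValidationRecord

        state = json.loads(path.read_text())
        self.base_uri = state["base_uri"]
        self._counters = dict(state["counters"])
        self.datasets = {
            u: Dataset.from_dict(d) for u, d in state["datasets"].items()
        }
        self.models = {u: Model.from_dict(m) for u, m in state["models"].items()}
        self.validation_records = {
            u: ValidationRecord.from_dict(r)
            for u, r in state["validation_records"].items()
        }
        self.ad_models = {
            u: ADModel.from_dict(a) for u, a in state["ad_models"].items()
        }
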