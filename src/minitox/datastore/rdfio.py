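"""RDF exchange for framework resources (the master data-exchange format).

Datasets, features and compounds map to full triple structures using the
``ot:`` vocabulary; models, applicability domains and validation records
additionally carry a canonical-JSON state literal so the round trip is
lossless. Output is byte-deterministic: triples are emitted sorted.
"""

from __future__ import annotations

import json

from minitox import rdf, vocab
from minitox.datastore.resources import Compound, Dataset, Feature
from minitox.rdf import Literal, TripleGraph


class SchemaError(ValueError):
    pass


# -- writing ---------------------------------------------------------------


def _feature_triples(g: TripleGraph, f: Feature) -> None:
    g.add(f.uri, vocab.RDF_TYPE, vocab.OT_FEATURE)
    g.add(f.uri, vocab.DC_TITLE, Literal(f.name))
    g.add(f.uri, vocab.OT_VALUE_KIND, Literal(f.value_kind))
    g.add(f.uri, vocab.OT_HAS_SOURCE, f.has_source)
    for v in f.nominal_domain or ():
        g.add(f.uri, vocab.OT_ACCEPT_VALUE, Literal(v))
    if f.endpoint_ref:
        g.add(f.uri, vocab.OT_ENDPOINT_REF, f.endpoint_ref)
    if f.units:
        g.add(f.uri, vocab.OT_UNITS, Literal(f.units))


def _compound_triples(g: TripleGraph, c: Compound) -> None:
    g.add(c.uri, vocab.RDF_TYPE, vocab.OT_COMPOUND)
    g.add(c.uri, vocab.OT_SMILES, Literal(c.canonical_smiles))
    for name in c.names:
        g.add(c.uri, vocab.OT_NAME, Literal(name))
    if c.inchi is not None:
        g.add(c.uri, vocab.OT_INCHI, Literal(c.inchi))
    if c.origin_inventory:
        g.add(c.uri, vocab.OT_ORIGIN, Literal(c.origin_inventory))


def dataset_to_graph(d: Dataset) -> TripleGraph:
    g = TripleGraph()
    g.add(d.uri, vocab.RDF_TYPE, vocab.OT_DATASET)
    if d.title:
        g.add(d.uri, vocab.DC_TITLE, Literal(d.title))
    if d.created:
        g.add(d.uri, vocab.DC_DATE, Literal(d.created))
    for i, f in enumerate(d.features):
        g.add(d.uri, vocab.OT_FEATURE_P, f.uri)
        g.add(f.uri, vocab.OT_INDEX, Literal(i))
        _feature_triples(g, f)
    for i, (curi, c) in enumerate(d.compounds.items()):
        entry = f"{d.uri}/entry/{i}"
        g.add(d.uri, vocab.OT_ENTRY_P, entry)
        g.add(entry, vocab.RDF_TYPE, vocab.OT_DATAENTRY)
        g.add(entry, vocab.OT_INDEX, Literal(i))
        g.add(entry, vocab.OT_COMPOUND_P, curi)
        _compound_triples(g, c)
        for j, furi in enumerate(sorted(d.entries.get(curi, {}))):
            vnode = f"{entry}/value/{j}"
            g.add(entry, vocab.OT_VALUES_P, vnode)
            g.add(vnode, vocab.RDF_TYPE, vocab.OT_FEATURE_VALUE)
            g.add(vnode, vocab.OT_FEATURE_P, furi)
            g.add(vnode, vocab.OT_VALUE_P, Literal(d.entries[curi][furi]))
    return g


def _stateful_to_graph(resource, type_class: str) -> TripleGraph:
    g = TripleGraph()
    g.add(resource.uri, vocab.RDF_TYPE, type_class)
    state = json.dumps(resource.to_dict(), sort_keys=True, separators=(",", ":"))
    g.add(resource.uri, vocab.OT_STATE, Literal(state))
    return g


def model_to_graph(m) -> TripleGraph:
    g = _stateful_to_graph(m, vocab.OT_MODEL)
    g.add(m.uri, vocab.OT_ALGORITHM_P, m.algorithm_uri)
    if m.training_dataset_uri:
        g.add(m.uri, vocab.OT_TRAINING_DATASET, m.training_dataset_uri)
    for furi in m.independent_feature_uris:
        g.add(m.uri, vocab.OT_INDEP, furi)
    if m.dependent_feature_uri:
        g.add(m.uri, vocab.OT_DEP, m.dependent_feature_uri)
    g.add(m.uri, vocab.OT_PREDICTED, m.predicted_feature_uri)
    g.add(m.uri, vocab.OT_CONFIDENCE, m.confidence_feature_uri)
    g.add(
        m.uri,
        vocab.OT_PARAMETERS,
        Literal(json.dumps(m.parameters, sort_keys=True, separators=(",", ":"))),
    )
    return g


def ad_to_graph(ad) -> TripleGraph:
    g = _stateful_to_graph(ad, vocab.OT_AD_MODEL)
    g.add(ad.uri, vocab.OT_METHOD, Literal(ad.method))
    return g


def validation_to_graph(r) -> TripleGraph:
    g = _stateful_to_graph(r, vocab.OT_VALIDATION)
    g.add(r.uri, vocab.OT_ALGORITHM_P, r.algorithm_uri)
    g.add(r.uri, vocab.OT_DATASET_HASH, Literal(r.dataset_hash))
    for uri in r.model_uris:
        g.add(r.uri, vocab.OT_MODEL_URIS, uri)
    return g


def rdf_write(resource, fmt: str = "turtle") -> str:
    """Serialize a Dataset, Feature, Model, ADModel or ValidationRecord."""
    from minitox.addomain import ADModel
    from minitox.algorithms import Model
    from minitox.validation import ValidationRecord

    if isinstance(resource, Dataset):
        g = dataset_to_graph(resource)
    elif isinstance(resource, Feature):
        g = TripleGraph()
        _feature_triples(g, resource)
    elif isinstance(resource, Model):
        g = model_to_graph(resource)
    elif isinstance(resource, ADModel):
        g = ad_to_graph(resource)
    elif isinstance(resource, ValidationRecord):
        g = validation_to_graph(resource)
    else:
        raise rdf.RDFError(f"unsupported resource kind: {type(resource).__name__}")
    return rdf.serialize(g, fmt)


# -- reading ---------------------------------------------------------------


def _read_feature(g: TripleGraph, furi: str) -> Feature:
    source = g.object(furi, vocab.OT_HAS_SOURCE)
    if source is None:
        raise SchemaError(f"feature {furi} lacks mandatory hasSource")
    domain = tuple(
        o.value for o in g.objects(furi, vocab.OT_ACCEPT_VALUE)
    ) or None
    return Feature(
        uri=furi,
        name=g.value(furi, vocab.DC_TITLE, ""),
        value_kind=g.value(furi, vocab.OT_VALUE_KIND, "string"),
        has_source=source,
        nominal_domain=domain,
        endpoint_ref=g.object(furi, vocab.OT_ENDPOINT_REF),
        units=g.value(furi, vocab.OT_UNITS),
    )


def _read_compound(g: TripleGraph, curi: str) -> Compound:
    smiles = g.value(curi, vocab.OT_SMILES)
    if smiles is None:
        raise SchemaError(f"compound {curi} lacks a structure")
    return Compound(
        uri=curi,
        canonical_smiles=smiles,
        names=[o.value for o in g.objects(curi, vocab.OT_NAME)],
        inchi=g.value(curi, vocab.OT_INCHI),
        origin_inventory=g.value(curi, vocab.OT_ORIGIN, ""),
    )


def graph_to_dataset(g: TripleGraph, duri: str) -> Dataset:
    features = sorted(
        g.objects(duri, vocab.OT_FEATURE_P),
        key=lambda f: g.value(f, vocab.OT_INDEX, 0),
    )
    d = Dataset(
        uri=duri,
        title=g.value(duri, vocab.DC_TITLE, ""),
        created=g.value(duri, vocab.DC_DATE, ""),
        features=[_read_feature(g, f) for f in features],
    )
    entries = sorted(
        g.objects(duri, vocab.OT_ENTRY_P),
        key=lambda e: g.value(e, vocab.OT_INDEX, 0),
    )
    for entry in entries:
        curi = g.object(entry, vocab.OT_COMPOUND_P)
        if curi is None:
            raise SchemaError(f"data entry {entry} lacks a compound")
        d.add_compound(_read_compound(g, curi))
        for vnode in g.objects(entry, vocab.OT_VALUES_P):
            furi = g.object(vnode, vocab.OT_FEATURE_P)
            value = g.value(vnode, vocab.OT_VALUE_P)
            if furi is None or value is None:
                raise SchemaError(f"feature value {vnode} is incomplete")
            d.set_value(curi, furi, value)
    return d


def rdf_read(document: str, fmt: str = "turtle"):
    """Reconstruct the resource serialized by :func:`rdf_write`."""
    from minitox.addomain import ADModel
    from minitox.algorithms import Model
    from minitox.validation import ValidationRecord

    g = rdf.parse(document, fmt)
    for type_class, builder in (
        (vocab.OT_DATASET, None),
        (vocab.OT_MODEL, Model),
        (vocab.OT_AD_MODEL, ADModel),
        (vocab.OT_VALIDATION, ValidationRecord),
    ):
        subjects = g.subjects(vocab.RDF_TYPE, type_class)
        if not subjects:
            continue
        uri = subjects[0]
        if builder is None:
            return graph_to_dataset(g, uri)
        state = g.value(uri, vocab.OT_STATE)
        if state is None:
            raise SchemaError(f"resource {uri} lacks its state literal")
        return builder.from_dict(json.loads(state))
    # bare feature document
    feats = g.subjects(vocab.RDF_TYPE, vocab.OT_FEATURE)
    if feats:
        return _read_feature(g, feats[0])
    raise SchemaError("document contains no recognized resource")
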