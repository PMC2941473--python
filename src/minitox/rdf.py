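"""Minimal RDF triple graph with deterministic Turtle and RDF/XML exchange.

The serializations are byte-deterministic (triples sorted) and self-
round-tripping. The Turtle writer emits one N-Triples-style statement per
line, which is valid Turtle and keeps the reader small; RDF/XML goes through
``xml.etree`` so documents are well-formed XML.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Iterable, Iterator

from minitox.vocab import XSD

_XSD_DOUBLE = XSD + "double"
_XSD_INTEGER = XSD + "integer"


@dataclass(frozen=True)
class Literal:
    """Typed literal: ``kind`` is 'string' or 'number'."""

    value: object

    @property
    def kind(self) -> str:
        return "number" if isinstance(self.value, (int, float)) and not isinstance(self.value, bool) else "string"

    def lexical(self) -> str:
        if self.kind == "number":
            return repr(self.value)
        return str(self.value)

    def sort_key(self) -> tuple:
        return (self.kind, self.lexical())


class RDFError(ValueError):
    pass


class TripleGraph:
    """A set of (subject-URI, predicate-URI, URI-or-Literal) triples."""

    def __init__(self, triples: Iterable[tuple] = ()) -> None:
        self._triples: set[tuple] = set()
        for s, p, o in triples:
            self.add(s, p, o)

    def add(self, s: str, p: str, o) -> None:
        if not isinstance(s, str) or not isinstance(p, str):
            raise RDFError("subject and predicate must be URIs")
        if not isinstance(o, (str, Literal)):
            raise RDFError(f"object must be a URI or Literal, got {type(o).__name__}")
        self._triples.add((s, p, o))

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[tuple]:
        return iter(self.sorted())

    def __contains__(self, triple: tuple) -> bool:
        return triple in self._triples

    def sorted(self) -> list[tuple]:
        def key(t):
            s, p, o = t
            okey = ("uri", o) if isinstance(o, str) else ("lit",) + o.sort_key()
            return (s, p, okey)

        return sorted(self._triples, key=key)

    def objects(self, s: str, p: str) -> list:
        return [o for (s2, p2, o) in self.sorted() if s2 == s and p2 == p]

    def object(self, s: str, p: str, default=None):
        objs = self.objects(s, p)
        return objs[0] if objs else default

    def subjects(self, p: str, o) -> list[str]:
        return sorted({s for (s, p2, o2) in self._triples if p2 == p and o2 == o})

    def value(self, s: str, p: str, default=None):
        o = self.object(s, p)
        if o is None:
            return default
        return o.value if isinstance(o, Literal) else o


# -- Turtle ----------------------------------------------------------------

_IRI = r"<([^>]*)>"
_STRLIT = r'"((?:[^"\\]|\\.)*)"'
_TTL_LINE = re.compile(
    rf"^{_IRI}\s+{_IRI}\s+(?:{_IRI}|{_STRLIT}(?:\^\^{_IRI})?)\s*\.$"
)


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t")


def _unescape(s: str) -> str:
    return (
        s.replace("\\t", "\t")
        .replace("\\r", "\r")
        .replace("\\n", "\n")
        .replace('\\"', '"')
        .replace("\\\\", "\\")
    )


def _number_from_lexical(lex: str):
    try:
        return int(lex)
    except ValueError:
        return float(lex)


def to_turtle(g: TripleGraph) -> str:
    lines = []
    for s, p, o in g.sorted():
        if isinstance(o, str):
            obj = f"<{o}>"
        elif o.kind == "number":
            dt = _XSD_INTEGER if isinstance(o.value, int) else _XSD_DOUBLE
            obj = f'"{o.lexical()}"^^<{dt}>'
        else:
            obj = f'"{_escape(o.lexical())}"'
        lines.append(f"<{s}> <{p}> {obj} .")
    return "\n".join(lines) + ("\n" if lines else "")


def from_turtle(text: str) -> TripleGraph:
    g = TripleGraph()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("@prefix"):
            continue
        m = _TTL_LINE.match(line)
        if not m:
            raise RDFError(f"unparseable turtle statement on line {lineno}: {raw!r}")
        s, p, ouri, olit, odt = m.groups()
        if ouri is not None:
            g.add(s, p, ouri)
        elif odt in (_XSD_DOUBLE, _XSD_INTEGER):
            g.add(s, p, Literal(_number_from_lexical(olit)))
        else:
            g.add(s, p, Literal(_unescape(olit)))
    return g


# -- RDF/XML ---------------------------------------------------------------

_RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

_NCNAME = re.compile(r"[A-Za-z_][A-Za-z0-9_.-]*$")


def _split_predicate(p: str) -> tuple[str, str]:
    """Split a predicate URI into (namespace, XML-safe local name)."""
    for sep in ("#", "/", ":"):
        idx = p.rfind(sep)
        if idx >= 0 and _NCNAME.match(p[idx + 1 :]):
            return p[: idx + 1], p[idx + 1 :]
    raise RDFError(f"predicate {p!r} cannot map to an XML property element")


def to_rdfxml(g: TripleGraph) -> str:
    ET.register_namespace("rdf", _RDF_NS)
    root = ET.Element(f"{{{_RDF_NS}}}RDF")
    by_subject: dict[str, list[tuple]] = {}
    for s, p, o in g.sorted():
        by_subject.setdefault(s, []).append((p, o))
    for s in sorted(by_subject):
        desc = ET.SubElement(root, f"{{{_RDF_NS}}}Description")
        desc.set(f"{{{_RDF_NS}}}about", s)
        for p, o in by_subject[s]:
            ns, local = _split_predicate(p)
            el = ET.SubElement(desc, f"{{{ns}}}{local}")
            if isinstance(o, str):
                el.set(f"{{{_RDF_NS}}}resource", o)
            else:
                if o.kind == "number":
                    dt = _XSD_INTEGER if isinstance(o.value, int) else _XSD_DOUBLE
                    el.set(f"{{{_RDF_NS}}}datatype", dt)
                el.text = o.lexical()
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def from_rdfxml(text: str) -> TripleGraph:
    g = TripleGraph()
    root = ET.fromstring(text)
    for desc in root:
        s = desc.get(f"{{{_RDF_NS}}}about")
        if s is None:
            raise RDFError("rdf:Description without rdf:about")
        for el in desc:
            p = el.tag.replace("{", "").replace("}", "")
            res = el.get(f"{{{_RDF_NS}}}resource")
            if res is not None:
                g.add(s, p, res)
                continue
            dt = el.get(f"{{{_RDF_NS}}}datatype")
            lex = el.text or ""
            if dt in (_XSD_DOUBLE, _XSD_INTEGER):
                g.add(s, p, Literal(_number_from_lexical(lex)))
            else:
                g.add(s, p, Literal(lex))
    return g


def serialize(g: TripleGraph, fmt: str) -> str:
    if fmt == "turtle":
        return to_turtle(g)
    if fmt == "rdfxml":
        return to_rdfxml(g)
    raise RDFError(f"unsupported RDF format: {fmt!r}")


def parse(text: str, fmt: str) -> TripleGraph:
    if fmt == "turtle":
        return from_turtle(text)
    if fmt == "rdfxml":
        return from_rdfxml(text)
    raise RDFError(f"unsupported RDF format: {fmt!r}")
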