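"""Applicability-domain models: distance-to-training and descriptor-range.

An AD algorithm applied to a dataset yields an AD model, which is then used
to reason about the applicability of predictions for new query compounds.
AD findings are reported alongside predictions, never used to suppress them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from minitox.chemgraph import (
    molecular_descriptors,
    parse_smiles,
    tanimoto,
)
from minitox.algorithms import _fp_cached
from minitox.datastore.resources import Dataset, NUMERIC

SIMILARITY = "similarity"
RANGE = "range"


@dataclass
class ADResult:
    inside: bool
    score: float


@dataclass
class ADModel:
    uri: str
    method: str
    threshold: float = 0.3
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    training_smiles: list[str] = field(default_factory=list)
    fp_max_path_atoms: int = 7
    fp_length: int = 1024

    def __post_init__(self) -> None:
        if self.method not in (SIMILARITY, RANGE):
            raise ValueError(f"unknown AD method: {self.method}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0,1]")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound for {name} has min > max")

    def to_dict(self) -> dict:
        return {
            "uri": self.uri,
            "method": self.method,
            "threshold": self.threshold,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "training_smiles": list(self.training_smiles),
            "fp_max_path_atoms": self.fp_max_path_atoms,
            "fp_length": self.fp_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ADModel":
        return cls(
            uri=d["uri"],
            method=d["method"],
            threshold=d["threshold"],
            bounds={k: tuple(v) for k, v in d["bounds"].items()},
            training_smiles=list(d["training_smiles"]),
            fp_max_path_atoms=d.get("fp_max_path_atoms", 7),
            fp_length=d.get("fp_length", 1024),
        )


def build_ad(
    dataset: Dataset, method: str, params: dict | None = None, uri: str = ""
) -> ADModel:
    params = params or {}
    if not dataset.compounds:
        raise ValueError("cannot build an applicability domain on an empty dataset")
    if method == SIMILARITY:
        return ADModel(
            uri=uri,
            method=SIMILARITY,
            threshold=float(params.get("t", 0.3)),
            training_smiles=sorted(
                c.canonical_smiles for c in dataset.compounds.values()
            ),
            fp_max_path_atoms=int(params.get("fp_max_path_atoms", 7)),
            fp_length=int(params.get("fp_length", 1024)),
        )
    if method == RANGE:
        numeric = [f for f in dataset.features if f.value_kind == NUMERIC]
        names = params.get("features")
        if names is not None:
            numeric = [f for f in numeric if f.name in names or f.uri in names]
        bounds: dict[str, tuple[float, float]] = {}
        for f in numeric:
            values = [
                float(dataset.get_value(c, f.uri))
                for c in dataset.compounds
                if dataset.get_value(c, f.uri) is not None
            ]
            if values:
                bounds[f.name] = (min(values), max(values))
        if not bounds:
            raise ValueError("range AD needs numeric descriptor features with values")
        return ADModel(uri=uri, method=RANGE, bounds=bounds)
    raise ValueError(f"unknown AD method: {method}")


def apply_ad(ad: ADModel, smiles: str) -> ADResult:
    """Score a query structure against a trained applicability domain.

    similarity: score = max Tanimoto to the training set, inside iff >= t.
    range: score = fraction of descriptors inside bounds, inside iff all are.
    """
    g = parse_smiles(smiles)  # raises on unparseable structure
    if ad.method == SIMILARITY:
        fp = _fp_cached(smiles, ad.fp_max_path_atoms, ad.fp_length)
        score = max(
            tanimoto(fp, _fp_cached(s, ad.fp_max_path_atoms, ad.fp_length))
            for s in ad.training_smiles
        )
        return ADResult(inside=score >= ad.threshold, score=score)
    vec = molecular_descriptors(g).as_dict()
    inside_count = 0
    considered = 0
    for name, (lo, hi) in ad.bounds.items():
        if name not in vec:
            continue
        considered += 1
        if lo <= vec[name] <= hi:
            inside_count += 1
    if considered == 0:
        return ADResult(inside=False, score=0.0)
    score = inside_count / considered
    return ADResult(inside=score == 1.0, score=score)
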