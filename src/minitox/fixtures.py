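"""Synthetic toy QSAR data with a planted structure-activity signal.

Molecules are assembled from a small fragment grammar (alkyl chains,
branches, benzene rings, ethers, carbonyls) that never produces nitrogen, so
grafting the charged nitro toxicophore plants a substructure signal that is
guaranteed detectable in path fingerprints. Everything is deterministic
given the seed, and all molecules stay within 20 heavy atoms.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass

from minitox.chemgraph import canonical_smiles, molecular_descriptors, parse_smiles
from minitox.datastore.csvio import IngestResult, ingest_training_csv
from minitox.datastore.resources import Compound, Dataset, Feature, NUMERIC
from minitox.services import endpoint_uri

#: nitro group grafted through a carbon atom
DEFAULT_TOXICOPHORE = "C[N+](=O)[O-]"

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass
class FixtureSpec:
    n: int = 100
    toxicophore: str = DEFAULT_TOXICOPHORE
    prevalence: float = 0.5
    noise: float = 0.0
    seed: int = 0
    beta: tuple[float, float, float] = (1.0, 2.0, 0.5)  # b0 + b1*count + b2*(MW/100)
    sigma: float = 0.0
    endpoint_label: str = "Mutagenicity"

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0,1]")
        if not 0.0 <= self.noise <= 0.5:
            raise ValueError("noise must lie in [0, 0.5]")


def _random_scaffold(rng: random.Random, max_heavy: int = 14) -> str:
    parts = []
    heavy = 0
    if rng.random() < 0.4:
        parts.append("c1ccccc1")
        heavy += 6
    length = rng.randint(2, 6)
    for i in range(length):
        if heavy >= max_heavy:
            break
        parts.append("O" if (i > 0 and rng.random() < 0.15) else "C")
        heavy += 1
        if parts[-1] == "C" and heavy + 2 <= max_heavy and rng.random() < 0.3:
            branch = rng.choice(["(C)", "(CC)", "(=O)"])
            parts.append(branch)
            heavy += branch.count("C") + branch.count("O")
    if parts == ["c1ccccc1"]:
        parts.append("C")
        heavy += 1
    return "".join(parts)


def _generate_unique(
    rng: random.Random, count: int, graft: str, copies: int = 1
) -> list[str]:
    """Distinct canonical structures, each with `copies` grafted toxicophores."""
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < count:
        attempts += 1
        if attempts > count * 500 + 1000:
            raise RuntimeError("fragment grammar exhausted; lower n")
        smiles = _random_scaffold(rng) + graft * copies
        canon = canonical_smiles(parse_smiles(smiles))
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    return out


def generate_classification_fixture(spec: FixtureSpec) -> tuple[IngestResult, str]:
    """Toy binary-activity dataset; label = carries-toxicophore, then flipped
    independently with probability `noise`. Returns the ingest result (with
    the dataset) and the CSV text."""
    rng = random.Random(spec.seed)
    n_pos = round(spec.n * spec.prevalence)
    positives = _generate_unique(rng, n_pos, spec.toxicophore)
    neg_rng_smiles = []
    seen = set(positives)
    while len(neg_rng_smiles) < spec.n - n_pos:
        cand = _generate_unique(rng, 1, "")[0]
        if cand not in seen:
            seen.add(cand)
            neg_rng_smiles.append(cand)
    rows = [(s, True) for s in positives] + [(s, False) for s in neg_rng_smiles]
    rng.shuffle(rows)
    lines = ["smiles,activity"]
    for smiles, is_pos in rows:
        label = is_pos
        if spec.noise > 0 and rng.random() < spec.noise:
            label = not label
        lines.append(f"{smiles},{ACTIVE if label else INACTIVE}")
    csv_text = "\n".join(lines) + "\n"
    result = ingest_training_csv(
        io.StringIO(csv_text),
        dataset_uri=f"urn:minitox:dataset/fixture-cls-{spec.seed}",
        title=f"classification fixture (n={spec.n}, seed={spec.seed})",
    )
    result.dataset.feature(result.activity_feature_uri).endpoint_ref = endpoint_uri(
        spec.endpoint_label
    )
    return result, csv_text


def generate_regression_fixture(spec: FixtureSpec) -> tuple[Dataset, str]:
    """Toy regression dataset: y = b0 + b1*(toxicophore count) + b2*(MW/100)
    + Normal(0, sigma)."""
    rng = random.Random(spec.seed)
    counts = [rng.choice((0, 1, 2, 3)) for _ in range(spec.n)]
    structures: list[tuple[str, int]] = []
    seen: set[str] = set()
    for c in counts:
        while True:
            smiles = _random_scaffold(rng) + spec.toxicophore * c
            canon = canonical_smiles(parse_smiles(smiles))
            if canon not in seen:
                seen.add(canon)
                structures.append((canon, c))
                break
    b0, b1, b2 = spec.beta
    uri = f"urn:minitox:dataset/fixture-reg-{spec.seed}"
    dataset = Dataset(
        uri=uri, title=f"regression fixture (n={spec.n}, seed={spec.seed})"
    )
    target = Feature(
        uri=uri + "/feature/y",
        name="y",
        value_kind=NUMERIC,
        has_source=uri,
        endpoint_ref=endpoint_uri(spec.endpoint_label),
    )
    dataset.add_feature(target)
    lines = ["smiles,activity"]
    for i, (canon, count) in enumerate(structures, start=1):
        mw = molecular_descriptors(parse_smiles(canon)).molecular_weight
        y = b0 + b1 * count + b2 * (mw / 100.0)
        if spec.sigma > 0:
            y += rng.gauss(0.0, spec.sigma)
        curi = f"{uri}/compound/{i}"
        dataset.add_compound(Compound(uri=curi, canonical_smiles=canon))
        dataset.set_value(curi, target.uri, y)
        lines.append(f"{canon},{y!r}")
    return dataset, "\n".join(lines) + "\n"
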