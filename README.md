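# minitox

A desk-scale, fully self-contained predictive-toxicology toolkit. It wires
together the classic components of an interoperable QSAR framework —
compounds, datasets, features, algorithms, models, applicability domains,
validation, an endpoint ontology, asynchronous tasks and reports — around
RDF as the exchange format, and exposes two end-user workflows:

* **toxpredict** — predict the toxicity of a structure in five logged stages
  (structure search, display/check, ontology-driven model selection,
  task-based estimation with descriptor auto-resolution and applicability
  domain, report);
* **toxcreate** — build a model from a `smiles,activity` CSV, cross-validate
  it with stored split plans, persist it, and predict/compare later.

No external data or network is needed: a synthetic-fixture module generates
toy datasets with a planted structure-activity signal (a charged nitro
toxicophore grafted onto a nitrogen-free fragment grammar).

## Layout

| module | role |
| --- | --- |
| `minitox.chemgraph` | SMILES-subset parser, canonical SMILES (Morgan-style refinement + tie-break search), structure checks, descriptors (`MW`, `HeavyAtoms`, `Rings`, `AromaticAtoms`, `HBD`, `HBA`), linear path fingerprints (FNV-1a), Tanimoto |
| `minitox.datastore` | Compound/Feature/Dataset model with `hasSource` provenance, CRUD + search + endpoint queries, CSV and minimal SDF V2000 readers, RDF/XML + Turtle exchange |
| `minitox.algorithms` | algorithm registry with template metadata and type ontology; descriptor calculation, chi-square feature ranking, similarity-weighted k-NN (with `s_min` unpredicted gate), OLS regression |
| `minitox.addomain` | similarity- and range-based applicability domains |
| `minitox.validation` | split plans with stored seeds and explicit assignments, train/test / k-fold / LOO runs, confusion/precision/recall/F2, ROC + AUC (tie-aware), MSE/RMSE/R², reproducible validation records |
| `minitox.services` | triple store with basic-graph-pattern queries, endpoint + algorithm ontologies, async task contract, `hasSource` feature auto-resolution |
| `minitox.reports` | deterministic HTML/structured reports, the two workflows, model comparison and feature-selection evaluation |
| `minitox.fixtures` | seeded synthetic classification/regression datasets |

## CLI

```sh
# make a toy dataset
minitox --store st fixtures make --n 200 --noise 0.1 --seed 42 --out toy.csv

# build + cross-validate a model (persisted under ./st)
minitox --store st toxcreate build toy.csv --k 10 --seed 42 --out report.html

# predict a structure with every stored model (five STEP markers are logged)
minitox --store st toxpredict --query "CCC[N+](=O)[O-]" --ad similarity:t=0.3 --out pred.html

# predict the same structure with several stored models and compare
minitox --store st toxcreate predict "CCO"

# independent validation and record ranking
minitox --store st validate --algorithm knn --dataset <uri> --dependent-feature <uri> --k 10 --seed 42
minitox --store st compare <record-uri> <record-uri> --criterion auc
```

## Notes

* RDF serializations are byte-deterministic (sorted triples); Turtle uses
  one statement per line, RDF/XML is emitted through `xml.etree`.
* Canonical SMILES is implementation-canonical: deterministic and
  input-order independent, but not aligned with any external toolkit.
* Aromaticity is not perceived — lowercase input is trusted, so a
  Kekulé-written ring and an aromatic-written ring are distinct graphs.
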