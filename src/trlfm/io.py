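"""Readers and writers for expression tables, annotation maps, ontologies,
good-rule criteria configs and rule-model JSON.

File conventions
----------------
* Expression tables are TSV, samples in rows and genes in columns; the first
  column holds the sample identifier and one column (``class`` by default)
  holds the class label.  Values are either continuous (dot-decimal floats)
  or discretization interval indices (non-negative integers).
* Annotation maps are two-column TSV: ``gene<TAB>term``.
* Ontologies are either a two-column child->parent edge-list TSV restricted
  to is_a relations, or an OBO file (only ``is_a`` edges are used).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Dataset",
    "AnnotationMap",
    "OntologyGraph",
    "GoodRuleCriteria",
    "read_expression_table",
    "write_expression_table",
    "read_annotations",
    "write_annotations",
    "read_ontology",
    "write_ontology",
    "load_criteria",
    "serialize_rule_model",
    "deserialize_rule_model",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A sample x variable expression table with one class label per sample.

    ``values`` is a pandas DataFrame indexed by ``sample_ids`` with
    ``variable_names`` as columns; float dtype for continuous data, integer
    interval indices after discretization (``discrete=True``).
    """

    values: pd.DataFrame
    class_labels: list[str]
    class_domain: tuple[str, ...]
    discrete: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate variable name: {dup!r}")
        if len(self.class_labels) != len(self.values):
            raise ValueError("class_labels length does not match sample count")
        if len(self.class_domain) < 2:
            raise ValueError("class_domain must contain at least two classes")
        unknown = set(self.class_labels) - set(self.class_domain)
        if unknown:
            raise ValueError(f"labels outside class_domain: {sorted(unknown)}")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression table")

    # -- convenience accessors ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.class_labels, dtype=object)

    def select_variables(self, variables: Sequence[str]) -> "Dataset":
        """Project onto a subset of variables (sample order preserved)."""
        return Dataset(
            values=self.values.loc[:, list(variables)].copy(),
            class_labels=list(self.class_labels),
            class_domain=self.class_domain,
            discrete=self.discrete,
        )

    def take_samples(self, indices: Sequence[int]) -> "Dataset":
        idx = list(indices)
        return Dataset(
            values=self.values.iloc[idx].copy(),
            class_labels=[self.class_labels[i] for i in idx],
            class_domain=self.class_domain,
            discrete=self.discrete,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.discrete == other.discrete
            and self.class_domain == other.class_domain
            and self.class_labels == other.class_labels
            and self.values.equals(other.values)
            and self.sample_ids == other.sample_ids
            and self.variable_names == other.variable_names
        )


class AnnotationMap(Mapping):
    """Gene symbol -> set of ontology term IDs (e.g. a GO-annotation extract)."""

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, frozenset[str]] = {}
        for gene, terms in entries.items():
            ts = frozenset(terms)
            if not ts:
                raise ValueError(f"gene {gene!r} has an empty term set")
            self.entries[gene] = ts

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self.entries[gene]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, ontology: "OntologyGraph") -> None:
        """Every annotated term must exist in the companion ontology."""
        for gene, terms in self.entries.items():
            orphan = terms - ontology.terms
            if orphan:
                raise ValueError(
                    f"gene {gene!r} annotated to terms absent from the "
                    f"ontology: {sorted(orphan)}"
                )


class OntologyGraph:
    """A rooted is_a DAG of ontology terms, edges directed child -> parent."""

    def __init__(self, parent_edges: Iterable[tuple[str, str]]):
        g = nx.DiGraph()
        for child, parent in parent_edges:
            g.add_edge(child, parent)
        if g.number_of_nodes() == 0:
            raise ValueError("ontology has no terms")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {sorted(roots)}")
        self.graph = g
        self.root: str = roots[0]
        self.terms: frozenset[str] = frozenset(g.nodes)

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable via is_a edges, including ``term`` itself."""
        if term not in self.terms:
            raise KeyError(f"term {term!r} not in ontology")
        return frozenset(nx.descendants(self.graph, term)) | {term}

    def parents(self, term: str) -> list[str]:
        return sorted(self.graph.successors(term))

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)


@dataclass(frozen=True)
class GoodRuleCriteria:
    """Admission thresholds a rule must satisfy to enter the final model."""

    min_cf: float = 0.85
    min_coverage: int = 4
    max_fp_rate: float = 0.1
    max_conjuncts: int = 3
    inductive_strengthening: int = 1
    beam_width: int = 1000
    cf_function: str = "laplace"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_cf <= 1.0:
            raise ValueError("min_cf must lie in [0, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be a positive integer")
        if not 0.0 <= self.max_fp_rate <= 1.0:
            raise ValueError("max_fp_rate must lie in [0, 1]")
        if self.max_conjuncts < 1:
            raise ValueError("max_conjuncts must be a positive integer")
        if self.inductive_strengthening < 0:
            raise ValueError("inductive_strengthening must be non-negative")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.cf_function not in ("laplace", "precision"):
            raise ValueError("cf_function must be 'laplace' or 'precision'")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

_INT_TOKEN = frozenset("0123456789")


def read_expression_table(path, label_column: str = "class") -> Dataset:
    """Read a TSV expression table (first column = sample ID).

    The class domain is inferred from distinct labels in order of first
    appearance.  Values are parsed as interval indices (all-integer table)
    or floats otherwise.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    if label_column not in header[1:]:
        raise ValueError(f"{path}: missing label column {label_column!r}")
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"{path}: row {lineno} has {len(row)} fields, expected {width}")
    label_idx = header.index(label_column)
    var_cols = [(i, name) for i, name in enumerate(header) if i not in (0, label_idx)]

    sample_ids: list[str] = []
    seen: set[str] = set()
    labels: list[str] = []
    data: list[list[str]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        sid = row[0]
        if sid in seen:
            raise ValueError(f"{path}: row {lineno}: duplicate sample ID {sid!r}")
        seen.add(sid)
        sample_ids.append(sid)
        labels.append(row[label_idx])
        data.append([row[i] for i, _ in var_cols])

    discrete = all(tok and set(tok) <= _INT_TOKEN for row in data for tok in row)
    dtype = int if discrete else float
    values = pd.DataFrame(
        np.array(data, dtype=object).astype(dtype) if data else [],
        index=pd.Index(sample_ids, name="sample"),
        columns=[name for _, name in var_cols],
    )
    domain = tuple(dict.fromkeys(labels))
    return Dataset(values=values, class_labels=labels, class_domain=domain, discrete=discrete)


def write_expression_table(dataset: Dataset, path, label_column: str = "class") -> None:
    out = dataset.values.copy()
    out.insert(len(out.columns), label_column, dataset.class_labels)
    out.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def read_annotations(path) -> AnnotationMap:
    """Read a two-column ``gene<TAB>term`` TSV into an :class:`AnnotationMap`."""
    entries: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields, got {len(row)}")
            gene, term = row[0].strip(), row[1].strip()
            entries.setdefault(gene, set()).add(term)
    return AnnotationMap(entries)


def write_annotations(annotations: AnnotationMap, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                w.writerow([gene, term])


# ---------------------------------------------------------------------------
# ontologies
# ---------------------------------------------------------------------------


def read_ontology(path) -> OntologyGraph:
    """Read an ontology from an edge-list TSV, or from OBO when the file
    ends in ``.obo`` (only ``is_a`` edges are retained)."""
    spath = str(path)
    if spath.endswith(".obo"):
        import obonet

        multigraph = obonet.read_obo(spath)
        edges = [
            (child, parent)
            for child, parent, key in multigraph.edges(keys=True)
            if key == "is_a"
        ]
        return OntologyGraph(edges)
    edges = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields, got {len(row)}")
            edges.append((row[0].strip(), row[1].strip()))
    return OntologyGraph(edges)


def write_ontology(ontology: OntologyGraph, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for child, parent in ontology.edges():
            w.writerow([child, parent])


# ---------------------------------------------------------------------------
# criteria configs
# ---------------------------------------------------------------------------


def load_criteria(path) -> GoodRuleCriteria:
    """Load good-rule criteria from a YAML or JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    allowed = set(GoodRuleCriteria.__dataclass_fields__)
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown criteria fields {sorted(unknown)}")
    return GoodRuleCriteria(**cfg)


# ---------------------------------------------------------------------------
# rule-model JSON
# ---------------------------------------------------------------------------


def _bound_to_json(x: float):
    if math.isinf(x):
        return "+inf" if x > 0 else "-inf"
    return x


def _bound_from_json(x) -> float:
    if x == "+inf":
        return math.inf
    if x == "-inf":
        return -math.inf
    return float(x)


def serialize_rule_model(model, path) -> None:
    """Write a rule model to JSON (human-auditable IF-THEN form).

    Interval bounds are included when the model carries a discretization
    scheme; +/- infinity are written as distinguished string tokens.
    """
    from .rl import RuleModel  # local import: rl depends on io's Dataset

    assert isinstance(model, RuleModel)
    doc = {
        "criteria": dict(model.criteria.__dict__),
        "class_domain": list(model.class_domain),
        "provenance": model.provenance,
        "rules": [],
    }
    scheme = model.scheme
    for rule in model.rules:
        conjuncts = []
        for var, interval in rule.conjuncts:
            entry = {"variable": var, "interval": interval}
            if scheme is not None and var in scheme.cuts:
                lo, hi = scheme.interval_bounds(var, interval)
                entry["low"] = _bound_to_json(lo)
                entry["high"] = _bound_to_json(hi)
            conjuncts.append(entry)
        doc["rules"].append(
            {
                "conjuncts": conjuncts,
                "consequent": rule.consequent,
                "tp": rule.tp,
                "fp": rule.fp,
                "coverage": rule.coverage,
                "cf": rule.cf,
                "p_value": rule.p_value,
            }
        )
    if scheme is not None:
        doc["scheme"] = {v: list(c) for v, c in scheme.cuts.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def deserialize_rule_model(path):
    """Inverse of :func:`serialize_rule_model`."""
    from .ebd import DiscretizationScheme
    from .rl import Rule, RuleModel

    with open(path) as fh:
        doc = json.load(fh)
    criteria = GoodRuleCriteria(**doc["criteria"])
    rules = []
    for r in doc["rules"]:
        rules.append(
            Rule(
                conjuncts=tuple((c["variable"], c["interval"]) for c in r["conjuncts"]),
                consequent=r["consequent"],
                tp=r["tp"],
                fp=r["fp"],
                cf=r["cf"],
                p_value=r["p_value"],
            )
        )
    scheme = None
    if "scheme" in doc:
        scheme = DiscretizationScheme(
            cuts={v: list(map(float, c)) for v, c in doc["scheme"].items()}
        )
    return RuleModel(
        rules=tuple(rules),
        criteria=criteria,
        class_domain=tuple(doc["class_domain"]),
        scheme=scheme,
        provenance=doc.get("provenance", {}),
    )
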