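"""Synthetic fixtures: toy ontologies with module-structured annotations and
case/control expression pairs carrying a planted, transferable signal.

The generator emulates the data regime the framework targets: small-sample
case/control expression tables whose informative genes fall into functional
modules, with only partial gene-symbol overlap between a source and a
target dataset.  Informative genes of the same planted module are annotated
to leaves of the same well-separated ontology branch, so a source marker
and a differently named target marker can only be linked through functional
-module discovery -- the cross-symbol transfer scenario.

Expression is Gaussian and class-conditional: informative genes shift their
mean by ``effect_size`` standard deviations between classes (direction
alternating per gene), noise genes are standard normal.  Everything is
deterministic under ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationMap, Dataset, OntologyGraph

__all__ = [
    "SynthSpec",
    "planted_symbols",
    "make_ontology_and_annotations",
    "make_expression_pair",
    "worked_example_dataset",
    "WORKED_EXAMPLE_RULE",
]

ROOT = "T:ROOT"


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic source/target study."""

    n_samples: int = 100
    n_genes: int = 30
    n_modules: int = 2
    genes_per_module: int = 4
    effect_size: float = 2.0
    case_fraction: float = 0.5
    symbol_overlap_fraction: float = 0.5
    noise_annotation_rate: float = 0.0
    terms_per_module: int = 4
    distribution: str = "normal"  # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("case_fraction", "symbol_overlap_fraction", "noise_annotation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_modules < 2:
            raise ValueError("need at least two planted modules")
        if self.n_genes < self.n_modules * self.genes_per_module:
            raise ValueError("n_genes smaller than the planted informative genes")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be 'normal' or 'lognormal'")


def planted_symbols(spec: SynthSpec) -> list[dict[str, list[str]]]:
    """Per-module informative gene symbols.

    Each module contributes ``genes_per_module`` informative genes to the
    source and to the target; a ``symbol_overlap_fraction`` of them share
    the same symbol, the rest differ but sit in the same module.
    """
    out = []
    for m in range(1, spec.n_modules + 1):
        n_shared = round(spec.symbol_overlap_fraction * spec.genes_per_module)
        shared = [f"SH{m}_{i}" for i in range(1, n_shared + 1)]
        only = spec.genes_per_module - n_shared
        src = shared + [f"SRC{m}_{i}" for i in range(1, only + 1)]
        tgt = shared + [f"TGT{m}_{i}" for i in range(1, only + 1)]
        out.append({"source": src, "target": tgt, "all": sorted(set(src + tgt))})
    return out


def make_ontology_and_annotations(spec: SynthSpec) -> tuple[OntologyGraph, AnnotationMap]:
    """One root, ``n_modules`` separated branches; genes of planted module m
    annotate only leaves of branch m (plus optional cross-branch noise)."""
    rng = np.random.default_rng(spec.seed)
    edges: list[tuple[str, str]] = []
    branch_leaves: list[list[str]] = []
    for m in range(1, spec.n_modules + 1):
        branch = f"T:M{m}"
        edges.append((branch, ROOT))
        leaves = [f"T:M{m}L{j}" for j in range(1, spec.terms_per_module + 1)]
        edges.extend((leaf, branch) for leaf in leaves)
        branch_leaves.append(leaves)
    ontology = OntologyGraph(edges)

    entries: dict[str, set[str]] = {}
    modules = planted_symbols(spec)
    for mi, module in enumerate(modules):
        leaves = branch_leaves[mi]
        # most leaves per gene: leaf ICs stay near the branch IC, so
        # within-branch similarity is high and branches are well separated
        n_pick = max(2, len(leaves) - 1) if len(leaves) > 2 else len(leaves)
        for gene in module["all"]:
            picked = rng.choice(len(leaves), size=n_pick, replace=False)
            entries[gene] = {leaves[j] for j in sorted(picked)}
            if spec.noise_annotation_rate > 0 and rng.random() < spec.noise_annotation_rate:
                other = rng.choice([i for i in range(spec.n_modules) if i != mi])
                foreign = branch_leaves[other]
                entries[gene].add(foreign[int(rng.integers(len(foreign)))])
    return ontology, AnnotationMap(entries)


def _expression_table(
    rng: np.random.Generator,
    informative: list[str],
    noise: list[str],
    spec: SynthSpec,
    prefix: str,
) -> Dataset:
    n = spec.n_samples
    n_case = round(spec.case_fraction * n)
    labels = ["Case"] * n_case + ["Control"] * (n - n_case)
    genes = informative + noise
    X = rng.standard_normal((n, len(genes)))
    for j, _gene in enumerate(informative):
        direction = 1.0 if j % 2 == 0 else -1.0
        X[:n_case, j] += direction * spec.effect_size
    if spec.distribution == "lognormal":
        X = np.exp(X)
    values = pd.DataFrame(
        X, index=pd.Index([f"{prefix}{i + 1}" for i in range(n)], name="sample"),
        columns=genes,
    )
    return Dataset(values=values, class_labels=labels,
                   class_domain=("Case", "Control"), discrete=False)


def make_expression_pair(spec: SynthSpec) -> tuple[Dataset, Dataset]:
    """A (source, target) dataset pair with the planted module signal.

    Source and target carry disjoint noise-gene symbols and the per-module
    informative symbols from :func:`planted_symbols`.
    """
    rng = np.random.default_rng(spec.seed + 1)
    modules = planted_symbols(spec)
    src_inf = [g for m in modules for g in m["source"]]
    tgt_inf = [g for m in modules for g in m["target"]]
    n_noise = spec.n_genes - spec.n_modules * spec.genes_per_module
    src_noise = [f"NS{i + 1}" for i in range(n_noise)]
    tgt_noise = [f"NT{i + 1}" for i in range(n_noise)]
    source = _expression_table(rng, src_inf, src_noise, spec, "S")
    target = _expression_table(rng, tgt_inf, tgt_noise, spec, "T")
    return source, target


# -- worked two-marker example ------------------------------------------------

#: The printed reference rule of the two-marker example: gene1 in its upper
#: interval (> 1680) and gene2 in its lower interval (<= 28.6) predicts Case.
WORKED_EXAMPLE_RULE = (("gene1", 1), ("gene2", 0))


def worked_example_dataset() -> Dataset:
    """The two-marker discrete dataset behind the reference rule statistics.

    60 instances match (gene1 = high, gene2 = low): 56 Case and 4 Control,
    so the rule IF (gene1 > 1680) AND (gene2 <= 28.6) THEN Case scores
    TP = 56, FP = 4, coverage = 60.  Sixty filler instances (30 per class)
    spread over the non-matching value combinations keep the Fisher table
    well-defined.  Regeneration is deterministic.
    """
    rows: list[tuple[int, int, str]] = []
    rows += [(1, 0, "Case")] * 56
    rows += [(1, 0, "Control")] * 4
    filler_patterns = [(0, 0), (0, 1), (1, 1)]
    for cls in ("Case", "Control"):
        for i in range(30):
            g1, g2 = filler_patterns[i % len(filler_patterns)]
            rows.append((g1, g2, cls))
    values = pd.DataFrame(
        [(g1, g2) for g1, g2, _ in rows],
        index=pd.Index([f"W{i + 1}" for i in range(len(rows))], name="sample"),
        columns=["gene1", "gene2"],
    )
    return Dataset(
        values=values,
        class_labels=[cls for _, _, cls in rows],
        class_domain=("Case", "Control"),
        discrete=True,
    )
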