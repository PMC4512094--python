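"""Functional-module discovery over an ontology-annotated gene list.

Protocol: map each gene to its annotating terms, take the union of terms,
build a pairwise semantic-similarity matrix (Lin by default, over
information content computed from the supplied annotation corpus), cluster
the terms spectrally (Ng-Jordan-Weiss), choose the cluster count by the
overall average silhouette, retain clusters whose average silhouette meets a
threshold (0.5 by default), and map each gene into every retained cluster
containing at least one of its annotating terms.  A gene may belong to
several modules; such genes are the multi-functional ones.

The information-content corpus is the annotation map itself (each gene's
terms propagated to all ancestors), so module discovery needs no external
resource; IC values therefore shift with the corpus supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .io import AnnotationMap, OntologyGraph

__all__ = [
    "TermSimilarityMatrix",
    "FunctionalModule",
    "SemanticSimilarity",
    "term_union",
    "spectral_cluster",
    "silhouette",
    "select_k",
    "build_modules",
    "discover_modules",
]


@dataclass
class TermSimilarityMatrix:
    """Symmetric term x term similarity matrix with unit diagonal."""

    terms: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.terms)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match term list")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("diagonal must be exactly 1")
        self.matrix = np.clip(m, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class FunctionalModule:
    """A retained term cluster with the genes mapped into it (FM_k)."""

    module_id: str
    terms: frozenset[str]
    genes: frozenset[str]
    avg_silhouette: float
    theme: str | None = None  # free-text label, never computed


def term_union(
    annotations: AnnotationMap, genes
) -> tuple[list[str], list[str]]:
    """Union of annotating terms over the gene list.

    Returns (sorted term list, sorted list of unmapped genes).  Unmapped
    genes are reported, not fatal.
    """
    terms: set[str] = set()
    unmapped: list[str] = []
    for g in genes:
        if g in annotations:
            terms |= annotations[g]
        else:
            unmapped.append(g)
    return sorted(terms), sorted(set(unmapped))


class SemanticSimilarity:
    """Information content and pairwise term similarity over an annotation
    corpus.

    IC(t) = -log p(t) with p(t) the fraction of corpus genes annotated
    (after ancestor propagation) to t; IC(root) = 0.  Similarity is Lin
    (default), 2*IC(MICA)/(IC(t1)+IC(t2)), or max-normalized Resnik,
    IC(MICA)/max IC.  Both lie in [0, 1] as the clustering affinity needs.
    """

    def __init__(
        self,
        annotations: AnnotationMap,
        ontology: OntologyGraph,
        measure: str = "lin",
    ):
        if measure not in ("lin", "resnik"):
            raise ValueError("measure must be 'lin' or 'resnik'")
        annotations.validate_against(ontology)
        self.ontology = ontology
        self.measure = measure
        self._anc: dict[str, frozenset[str]] = {
            t: ontology.ancestors(t) for t in ontology.terms
        }
        # ancestor propagation: a gene counts for every ancestor of its terms
        gene_count: dict[str, int] = {t: 0 for t in ontology.terms}
        for gene, terms in annotations.entries.items():
            closed: set[str] = set()
            for t in terms:
                closed |= self._anc[t]
            for t in closed:
                gene_count[t] += 1
        total = gene_count[ontology.root]
        if total == 0:
            raise ValueError("annotation corpus is empty")
        self._ic: dict[str, float] = {
            t: (-math.log(c / total) if c > 0 else math.inf)
            for t, c in gene_count.items()
        }
        self._max_ic = max(v for v in self._ic.values() if math.isfinite(v))

    def information_content(self, term: str) -> float:
        if term not in self._ic:
            raise KeyError(f"term {term!r} not in ontology")
        return self._ic[term]

    def _mica_ic(self, t1: str, t2: str) -> float:
        common = self._anc[t1] & self._anc[t2]
        return max(self._ic[t] for t in common if math.isfinite(self._ic[t]))

    def similarity(self, t1: str, t2: str) -> float:
        ic1, ic2 = self._ic[t1], self._ic[t2]
        if t1 == t2:
            return 1.0
        if self.measure == "resnik":
            if self._max_ic == 0:
                return 0.0
            return self._mica_ic(t1, t2) / self._max_ic
        if not math.isfinite(ic1) or not math.isfinite(ic2):
            # unannotated term: no corpus evidence, only identity is similar
            return 0.0
        if ic1 + ic2 == 0:
            return 0.0
        return 2.0 * self._mica_ic(t1, t2) / (ic1 + ic2)

    def matrix(self, terms) -> TermSimilarityMatrix:
        terms = list(terms)
        n = len(terms)
        m = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = self.similarity(terms[i], terms[j])
        return TermSimilarityMatrix(terms=terms, matrix=m)


def spectral_cluster(S: TermSimilarityMatrix, k: int, seed: int = 0) -> dict[str, int]:
    """Ng-Jordan-Weiss spectral clustering of the terms into k groups.

    Affinity is the similarity matrix with zeroed diagonal; embed the terms
    with the top-k eigenvectors of the symmetric-normalized affinity,
    row-normalize, and run seeded k-means (10 restarts).
    """
    n = len(S)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    A = S.matrix.copy()
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = (A * dinv[None, :]) * dinv[:, None]
    evals, evecs = np.linalg.eigh(L)
    X = evecs[:, -k:]  # top-k eigenvectors
    norms = np.linalg.norm(X, axis=1)
    X = X / np.where(norms > 0, norms, 1.0)[:, None]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    if len(set(labels)) < k:
        for retry in range(1, 6):  # restart budget if a cluster empties
            km = KMeans(n_clusters=k, n_init=10, random_state=seed + retry)
            labels = km.fit_predict(X)
            if len(set(labels)) == k:
                break
    return {t: int(c) for t, c in zip(S.terms, labels)}


def silhouette(
    S: TermSimilarityMatrix, assignment: dict[str, int]
) -> tuple[dict[str, float], dict[int, float], float]:
    """Silhouette scores under distance d = 1 - similarity.

    Returns (per-term, per-cluster average, overall average).  Terms in
    singleton clusters score 0, as do terms with a == b == 0 (all-identical
    degenerate case).  A single overall cluster has no defined silhouette.
    """
    labels = np.array([assignment[t] for t in S.terms])
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    D = 1.0 - S.matrix
    n = len(S)
    per_term: dict[str, float] = {}
    for i in range(n):
        own = labels == labels[i]
        own_size = int(own.sum())
        if own_size == 1:
            per_term[S.terms[i]] = 0.0
            continue
        a = D[i, own].sum() / (own_size - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        per_term[S.terms[i]] = 0.0 if denom == 0 else (b - a) / denom
    s = np.array([per_term[t] for t in S.terms])
    per_cluster = {c: float(s[labels == c].mean()) for c in clusters}
    return per_term, per_cluster, float(s.mean())


def select_k(
    S: TermSimilarityMatrix, k_range=None, seed: int = 0
) -> tuple[int, dict[str, int]]:
    """Pick the cluster count maximizing the overall average silhouette.

    Default range is 2 .. min(15, n_terms - 1); ties go to the smallest k.
    """
    n = len(S)
    if k_range is None:
        k_range = range(2, min(15, n - 1) + 1)
    ks = [k for k in k_range if 2 <= k <= n]
    if not ks:
        raise ValueError("empty k range")
    best = None
    for k in sorted(ks):
        assignment = spectral_cluster(S, k, seed=seed)
        if len(set(assignment.values())) < 2:
            continue
        _, _, overall = silhouette(S, assignment)
        if best is None or overall > best[0] + 1e-12:
            best = (overall, k, assignment)
    if best is None:
        raise ValueError("no valid clustering in range")
    return best[1], best[2]


def build_modules(
    annotations: AnnotationMap,
    genes,
    assignment: dict[str, int],
    per_cluster_silhouette: dict[int, float],
    threshold: float = 0.5,
) -> list[FunctionalModule]:
    """Retain clusters with average silhouette >= threshold and map genes in.

    Gene g joins the module of cluster C iff M(g) intersects C; genes may
    join several modules.  Modules with no genes are dropped; survivors are
    numbered FM1.. in descending gene-count order.
    """
    cluster_terms: dict[int, set[str]] = {}
    for term, c in assignment.items():
        cluster_terms.setdefault(c, set()).add(term)
    raw = []
    for c, terms in cluster_terms.items():
        sil = per_cluster_silhouette.get(c, 0.0)
        if sil < threshold:
            continue
        members = frozenset(
            g for g in genes if g in annotations and annotations[g] & terms
        )
        if not members:
            continue
        raw.append((terms, members, sil, c))
    raw.sort(key=lambda r: (-len(r[1]), sorted(r[0])))
    return [
        FunctionalModule(
            module_id=f"FM{i + 1}",
            terms=frozenset(terms),
            genes=members,
            avg_silhouette=sil,
        )
        for i, (terms, members, sil, _) in enumerate(raw)
    ]


def discover_modules(
    genes,
    annotations: AnnotationMap,
    ontology: OntologyGraph,
    k_range=None,
    threshold: float = 0.5,
    measure: str = "lin",
    seed: int = 0,
) -> list[FunctionalModule]:
    """End-to-end module discovery for a gene list (the full protocol).

    Returns an empty list when fewer than three distinct annotated terms
    exist (no meaningful clustering is possible).
    """
    terms, _unmapped = term_union(annotations, genes)
    if len(terms) < 3:
        return []
    sim = SemanticSimilarity(annotations, ontology, measure=measure)
    S = sim.matrix(terms)
    _, assignment = select_k(S, k_range=k_range, seed=seed)
    _, per_cluster, _ = silhouette(S, assignment)
    annotated = [g for g in genes if g in annotations]
    return build_modules(annotations, annotated, assignment, per_cluster, threshold=threshold)
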