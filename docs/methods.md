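# Methods

This note documents the models, numerical choices and defaults behind
`trlfm`, and what the synthetic fixtures do and do not establish.

## Supervised Bayesian discretization

Each variable is discretized independently of the others against the class
labels. A partition `M` with cuts `c1 < … < ck` is scored

```
score(M) = log P(M) + Σ_intervals log DirMult(n_1..n_C | α)
log DirMult = log Γ(Cα) − log Γ(Cα + n) + Σ_c [log Γ(α + n_c) − log Γ(α)]
```

with symmetric Dirichlet weight `α = 1` per class. Candidate cuts lie at
midpoints between consecutive distinct sorted values (B candidates for
B+1 value groups); the optimum over all `2^B` subsets is found exactly by
an `O(B²)` dynamic program with fully vectorized segment scores.

**Structure prior.** The default per-cut penalty is `λ = log B`, the
log-multiplicity of single-cut hypotheses. A constant penalty such as
`log 2` is not size-consistent: at 100 samples it accepts 5–15 spurious
cuts on most pure-noise variables (the maximum of ~`2^B` random partition
scores easily exceeds a constant toll), which destroys the
single-interval filtering role of the discretizer. With `λ = log B`,
measured noise-variable retention is ~4% while class-shifted variables at
effect size 2 are always retained. `λ` is exposed (`lam=`, `--lam`) for
users who want a fixed penalty.

**Conventions.** Intervals are right-closed, `(c_{i−1}, c_i]`, so a value
equal to a cut falls below it and `value > cut` selects the upper
interval; out-of-range test values fall into the open end intervals.
Ties between equal-score partitions are broken toward fewer cuts, then
the lexicographically smallest cut sequence — discretization is fully
deterministic. Within cross-validation the scheme is computed on each
training fold only and applied to the held-out fold.

## Functional-module discovery

* **Corpus.** Information content is computed from the supplied
  annotation map itself (each gene's terms propagated to all is_a
  ancestors): `IC(t) = −log(genes at-or-below t / genes at root)`. This
  keeps the tool self-contained, but IC values — and hence similarities
  and modules — shift with the corpus supplied; users wanting genome-wide
  IC should pass a genome-wide annotation file.
* **Similarity.** Lin similarity by default; max-normalized Resnik as an
  alternative. Both live in [0, 1], as required of a spectral affinity.
  Terms never annotated in the corpus have undefined (infinite) IC and
  similarity 0 to everything but themselves.
* **Clustering.** Ng–Jordan–Weiss: zero-diagonal affinity, symmetric
  normalization `D^{-1/2} A D^{-1/2}`, top-k eigenvectors, row
  normalization, k-means (10 restarts, seeded; up to 5 reseeded retries
  if a cluster empties). Zero-degree terms get a zero embedding row
  rather than a division by zero.
* **Choosing k.** Overall average silhouette (distance `1 − similarity`)
  maximized over `k = 2 … min(15, n_terms − 1)`; ties go to the smallest
  k. Singleton clusters and all-identical-distance configurations score 0
  by convention; a single overall cluster raises rather than returning a
  misleading number.
* **Retention and mapping.** Clusters with average silhouette ≥ 0.5
  (threshold exposed) become modules; a gene joins every retained cluster
  that contains at least one of its annotating terms; empty modules are
  dropped and survivors numbered FM1… by descending gene count.

## Rule learning

* **Statistics.** An instance matches a rule iff every conjunct's interval
  contains its value; TP/FP are matches with/without the consequent
  class. CF defaults to the Laplace estimate (robust at small coverage);
  precision is available. The reported p-value is the one-sided
  (enrichment) Fisher exact tail of the 2×2 matched × class table,
  attached to model rules; it is never used to steer the search.
* **Search.** The beam is a bounded priority queue under the total order
  (CF desc, coverage desc, antecedent length asc, lexicographic
  antecedent, consequent), duplicates (same conjunct set + consequent)
  suppressed. All single-conjunct rules — and any prior rules — seed the
  beam; every beam rule below the conjunct cap is specialized once by
  appending one conjunct on a fresh variable; search stops at a fixed
  point. Admission to the beam is by rank only; the good-rule criteria
  select the output model from the final beam. This keeps the search
  complete — with an unbounded beam it provably enumerates the whole rule
  space, which the test suite checks against exhaustive search — while
  the criteria still prune everything the model reports. Inductive
  strengthening (default 1) is applied at model admission in beam order:
  a rule must cover at least that many true positives not covered by
  rules already accepted.
* **Defaults.** min CF 0.85, min coverage 4, max FP rate 0.1, max
  conjuncts 3, beam width 1000, Laplace CF. The learner is deterministic;
  the `seed` argument exists for interface symmetry with the stochastic
  stages.
* **Prediction.** Matching rules vote with weight CF; the AUC score is
  (sum of CF for positive-class matches) − (sum for the rest), with the
  first class of the domain as positive. No-match instances are abstained
  on and scored 0 (neutral), which makes an abstention a tie against
  every opposite-class instance in the rank-based AUC. How an abstaining
  disjunctive rule set should score instances is a genuinely open design
  point; weighted voting was chosen for monotonicity in rule confidence.

## Transfer

`Set1` is the union of antecedent variables over all source models (or a
literal biomarker list); `Set2` the target's EBD-selected variables;
modules are discovered over `Set1 ∪ Set2` once per target dataset,
outside the CV fold loop (Set2 and the priors are rebuilt per training
fold). Eligibility follows the module-co-membership condition; `union`
mode lets any module license, `fm:FMk` restricts to one module for
per-module experiments. Priors are instantiated over the target's own
discretized ranges only — cross-platform interval mapping is deliberately
avoided — and are re-scored and filtered on the target exactly like
native rules. Identical symbols transfer through their own modules; a raw
symbol-overlap mode (`also_identical`) exists for emulating
identical-variable-only transfer.

A consequence of this faithful construction worth stating plainly:
because each prior is a single-conjunct rule over a target variable and
interval, it coincides with one of the learner's own initial rules, and
under duplicate suppression with a total-order beam the seeded search
returns exactly the baseline model. Seeding therefore never degrades the
target model (the reduction contract holds identically), and the
framework's observable transfer product is the eligibility/provenance
mapping — which source marker licensed which target marker through which
module — plus the per-module evaluation harness built on it.

## Synthetic fixtures

The generator emulates small-sample case/control expression studies with
module-structured signal: `n_modules` well-separated ontology branches
under one root; each planted gene annotated to most leaves of its branch
(dense annotation keeps within-branch Lin similarity high, so branches
are separable at silhouette ≥ 0.5); class-conditional Gaussian expression
with mean shift `effect_size` (default 2 SD, alternating direction) for
informative genes and standard normal noise genes; a log-normal option.
Defaults: 100 samples, 30 genes, 2 modules × 4 informative genes each,
case fraction 0.5, symbol overlap 0.5 between source and target
informative genes, no noise annotations. Everything is deterministic
under `seed`.

What the fixtures do **not** model: probe-level noise, batch effects,
correlated co-expression within modules, annotation incompleteness or
bias, and realistic ontology depth. Passing the recovery and transfer
tests therefore demonstrates correctness of the machinery under clean
planted structure, not expected performance on real microarray
collections.

The worked two-marker dataset is fixed, not sampled: 60 matching
instances (56 Case, 4 Control) and 60 non-matching filler instances split
evenly between classes over the remaining value combinations; the
reference statistics depend only on the matching block, the filler only
keeps the Fisher table well-defined.

## Problem sizes in tests and the acceptance script

Oracle-equivalence tests run at exhaustive-enumeration scale (≤ 10
samples for discretization, ≤ 3 binary variables × 8 instances for rule
search, 2×2 tables with N ≤ 12, paired lists of n ≤ 8). Pipeline and
transfer tests use 40–120-sample, 8–30-gene fixtures with 3–10-fold CV;
the directional transfer check averages 20 seeded source/target pairs at
40 samples × 8 genes with 3-fold CV. The acceptance script runs the
module pipeline on the default fixture (12 planted genes, 8 terms, 2
branches). These sizes were chosen to keep every check exact or tightly
seeded while exercising the same code paths as full-size runs.

## Known limitations

* The certainty factor of the canonical two-marker illustration (0.98 for
  TP=56/FP=4) matches neither precision (0.933) nor the binary Laplace
  estimate (0.919); the evaluation function behind that printed value is
  not recoverable, so `trlfm` reports its own CF definitions and leaves
  the discrepancy documented rather than emulated.
* Hierarchical class variables, rule post-pruning, probability
  calibration, negative-transfer detection and non-ontology knowledge
  sources are out of scope.
* The silhouette-selected k is a heuristic; strongly overlapping term
  clusters can fall below the 0.5 retention threshold wholesale, in which
  case no modules — and no transfer — occur (the learner then runs as
  baseline).
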