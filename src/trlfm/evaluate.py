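"""Evaluation harness: stratified cross-validation with an abstaining
classifier, rank-based AUC, leave-one-dataset-out experiment enumeration,
and paired significance testing.

AUC uses the rank (Mann-Whitney) estimator with half credit for ties;
abstentions enter at the neutral score 0 and therefore count as ties
against every opposite-class instance.  Discretization is recomputed within
each training fold and applied to the held-out fold, so no information
leaks; functional modules, when transfer is evaluated, are discovered once
per target dataset outside the fold loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, wilcoxon
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .ebd import apply_scheme, discretize_dataset, select_features
from .fm import FunctionalModule
from .io import Dataset, GoodRuleCriteria
from .rl import ABSTAIN, learn_rules, predict
from .transfer import TransferSpec, eligible_targets, generate_prior_rules

__all__ = [
    "CVResult",
    "TransferContext",
    "stratified_kfold",
    "auc",
    "cross_validate",
    "experiment_grid",
    "signed_rank_test",
    "benjamini_hochberg",
]


@dataclass
class CVResult:
    """Per-fold AUCs with their mean, standard error and abstention rate."""

    fold_aucs: list[float]
    abstentions: int
    n_test: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sem(self) -> float:
        a = np.asarray(self.fold_aucs)
        if len(a) < 2:
            return 0.0
        return float(a.std(ddof=1) / np.sqrt(len(a)))

    @property
    def abstention_rate(self) -> float:
        return self.abstentions / self.n_test if self.n_test else 0.0


def stratified_kfold(dataset: Dataset, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Stratified fold index lists; per-class counts differ by <= 1 across
    folds.  If the smallest class has fewer than k members, k is reduced to
    that count (with a warning)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = dataset.labels_array()
    smallest = min(int((y == c).sum()) for c in dataset.class_domain)
    if smallest < k:
        warnings.warn(
            f"reducing folds from {k} to {smallest}: smallest class has "
            f"{smallest} samples", stacklevel=2,
        )
        k = smallest
    if k < 2:
        raise ValueError("not enough samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def auc(scores, labels, positive) -> float:
    """Rank-based AUC (Mann-Whitney estimator, half credit for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class TransferContext:
    """Frozen transfer inputs for evaluating TRL-FM under cross-validation:
    Set1 and the functional modules are fixed for the target dataset, while
    Set2 and the priors are rebuilt from each training fold's scheme."""

    set1: frozenset[str]
    modules: list[FunctionalModule] = field(default_factory=list)
    mode: str = "union"


def cross_validate(
    dataset: Dataset,
    criteria: GoodRuleCriteria | None = None,
    k: int = 10,
    seed: int = 0,
    transfer: TransferContext | None = None,
) -> CVResult:
    """Cross-validated AUC of the (optionally transfer-seeded) rule learner.

    Per fold: discretize on the training split only, select features, seed
    with priors when a transfer context is given, learn, then score the
    held-out fold (abstentions score 0, i.e. neutral).
    """
    criteria = criteria or GoodRuleCriteria()
    if transfer is not None and dataset.discrete:
        raise ValueError("transfer evaluation needs a continuous dataset "
                         "(priors are instantiated over fold-level schemes)")
    folds = stratified_kfold(dataset, k=k, seed=seed)
    n = dataset.n_samples
    positive = dataset.class_domain[0]
    fold_aucs: list[float] = []
    abstained = 0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train = dataset.take_samples(train_idx)
        test = dataset.take_samples(test_idx)
        if dataset.discrete:
            model = learn_rules(train, criteria, seed=seed)
            test_disc = test
        else:
            scheme = discretize_dataset(train)
            selected = select_features(scheme)
            train_disc = apply_scheme(train.select_variables(selected), scheme)
            test_disc = apply_scheme(test.select_variables(selected), scheme)
            priors = []
            if transfer is not None:
                spec = TransferSpec(
                    set1=transfer.set1, set2=frozenset(selected),
                    modules=transfer.modules, mode=transfer.mode,
                )
                eligibility = eligible_targets(spec)
                priors = generate_prior_rules(
                    sorted(eligibility), scheme, dataset.class_domain,
                    provenance=eligibility,
                ).rules
            model = learn_rules(train_disc, criteria, priors=priors, seed=seed)
        scores = []
        for sid in test_disc.sample_ids:
            cls, score = predict(model, test_disc.values.loc[sid])
            if cls == ABSTAIN:
                abstained += 1
            scores.append(score)
        fold_aucs.append(auc(scores, test.class_labels, positive))
    return CVResult(fold_aucs=fold_aucs, abstentions=abstained, n_test=n)


def experiment_grid(studies) -> list[tuple[str, int, tuple[int, ...]]]:
    """Leave-one-dataset-out-as-target enumeration.

    ``studies`` maps study name -> list of datasets (or dataset names).
    Each study of n datasets yields n experiments (target = D_i, sources =
    the rest), so the grid size is the sum of study sizes.
    """
    if not isinstance(studies, dict):
        studies = {str(i): s for i, s in enumerate(studies)}
    grid = []
    for name, datasets in studies.items():
        n = len(datasets)
        if n < 2:
            raise ValueError(f"study {name!r} needs at least two datasets")
        for i in range(n):
            sources = tuple(j for j in range(n) if j != i)
            grid.append((name, i, sources))
    return grid


def signed_rank_test(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties in |differences|, otherwise the normal
    approximation with tie correction.  All-zero differences give p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    absd = np.abs(d)
    exact_ok = d.size <= 25 and len(np.unique(absd)) == len(absd)
    method = "exact" if exact_ok else "approx"
    res = wilcoxon(d, alternative="two-sided", method=method)
    return float(res.pvalue)


def benjamini_hochberg(pvalues) -> list[float]:
    """Step-up false-discovery-rate adjustment; output order matches input."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]
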