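"""Classification rule learning by general-to-specific beam search.

Rules have the form IF (var1 = interval_i) AND ... THEN (class = c) over a
discretized dataset, with statistics TP, FP, coverage = TP + FP, a
certainty factor CF (Laplace estimate by default, precision optionally) and
a Fisher's exact-test p-value for the association between matching the
antecedent and carrying the consequent class.

The search starts from every single-conjunct rule (one per variable x
interval x class; for a binary Case/Control task every discretized marker
value spawns one Case rule and one Control rule), keeps the ``beam_width``
best rules under a total order (CF desc, coverage desc, antecedent length
asc, lexicographic antecedent, consequent), and repeatedly specializes beam
rules by appending one conjunct on a fresh variable.  Search stops when no
specialization can improve the beam.  The final model is the set of beam
rules satisfying the good-rule criteria (minimum CF, minimum coverage,
maximum false-positive rate, maximum conjuncts), admitted in beam order
subject to inductive strengthening: a rule must cover at least that many
true positives not covered by rules already admitted.  Covering is with
replacement -- no training instance is ever removed during learning.

With an unbounded beam the search enumerates the complete rule space up to
``max_conjuncts``, so the model coincides with exhaustive search; the
good-rule criteria prune the output, not the traversal.

The learner can seed the beam with prior rules (knowledge transfer): their
statistics are recomputed on the training data and they compete under
exactly the same criteria as natively induced rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io import Dataset, GoodRuleCriteria

__all__ = [
    "ABSTAIN",
    "Rule",
    "Beam",
    "RuleModel",
    "certainty_factor",
    "fisher_exact_p",
    "rule_statistics",
    "initial_rules",
    "specialize",
    "is_good",
    "learn_rules",
    "predict",
]

ABSTAIN = "ABSTAIN"


@dataclass(frozen=True)
class Rule:
    """An IF-THEN rule: conjuncts are (variable, interval index) pairs."""

    conjuncts: tuple[tuple[str, int], ...]
    consequent: str
    tp: int = 0
    fp: int = 0
    cf: float = 0.0
    p_value: float = 1.0

    def __post_init__(self) -> None:
        variables = [v for v, _ in self.conjuncts]
        if len(variables) != len(set(variables)):
            raise ValueError("conjuncts must reference distinct variables")

    @property
    def coverage(self) -> int:
        return self.tp + self.fp

    def identity(self) -> tuple:
        """Duplicate key: conjunct set (order-free) plus consequent."""
        return (frozenset(self.conjuncts), self.consequent)

    def sort_key(self) -> tuple:
        """Total beam order: CF desc, coverage desc, shorter first, then
        lexicographic antecedent and consequent."""
        return (-self.cf, -self.coverage, len(self.conjuncts),
                tuple(sorted(self.conjuncts)), self.consequent)

    def describe(self) -> str:
        cond = " AND ".join(f"({v} = I{i})" for v, i in self.conjuncts) or "(TRUE)"
        return (f"IF {cond} THEN (class = {self.consequent})  "
                f"[CF={self.cf:.3f}, P={self.p_value:.3g}, TP={self.tp}, FP={self.fp}]")


def certainty_factor(tp: int, fp: int, method: str = "laplace", n_classes: int = 2) -> float:
    """Rule confidence: precision tp/(tp+fp) (0 at zero coverage) or the
    Laplace estimate (tp+1)/(tp+fp+C) with C the number of classes."""
    if tp < 0 or fp < 0:
        raise ValueError("tp and fp must be non-negative")
    if method == "precision":
        return tp / (tp + fp) if tp + fp else 0.0
    if method == "laplace":
        return (tp + 1) / (tp + fp + n_classes)
    raise ValueError(f"unknown CF method {method!r}")


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p for the 2x2 table [[a, b], [c, d]]:
    the hypergeometric tail P(X >= a) at fixed margins."""
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    n_total = a + b + c + d
    if a + b == 0 or n_total == 0:
        return 1.0
    # population n_total, successes a+c, draws a+b
    return float(min(1.0, hypergeom.sf(a - 1, n_total, a + c, a + b)))


class _Matcher:
    """Vectorized rule matching against a discrete dataset."""

    def __init__(self, dataset: Dataset):
        if not dataset.discrete:
            raise ValueError("rule learning requires a discrete dataset")
        self.dataset = dataset
        self.X = dataset.values.to_numpy()
        self.col = {v: j for j, v in enumerate(dataset.variable_names)}
        self.y = dataset.labels_array()
        self.class_domain = dataset.class_domain
        self.class_size = {c: int((self.y == c).sum()) for c in dataset.class_domain}
        self.n = dataset.n_samples

    def match_mask(self, rule: Rule) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        for var, interval in rule.conjuncts:
            if var not in self.col:
                raise KeyError(f"unknown variable in antecedent: {var!r}")
            mask &= self.X[:, self.col[var]] == interval
        return mask

    def statistics(self, rule: Rule, criteria: GoodRuleCriteria,
                   with_p: bool = True) -> Rule:
        mask = self.match_mask(rule)
        pos = self.y == rule.consequent
        tp = int((mask & pos).sum())
        fp = int(mask.sum()) - tp
        cf = certainty_factor(tp, fp, method=criteria.cf_function,
                              n_classes=len(self.class_domain))
        # the p-value is reported, not searched on, so it can be deferred
        # during beam expansion and attached to final model rules only
        p = self.fisher_p(rule.consequent, tp, fp) if with_p else 1.0
        return replace(rule, tp=tp, fp=fp, cf=cf, p_value=p)

    def fisher_p(self, consequent: str, tp: int, fp: int) -> float:
        n_pos = self.class_size.get(consequent, 0)
        fn = n_pos - tp
        tn = self.n - tp - fp - fn
        return fisher_exact_p(tp, fp, fn, tn)


def rule_statistics(rule: Rule, dataset: Dataset,
                    criteria: GoodRuleCriteria | None = None) -> Rule:
    """Recompute TP, FP, CF and Fisher p for a rule on a discrete dataset.

    An instance matches iff every conjunct's interval contains its value;
    TP are matches of the consequent class, FP the remaining matches.
    """
    return _Matcher(dataset).statistics(rule, criteria or GoodRuleCriteria())


class Beam:
    """Bounded rule queue ordered by :meth:`Rule.sort_key`, duplicates
    (same conjunct set and consequent) suppressed."""

    def __init__(self, width: int):
        if width < 1:
            raise ValueError("beam width must be >= 1")
        self.width = width
        self._rules: dict[tuple, Rule] = {}

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self):
        return iter(sorted(self._rules.values(), key=Rule.sort_key))

    def add(self, rule: Rule) -> bool:
        """Insert unless duplicate or outranked by a full beam's worst rule.
        Returns True when the rule is on the beam afterwards as a new entry."""
        key = rule.identity()
        if key in self._rules:
            return False
        if len(self._rules) < self.width:
            self._rules[key] = rule
            return True
        worst_key, worst = max(self._rules.items(), key=lambda kv: kv[1].sort_key())
        if rule.sort_key() < worst.sort_key():
            del self._rules[worst_key]
            self._rules[key] = rule
            return True
        return False


def _interval_counts(dataset: Dataset) -> dict[str, int]:
    X = dataset.values
    return {v: int(X[v].max()) + 1 if len(X) else 1 for v in dataset.variable_names}


def initial_rules(dataset: Dataset, criteria: GoodRuleCriteria | None = None,
                  n_intervals: dict[str, int] | None = None) -> list[Rule]:
    """All single-conjunct rules: one per variable x interval x class.

    For a binary Case/Control task each discretized marker value spawns two
    rules, one predicting each class.
    """
    criteria = criteria or GoodRuleCriteria()
    matcher = _Matcher(dataset)
    counts = n_intervals or _interval_counts(dataset)
    rules = []
    for var in dataset.variable_names:
        for interval in range(counts[var]):
            for cls in dataset.class_domain:
                rule = Rule(conjuncts=((var, interval),), consequent=cls)
                rules.append(matcher.statistics(rule, criteria))
    return rules


def _specialize_with(matcher: _Matcher, rule: Rule, criteria: GoodRuleCriteria,
                     counts: dict[str, int], with_p: bool = True) -> list[Rule]:
    if len(rule.conjuncts) >= criteria.max_conjuncts:
        return []
    used = {v for v, _ in rule.conjuncts}
    children = []
    for var in matcher.dataset.variable_names:
        if var in used:
            continue
        for interval in range(counts[var]):
            child = Rule(conjuncts=rule.conjuncts + ((var, interval),),
                         consequent=rule.consequent)
            children.append(matcher.statistics(child, criteria, with_p=with_p))
    return children


def specialize(rule: Rule, dataset: Dataset, criteria: GoodRuleCriteria | None = None,
               n_intervals: dict[str, int] | None = None) -> list[Rule]:
    """All one-conjunct extensions of a rule on variables it does not yet
    test, statistics recomputed.  Empty at the conjunct cap."""
    criteria = criteria or GoodRuleCriteria()
    counts = n_intervals or _interval_counts(dataset)
    return _specialize_with(_Matcher(dataset), rule, criteria, counts)


def _is_good_with(matcher: _Matcher, rule: Rule, criteria: GoodRuleCriteria,
                  covered_positives: set[int] | None = None) -> bool:
    if len(rule.conjuncts) > criteria.max_conjuncts:
        return False
    if rule.cf < criteria.min_cf:
        return False
    if rule.coverage < criteria.min_coverage:
        return False
    negatives = matcher.n - matcher.class_size.get(rule.consequent, 0)
    fp_rate = rule.fp / negatives if negatives else 0.0
    if fp_rate > criteria.max_fp_rate:
        return False
    if covered_positives is not None and criteria.inductive_strengthening > 0:
        mask = matcher.match_mask(rule) & (matcher.y == rule.consequent)
        new = set(np.flatnonzero(mask).tolist()) - covered_positives
        if len(new) < criteria.inductive_strengthening:
            return False
    return True


def is_good(rule: Rule, criteria: GoodRuleCriteria, dataset: Dataset,
            covered_positives: set[int] | None = None) -> bool:
    """Good-rule test: CF, coverage, false-positive rate and length bounds,
    plus inductive strengthening against already-admitted rules.

    The FP rate denominator is the number of training instances not of the
    rule's consequent class.  ``covered_positives`` holds sample positions
    (within ``dataset``) of true positives already covered by the model
    under construction; when given, the rule must add at least
    ``criteria.inductive_strengthening`` new ones.
    """
    return _is_good_with(_Matcher(dataset), rule, criteria, covered_positives)


@dataclass
class RuleModel:
    """The learned disjunctive rule set, ordered by the beam key."""

    rules: tuple[Rule, ...]
    criteria: GoodRuleCriteria
    class_domain: tuple[str, ...]
    scheme: object | None = None  # DiscretizationScheme of the training data
    provenance: dict = field(default_factory=dict)

    def variables(self) -> set[str]:
        return {v for r in self.rules for v, _ in r.conjuncts}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleModel):
            return NotImplemented
        return (self.rules == other.rules and self.criteria == other.criteria
                and self.class_domain == other.class_domain)


def learn_rules(dataset: Dataset, criteria: GoodRuleCriteria | None = None,
                priors: Sequence[Rule] = (), seed: int = 0) -> RuleModel:
    """Beam-search rule induction on a discrete dataset.

    ``priors`` seed the beam (statistics recomputed here); they are treated
    exactly like natively induced rules, so priors failing the good-rule
    criteria never reach the model.  ``seed`` is accepted for interface
    symmetry; the search itself is deterministic.
    """
    criteria = criteria or GoodRuleCriteria()
    matcher = _Matcher(dataset)
    counts = _interval_counts(dataset)
    beam = Beam(criteria.beam_width)

    seeds = [matcher.statistics(Rule(conjuncts=p.conjuncts, consequent=p.consequent),
                                criteria, with_p=False) for p in priors]
    for rule in seeds:
        beam.add(rule)
    for var in dataset.variable_names:
        for interval in range(counts[var]):
            for cls in dataset.class_domain:
                rule = Rule(conjuncts=((var, interval),), consequent=cls)
                beam.add(matcher.statistics(rule, criteria, with_p=False))

    expanded: set[tuple] = set()
    while True:
        frontier = [r for r in beam if r.identity() not in expanded
                    and len(r.conjuncts) < criteria.max_conjuncts]
        if not frontier:
            break
        for rule in frontier:
            expanded.add(rule.identity())
            for child in _specialize_with(matcher, rule, criteria, counts,
                                          with_p=False):
                beam.add(child)

    accepted: list[Rule] = []
    covered: set[int] = set()
    for rule in beam:
        if not _is_good_with(matcher, rule, criteria, covered_positives=covered):
            continue
        rule = replace(rule, p_value=matcher.fisher_p(rule.consequent, rule.tp, rule.fp))
        accepted.append(rule)
        mask = matcher.match_mask(rule) & (matcher.y == rule.consequent)
        covered |= set(np.flatnonzero(mask).tolist())
    return RuleModel(rules=tuple(accepted), criteria=criteria,
                     class_domain=dataset.class_domain)


def predict(model: RuleModel, instance) -> tuple[str, float]:
    """Classify one discretized instance by CF-weighted rule voting.

    ``instance`` maps variable names to interval indices (a pandas Series
    row of a discrete dataset works).  Returns (class or ABSTAIN, score);
    the score for AUC is the summed CF of matching rules predicting the
    positive class (first class of the domain) minus the sum for the other
    classes, 0 on abstention (neutral).
    """
    votes: dict[str, float] = {c: 0.0 for c in model.class_domain}
    matched = False
    for rule in model.rules:
        if all(var in instance and instance[var] == interval
               for var, interval in rule.conjuncts):
            votes[rule.consequent] += rule.cf
            matched = True
    positive = model.class_domain[0]
    score = votes[positive] - sum(v for c, v in votes.items() if c != positive)
    if not matched:
        return ABSTAIN, 0.0
    best = max(model.class_domain, key=lambda c: votes[c])
    return best, score
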