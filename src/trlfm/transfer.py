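"""Knowledge transfer across expression datasets via functional mapping.

Set1 is the set of variables appearing in the antecedents of the source
rule model(s) -- or a literal biomarker list when no source dataset is
available.  Set2 is the target's discretization-selected variable set.  A
target variable a_Tj is eligible for prior-rule instantiation when

    (a_Tj in Set2)  and  ({a_Si, a_Tj} in FM_k)  and  (a_Si in Set1)

for some functional module FM_k (a single designated module in
``single_fm`` mode, any module in ``union`` mode).  For every eligible
variable one single-conjunct prior rule is instantiated per (discrete range
x class value) of the TARGET's own discretization -- e.g. a two-interval
marker under Case/Control yields IF(a=LOW)->Case, IF(a=HIGH)->Case,
IF(a=LOW)->Control, IF(a=HIGH)->Control.  Instantiating over the target's
own ranges sidesteps mapping interval values across platforms.  The priors
seed the beam of the rule learner on the target; their statistics are
recomputed there and priors failing the good-rule criteria are pruned like
any other rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ebd import DiscretizationScheme, apply_scheme, discretize_dataset, select_features
from .fm import FunctionalModule, discover_modules
from .io import AnnotationMap, Dataset, GoodRuleCriteria, OntologyGraph
from .rl import Rule, RuleModel, learn_rules

__all__ = [
    "PriorRuleSet",
    "TransferSpec",
    "TrlfmResult",
    "source_variables",
    "eligible_targets",
    "generate_prior_rules",
    "rl_baseline",
    "trlfm_learn",
]


@dataclass
class PriorRuleSet:
    """Single-conjunct prior rules plus the licensing provenance triples.

    ``provenance`` maps each target variable to the (a_Si, a_Tj, FM_k)
    triples that licensed its instantiation.
    """

    rules: list[Rule] = field(default_factory=list)
    provenance: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)


@dataclass
class TransferSpec:
    """Inputs of the eligibility condition."""

    set1: frozenset[str]
    set2: frozenset[str]
    modules: list[FunctionalModule]
    mode: str = "union"  # "union" or "fm:<module_id>"

    def __post_init__(self) -> None:
        if self.mode != "union" and not self.mode.startswith("fm:"):
            raise ValueError("mode must be 'union' or 'fm:<module_id>'")

    def in_scope_modules(self) -> list[FunctionalModule]:
        if self.mode == "union":
            return list(self.modules)
        wanted = self.mode[3:]
        chosen = [m for m in self.modules if m.module_id == wanted]
        if not chosen:
            raise ValueError(f"no module with id {wanted!r}")
        return chosen


def source_variables(sources) -> frozenset[str]:
    """Set1: union of antecedent variables over source rule models, or a
    literal biomarker name list."""
    names: set[str] = set()
    for item in sources:
        if isinstance(item, RuleModel):
            names |= item.variables()
        elif isinstance(item, str):
            names.add(item)
        else:
            raise TypeError(f"unsupported source entry: {type(item).__name__}")
    return frozenset(names)


def eligible_targets(spec: TransferSpec) -> dict[str, list[tuple[str, str, str]]]:
    """Target variables licensed for prior-rule instantiation.

    Returns a mapping a_Tj -> sorted provenance triples (a_Si, a_Tj, FM_k).
    A symbol present in both sets licenses itself whenever it co-occurs
    with itself in a module.
    """
    out: dict[str, list[tuple[str, str, str]]] = {}
    for module in spec.in_scope_modules():
        src_in = sorted(spec.set1 & module.genes)
        tgt_in = sorted(spec.set2 & module.genes)
        if not src_in or not tgt_in:
            continue
        for a_tj in tgt_in:
            triples = out.setdefault(a_tj, [])
            for a_si in src_in:
                triples.append((a_si, a_tj, module.module_id))
    return {v: sorted(set(ts)) for v, ts in sorted(out.items())}


def identical_symbol_targets(set1: frozenset[str], set2: frozenset[str]) -> list[str]:
    """Raw symbol-overlap eligibility (the transfer mechanism TRL-FM
    generalizes); used for emulation runs via ``also_identical``."""
    return sorted(set1 & set2)


def generate_prior_rules(
    eligible,
    target_scheme: DiscretizationScheme,
    classes,
    provenance: dict[str, list[tuple[str, str, str]]] | None = None,
) -> PriorRuleSet:
    """Instantiate one prior rule per (discrete range x class) of every
    eligible target variable, over the target's own discretization."""
    prior = PriorRuleSet(provenance=dict(provenance or {}))
    for var in eligible:
        if var not in target_scheme.cuts:
            raise KeyError(f"eligible variable {var!r} missing from target scheme")
        for interval in range(target_scheme.n_intervals(var)):
            for cls in classes:
                prior.rules.append(Rule(conjuncts=((var, interval),), consequent=cls))
    return prior


def rl_baseline(
    target: Dataset, criteria: GoodRuleCriteria | None = None, seed: int = 0
) -> tuple[RuleModel, DiscretizationScheme]:
    """Baseline rule learning on the target alone: EBD discretization,
    single-interval filtering, beam-search induction."""
    criteria = criteria or GoodRuleCriteria()
    if target.discrete:
        model = learn_rules(target, criteria, seed=seed)
        return model, DiscretizationScheme(cuts={})
    scheme = discretize_dataset(target)
    selected = select_features(scheme)
    discrete = apply_scheme(target.select_variables(selected), scheme)
    model = learn_rules(discrete, criteria, seed=seed)
    model.scheme = scheme
    return model, scheme


@dataclass
class TrlfmResult:
    """Everything a transfer run produces, for auditing the mapping."""

    model: RuleModel
    scheme: DiscretizationScheme
    set1: frozenset[str]
    set2: frozenset[str]
    modules: list[FunctionalModule]
    eligibility: dict[str, list[tuple[str, str, str]]]
    priors: PriorRuleSet


def trlfm_learn(
    sources,
    target: Dataset,
    annotations: AnnotationMap,
    ontology: OntologyGraph,
    criteria: GoodRuleCriteria | None = None,
    mode: str = "union",
    seed: int = 0,
    also_identical: bool = False,
    k_range=None,
    silhouette_threshold: float = 0.5,
    modules: list[FunctionalModule] | None = None,
) -> TrlfmResult:
    """Full transfer pipeline onto a continuous target dataset.

    EBD selects Set2; functional modules are discovered over Set1 union
    Set2 (or supplied precomputed via ``modules``); eligible target
    variables license prior rules over the target's own discrete ranges;
    the seeded learner induces the final model.  With no functional link
    between the sets the result reduces exactly to :func:`rl_baseline`.
    """
    criteria = criteria or GoodRuleCriteria()
    set1 = source_variables(sources)

    if target.discrete:
        scheme = DiscretizationScheme(
            cuts={v: [0.5] for v in target.variable_names}  # placeholder bounds
        )
        discrete = target
        set2 = frozenset(target.variable_names)
    else:
        scheme = discretize_dataset(target)
        selected = select_features(scheme)
        discrete = apply_scheme(target.select_variables(selected), scheme)
        set2 = frozenset(selected)

    if modules is None:
        modules = discover_modules(
            sorted(set1 | set2), annotations, ontology,
            k_range=k_range, threshold=silhouette_threshold, seed=seed,
        )
    spec = TransferSpec(set1=set1, set2=set2, modules=modules, mode=mode)
    eligibility = eligible_targets(spec)
    eligible = sorted(eligibility)
    if also_identical:
        for var in identical_symbol_targets(set1, set2):
            if var not in eligibility:
                eligibility[var] = [(var, var, "identical")]
        eligible = sorted(eligibility)

    scheme_for_priors = scheme
    if target.discrete:
        from .rl import _interval_counts

        counts = _interval_counts(discrete)
        scheme_for_priors = DiscretizationScheme(
            cuts={v: [i + 0.5 for i in range(counts[v] - 1)] for v in counts}
        )
    priors = generate_prior_rules(
        eligible, scheme_for_priors, discrete.class_domain, provenance=eligibility
    )
    model = learn_rules(discrete, criteria, priors=priors.rules, seed=seed)
    model.scheme = None if target.discrete else scheme
    model.provenance = {
        "set1": sorted(set1),
        "set2": sorted(set2),
        "mode": mode,
        "eligibility": {v: [list(t) for t in ts] for v, ts in eligibility.items()},
        "modules": {m.module_id: sorted(m.genes) for m in modules},
    }
    return TrlfmResult(
        model=model, scheme=scheme, set1=set1, set2=set2,
        modules=modules, eligibility=eligibility, priors=priors,
    )
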