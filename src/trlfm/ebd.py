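"""Supervised Bayesian discretization (EBD) and single-interval filtering.

Each continuous variable is discretized independently against the class
labels.  A partition of the real line into half-open intervals
(-inf, c1], (c1, c2], ..., (ck, +inf) is scored by

    log P(M) + sum over intervals of the log Dirichlet-multinomial
    marginal likelihood of the interval's class counts,

with a symmetric Dirichlet prior (alpha per class) and a structure prior
log P(M) = -k * lam for k cut points.  Candidate cut points lie at midpoints
between consecutive distinct sorted values, so the optimum over all such
partitions is found exactly by dynamic programming over boundary positions
(quadratic in the number of distinct values).

Variables whose optimal partition is a single interval carry no class signal
under this score and are filtered out; the survivors are the "relevant
variables" fed to functional-module discovery and rule learning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import Dataset

__all__ = [
    "DiscretizationScheme",
    "interval_score",
    "ebd_discretize",
    "discretize_dataset",
    "apply_scheme",
    "select_features",
    "DEFAULT_ALPHA",
    "DEFAULT_LAMBDA",
]

DEFAULT_ALPHA = 1.0
#: ``lam=None`` selects the adaptive per-cut penalty log(B) for B candidate
#: boundaries; this Occam-factor (union-bound) correction keeps spurious cuts
#: on noise variables rare regardless of sample size.
DEFAULT_LAMBDA = None


@dataclass
class DiscretizationScheme:
    """Per-variable ordered cut points defining right-closed intervals.

    Interval ``i`` of a variable with cuts ``c1 < ... < ck`` is
    ``(c_i, c_{i+1}]`` with ``c_0 = -inf`` and ``c_{k+1} = +inf``; a value
    equal to a cut falls in the interval below it (``x <= c``).
    """

    cuts: dict[str, list[float]]
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, cs in self.cuts.items():
            if any(b <= a for a, b in zip(cs, cs[1:])):
                raise ValueError(f"cut points for {var!r} not strictly increasing")

    def n_intervals(self, variable: str) -> int:
        return len(self.cuts[variable]) + 1

    def interval_of(self, variable: str, value: float) -> int:
        cs = self.cuts[variable]
        return int(np.searchsorted(cs, value, side="left"))

    def interval_bounds(self, variable: str, interval: int) -> tuple[float, float]:
        cs = self.cuts[variable]
        if not 0 <= interval <= len(cs):
            raise IndexError(f"interval {interval} out of range for {variable!r}")
        lo = cs[interval - 1] if interval > 0 else -math.inf
        hi = cs[interval] if interval < len(cs) else math.inf
        return lo, hi


def interval_score(class_counts, alpha: float = DEFAULT_ALPHA) -> float:
    """Log Dirichlet-multinomial marginal likelihood of one interval.

    For class counts n_1..n_C and symmetric prior alpha:

        log Gamma(C*alpha) - log Gamma(C*alpha + n)
        + sum_c [log Gamma(alpha + n_c) - log Gamma(alpha)]

    An empty interval scores 0 (log of an empty product).
    """
    counts = np.asarray(class_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("at least one class is required")
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    n = counts.sum()
    c = counts.size
    return float(
        gammaln(c * alpha)
        - gammaln(c * alpha + n)
        + np.sum(gammaln(alpha + counts) - gammaln(alpha))
    )


def ebd_discretize(
    values,
    labels,
    alpha: float = DEFAULT_ALPHA,
    lam: float | None = DEFAULT_LAMBDA,
    class_domain=None,
) -> tuple[list[float], float]:
    """Exact optimal cut points for one variable; returns (cuts, score).

    ``lam`` is the structure-prior penalty per cut; ``None`` (default)
    uses log(B) for B candidate boundaries, so the penalty matches the
    multiplicity of single-cut hypotheses and pure-noise variables rarely
    earn a cut.  Ties are broken toward fewer intervals, then the
    lexicographically smallest cut sequence, so output is deterministic.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    labels = np.asarray(labels, dtype=object)
    if labels.shape != values.shape:
        raise ValueError("labels not aligned with values")
    domain = list(class_domain) if class_domain is not None else list(dict.fromkeys(labels))
    class_idx = {cls: j for j, cls in enumerate(domain)}
    y = np.array([class_idx[l] for l in labels])

    order = np.argsort(values, kind="stable")
    sv, sy = values[order], y[order]
    # group runs of equal values; per-group class counts
    distinct, starts = np.unique(sv, return_index=True)
    g = len(distinct)
    counts = np.zeros((g, len(domain)), dtype=int)
    bounds = list(starts) + [len(sv)]
    for gi in range(g):
        seg = sy[bounds[gi] : bounds[gi + 1]]
        np.add.at(counts[gi], seg, 1)
    cum = np.vstack([np.zeros(len(domain), dtype=int), np.cumsum(counts, axis=0)])
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    if lam is None:
        lam = math.log(max(g - 1, 2))

    # all segment scores at once: seg[i, j] scores the interval spanning
    # value groups i..j-1
    c = len(domain)
    ii, jj = np.triu_indices(g + 1, k=1)
    seg_counts = (cum[jj] - cum[ii]).astype(float)
    seg_vals = (
        gammaln(c * alpha)
        - gammaln(c * alpha + seg_counts.sum(axis=1))
        + (gammaln(alpha + seg_counts) - gammaln(alpha)).sum(axis=1)
    )
    seg = np.full((g + 1, g + 1), -np.inf)
    seg[ii, jj] = seg_vals

    # dp over boundary positions; ties -> fewer cuts, then lexicographically
    # smallest cut sequence
    dp_score = np.empty(g + 1)
    dp_score[0] = 0.0
    dp_ncuts = np.zeros(g + 1, dtype=int)
    dp_cuts: list[tuple] = [()] * (g + 1)
    penalties = np.concatenate([[0.0], np.full(g, lam)])
    for j in range(1, g + 1):
        cand = dp_score[:j] - penalties[:j] + seg[np.arange(j), j]
        best_score = cand.max()
        tied = np.flatnonzero(cand == best_score)
        cand_ncuts = dp_ncuts[tied] + (tied > 0)
        tied = tied[cand_ncuts == cand_ncuts.min()]
        best_i = int(tied[0])
        if len(tied) > 1:
            options = [
                dp_cuts[i] + ((midpoints[i - 1],) if i > 0 else ()) for i in tied
            ]
            best_i = int(tied[options.index(min(options))])
        dp_score[j] = best_score
        dp_ncuts[j] = dp_ncuts[best_i] + (1 if best_i > 0 else 0)
        dp_cuts[j] = dp_cuts[best_i] + ((midpoints[best_i - 1],) if best_i > 0 else ())
    return list(dp_cuts[g]), float(dp_score[g])


def discretize_dataset(
    dataset: Dataset, alpha: float = DEFAULT_ALPHA, lam: float | None = DEFAULT_LAMBDA
) -> DiscretizationScheme:
    """Run EBD independently on every variable of a continuous dataset."""
    if dataset.discrete:
        raise ValueError("dataset is already discrete")
    cuts: dict[str, list[float]] = {}
    scores: dict[str, float] = {}
    labels = dataset.labels_array()
    for var in dataset.variable_names:
        c, s = ebd_discretize(
            dataset.values[var].to_numpy(),
            labels,
            alpha=alpha,
            lam=lam,
            class_domain=dataset.class_domain,
        )
        cuts[var] = c
        scores[var] = s
    return DiscretizationScheme(cuts=cuts, scores=scores)


def apply_scheme(dataset: Dataset, scheme: DiscretizationScheme) -> Dataset:
    """Map every value to its interval index under the training scheme.

    Values beyond the training range fall into the open end intervals.
    """
    missing = [v for v in dataset.variable_names if v not in scheme.cuts]
    if missing:
        raise ValueError(f"variables missing from scheme: {missing}")
    import pandas as pd

    cols = {
        var: np.searchsorted(scheme.cuts[var], dataset.values[var].to_numpy(), side="left")
        for var in dataset.variable_names
    }
    values = pd.DataFrame(cols, index=dataset.values.index)[dataset.variable_names]
    return Dataset(
        values=values.astype(int),
        class_labels=list(dataset.class_labels),
        class_domain=dataset.class_domain,
        discrete=True,
    )


def select_features(scheme: DiscretizationScheme) -> list[str]:
    """Variables with at least two intervals; single-interval variables
    cannot discriminate the class and are dropped."""
    return [v for v in scheme.cuts if len(scheme.cuts[v]) >= 1]
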