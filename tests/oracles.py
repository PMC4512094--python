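"""Independent brute-force oracles the implementation is checked against.

Everything here recomputes quantities by direct enumeration or closed
forms, deliberately avoiding the code paths under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from trlfm.ebd import interval_score


def exhaustive_discretize(values, labels, alpha=1.0, lam=None, class_domain=None):
    """Best partition by enumerating every subset of candidate boundaries.

    Scores are folded left-to-right exactly as a prefix recursion would,
    so equality with the dynamic program is exact, not approximate.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    domain = list(class_domain) if class_domain is not None else list(dict.fromkeys(labels))
    order = np.argsort(values, kind="stable")
    sv, sl = values[order], labels[order]
    distinct = np.unique(sv)
    g = len(distinct)
    if lam is None:
        lam = math.log(max(g - 1, 2))
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0

    def counts(lo, hi):  # class counts of value groups lo..hi-1
        sel = (sv >= distinct[lo]) & (sv <= distinct[hi - 1])
        return [int(((sl == c) & sel).sum()) for c in domain]

    best = None
    for r in range(g):
        for cut_positions in itertools.combinations(range(1, g), r):
            edges = [0, *cut_positions, g]
            score = interval_score(counts(edges[0], edges[1]), alpha=alpha)
            for lo, hi in zip(edges[1:], edges[2:]):
                score = (score - lam) + interval_score(counts(lo, hi), alpha=alpha)
            cuts = tuple(midpoints[p - 1] for p in cut_positions)
            cand = (score, len(cuts), cuts)
            if (best is None or cand[0] > best[0]
                    or (cand[0] == best[0] and cand[1] < best[1])
                    or (cand[0] == best[0] and cand[1] == best[1] and cand[2] < best[2])):
                best = cand
    return list(best[2]), best[0]


def hypergeom_tail(a, b, c, d):
    """P(X >= a) by direct summation of hypergeometric point masses."""
    n_total = a + b + c + d
    k = a + c  # successes in population
    n = a + b  # draws
    if n == 0 or n_total == 0:
        return 1.0
    denom = math.comb(n_total, n)
    total = 0
    for x in range(a, min(k, n) + 1):
        if n - x > n_total - k:
            continue
        total += math.comb(k, x) * math.comb(n_total - k, n - x)
    return total / denom


def brute_rule_stats(conjuncts, consequent, dataset):
    """Per-instance matching loop: (tp, fp)."""
    tp = fp = 0
    for sid, label in zip(dataset.sample_ids, dataset.class_labels):
        row = dataset.values.loc[sid]
        if all(row[v] == i for v, i in conjuncts):
            if label == consequent:
                tp += 1
            else:
                fp += 1
    return tp, fp


def enumerate_rule_space(dataset, max_conjuncts):
    """All syntactically valid rules up to the conjunct cap."""
    variables = dataset.variable_names
    intervals = {v: int(dataset.values[v].max()) + 1 for v in variables}
    for k in range(1, max_conjuncts + 1):
        for var_subset in itertools.combinations(variables, k):
            for ivals in itertools.product(*(range(intervals[v]) for v in var_subset)):
                for cls in dataset.class_domain:
                    yield tuple(zip(var_subset, ivals)), cls


def pair_counting_auc(scores, labels, positive):
    """O(n^2) concordant/discordant pair count with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def exact_signed_rank_p(diffs):
    """Two-sided exact Wilcoxon signed-rank p by sign-assignment
    enumeration (no ties in |diffs| assumed; zeros dropped)."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = {i: r + 1 for r, i in enumerate(sorted(range(n), key=lambda i: abs(d[i])))}
    w_obs = sum(ranks[i] for i in range(n) if d[i] > 0)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(ranks[i] for i in range(n) if signs[i]))
    ws = np.array(ws)
    cdf = (ws <= w_obs).mean()
    sf = (ws >= w_obs).mean()
    return min(1.0, 2 * min(cdf, sf))


def step_up_bh(pvalues):
    """Benjamini-Hochberg by the textbook step-up rule."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted
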