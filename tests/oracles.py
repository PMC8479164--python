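"""Independent brute-force oracles used to pin expected values.

Each oracle re-derives its statistic from first principles (explicit
sorting, exhaustive enumeration, grid search) without touching the package
implementation paths it is used to check.
"""

from itertools import combinations

import numpy as np
import pandas as pd


def explicit_average_ranks(values):
    """Ascending ranks with average ties, by explicit sort-and-walk."""
    v = list(values)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_rank_score(values: pd.DataFrame, sig_genes, universe_genes):
    """Normalized mean-rank score per sample via explicit rank assembly."""
    universe_genes = list(universe_genes)
    pos = {g: k for k, g in enumerate(universe_genes)}
    g = len(sig_genes)
    n = len(universe_genes)
    out = {}
    for s in values.columns:
        ranks = explicit_average_ranks(values.loc[universe_genes, s])
        mean_rank = sum(ranks[pos[gene]] for gene in sig_genes) / g
        lo = (g + 1) / 2.0
        hi = n - (g - 1) / 2.0
        out[s] = (mean_rank - lo) / (hi - lo)
    return pd.Series(out)


def brute_auc(scores, labels):
    """All-pairs enumeration: wins count 1, ties count 1/2."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_youden(scores, labels):
    """Exhaustive search over all midpoint thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = sorted(set(scores))
    best = None
    for a, b in zip(uniq[:-1], uniq[1:]):
        t = (a + b) / 2.0
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s > t)
        fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s <= t)
        tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s <= t)
        fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s > t)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, (t, sens, spec, j))
    return best[1]


def exact_ranksum_p(a, b):
    """Exact two-sided Wilcoxon rank-sum p by enumeration over all
    group assignments (symmetric two-tailed region)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = explicit_average_ranks(pooled)
    obs = sum(ranks[:n1])
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), n1):
        s = sum(ranks[i] for i in comb)
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def grid_cox_loglik_argmax(times, events, x, lo=-4.0, hi=4.0, step=5e-4):
    """Grid-search maximizer of the explicit Cox partial log-likelihood
    (single covariate, no ties)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    betas = np.arange(lo, hi + step, step)
    ll = np.zeros_like(betas)
    for et in np.sort(times[events == 1]):
        risk = times >= et
        i = np.where((times == et) & (events == 1))[0][0]
        ll += betas * x[i] - np.log(
            np.exp(np.outer(betas, x[risk])).sum(axis=1)
        )
    return float(betas[np.argmax(ll)])
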