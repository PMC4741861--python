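"""Brute-force reference implementations used only to verify the package.

Each oracle is a direct, loop-based transcription of a definition; none
shares code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def pair_count_auc(scores, labels) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly,
    ties counting 1/2."""
    scores = list(map(float, scores))
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_youden(scores, labels) -> float:
    """Exhaustive threshold search for the Youden-J maximizer.

    Candidates are the observed scores; positive at-threshold; ties on J
    resolved toward higher specificity, then the lower threshold.
    """
    scores = list(map(float, scores))
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    best = None
    for t in sorted(set(scores)):
        sens = sum(1 for s in pos if s >= t) / len(pos)
        spec = sum(1 for s in neg if s < t) / len(neg)
        j = sens + spec - 1
        key = (j, spec, -t)  # maximize J, then spec, then prefer lower t
        if best is None or key > best[0]:
            best = (key, t)
    return best[1]


def brute_delta_d(profile, pos_centroid, neg_centroid) -> float:
    """Two-norm distance difference computed with explicit loops."""
    dp = math.sqrt(sum((p - c) ** 2 for p, c in zip(profile, pos_centroid)))
    dn = math.sqrt(sum((p - c) ** 2 for p, c in zip(profile, neg_centroid)))
    return dp - dn


def brute_mean_pairwise_pearson(rows) -> float:
    """Average Pearson r over all unordered row pairs, textbook formula."""
    rows = [np.asarray(r, dtype=float) for r in rows]

    def pearson(a, b):
        am, bm = a - a.mean(), b - b.mean()
        return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))

    vals = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            vals.append(pearson(rows[i], rows[j]))
    return float(np.mean(vals))


def hypergeom_upper_tail(overlap: int, N: int, K: int, n: int) -> float:
    """P(X >= overlap) by the explicit combinatorial sum."""
    total = 0
    for i in range(overlap, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


def dfs_propagated(direct: dict, edges: list, term: str) -> set:
    """Union of direct gene sets over a term and its DFS-reachable
    descendants (each counted once)."""
    children: dict = {}
    for p, c in edges:
        children.setdefault(p, []).append(c)
    seen, stack, genes = set(), [term], set()
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        genes |= set(direct.get(t, ()))
        stack.extend(children.get(t, ()))
    return genes
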