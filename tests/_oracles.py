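"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in plain Python loops, straight from
the definitions, and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

NEG = float("-inf")


def kernel(a: float, b: float) -> float:
    if a > b:
        return 1.0
    if a == b:
        return 0.5
    return 0.0


def brute_wafroc(nl_normal, ll, weights) -> float:
    """Enumerate every (lesion, normal case) pair of the weighted AFROC FOM.

    ``nl_normal``: list per normal case of NL ratings; ``ll``: list per
    abnormal case of per-lesion ratings (NEG for unmarked); ``weights``:
    matching per-lesion weights.
    """
    K1, K2 = len(nl_normal), len(ll)
    total = 0.0
    for marks in nl_normal:
        fp = max(marks) if marks else NEG
        for a in range(K2):
            for rating, w in zip(ll[a], weights[a]):
                total += w * kernel(rating, fp)
    return total / (K1 * K2)


def brute_inferred_roc(nl_all, ll, n_normal) -> float:
    """Wilcoxon statistic on per-case highest ratings, counted pair by pair."""
    highest = []
    for k, marks in enumerate(nl_all):
        h = max(marks) if marks else NEG
        if k >= n_normal:
            lesions = ll[k - n_normal]
            if lesions:
                h = max(h, max(lesions))
        highest.append(h)
    normals = highest[:n_normal]
    abnormals = highest[n_normal:]
    total = sum(kernel(ha, hn) for ha in abnormals for hn in normals)
    return total / (len(normals) * len(abnormals))


def brute_n_pairs(levels: int) -> int:
    return sum(1 for _ in itertools.combinations(range(levels), 2))


def permutation_ttest_p(a, b, rng, n_perm: int = 2000) -> float:
    """Two-sided permutation p-value for a difference in group means."""
    pooled = list(a) + list(b)
    observed = abs(sum(a) / len(a) - sum(b) / len(b))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        ga = [pooled[i] for i in perm[: len(a)]]
        gb = [pooled[i] for i in perm[len(a):]]
        if abs(sum(ga) / len(ga) - sum(gb) / len(gb)) >= observed - 1e-12:
            hits += 1
    return hits / n_perm


def weighted_dose_sum(doses, weights, remainder_organs, remainder_weight) -> float:
    e = sum(weights[o] * doses.get(o, 0.0) for o in weights)
    rem = [doses.get(o, 0.0) for o in remainder_organs]
    return e + remainder_weight * (sum(rem) / len(rem))
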