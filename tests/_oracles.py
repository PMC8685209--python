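"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's own code paths: reachability by
fixed-point iteration, Resnik by exhaustive common-ancestor enumeration,
AUC by concordant/discordant/tie pair counting, and the Mann-Whitney
p-value by exhaustive permutation enumeration.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence


def brute_ancestors(parents: Mapping[str, frozenset[str]], term: str) -> set[str]:
    """Reflexive-transitive closure by fixed-point iteration over parent edges."""
    closure = {term}
    while True:
        grown = set(closure)
        for t in closure:
            grown |= set(parents[t])
        if grown == closure:
            return closure
        closure = grown


def brute_common_ancestors(parents, a: str, b: str) -> set[str]:
    return brute_ancestors(parents, a) & brute_ancestors(parents, b)


def brute_ic(profiles: Sequence[set[str]], parents) -> dict[str, float]:
    """Presence-propagated corpus IC, counted profile by profile."""
    nonempty = [p for p in profiles if p]
    counts: dict[str, int] = {}
    for p in nonempty:
        hit = set()
        for t in p:
            hit |= brute_ancestors(parents, t)
        for a in hit:
            counts[a] = counts.get(a, 0) + 1
    return {t: -math.log(n / len(nonempty)) for t, n in counts.items()}


def brute_resnik(a: str, b: str, ic: Mapping[str, float], parents) -> float:
    return max(ic.get(c, 0.0) for c in brute_common_ancestors(parents, a, b))


def brute_bma(A: set[str], B: set[str], ic, parents) -> float:
    if not A or not B:
        return 0.0
    bests = [max(brute_resnik(a, b, ic, parents) for b in B) for a in A]
    bests += [max(brute_resnik(a, b, ic, parents) for a in A) for b in B]
    return sum(bests) / len(bests)


def brute_auc(true_scores: Sequence[float], false_scores: Sequence[float]) -> float:
    """(concordant + 0.5 * tied) / (n_true * n_false) by exhaustive counting."""
    num = 0.0
    for t in true_scores:
        for f in false_scores:
            if t > f:
                num += 1.0
            elif t == f:
                num += 0.5
    return num / (len(true_scores) * len(false_scores))


def exact_mwu_two_sided(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) over the permutation null,
    capped at 1 (the convention scipy's exact method uses).
    """
    pooled = list(xs) + list(ys)
    n1 = len(xs)

    def u_stat(group1: Sequence[float], group2: Sequence[float]) -> float:
        u = 0.0
        for a in group1:
            for b in group2:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_stat(xs, ys)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in comb]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(u_stat(g1, g2))
    n = len(us)
    p_le = sum(u <= u_obs for u in us) / n
    p_ge = sum(u >= u_obs for u in us) / n
    return min(1.0, 2 * min(p_le, p_ge))
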