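"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: Fisher's exact test is
re-derived by enumerating all tables with the observed margins in exact
rational arithmetic, and the Mann-Whitney null by enumerating every
assignment of the pooled observations to the two groups.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric point probabilities <= the observed table's,
    over all tables with the observed margins (exact rationals)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmfs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)}
    p_obs = pmfs[a]
    return float(min(Fraction(1), sum(p for p in pmfs.values() if p <= p_obs)))


def fisher_margin_oracle(r1: int, r2: int, c1: int) -> dict[int, float]:
    """Two-sided p for every feasible table with the given margins."""
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmfs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)}
    out = {}
    for a, p_obs in pmfs.items():
        out[a] = float(min(Fraction(1), sum(p for p in pmfs.values() if p <= p_obs)))
    return out


def mann_whitney_exact_oracle(group_a, group_b) -> tuple[float, float]:
    """(U of group_a, two-sided exact p) by full enumeration of all
    assignments of the pooled sample to group labels (no ties allowed)."""
    pooled = sorted(list(group_a) + list(group_b))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n_a = len(group_a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}

    def u_of(subset) -> float:
        r = sum(ranks[v] for v in subset)
        return r - n_a * (n_a + 1) / 2.0

    u_obs = u_of(group_a)
    us = [u_of(s) for s in combinations(pooled, n_a)]
    n_tot = len(us)
    cdf_le = sum(u <= u_obs for u in us) / n_tot
    cdf_ge = sum(u >= u_obs for u in us) / n_tot
    return u_obs, min(1.0, 2.0 * min(cdf_le, cdf_ge))
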