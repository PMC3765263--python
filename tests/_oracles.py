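"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by a route structurally different
from the implementation it checks: exhaustive recursion over nested pair
sets for folding, exact rational tail sums for the digital-expression
test, and draw enumeration for the hypergeometric tail.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def fold_oracle_min_energy(seq: str, min_loop: int = 3) -> float:
    """Minimum energy over all pseudoknot-free pairings, by recursion on
    arbitrary position subsets (decide the fate of the first free position,
    split the remainder inside/outside its partner)."""
    memo = {}

    def rec(avail):
        if len(avail) < 2:
            return 0.0
        if avail in memo:
            return memo[avail]
        i, rest = avail[0], avail[1:]
        best = rec(rest)  # i unpaired
        for j in rest:
            if j - i <= min_loop:
                continue
            e = PAIR_ENERGY.get((seq[i], seq[j]))
            if e is None:
                continue
            inside = tuple(p for p in rest if p < j)
            outside = tuple(p for p in rest if p > j)
            cand = e + rec(inside) + rec(outside)
            if cand < best:
                best = cand
        memo[avail] = best
        return best

    return rec(tuple(range(len(seq))))


def ac_pvalue_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided Audic-Claverie p as an exact rational.

    pmf p(y|x) = r^y C(x+y, y) / (1+r)^(x+y+1) with r = N2/N1, accumulated
    with exact Fractions; p = min(1, 2*min(lower, upper)).
    """
    r = Fraction(n2, n1)
    pmf = Fraction(1, 1) / (1 + r) ** (x + 1)  # p(0|x)
    lower = pmf
    for t in range(y):
        pmf = pmf * r * (x + t + 1) / ((t + 1) * (1 + r))
        lower += pmf
    upper = 1 - lower + pmf
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_upper_tail_enum(N: int, n: int, M: int, m: int) -> Fraction:
    """P(overlap >= m) by enumerating all C(N, n) candidate draws."""
    term = set(range(M))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for g in draw if g in term) >= m:
            hits += 1
    return Fraction(hits, total if total else 1)
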