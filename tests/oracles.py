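"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own code paths: plain-Python column
walks, a memoized three-state alignment recursion, and exhaustive
spanning-tree search.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

ACGT = set("ACGT")


def brute_snp_percent(row_a: str, row_b: str) -> tuple[float, int]:
    """Column-by-column SNP% walk."""
    comparable = 0
    mismatches = 0
    for x, y in zip(row_a, row_b):
        if x in ACGT and y in ACGT:
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        return float("nan"), 0
    return 100.0 * mismatches / comparable, comparable


def brute_align_score(a: str, b: str, match, mismatch, gap_open, gap_extend) -> float:
    """Optimal global affine-gap score by memoized recursion over
    (position, position, last-move state); independent of the package's
    vectorized dynamic program."""

    neg = float("-inf")

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "M" else neg
        vals = []
        if state == "M" and i > 0 and j > 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            vals = [best(i - 1, j - 1, s) + sub for s in "MXY"]
        elif state == "X" and i > 0:
            vals = [
                best(i - 1, j, "M") + gap_open,
                best(i - 1, j, "X") + gap_extend,
                best(i - 1, j, "Y") + gap_open,
            ]
        elif state == "Y" and j > 0:
            vals = [
                best(i, j - 1, "M") + gap_open,
                best(i, j - 1, "X") + gap_open,
                best(i, j - 1, "Y") + gap_extend,
            ]
        return max(vals) if vals else neg

    return max(best(len(a), len(b), s) for s in "MXY")


def brute_min_spanning_weight(n: int, weights) -> float:
    """Minimum spanning-tree weight by exhaustive search over all edge
    subsets of size n-1 (feasible for n <= 7).  ``weights[(i, j)]`` for
    i < j."""
    if n == 1:
        return 0.0
    edges = sorted(weights)
    best = None
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok and len({find(i) for i in range(n)}) == 1:
            w = sum(weights[e] for e in subset)
            if best is None or w < best:
                best = w
    return best
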