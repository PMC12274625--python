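"""Independent brute-force oracles used across the test suite."""

from itertools import combinations
from math import comb


def enumerated_overlap_counts(K: int, n: int, N: int) -> dict[int, int]:
    """Number of size-n draws from N items (K marked) with each overlap size,
    by explicit enumeration of every draw."""
    marked = set(range(K))
    counts: dict[int, int] = {}
    for draw in combinations(range(N), n):
        k = len(marked.intersection(draw))
        counts[k] = counts.get(k, 0) + 1
    return counts


def enumerated_upper_tail(k: int, K: int, n: int, N: int) -> float:
    counts = enumerated_overlap_counts(K, n, N)
    total = sum(counts.values())
    return sum(c for kk, c in counts.items() if kk >= k) / total


def comb_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Closed-form combinatorial upper tail (independent of scipy)."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total
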