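"""Independent brute-force oracle for the two-sided Fisher exact test.

Enumerates every 2×2 table with the observed margins, computes each
table's hypergeometric probability as an exact rational number, and sums
the probabilities of all tables no more probable than the observed one
(with the same 1e-7 relative tie slack the implementation documents).
Kept deliberately free of any code from the package under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterator

TIE = Fraction(10**7 + 1, 10**7)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    N, K, n = a + b + c + d, a + c, a + b
    if N == 0:
        return 1.0
    denom = math.comb(N, n)
    k_min, k_max = max(0, n - (N - K)), min(n, K)
    pmf = {
        k: Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
        for k in range(k_min, k_max + 1)
    }
    threshold = pmf[a] * TIE
    total = sum(p for p in pmf.values() if p <= threshold)
    return float(min(total, Fraction(1)))


def iter_all_tables(max_total: int) -> Iterator[tuple[int, int, int, int, float]]:
    """Yield every table with N ≤ max_total together with its oracle P.

    Enumeration is margin-grouped so each margin's pmf is computed once.
    """
    for N in range(0, max_total + 1):
        for n in range(0, N + 1):
            denom = math.comb(N, n) if N else 1
            for K in range(0, N + 1):
                k_min, k_max = max(0, n - (N - K)), min(n, K)
                pmf = [
                    Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
                    for k in range(k_min, k_max + 1)
                ]
                for i, a in enumerate(range(k_min, k_max + 1)):
                    threshold = pmf[i] * TIE
                    p = float(min(sum(q for q in pmf if q <= threshold), Fraction(1)))
                    yield a, n - a, K - a, N - K - (n - a), p
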