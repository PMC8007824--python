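"""Independent brute-force oracles for the exact tests.

These work in exact rational arithmetic by enumerating complete 2x2 tables
(not the implementation's margin-indexed weights), so agreement with the
package is a genuine cross-check rather than a re-run of the same code
path.
"""

from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating every table with the observed
    margins and summing the probabilities of tables no more likely than the
    observed one."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def prob(x: int) -> Fraction:
        # P(table) = C(r1, x) * C(r2, c1 - x) / C(n, c1)
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), comb(n, c1))

    observed = prob(a)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= observed)
    return float(total)


def hypergeom_tail_oracle(k: int, M: int, K: int, n: int) -> float:
    """P[X >= k] with X ~ Hypergeometric(M, K, n), exact combinatorics."""
    hi = min(K, n)
    if k > hi:
        return 0.0
    total = sum(comb(K, x) * comb(M - K, n - x) for x in range(max(k, 0), hi + 1))
    return float(Fraction(total, comb(M, n)))


def binom_tail_oracle(k: int, n: int, p: Fraction) -> float:
    """P[X >= k] with X ~ Binomial(n, p), exact rational arithmetic."""
    p = Fraction(p)
    total = sum(
        comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(max(k, 0), n + 1)
    )
    return float(total)
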