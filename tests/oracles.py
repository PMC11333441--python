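"""Independent exact-arithmetic oracles for the statistical primitives.

Everything here is computed from first principles with integer
combinatorics (math.comb, fractions.Fraction) — no scipy — so these
functions can serve as ground truth for the package's Fisher and binomial
tests.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_pmf(k: int, a_total: int, b_total: int, k_total: int) -> Fraction:
    """P(X = k) for the number of row-1 successes in a 2x2 table with
    margins (a_total, b_total) x (k_total, rest), under independence."""
    return Fraction(
        comb(a_total, k) * comb(b_total, k_total - k), comb(a_total + b_total, k_total)
    )


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by full enumeration.

    Sums the probabilities of all tables with the same margins whose
    hypergeometric probability does not exceed the observed one (with the
    same tiny relative tolerance scipy uses for ties).
    """
    row1 = a + b
    row2 = c + d
    col1 = a + c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    total = Fraction(0)
    # match scipy's gamma = 1 + 1e-7 relative tie tolerance
    thresh_num = p_obs.numerator * (10**7 + 1)
    for k in range(lo, hi + 1):
        pk = hypergeom_pmf(k, row1, row2, col1)
        # pk <= p_obs * (1 + 1e-7) in exact arithmetic
        if pk.numerator * p_obs.denominator * 10**7 <= thresh_num * pk.denominator:
            total += pk
    return float(min(total, Fraction(1)))


def binom_two_sided(k: int, n: int) -> float:
    """Two-sided exact binomial p at p0 = 1/2 by minimum-likelihood summation.

    With p0 = 1/2 the pmf is proportional to comb(n, i), so outcome
    inclusion reduces to an exact integer comparison comb(n, i) <=
    comb(n, k).
    """
    target = comb(n, k)
    total = sum(comb(n, i) for i in range(n + 1) if comb(n, i) <= target)
    return min(1.0, total / 2**n)


def binom_exact_size(n: int, alpha: float = 0.05) -> float:
    """Exact rejection probability of the two-sided binomial test at n, p=1/2."""
    return sum(
        comb(n, k) / 2**n for k in range(n + 1) if binom_two_sided(k, n) < alpha
    )
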