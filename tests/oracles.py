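"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — O(n^2) scans and exact rational
arithmetic over the full combinatorial support — so that agreement with
the fast library routines is meaningful.
"""

from fractions import Fraction
from math import comb

from mcpgchip.intervals import as_interval


def brute_force_overlaps(set_a, set_b):
    """All-pairs interval overlap, the reference for find_overlaps."""
    out = {}
    for i, a in enumerate(set_a):
        ai = as_interval(a)
        hits = []
        for j, b in enumerate(set_b):
            bi = as_interval(b)
            if ai.chrom == bi.chrom and ai.start < bi.end and bi.start < ai.end:
                hits.append(j)
        if hits:
            out[i] = hits
    return out


def hypergeom_pmf_fraction(k: int, N: int, K: int, n: int) -> Fraction:
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) by exact summation over the support."""
    hi = min(K, n)
    return sum(
        (hypergeom_pmf_fraction(x, N, K, n) for x in range(max(k, max(0, n - (N - K))), hi + 1)),
        Fraction(0),
    )


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p for [[a,b],[c,d]]: sum of tables with
    point probability <= that of the observed table (with a tiny relative
    slack for the comparison, matching the conventional implementation)."""
    N = a + b + c + d
    K = a + b  # row-1 total
    n = a + c  # col-1 total
    p_obs = hypergeom_pmf_fraction(a, N, K, n)
    cutoff = p_obs * Fraction(10000001, 10000000)
    total = Fraction(0)
    for x in range(max(0, n - (N - K)), min(K, n) + 1):
        p = hypergeom_pmf_fraction(x, N, K, n)
        if p <= cutoff:
            total += p
    return total


def binom_point_mass_fraction(k: int, n: int) -> Fraction:
    """Binomial(n, 1/2) point probability in exact big-integer arithmetic."""
    return Fraction(comb(n, k), 2**n)


def binom_upper_tail_fraction(k: int, n: int) -> Fraction:
    return Fraction(sum(comb(n, x) for x in range(k, n + 1)), 2**n)
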