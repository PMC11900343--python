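"""Independent brute-force oracles used by the test suite.

Each oracle is written from the definition of the statistic it checks —
exact rational arithmetic or explicit enumeration — and shares no code with
the implementation under test.
"""

from fractions import Fraction
from math import comb

from popsweep.genotypes import MISSING


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> Fraction:
    """Exact two-sided Hardy–Weinberg p-value by enumerating every
    heterozygote count compatible with the observed allele counts."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa

    def prob(h: int) -> Fraction:
        if (nA - h) % 2 or (na - h) % 2:
            return Fraction(0)
        hom_A = (nA - h) // 2
        hom_a = (na - h) // 2
        if hom_A < 0 or hom_a < 0:
            return Fraction(0)
        # multinomial genotype count × 2^h over the allele-permanence constant
        ways = Fraction(
            comb(n, h) * comb(n - h, hom_A) * 2**h
        )
        total = Fraction(comb(2 * n, nA))
        return ways / total

    probs = {h: prob(h) for h in range(min(nA, na) + 1)}
    p_obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= p_obs)


def wc_components_scalar(group1_col, group2_col):
    """Weir–Cockerham (1984) a, b, c for one site, straight from the
    published two-population formulas in scalar arithmetic.

    Returns None when either group has < 2 called diploids.
    """
    def summarize(col):
        called = [g for g in col if g != MISSING]
        n = len(called)
        if n < 2:
            return None
        p = sum(called) / (2 * n)
        h = sum(1 for g in called if g == 1) / n
        return n, p, h

    s1, s2 = summarize(group1_col), summarize(group2_col)
    if s1 is None or s2 is None:
        return None
    (n1, p1, h1), (n2, p2, h2) = s1, s2
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2_ = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (n_bar / n_c) * (
        s2_ - (p_bar * (1 - p_bar) - s2_ * (r - 1) / r - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2_ * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    return a, b, c


def pi_pairwise_enumeration(col) -> float:
    """Mean pairwise difference at one site by explicit enumeration of every
    allele pair in the group."""
    alleles = []
    for g in col:
        if g == MISSING:
            continue
        alleles.extend([1] * int(g) + [0] * (2 - int(g)))
    n = len(alleles)
    if n < 2:
        return 0.0
    diffs = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if alleles[i] != alleles[j]
    )
    return diffs / comb(n, 2)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n), by exact summation."""
    total = comb(N, n)
    return sum(
        Fraction(comb(K, x) * comb(N - K, n - x), total)
        for x in range(k, min(K, n) + 1)
    )
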