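"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: exact rational
binomial tails via ``fractions.Fraction``, and explicit per-individual
Monte-Carlo simulations of the presence/absence process.
"""

from fractions import Fraction
from math import comb, exp

import numpy as np


def binom_tail_exact(m: int, n: int, p: Fraction) -> Fraction:
    """sum_{i=m}^{n} C(n,i) p^i (1-p)^(n-i) as an exact rational."""
    if m <= 0:
        return Fraction(1)
    return sum(
        (Fraction(comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(m, n + 1)),
        Fraction(0),
    )


def present(lam: float, size, rng) -> np.ndarray:
    """Bernoulli presence draws: a Poisson(lam) count is >= 2."""
    return rng.poisson(lam, size) >= 2


def mc_fp_coverage(lam: float, n: int, m: int, reps: int, seed: int) -> tuple[float, float]:
    """Simulate the marker rule for an ordinary k-mer: present in >= m of n
    males and absent in all n females.  Returns (estimate, standard error)."""
    rng = np.random.default_rng(seed)
    males = present(lam, (reps, n), rng).sum(axis=1) >= m
    females = present(lam, (reps, n), rng).sum(axis=1) == 0
    hits = males & females
    p = hits.mean()
    return p, np.sqrt(max(p * (1 - p), 1e-300) / reps)


def mc_fp_het(lam: float, p_h1: float, n: int, m: int, reps: int, seed: int) -> tuple[float, float]:
    """Simulate the two-allele heterozygous case: each allele j carries rate
    p_hj*lam and is a false marker independently; the rate sums the alleles."""
    rng = np.random.default_rng(seed)
    total = np.zeros(reps, dtype=float)
    for ph in (p_h1, 1.0 - p_h1):
        males = present(ph * lam, (reps, n), rng).sum(axis=1) >= m
        females = present(ph * lam, (reps, n), rng).sum(axis=1) == 0
        total += (males & females).astype(float)
    p = total.mean()
    var = total.var(ddof=1)
    return p, np.sqrt(var / reps)


def mc_tpr(lam: float, n: int, m: int, reps: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    hits = present(lam, (reps, n), rng).sum(axis=1) >= m
    p = hits.mean()
    return p, np.sqrt(max(p * (1 - p), 1e-300) / reps)


def mc_read_sort(N: int, M: int, p: float, reps: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    hits = (rng.random((reps, N)) < p).sum(axis=1) >= M
    q = hits.mean()
    return q, np.sqrt(max(q * (1 - q), 1e-300) / reps)
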