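"""Closed-form error models for population k-mer marker identification.

The coverage model: the multiplicity X of a k-mer in one individual's short
reads is Poisson with rate

    lambda = d * (1 - r)^k * (l - k + 1) / l

(d sequencing depth, l read length, r per-site error).  A k-mer is called
present only when X >= 2, so the absence probability is
q_o = P(X<=1) = (1 + lambda) * exp(-lambda).

From this follow the false-positive rate of marker identification due to
coverage fluctuations alone (f1), due to autosomal heterozygosity (f2, with
the two alleles of a heterozygous site splitting the rate as
lambda_j = p_hj * lambda), their kh-weighted total f, the true-positive rate
of marker identification (binomial tail over >= m of n males), and the
binomial model for recovering at least M of the N markers carried by an
error-prone long read.

The lower summation limit m is 2n/3 rounded to the nearest integer by
default (see :func:`sexmer.markers.male_presence_threshold`); ceiling and
floor variants are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .markers import Rule, male_presence_threshold


@dataclass
class TheoryParams:
    """All symbols of the closed-form models, with the defaults used
    throughout: n individuals per sex at depth d=5x, 150 bp reads with 1%
    error, k=21, autosomal heterozygosity h=0.001 per site."""

    n: int = 5
    d: float = 5.0
    l: int = 150
    r: float = 0.01
    k: int = 21
    h: float = 0.001
    r3: float = 0.1
    presence_min: int = 2
    m_rule: Rule = "round"

    def __post_init__(self) -> None:
        for name in ("r", "h", "r3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.l <= self.k or self.k < 1:
            raise ValueError(f"need l > k >= 1, got l={self.l}, k={self.k}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.d < 0:
            raise ValueError(f"d must be >= 0, got {self.d}")

    @property
    def m(self) -> int:
        return male_presence_threshold(self.n, self.m_rule)


@dataclass
class HetAlleleDistribution:
    """Discrete distribution of the minor-allele read fraction p_h1 at a
    heterozygous site.  The default 5-point distribution is the published
    population estimate from biallelic SNVs (values 0.05..0.45 in steps of
    0.1 with probabilities 92.77%, 2.59%, 1.80%, 1.48%, 1.36%)."""

    values: tuple[float, ...] = (0.05, 0.15, 0.25, 0.35, 0.45)
    probs: tuple[float, ...] = (0.9277, 0.0259, 0.0180, 0.0148, 0.0136)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.probs):
            raise ValueError("values and probs must align")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {sum(self.probs)}, not 1")
        if any(not 0.0 < v <= 0.5 for v in self.values):
            raise ValueError("p_h1 values must lie in (0, 0.5]")


@dataclass
class MarkerCensus:
    """Genome-wide k-mer counts entering the marker precision formula:
    YSK true sex-limited-specific k-mers, AXK autosome+X k-mers."""

    YSK: int
    AXK: int

    def __post_init__(self) -> None:
        if self.YSK < 0 or self.AXK < 0:
            raise ValueError("census counts must be >= 0")


def lambda_rate(d: float, r: float, k: int, l: int) -> float:
    """Poisson rate of k-mer multiplicity: d*(1-r)^k*(l-k+1)/l."""
    if l <= k:
        raise ValueError(f"need l > k, got l={l}, k={k}")
    return d * (1.0 - r) ** k * (l - k + 1) / l


def absence_prob(lam: float) -> float:
    """q_o = P(X<=1) = (1+lambda)*exp(-lambda): k-mer seen at most once."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return float((1.0 + lam) * math.exp(-lam))


def presence_prob(lam: float) -> float:
    return 1.0 - absence_prob(lam)


def _binom_tail(m: int, n: int, p: float) -> float:
    """P(Bin(n,p) >= m); 1 when m <= 0, 0 when m > n."""
    if m <= 0:
        return 1.0
    if m > n:
        return 0.0
    return float(binom.sf(m - 1, n, p))


def fp_coverage(params: TheoryParams) -> float:
    """f1: probability an autosome/X k-mer passes the marker rule by chance.

    The k-mer must be absent (X<=1) in all n females and present in at least
    m of n males: f1 = q_o^n * sum_{i=m}^{n} C(n,i) p_o^i q_o^{n-i}.
    """
    lam = lambda_rate(params.d, params.r, params.k, params.l)
    q = absence_prob(lam)
    return q ** params.n * _binom_tail(params.m, params.n, 1.0 - q)


def fp_heterozygosity(params: TheoryParams, p_h1: float) -> float:
    """f2: false-positive rate from a heterozygous autosomal site.

    Each allele j carries the split rate lambda_j = p_hj*lambda and is a
    false marker when present in >= m males and absent in all females; f2
    sums the two alleles.
    """
    if not 0.0 < p_h1 < 1.0:
        raise ValueError(f"p_h1 must be in (0,1), got {p_h1}")
    lam = lambda_rate(params.d, params.r, params.k, params.l)
    total = 0.0
    for ph in (p_h1, 1.0 - p_h1):
        q = absence_prob(ph * lam)
        total += q ** params.n * _binom_tail(params.m, params.n, 1.0 - q)
    return total


def fp_total(params: TheoryParams, het_dist: HetAlleleDistribution | None = None) -> float:
    """Total false-positive rate f = (1-kh) f1 + kh * E[f2(p_h1)].

    A k-mer window covers a heterozygous site with probability ~ k*h (single
    het site per window; multi-site windows are negligible, see
    :func:`het_multi_site_prob`).
    """
    if het_dist is None:
        het_dist = HetAlleleDistribution()
    kh = params.k * params.h
    if kh >= 1.0:
        raise ValueError(f"k*h must be < 1, got {kh}")
    f1 = fp_coverage(params)
    f2_avg = sum(p * fp_heterozygosity(params, x) for x, p in zip(het_dist.values, het_dist.probs))
    return (1.0 - kh) * f1 + kh * f2_avg


def tpr_msk(params: TheoryParams, effective_depth: float | None = None) -> float:
    """True-positive rate: a genuine sex-limited k-mer is present in >= m of
    n males (the female-absence factor is ~1 for true markers).

    ``effective_depth`` substitutes for d in lambda; it exists because a
    single-copy Y k-mer may see half the autosomal depth depending on how d
    is defined.  Default: d as given.
    """
    d = params.d if effective_depth is None else effective_depth
    if d <= 0:
        raise ValueError(f"effective depth must be > 0, got {d}")
    lam = lambda_rate(d, params.r, params.k, params.l)
    return _binom_tail(params.m, params.n, presence_prob(lam))


def read_sort_prob(N: int, M: int, p: float) -> float:
    """Probability >= M of the N markers on a long read survive sequencing.

    Each marker survives independently with p = (1-r3)^k; the result is the
    binomial upper tail sum_{i=M}^{N} C(N,i) p^i (1-p)^{N-i}.
    """
    if N < 0 or M < 0:
        raise ValueError("N and M must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    return _binom_tail(M, N, p)


def long_read_kmer_survival(r3: float, k: int) -> float:
    """p = (1-r3)^k: a k-mer is sequenced without error on a long read."""
    return (1.0 - r3) ** k


def het_multi_site_prob(k: int, h: float) -> float:
    """Probability a k-mer window contains more than one heterozygous site:
    1 - (1-h)^k - k h (1-h)^(k-1).  ~2.1e-4 at k=21, h=0.001, which is why
    single-site treatment suffices."""
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"h must be in [0,1], got {h}")
    return 1.0 - (1.0 - h) ** k - k * h * (1.0 - h) ** (k - 1)


def misid_prob(k: int, r: float) -> float:
    """Probability a sequencing error turns one k-mer into a *specific* other
    k-mer at edit distance 1: (1-r)^(k-1) * r/3.  ~0.3% at k=21, r=0.01,
    justifying its neglect in f2."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0,1], got {r}")
    return (1.0 - r) ** (k - 1) * r / 3.0


def msk_precision(census: MarkerCensus, tpr: float, fpr: float) -> float:
    """Expected marker precision YSK*TPR / (YSK*TPR + AXK*FPR)."""
    if not (0.0 <= tpr <= 1.0 and 0.0 <= fpr <= 1.0):
        raise ValueError("rates must be in [0,1]")
    denom = census.YSK * tpr + census.AXK * fpr
    if denom <= 0:
        raise ValueError("undefined precision: YSK*TPR + AXK*FPR is zero")
    return census.YSK * tpr / denom
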