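"""Closed-form error models for population k-mer marker identification.

Evaluates the false-positive and true-positive rates of marker selection for
a 5-vs-5 cohort at 5x depth, and the probability that an error-prone long
read keeps enough markers to be classified.
"""

from sexmer import (
    HetAlleleDistribution,
    TheoryParams,
    fp_coverage,
    fp_total,
    long_read_kmer_survival,
    read_sort_prob,
    tpr_msk,
)

params = TheoryParams(n=5, d=5, l=150, r=0.01, k=21, h=0.001)

print(f"coverage false-positive rate f1      = {fp_coverage(params):.3g}")
print(f"  (at n=10: {fp_coverage(TheoryParams(n=10, d=5, l=150, r=0.01, k=21)):.3g})")
print(f"total false-positive rate f (h=1e-3) = {fp_total(params, HetAlleleDistribution()):.3g}")
print(f"marker true-positive rate TPR        = {tpr_msk(params):.4f}")

# a 10 kb Nanopore-like read (r3=0.1) over a region carrying 70 markers,
# needing 7 surviving hits per kb to pass the density filter
p = long_read_kmer_survival(r3=0.1, k=21)
print(f"k-mer survival on a 10% -error read  = {p:.4f}")
print(f"P(>=70 of 700 markers survive)       = {read_sort_prob(700, 70, p):.6f}")

# reading: f1 is ~4e-5 per autosomal k-mer, so a 3 Gb genome yields ~1e5
# coverage false markers at n=5 but essentially none at n=10; TPR ~0.98
# means almost every genuine Y k-mer is recovered; and even at 10% read
# error, where only ~11% of marker k-mers survive intact, a marker-dense
# 10 kb region still clears the 7/kb filter ~80% of the time.
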