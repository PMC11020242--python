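# Methods

## The problem

In most vertebrate genome projects the sex-limited chromosome (Y in XY
systems, W in ZW systems) is the hardest to assemble: it is haploid,
repeat-rich, and its reads are a small minority of a whole-genome run.
`sexmer` implements a population k-mer strategy for isolating it *before*
assembly: short reads from n males and n females are reduced to per-individual
k-mer presence sets; k-mers present in most males and in no female are
sex-limited-chromosome markers (here called MSK, male-specific k-mers); long
reads or contigs are then classified by the density of marker hits per
kilobase. The whole procedure needs no reference genome for the target
chromosome.

## Marker identification model

Per individual, the multiplicity X of a k-mer in a short-read set is modelled
as Poisson with rate

    lambda = d (1 - r)^k (l - k + 1) / l

where d is depth, l read length, r per-site error. A k-mer is *present* only
when X >= 2 (singletons are almost always sequencing errors), so the absence
probability is q_o = (1 + lambda) e^(-lambda) and p_o = 1 - q_o.

A k-mer is selected as a marker when present in at least m of n males and in
no female, with m = 2n/3. **Rounding rule for m:** we use the nearest integer
(so m=3 at n=5, m=7 at n=10); the ceiling and floor variants are options.
The nearest-integer rule is the one whose closed-form coverage false-positive
rate matches the model's reference values at both n=5 (≈4.4e-5) and n=10
(≈1.9e-9); the ceiling gives ≈3.9e-5 at n=5.

Closed forms implemented in `sexmer.theory`:

- `fp_coverage` — f1 = q_o^n * sum_{i=m..n} C(n,i) p_o^i q_o^(n-i): an
  ordinary autosome/X k-mer slips through because all n females miss it by
  coverage chance while >= m males see it.
- `fp_heterozygosity` — the two alleles of a heterozygous autosomal site
  split the rate as lambda_j = p_hj * lambda (p_h1 + p_h2 = 1); each allele
  is a false marker by the same rule; f2 sums both.
- `fp_total` — f = (1 - kh) f1 + kh E[f2(p_h1)], with the expectation over a
  5-point empirical distribution of p_h1 (0.05..0.45 with probabilities
  92.77/2.59/1.80/1.48/1.36%), a built-in default the caller can override.
  Windows with more than one heterozygous site (probability
  `het_multi_site_prob(k,h)` ≈ 2.1e-4 at k=21, h=0.001) and error-induced
  k-mer identity switches (`misid_prob` ≈ 0.3%) are neglected, and the
  implementation exposes both neglected terms so the approximation can be
  checked at other parameter values.
- `tpr_msk` — the binomial tail P(>= m of n males present); the
  female-absence factor for a genuine Y k-mer is ~1. `effective_depth` is
  exposed because whether a single-copy Y k-mer sees d or d/2 depends on how
  d is defined (per haploid copy vs per genome); default d as given.
- `read_sort_prob` — a long read carrying N marker positions retains each
  with probability p = (1 - r3)^k; the probability at least M survive is the
  binomial upper tail.
- `msk_precision` — expected marker precision YSK*TPR / (YSK*TPR + AXK*FPR)
  given genome-wide census counts.

Binomial tails are computed with `scipy.stats.binom.sf`; the test suite
checks them against exact rational summation to 1e-10 relative error for
n <= 20.

## Read sorting

A read of length L scores `msk_hits` = number of k-positions whose canonical
k-mer is a marker (occurrences, not distinct markers; a `distinct` flag
flips this), and density = hits * 1000 / L. The denominator is the full read
length, not L - k + 1; for multi-kilobase reads the difference is below a
percent and the choice is fixed and documented. A read is selected when
density >= threshold AND hits >= min_hits (default 1, so a threshold of 0
never selects marker-free reads). Equality selects: only *lower* density is
excluded. The default threshold is 7 markers/kb — the genome-wide average
marker density across the human Y — because no portable procedure exists for
computing the target-chromosome average before that chromosome is assembled;
when a reference for the sex-limited chromosome is available,
`estimate_density_threshold` computes the average marker density directly
from it instead.

## Synthetic data

The generator produces the statistical structure the method assumes, at desk
scale, with exact ground truth:

- **Genome** — i.i.d. uniform autosome and X-analog; the Y-analog is a copy
  of an X segment mutated at `xy_divergence` per site, preceded by a
  PAR-like segment copied verbatim from X, optionally followed by novel
  random sequence (`y_novel_frac`, default 0, so marker density on Y is set
  by the divergence alone: at 1% divergence ~19% of Y 21-mers are
  Y-specific, ≈190 markers/kb). Defaults are 5 Mb autosome, 2 Mb X, 0.5 Mb
  Y, 20 kb PAR — large enough that marker counts are in the 10^4-10^5 range,
  small enough that every stage runs in seconds to minutes.
- **Individuals** — diploid; males carry autosome x2, X, Y; females
  autosome x2, X x2. Heterozygosity is autosomal only (the model ignores X
  heterozygosity).
- **Population heterogeneity** — by default, shared biallelic polymorphism:
  variant sites, alternative alleles and frequencies (uniform on
  [0.05, 0.5]) are drawn once per population, and individuals sample
  Hardy-Weinberg genotypes. Site density is calibrated so the per-individual
  heterozygosity rate is h. This is deliberate: the false-positive mechanism
  of the f2 model is an alternative allele carried by several males and, by
  chance, no female — private per-individual mutations can never pass an
  m >= 2 carrier threshold and would make marker F1 insensitive to h. A
  `private` mode (independent per-individual mutations) is retained.
- **Short reads** — uniform sampling over haplotypes, per-haploid-copy depth
  d (a diploid autosome receives 2d), substitution errors only at r = 0.009
  by default (the small indel rates of Illumina simulators are negligible
  for presence/absence k-mer analysis). A deterministic `tiling` mode
  (stride l/2, every tile emitted twice) guarantees every genomic k-mer is
  covered >= 2x — the regime the presence rule assumes — and is used for
  noise-free exact-recovery checks.
- **Long reads** — chromosome chosen proportional to length x copy number,
  Gaussian-truncated lengths, substitution + insertion + deletion errors.
  Presets: hifi (0.4/0.3/0.3% errors, 12 +- 1 kb), clr (5/3/2%, 7.5 +- 3 kb),
  ont (4/2/3%, 15 +- 8 kb). Each read id and an origins table record the
  true chromosome, reference interval, and for Y reads the fraction of
  bases outside the PAR.

What the generator does **not** emulate: repeats and segmental duplication
(the hard part of real Y assembly), GC and coverage bias, quality-score
structure, structural variation, and chromosome-scale genome sizes. Passing
tests therefore demonstrate the statistical logic of marker selection and
density sorting, not performance on repeat-rich real chromosomes.

## Evaluation

Marker sets are scored as set precision/recall/F1 against the exact truth
set (canonical Y k-mers absent from autosome+X, computed by brute-force set
difference). Read partitions are scored per read against origin labels; a Y
read counts as target only when >= 50% of its bases are outside the PAR
(PAR reads carry no markers by construction and would otherwise dominate the
recall penalty; the cutoff is configurable, and an `exclude` policy drops
boundary-straddling reads entirely for exact-recovery checks).

`degrade_marker_precision` spikes ceil(|true|(1-pi)/pi) decoy k-mers sampled
from the autosome+X pool into the truth set, reaching precision pi to within
1/|true|. At the default desk scale, 70% precision implies ~40k decoys over
~7 Mb of autosome+X, i.e. ~5.5 decoys/kb. On a chromosome-scale genome the
same precision yields well under 1 decoy/kb (the autosome:Y size ratio is an
order of magnitude larger), so the desk-scale setting is the *harder* test
of the density filter; it still sits far enough below the 7/kb threshold
(after error thinning by (1-r3)^k) that sorting F1 stays above 90%.

## Sweep experiments

- `run_population_sweep` — marker F1 over a grid of (individuals per sex,
  heterozygosity), 5 replicates by default, each replicate regenerating
  genome and population from counter-derived seeds. Run on a scaled genome
  (300/100/30 kb, 5 kb PAR) so a full grid takes minutes; the assertions are
  trend assertions (F1 rises with n, falls with h), not curve values, since
  absolute F1 depends on genome scale.
- `run_precision_sweep` — read-sorting F1 over marker precision levels and
  technology presets, reporting decoy counts and densities alongside.

## Numerical and design notes

- Canonical k-mer = lexicographic min(seq, revcomp); k odd (no
  self-complementary k-mers); k in [3, 63], 2-bit packed uint64 keys for
  k <= 31 (numeric order = lexicographic order), fixed-width bytes above.
  Windows containing any non-ACGT symbol are skipped entirely.
- Counting is exact (no sketches). The window packer is a single-pass
  rolling kernel (numba-compiled when available, with a pure numpy
  fallback); marker membership uses a 24-bit occupancy prefilter before
  binary search.
- Selection intersects sorted key arrays, so results are independent of
  input order; ties and duplicates cannot occur by construction.
- The pooled-depth band filter (keep k-mers whose pooled male count is
  within a window around the haploid expectation n*d/2) is available but
  off by default: the core selection is presence/absence, and the band is
  an orthogonal single-copy enrichment heuristic.
- All randomness flows from explicit seeds; population members get distinct
  counter-derived seeds. Outputs are deterministic given seeds and
  parameters, independent of batching.
- Degenerate inputs: empty read streams warn and return empty tables; reads
  shorter than k score zero and are never selected; an empty marker file is
  usable (nothing selected); division-by-zero conventions for
  precision/recall are 0.

## Known limitations

- No repeat or duplication model: real sex chromosomes contain ampliconic
  and heterochromatic repeats whose k-mers recur within Y, inflating marker
  density variance in ways the uniform genome does not show.
- The 7/kb default threshold is the human value; other genomes need the
  reference-based estimate or a calibration sweep.
- The heterozygosity model is biallelic SNVs only; indel and structural
  polymorphism also create population-specific k-mers.
- W-chromosome (ZW) workflows are supported by swapping the group labels,
  not by a separate code path.
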