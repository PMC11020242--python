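"""Synthetic genomes, populations and reads with known sex-chromosome truth.

The generator emulates the statistical structure the marker method relies
on, at desk scale: a uniform-random autosome and X-analog; a Y-analog built
from an X segment mutated at a configurable X-Y divergence, sharing a
PAR-like segment verbatim with X (and optionally carrying novel sequence);
diploid individuals with per-site autosomal heterozygosity; short reads with
substitution errors; and long reads with substitution+indel errors under
HiFi/CLR/ONT-like presets, each read labelled with its true chromosome of
origin.  Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .kmers import KmerSpec, SENTINEL, codes_to_str, window_keys

Sex = Literal["male", "female"]

#: per-technology (substitution, insertion, deletion, mean len, sd len) rates
LONG_READ_PRESETS: dict[str, tuple[float, float, float, int, int]] = {
    "hifi": (0.004, 0.003, 0.003, 12_000, 1_000),
    "clr": (0.05, 0.03, 0.02, 7_500, 3_000),
    "ont": (0.04, 0.02, 0.03, 15_000, 8_000),
}


@dataclass(frozen=True)
class GenomeConfig:
    """Desk-scale genome layout.

    The Y-analog is composed of: a PAR copied verbatim from the start of X,
    then a copy of the following X segment mutated at ``xy_divergence`` per
    site, then (optionally) novel random sequence for a ``y_novel_frac``
    fraction of the non-PAR length.  ``y_novel_frac`` defaults to 0 so the
    Y-specific marker density is controlled by the divergence alone.
    """

    autosome_len: int = 5_000_000
    x_len: int = 2_000_000
    y_len: int = 500_000
    par_len: int = 20_000
    xy_divergence: float = 0.01
    y_novel_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.autosome_len, self.x_len, self.y_len, self.par_len) < 0:
            raise ValueError("lengths must be >= 0")
        if self.par_len > min(self.x_len, self.y_len):
            raise ValueError("par_len exceeds X or Y length")
        if not 0.0 <= self.xy_divergence <= 1.0:
            raise ValueError("xy_divergence must be in [0,1]")
        if not 0.0 <= self.y_novel_frac <= 1.0:
            raise ValueError("y_novel_frac must be in [0,1]")
        from_x = self.par_len + round((self.y_len - self.par_len) * (1 - self.y_novel_frac))
        if from_x > self.x_len:
            raise ValueError("X too short to template the Y-analog")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability rate (never to itself)."""
    out = codes.copy()
    mask = rng.random(len(codes)) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return out


@dataclass
class SyntheticTruth:
    """Generated chromosomes plus exact Y-specific k-mer ground truth."""

    config: GenomeConfig
    chroms: dict[str, np.ndarray]  # 'autosome', 'X', 'Y' -> uint8 code arrays
    _kmer_cache: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def par_len(self) -> int:
        return self.config.par_len

    def true_specific_kmers(self, spec: KmerSpec) -> np.ndarray:
        """Canonical Y k-mers absent from autosome and X (sorted keys, exact)."""
        if spec.k not in self._kmer_cache:
            y = np.unique(window_keys(self.chroms["Y"], spec))
            ax = np.union1d(
                np.unique(window_keys(self.chroms["autosome"], spec)),
                np.unique(window_keys(self.chroms["X"], spec)),
            )
            self._kmer_cache[spec.k] = np.setdiff1d(y, ax, assume_unique=True)
        return self._kmer_cache[spec.k]

    def autosome_x_kmers(self, spec: KmerSpec) -> np.ndarray:
        """Sorted canonical k-mer keys of autosome+X (the decoy pool)."""
        return np.union1d(
            np.unique(window_keys(self.chroms["autosome"], spec)),
            np.unique(window_keys(self.chroms["X"], spec)),
        )

    def y_nonpar_fraction(self, start: int, length: int) -> float:
        """Fraction of a Y interval lying outside the PAR."""
        end = start + length
        overlap = max(0, min(end, self.config.y_len) - max(start, self.par_len))
        return overlap / length if length else 0.0


def generate_genome(config: GenomeConfig | None = None, **kwargs) -> SyntheticTruth:
    """Build the three-chromosome truth genome deterministically from a seed."""
    if config is None:
        config = GenomeConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    autosome = rng.integers(0, 4, config.autosome_len, dtype=np.uint8)
    x = rng.integers(0, 4, config.x_len, dtype=np.uint8)
    nonpar = config.y_len - config.par_len
    from_x_len = round(nonpar * (1 - config.y_novel_frac))
    par = x[: config.par_len].copy()
    diverged = _mutate(x[config.par_len : config.par_len + from_x_len], config.xy_divergence, rng)
    novel = rng.integers(0, 4, nonpar - from_x_len, dtype=np.uint8)
    y = np.concatenate([par, diverged, novel])
    return SyntheticTruth(config, {"autosome": autosome, "X": x, "Y": y})


def true_specific_kmers(truth: SyntheticTruth, spec: KmerSpec) -> np.ndarray:
    """Module-level alias for :meth:`SyntheticTruth.true_specific_kmers`."""
    return truth.true_specific_kmers(spec)


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

@dataclass
class PopulationVariants:
    """Shared biallelic autosomal polymorphism for one simulated population.

    Sites, alternative alleles and allele frequencies are drawn once per
    population; individuals then sample Hardy-Weinberg genotypes from them.
    This is the heterogeneity the marker false-positive model describes: an
    alternative-allele k-mer can be carried by several males and by chance
    no female, which a private per-individual mutation never achieves.
    """

    positions: np.ndarray
    alts: np.ndarray  # base codes
    freqs: np.ndarray  # alt allele frequencies

    def __len__(self) -> int:
        return len(self.positions)


#: mean per-site heterozygosity 2f(1-f) under f ~ U(0.05, 0.5), used to
#: calibrate polymorphic-site density so individuals are het at rate h
_MEAN_HET_PER_SITE = 0.365


def sample_population_variants(
    truth: SyntheticTruth, het_rate: float, seed: int,
    f_range: tuple[float, float] = (0.05, 0.5),
) -> PopulationVariants:
    """Draw the population's autosomal variant sites.

    Site density is ``het_rate / E[2f(1-f)]`` so that the expected fraction
    of sites at which any one individual is heterozygous equals ``het_rate``.
    """
    rng = np.random.default_rng(seed)
    a_len = len(truth.chroms["autosome"])
    density = het_rate / _MEAN_HET_PER_SITE
    n_sites = rng.binomial(a_len, min(density, 1.0))
    positions = np.sort(rng.choice(a_len, size=n_sites, replace=False))
    ref = truth.chroms["autosome"][positions]
    alts = (ref + rng.integers(1, 4, n_sites, dtype=np.uint8)) % 4
    freqs = rng.uniform(f_range[0], f_range[1], n_sites)
    return PopulationVariants(positions, alts, freqs)


@dataclass
class Individual:
    """A diploid individual as haplotype code arrays.

    Males carry autosome x2, X x1, Y x1; females autosome x2, X x2.
    Heterozygosity is applied to one autosomal haplotype only (sex-chromosome
    heterozygosity is ignored by the model).
    """

    label: str
    sex: Sex
    haplotypes: list[tuple[str, np.ndarray]]

    @property
    def total_len(self) -> int:
        return sum(len(h) for _, h in self.haplotypes)


def derive_individual(
    truth: SyntheticTruth,
    het_rate: float,
    sex: Sex,
    seed: int,
    label: str | None = None,
    variants: PopulationVariants | None = None,
) -> Individual:
    """Instantiate one diploid individual with autosomal heterozygosity.

    With ``variants`` (the population polymorphism model) each autosomal
    haplotype samples alleles at the shared sites by frequency; otherwise
    each autosomal site mutates privately on the second haplotype with
    probability ``het_rate``.  X and Y are carried unmodified either way.
    """
    if not 0.0 <= het_rate <= 0.01:
        raise ValueError(f"het_rate must be in [0, 0.01], got {het_rate}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    rng = np.random.default_rng(seed)
    a = truth.chroms["autosome"]
    if variants is not None and len(variants):
        haps = []
        for hap_name in ("A_hap1", "A_hap2"):
            carry = rng.random(len(variants)) < variants.freqs
            hap = a.copy()
            hap[variants.positions[carry]] = variants.alts[carry]
            haps.append((hap_name, hap))
    else:
        haps = [("A_hap1", a), ("A_hap2", _mutate(a, het_rate, rng))]
    haps.append(("X_hap1", truth.chroms["X"]))
    if sex == "male":
        haps.append(("Y", truth.chroms["Y"]))
    else:
        haps.append(("X_hap2", truth.chroms["X"]))
    return Individual(label or f"{sex}", sex, haps)


# ---------------------------------------------------------------------------
# short reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShortReadSimConfig:
    """Illumina-like short-read simulation (substitution errors only).

    ``depth`` is per haploid copy: a diploid autosome receives 2*depth total.
    ``mode='tiling'`` replaces random sampling with a deterministic tiling of
    each haplotype at stride read_len//2, every tile emitted twice — this
    guarantees each genomic k-mer (k <= read_len//2 + 1) is covered at least
    twice, the regime the presence rule assumes in the error-free limit.
    """

    depth: float = 5.0
    read_len: int = 150
    error_rate: float = 0.009
    mode: Literal["random", "tiling"] = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0,1]")
        if self.depth < 0 or self.read_len < 1:
            raise ValueError("depth and read_len must be positive")


@dataclass
class ShortReadSet:
    """Simulated short reads, packed as sentinel-separated base codes."""

    packed: np.ndarray
    n_reads: int
    read_len: int
    source_label: str = ""

    @property
    def total_bases(self) -> int:
        return self.n_reads * self.read_len

    def records(self) -> Iterator[tuple[str, str]]:
        l = self.read_len
        for i in range(self.n_reads):
            chunk = self.packed[i * (l + 1) : i * (l + 1) + l]
            yield f"{self.source_label}_r{i}", codes_to_str(chunk)


def _read_matrix_to_packed(mat: np.ndarray) -> np.ndarray:
    out = np.full((mat.shape[0], mat.shape[1] + 1), SENTINEL, dtype=np.uint8)
    out[:, :-1] = mat
    return out.ravel()


def simulate_short_reads(individual: Individual, cfg: ShortReadSimConfig) -> ShortReadSet:
    """Draw short reads uniformly over the individual's haplotypes.

    Read counts per haplotype are Poisson(depth * hap_len / read_len) in
    random mode; substitution errors are applied per base at
    ``cfg.error_rate``.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    l = cfg.read_len
    mats: list[np.ndarray] = []
    n_total = 0
    for _, hap in individual.haplotypes:
        if len(hap) < l:
            continue
        if cfg.mode == "tiling":
            stride = max(1, l // 2)
            starts = np.arange(0, len(hap) - l + 1, stride)
            if starts[-1] != len(hap) - l:
                starts = np.append(starts, len(hap) - l)
            starts = np.repeat(starts, 2)  # every tile twice -> min coverage 2
        else:
            n = rng.poisson(cfg.depth * len(hap) / l)
            starts = rng.integers(0, len(hap) - l + 1, n)
        if len(starts) == 0:
            continue
        mat = hap[starts[:, None] + np.arange(l)]
        if cfg.error_rate > 0:
            mask = rng.random(mat.shape) < cfg.error_rate
            nerr = int(mask.sum())
            if nerr:
                mat[mask] = (mat[mask] + rng.integers(1, 4, nerr, dtype=np.uint8)) % 4
        mats.append(mat)
        n_total += len(starts)
    if not mats:
        return ShortReadSet(np.empty(0, dtype=np.uint8), 0, l, individual.label)
    packed = np.concatenate([_read_matrix_to_packed(m) for m in mats])
    return ShortReadSet(packed, n_total, l, individual.label)


def simulate_population(
    truth: SyntheticTruth,
    n_males: int,
    n_females: int,
    het_rate: float,
    cfg: ShortReadSimConfig,
    master_seed: int = 0,
    het_model: Literal["shared", "private"] = "shared",
) -> Iterator[tuple[Individual, ShortReadSet]]:
    """Yield (individual, reads) per member.

    The default heterozygosity model is shared population polymorphism
    (:func:`sample_population_variants`); ``het_model='private'`` reverts to
    independent per-individual mutations.  Every individual gets a distinct
    seed derived from the master seed by counter.
    """
    variants = None
    if het_model == "shared" and het_rate > 0:
        vseed = int(np.random.SeedSequence([master_seed, 990]).generate_state(1)[0] % (2**31))
        variants = sample_population_variants(truth, het_rate, vseed)
    counter = 0
    for sex, n in (("male", n_males), ("female", n_females)):
        for i in range(n):
            seed_pair = np.random.SeedSequence([master_seed, counter])
            s_ind, s_reads = (int(s) % (2**31) for s in seed_pair.generate_state(2))
            ind = derive_individual(truth, het_rate, sex, s_ind, label=f"{sex}{i}",
                                    variants=variants)
            reads = simulate_short_reads(ind, replace(cfg, seed=s_reads))
            counter += 1
            yield ind, reads


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LongReadSimConfig:
    """Long-read simulation with technology presets.

    ``depth`` is per haploid copy (autosomes at copy number 2 get twice the
    base yield).  Lengths are Gaussian, truncated below at ``length_min`` and
    above at the chromosome length.
    """

    depth: float = 25.0
    preset: str = "hifi"
    sub_rate: float | None = None
    ins_rate: float | None = None
    del_rate: float | None = None
    length_mean: int | None = None
    length_sd: int | None = None
    length_min: int = 500
    copy_number: tuple[tuple[str, int], ...] = (("autosome", 2), ("X", 1), ("Y", 1))
    seed: int = 0

    def rates(self) -> tuple[float, float, float, int, int]:
        base = LONG_READ_PRESETS[self.preset]
        return (
            self.sub_rate if self.sub_rate is not None else base[0],
            self.ins_rate if self.ins_rate is not None else base[1],
            self.del_rate if self.del_rate is not None else base[2],
            self.length_mean if self.length_mean is not None else base[3],
            self.length_sd if self.length_sd is not None else base[4],
        )

    def __post_init__(self) -> None:
        if self.preset not in LONG_READ_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; options {sorted(LONG_READ_PRESETS)}")
        sub, ins, dele, mean, sd = self.rates()
        if not all(0.0 <= v <= 1.0 for v in (sub, ins, dele)):
            raise ValueError("error rates must be in [0,1]")
        if mean < self.length_min or sd < 0:
            raise ValueError("invalid length distribution")


@dataclass
class LongReadSet:
    """Simulated long reads with per-read chromosome-of-origin truth."""

    ids: list[str]
    seqs: list[np.ndarray]
    origins: pd.DataFrame  # read_id, chrom, start, ref_len, y_nonpar_frac

    def __len__(self) -> int:
        return len(self.ids)

    def records(self) -> Iterator[tuple[str, str]]:
        for rid, codes in zip(self.ids, self.seqs):
            yield rid, codes_to_str(codes)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(zip(self.ids, self.seqs))


def _apply_long_read_errors(
    seq: np.ndarray, sub: float, ins: float, dele: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitutions, then per-base insertions (after a base) and deletions."""
    out = seq
    if sub > 0:
        out = _mutate(out, sub, rng)
    if ins <= 0 and dele <= 0:
        return out.copy() if out is seq else out
    u = rng.random(len(out))
    rep = np.ones(len(out), dtype=np.int64)
    rep[u < dele] = 0
    ins_mask = (u >= dele) & (u < dele + ins)  # a base is not both deleted and duplicated
    rep[ins_mask] = 2
    res = np.repeat(out, rep)
    if ins_mask.any():
        end_pos = np.cumsum(rep) - 1
        dup_pos = end_pos[ins_mask]
        res[dup_pos] = rng.integers(0, 4, len(dup_pos), dtype=np.uint8)
    return res


def simulate_long_reads(truth: SyntheticTruth, cfg: LongReadSimConfig) -> LongReadSet:
    """Sample long reads proportional to chromosome length x copy number.

    Each read id encodes its origin; the origins table additionally records
    the reference interval and, for Y reads, the fraction of bases outside
    the PAR.
    """
    sub, ins, dele, mean, sd = cfg.rates()
    rng = np.random.default_rng(cfg.seed)
    ids: list[str] = []
    seqs: list[np.ndarray] = []
    rows: list[tuple] = []
    idx = 0
    for chrom, copies in cfg.copy_number:
        source = truth.chroms.get(chrom)
        if source is None or len(source) == 0 or copies == 0:
            continue
        target = cfg.depth * len(source) * copies
        yielded = 0.0
        while yielded < target:
            length = int(np.clip(rng.normal(mean, sd), cfg.length_min, len(source)))
            start = int(rng.integers(0, len(source) - length + 1))
            read = _apply_long_read_errors(source[start : start + length], sub, ins, dele, rng)
            frac = truth.y_nonpar_fraction(start, length) if chrom == "Y" else 0.0
            rid = f"lr{idx}_{chrom}"
            ids.append(rid)
            seqs.append(read)
            rows.append((rid, chrom, start, length, frac))
            yielded += length
            idx += 1
    origins = pd.DataFrame(rows, columns=["read_id", "chrom", "start", "ref_len", "y_nonpar_frac"])
    return LongReadSet(ids, seqs, origins)
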