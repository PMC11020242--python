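"""Scoring against ground truth and the population / marker-precision sweeps.

The two experiment runners mirror the method's validation design: a
population sweep (marker F1 as a function of individuals per sex and of
population heterozygosity) and a precision sweep (long-read-sorting F1 as
the marker set is deliberately degraded with autosome/X decoy k-mers down to
a target precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kmers import KmerSpec, count_kmers, presence_set
from .markers import MarkerSet, select_male_specific
from .simulate import (
    GenomeConfig,
    LongReadSimConfig,
    ShortReadSimConfig,
    SyntheticTruth,
    generate_genome,
    simulate_long_reads,
    simulate_population,
)
from .sorting import DEFAULT_DENSITY_PER_KB, sort_reads


@dataclass
class EvalReport:
    """Precision/recall/F1 with the underlying confusion counts."""

    tp: int
    fp: int
    fn: int
    context: str = ""

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _as_keys(obj) -> np.ndarray:
    if isinstance(obj, MarkerSet):
        return obj.keys
    return np.asarray(obj)


def eval_marker_set(predicted, truth, context: str = "markers") -> EvalReport:
    """Compare a predicted marker set with the truth set (both as sorted key
    arrays or MarkerSets of the same k)."""
    p = np.unique(_as_keys(predicted))
    t = np.unique(_as_keys(truth))
    tp = len(np.intersect1d(p, t, assume_unique=True))
    return EvalReport(tp=tp, fp=len(p) - tp, fn=len(t) - tp, context=context)


def eval_read_partition(
    scores: pd.DataFrame,
    origins: pd.DataFrame,
    target: str = "Y",
    min_nonpar_frac: float = 0.5,
    boundary: str = "majority",
) -> EvalReport:
    """Per-read precision/recall of the selected partition vs origin truth.

    A read counts as target-origin when it comes from the target chromosome
    and (for Y) at least ``min_nonpar_frac`` of its bases lie outside the
    PAR — reads dominated by PAR sequence carry no specific markers by
    construction and should not be scored as misses.  ``boundary='exclude'``
    instead drops reads whose non-PAR fraction is strictly between 0 and 1
    (used for exact-recovery checks where boundary reads are ill-defined).
    """
    merged = scores.merge(origins, on="read_id", how="left", validate="one_to_one")
    missing = merged.loc[merged["chrom"].isna(), "read_id"].tolist()
    if missing:
        raise ValueError(f"reads without origin labels: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    if boundary == "exclude":
        # keep non-target reads and target reads fully outside the PAR; a
        # read partly or wholly inside the PAR is neither clean target nor
        # clean background and is dropped from scoring
        if target == "Y":
            drop = (merged["chrom"] == target) & (merged["y_nonpar_frac"] < 1.0)
            merged = merged[~drop]
        is_target = merged["chrom"] == target
    elif boundary == "majority":
        is_target = merged["chrom"] == target
        if target == "Y":
            is_target &= merged["y_nonpar_frac"] >= min_nonpar_frac
    else:
        raise ValueError(f"unknown boundary policy {boundary!r}")
    sel = merged["selected"].to_numpy(bool)
    tgt = is_target.to_numpy(bool)
    tp = int((sel & tgt).sum())
    fp = int((sel & ~tgt).sum())
    fn = int((~sel & tgt).sum())
    return EvalReport(tp=tp, fp=fp, fn=fn, context="reads")


def degrade_marker_precision(
    markers: MarkerSet,
    target_precision: float,
    decoy_pool: np.ndarray,
    seed: int = 0,
) -> tuple[MarkerSet, int]:
    """Spike decoy (non-target-chromosome) k-mers into a marker set.

    Adds ceil(|true| * (1-pi)/pi) decoys sampled without replacement from
    ``decoy_pool`` (k-mers of the other chromosomes, truth excluded) so the
    resulting precision is ~pi.  Returns the degraded set and the decoy
    count; the caller can convert the count into a genomic decoy density.
    """
    if not 0.0 < target_precision <= 1.0:
        raise ValueError(f"target_precision must be in (0,1], got {target_precision}")
    if target_precision == 1.0:
        return markers, 0
    pool = np.setdiff1d(np.asarray(decoy_pool), markers.keys)
    # guard the ceiling against float fuzz when the ratio is a whole number
    n_decoys = math.ceil(len(markers) * (1.0 - target_precision) / target_precision - 1e-9)
    if n_decoys > len(pool):
        raise ValueError(f"decoy pool too small: need {n_decoys}, have {len(pool)}")
    rng = np.random.default_rng(seed)
    decoys = rng.choice(pool, size=n_decoys, replace=False)
    keys = np.union1d(markers.keys, decoys)
    out = MarkerSet(
        markers.spec,
        keys,
        n_males=markers.n_males,
        n_females=markers.n_females,
        m_threshold=markers.m_threshold,
        depth_band=markers.depth_band,
    )
    return out, n_decoys


# ---------------------------------------------------------------------------
# end-to-end helpers and sweeps
# ---------------------------------------------------------------------------

def identify_markers(
    truth: SyntheticTruth,
    n_males: int,
    n_females: int,
    het_rate: float,
    spec: KmerSpec,
    sr_cfg: ShortReadSimConfig | None = None,
    master_seed: int = 0,
    min_count: int = 2,
) -> MarkerSet:
    """Simulate a population and run the count -> presence -> select pipeline."""
    sr_cfg = sr_cfg or ShortReadSimConfig()
    males, females = [], []
    for ind, reads in simulate_population(truth, n_males, n_females, het_rate, sr_cfg, master_seed):
        table = count_kmers(reads.packed, spec, source_label=ind.label)
        (males if ind.sex == "male" else females).append(presence_set(table, min_count))
    return select_male_specific(males, females)


#: genome used by the sweep experiments: small enough that a replicated grid
#: runs in minutes, large enough for stable F1 statistics (~28k Y k-mers)
SWEEP_GENOME = GenomeConfig(autosome_len=300_000, x_len=100_000, y_len=30_000, par_len=5_000)


def run_population_sweep(
    n_values: Sequence[int],
    het_values: Sequence[float],
    genome: GenomeConfig = SWEEP_GENOME,
    sr_cfg: ShortReadSimConfig | None = None,
    spec: KmerSpec | None = None,
    replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Marker-identification F1 over a (n individuals, heterozygosity) grid.

    Each replicate regenerates the genome and population with a distinct
    counter-derived seed.  Returns one row per (n, h, replicate).
    """
    spec = spec or KmerSpec(21)
    sr_cfg = sr_cfg or ShortReadSimConfig()
    rows = []
    for n in n_values:
        for h in het_values:
            for rep in range(replicates):
                gseed = int(np.random.SeedSequence([seed, n, int(h * 1e6), rep]).generate_state(1)[0] % (2**31))
                truth = generate_genome(replace(genome, seed=gseed))
                msk = identify_markers(truth, n, n, h, spec, sr_cfg, master_seed=gseed + 1)
                rep_eval = eval_marker_set(msk, truth.true_specific_kmers(spec))
                rows.append(
                    dict(n=n, h=h, replicate=rep, precision=rep_eval.precision,
                         recall=rep_eval.recall, f1=rep_eval.f1)
                )
    return pd.DataFrame(rows)


def run_precision_sweep(
    precisions: Sequence[float],
    presets: Sequence[str] = ("hifi",),
    genome: GenomeConfig | None = None,
    lr_cfg: LongReadSimConfig | None = None,
    spec: KmerSpec | None = None,
    threshold_per_kb: float = DEFAULT_DENSITY_PER_KB,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Read-sorting F1 as marker precision is degraded, per technology preset.

    Uses the exact truth marker set as the precision-1.0 baseline, spikes in
    autosome/X decoys to each target precision, simulates long reads, and
    sorts at the density threshold.  Also reports the decoy density per kb
    of autosome+X sequence.
    """
    spec = spec or KmerSpec(21)
    genome = genome or GenomeConfig()
    lr_cfg = lr_cfg or LongReadSimConfig()
    rows = []
    for rep in range(replicates):
        gseed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
        truth = generate_genome(replace(genome, seed=gseed))
        base = MarkerSet(spec, truth.true_specific_kmers(spec))
        pool = truth.autosome_x_kmers(spec)
        ax_len = genome.autosome_len + genome.x_len
        for preset in presets:
            reads = simulate_long_reads(truth, replace(lr_cfg, preset=preset, seed=gseed + 7))
            for pi in precisions:
                msk, n_decoys = degrade_marker_precision(base, pi, pool, seed=gseed + 13)
                res = sort_reads(reads.items(), msk, threshold_per_kb=threshold_per_kb)
                rep_eval = eval_read_partition(res.scores, reads.origins)
                rows.append(
                    dict(precision_target=pi, preset=preset, replicate=rep,
                         n_reads=len(reads), n_markers=len(msk), n_decoys=n_decoys,
                         decoy_density_per_kb=n_decoys * 1000.0 / ax_len,
                         read_precision=rep_eval.precision, read_recall=rep_eval.recall,
                         f1=rep_eval.f1)
                )
    return pd.DataFrame(rows)
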