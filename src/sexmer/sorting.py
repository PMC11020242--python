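"""Density-based sorting of long reads and contigs with marker k-mers.

A read is scored by the number of k-positions whose canonical k-mer belongs
to the marker set; density is hits per kilobase of read length.  Reads at or
above the density threshold (default 7 markers/kb, the genome-wide average
marker density on the human Y) are classified as coming from the sex-limited
chromosome.  Equality at the threshold selects: only *lower* density is
filtered out.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import io as seqio
from .kmers import KmerSpec, seq_to_codes, window_keys, SENTINEL
from .markers import MarkerSet

log = logging.getLogger(__name__)

DEFAULT_DENSITY_PER_KB = 7.0

SCORE_COLUMNS = ["read_id", "length", "msk_hits", "density_per_kb", "selected"]


@dataclass
class ReadScore:
    read_id: str
    length: int
    msk_hits: int
    density: float  # markers per kb
    selected: bool


_PREFILTER_BITS = 24


class _MarkerIndex:
    """Sorted marker keys plus a low-bits occupancy table that cheaply
    rejects the vast majority of non-marker windows before binary search."""

    def __init__(self, sorted_keys: np.ndarray):
        self.keys = sorted_keys
        self.prefilter = None
        if sorted_keys.dtype == np.uint64 and len(sorted_keys):
            mask = np.uint64((1 << _PREFILTER_BITS) - 1)
            table = np.zeros(1 << _PREFILTER_BITS, dtype=bool)
            table[(sorted_keys & mask).astype(np.int64)] = True
            self.prefilter = table
            self.mask = mask

    def membership(self, keys: np.ndarray) -> np.ndarray:
        if len(self.keys) == 0 or len(keys) == 0:
            return np.zeros(len(keys), dtype=bool)
        if self.prefilter is not None:
            cand = self.prefilter[(keys & self.mask).astype(np.int64)]
            out = np.zeros(len(keys), dtype=bool)
            idx = np.flatnonzero(cand)
            if len(idx):
                sub = keys[idx]
                pos = np.minimum(np.searchsorted(self.keys, sub), len(self.keys) - 1)
                out[idx] = self.keys[pos] == sub
            return out
        pos = np.minimum(np.searchsorted(self.keys, keys), len(self.keys) - 1)
        return self.keys[pos] == keys


def _membership(keys: np.ndarray, sorted_marker_keys: np.ndarray) -> np.ndarray:
    return _MarkerIndex(sorted_marker_keys).membership(keys)


def scan_sequence(
    seq: str | np.ndarray,
    markers: MarkerSet,
    read_id: str = "",
    threshold_per_kb: float = DEFAULT_DENSITY_PER_KB,
    min_hits: int = 1,
    distinct: bool = False,
) -> ReadScore:
    """Score one sequence: marker-hit positions, density/kb, selection flag.

    ``distinct=True`` counts distinct marker k-mers instead of hit positions.
    Sequences shorter than k score zero and are never selected.
    """
    codes = seq_to_codes(seq) if isinstance(seq, (str, bytes)) else seq
    length = len(codes)
    if length < markers.spec.k:
        return ReadScore(read_id, length, 0, 0.0, False)
    keys, valid = window_keys(codes, markers.spec, return_mask=True)
    hit = _membership(keys, markers.keys) & valid
    if distinct:
        hits = len(np.unique(keys[hit]))
    else:
        hits = int(hit.sum())
    density = hits * 1000.0 / length if length else 0.0
    selected = density >= threshold_per_kb and hits >= min_hits
    return ReadScore(read_id, length, hits, density, selected)


def _score_batch(
    ids: Sequence[str],
    code_list: Sequence[np.ndarray],
    markers: MarkerSet,
    threshold_per_kb: float,
    min_hits: int,
    distinct: bool,
    index: "_MarkerIndex | None" = None,
) -> pd.DataFrame:
    k = markers.spec.k
    if index is None:
        index = _MarkerIndex(markers.keys)
    lengths = np.array([len(c) for c in code_list], dtype=np.int64)
    sep = np.array([SENTINEL], dtype=np.uint8)
    packed = np.concatenate([x for c in code_list for x in (c, sep)]) if code_list else sep[:0]
    hits = np.zeros(len(code_list), dtype=np.int64)
    if len(packed) >= k:
        keys, valid = window_keys(packed, markers.spec, return_mask=True, lazy_mask=True)
        offsets = np.concatenate(([0], np.cumsum(lengths + 1)))[:-1]
        # hits are sparse: work on hit positions, validating each against the
        # (also sparse) non-ACGT positions instead of building full masks
        hit_pos = np.flatnonzero(index.membership(keys))
        if valid is None:
            inv_pos = np.flatnonzero(packed > 3)
            n_inv = np.searchsorted(inv_pos, hit_pos + k, side="left") - np.searchsorted(
                inv_pos, hit_pos, side="left"
            )
            hit_pos = hit_pos[n_inv == 0]
        else:
            hit_pos = hit_pos[valid[hit_pos]]
        read_of_hit = np.searchsorted(offsets, hit_pos, side="right") - 1
        # windows that straddle a read's trailing sentinel are already gone
        if distinct:
            for i in np.unique(read_of_hit):
                hits[i] = len(np.unique(keys[hit_pos[read_of_hit == i]]))
        else:
            hits = np.bincount(read_of_hit, minlength=len(code_list)).astype(np.int64)
    density = np.where(lengths > 0, hits * 1000.0 / np.maximum(lengths, 1), 0.0)
    selected = (density >= threshold_per_kb) & (hits >= min_hits)
    return pd.DataFrame(
        {
            "read_id": list(ids),
            "length": lengths,
            "msk_hits": hits,
            "density_per_kb": density,
            "selected": selected,
        }
    )


def score_reads(
    reads: Iterable[tuple[str, str | np.ndarray]],
    markers: MarkerSet,
    threshold_per_kb: float = DEFAULT_DENSITY_PER_KB,
    min_hits: int = 1,
    distinct: bool = False,
    batch_bases: int = 8_000_000,
) -> pd.DataFrame:
    """Score a stream of (id, sequence) records; one row per input read."""
    index = _MarkerIndex(markers.keys)
    frames: list[pd.DataFrame] = []
    ids: list[str] = []
    codes: list[np.ndarray] = []
    nbases = 0
    for rid, seq in reads:
        c = seq_to_codes(seq) if isinstance(seq, (str, bytes)) else seq
        ids.append(rid)
        codes.append(c)
        nbases += len(c)
        if nbases >= batch_bases:
            frames.append(_score_batch(ids, codes, markers, threshold_per_kb, min_hits, distinct, index))
            ids, codes, nbases = [], [], 0
    if ids or not frames:
        frames.append(_score_batch(ids, codes, markers, threshold_per_kb, min_hits, distinct, index))
    return pd.concat(frames, ignore_index=True)


@dataclass
class SortResult:
    scores: pd.DataFrame

    @property
    def selected_ids(self) -> list[str]:
        return self.scores.loc[self.scores["selected"], "read_id"].tolist()

    @property
    def rejected_ids(self) -> list[str]:
        return self.scores.loc[~self.scores["selected"], "read_id"].tolist()


def sort_reads(
    reads: Iterable[tuple[str, str | np.ndarray]],
    markers: MarkerSet,
    threshold_per_kb: float = DEFAULT_DENSITY_PER_KB,
    min_hits: int = 1,
    distinct: bool = False,
) -> SortResult:
    """Partition reads into selected (>= threshold density) and rejected.

    The partition is exhaustive and disjoint; the scores table carries one
    row per input read in input order.
    """
    if threshold_per_kb < 0:
        raise ValueError("threshold_per_kb must be >= 0")
    return SortResult(score_reads(reads, markers, threshold_per_kb, min_hits, distinct))


# contigs obey the identical contract; the alias exists because callers deal
# with assemblies, not read sets
sort_contigs = sort_reads


def sort_reads_file(
    in_path,
    markers: MarkerSet,
    out_dir,
    threshold_per_kb: float = DEFAULT_DENSITY_PER_KB,
    min_hits: int = 1,
    distinct: bool = False,
) -> SortResult:
    """File-level sorter: writes selected/rejected files mirroring the input
    format (records verbatim) plus a scores TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = seqio.sniff_format(in_path)
    ext = "fq" if fmt == "fastq" else "fa"

    records: list[tuple] = []
    skipped = 0

    def stream():
        nonlocal skipped
        from Bio import SeqIO

        with seqio.open_text(in_path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                try:
                    seq = str(rec.seq)
                except Exception:  # pragma: no cover - malformed record
                    skipped += 1
                    log.warning("skipping unreadable record after %d reads", len(records))
                    continue
                qual = None
                if fmt == "fastq":
                    q = rec.letter_annotations.get("phred_quality")
                    qual = "".join(chr(v + 33) for v in q) if q else "I" * len(seq)
                records.append((rec.id, seq, qual))
                yield rec.id, seq

    result = sort_reads(stream(), markers, threshold_per_kb, min_hits, distinct)
    sel = set(result.selected_ids)

    def emit(path, keep: bool):
        recs = [r for r in records if (r[0] in sel) == keep]
        if fmt == "fastq":
            seqio.write_fastq([(i, s, q) for i, s, q in recs], path)
        else:
            seqio.write_fasta([(i, s) for i, s, _ in recs], path)

    emit(out_dir / f"selected.{ext}", True)
    emit(out_dir / f"rejected.{ext}", False)
    result.scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
    if skipped:
        log.warning("%d unreadable records skipped", skipped)
    return result


def estimate_density_threshold(
    markers: MarkerSet,
    y_reference: str | np.ndarray | None = None,
    default: float = DEFAULT_DENSITY_PER_KB,
) -> float:
    """Marker density threshold, from a sex-limited reference when available.

    With a reference sequence (string, code array, or FASTA path) the
    genome-wide average marker density (hit positions x 1000 / length) is
    returned; without one the human-Y default of 7/kb applies.  References
    under 10 kb make the average unstable and are rejected.
    """
    if y_reference is None:
        return float(default)
    seq = y_reference
    if isinstance(y_reference, (str, Path)):
        try:
            if Path(str(y_reference)).exists():
                seq = "".join(s for _, s in seqio.read_seqs(y_reference))
        except OSError:  # a raw sequence string, not a path
            pass
    codes = seq_to_codes(seq) if isinstance(seq, (str, bytes)) else seq
    if len(codes) < 10_000:
        raise ValueError(f"reference too short for a stable estimate: {len(codes)} < 10000 bases")
    score = scan_sequence(codes, markers, threshold_per_kb=0.0, min_hits=0)
    if score.msk_hits == 0:
        warnings.warn("no marker hits on the reference; returning density 0.0", stacklevel=2)
    return score.density
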