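"""Selection of sex-limited-chromosome–specific k-mer markers.

A k-mer is a male-specific k-mer (MSK) when it is present (count >= 2) in at
least ``m`` of the ``n`` male individuals and in none of the female
individuals.  The critical value is m = 2n/3, rounded to the nearest
integer.  In a ZW system the caller swaps the group labels (females carry
the sex-limited W); the code is sex-symmetric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .kmers import (
    KmerCountTable,
    KmerSpec,
    PresenceSet,
    _empty_keys,
    keys_to_strings,
    string_to_key,
    strings_to_keys,
)

Rule = Literal["round", "ceil", "floor"]


@dataclass
class PopulationGroup:
    """One sex's individuals, as presence sets sharing a KmerSpec."""

    label: str
    members: Sequence[PresenceSet]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.label!r} has no members")
        specs = {m.spec.k for m in self.members}
        if len(specs) != 1:
            raise ValueError(f"group {self.label!r} mixes k values {sorted(specs)}")

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def spec(self) -> KmerSpec:
        return self.members[0].spec


@dataclass
class MarkerSet:
    """An MSK set with its selection provenance."""

    spec: KmerSpec
    keys: np.ndarray  # sorted canonical keys
    n_males: int = 0
    n_females: int = 0
    m_threshold: int = 0
    depth_band: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, kmer: str) -> bool:
        key = string_to_key(kmer, self.spec)
        i = np.searchsorted(self.keys, key)
        return bool(i < len(self.keys) and self.keys[i] == key)

    def to_strings(self) -> list[str]:
        return keys_to_strings(self.keys, self.spec)

    @classmethod
    def from_strings(cls, kmers, spec: KmerSpec, **meta) -> "MarkerSet":
        keys = np.unique(strings_to_keys(list(kmers), spec)) if kmers else _empty_keys(spec)
        return cls(spec, keys, **meta)


def male_presence_threshold(n: int, rule: Rule = "round") -> int:
    """Minimum number of carrier males, m = 2n/3 under the given rounding rule.

    The default is nearest-integer (half away from zero), clamped to [1, n].
    """
    if n < 1:
        raise ValueError(f"need at least one male individual, got n={n}")
    x = 2.0 * n / 3.0
    if rule == "round":
        m = int(np.floor(x + 0.5))
    elif rule == "ceil":
        m = int(np.ceil(x))
    elif rule == "floor":
        m = int(np.floor(x))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return max(1, min(n, m))


def _occurrence_counts(members: Sequence[PresenceSet]) -> tuple[np.ndarray, np.ndarray]:
    """Unique keys across members and the number of members carrying each."""
    allkeys = np.concatenate([m.keys for m in members])
    if len(allkeys) == 0:
        return allkeys, np.empty(0, dtype=np.int64)
    keys, counts = np.unique(allkeys, return_counts=True)
    return keys, counts.astype(np.int64)


def select_male_specific(
    males: PopulationGroup | Sequence[PresenceSet],
    females: PopulationGroup | Sequence[PresenceSet],
    rule: Rule = "round",
    depth_band: tuple[float, float] | None = None,
    pooled_male_counts: KmerCountTable | None = None,
) -> MarkerSet:
    """Select k-mers present in >= m males and in no female.

    ``depth_band`` optionally intersects the result with the pooled-male-depth
    window (see :func:`depth_band_filter`); it is off by default because the
    core selection is purely presence/absence.
    """
    if not isinstance(males, PopulationGroup):
        males = PopulationGroup("male", list(males))
    if not isinstance(females, PopulationGroup):
        females = PopulationGroup("female", list(females))
    if males.spec.k != females.spec.k:
        raise ValueError(f"k mismatch between groups: {males.spec.k} vs {females.spec.k}")
    m = male_presence_threshold(males.n, rule)

    keys, occ = _occurrence_counts(males.members)
    candidates = keys[occ >= m]
    female_union = (
        np.unique(np.concatenate([f.keys for f in females.members]))
        if females.members
        else candidates[:0]
    )
    if len(female_union) and len(candidates):
        pos = np.searchsorted(female_union, candidates)
        pos = np.minimum(pos, len(female_union) - 1)
        in_female = female_union[pos] == candidates
        candidates = candidates[~in_female]

    if depth_band is not None:
        if pooled_male_counts is None:
            raise ValueError("depth_band requires pooled_male_counts")
        band_keys = depth_band_filter(pooled_male_counts, 1.0, depth_band)
        candidates = np.intersect1d(candidates, band_keys, assume_unique=True)

    return MarkerSet(
        males.spec,
        candidates,
        n_males=males.n,
        n_females=females.n,
        m_threshold=m,
        depth_band=depth_band,
    )


def depth_band_filter(
    pooled_male_counts: KmerCountTable,
    expected_haploid_depth: float,
    band: tuple[float, float] = (0.5, 1.5),
) -> np.ndarray:
    """k-mers whose pooled male count lies in [lo*E, hi*E].

    E is the expected haploid pooled depth (n*d/2 for a male WGS pool): a
    single-copy Y k-mer sits near E while a diploid autosomal k-mer sits near
    2E, so a band around E enriches for sex-limited sequence.
    """
    if expected_haploid_depth <= 0:
        raise ValueError("expected_haploid_depth must be positive")
    lo = band[0] * expected_haploid_depth
    hi = band[1] * expected_haploid_depth
    mask = (pooled_male_counts.counts >= lo) & (pooled_male_counts.counts <= hi)
    return pooled_male_counts.keys[mask]


# ---------------------------------------------------------------------------
# marker file I/O
# ---------------------------------------------------------------------------

def write_markers(markers: MarkerSet, path, sidecar: bool = True) -> None:
    """One canonical k-mer per line, plus a JSON provenance sidecar."""
    from .kmers import _open_text

    with _open_text(path, "w") as fh:
        fh.writelines(s + "\n" for s in markers.to_strings())
    if sidecar:
        meta = {
            "k": markers.spec.k,
            "n_males": markers.n_males,
            "n_females": markers.n_females,
            "m_threshold": markers.m_threshold,
            "depth_band": markers.depth_band,
            "n_markers": len(markers),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def read_markers(path, spec: KmerSpec | None = None) -> MarkerSet:
    from .kmers import _open_text

    kmers: list[str] = []
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip().upper()
            if not s:
                continue
            if any(c not in "ACGT" for c in s):
                raise ValueError(f"{path}: line {lineno}: non-ACGT marker")
            kmers.append(s)
    meta: dict = {}
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    if spec is None:
        k = meta.get("k") or (len(kmers[0]) if kmers else None)
        if k is None:
            raise ValueError(f"{path}: empty marker file and no KmerSpec given")
        spec = KmerSpec(int(k))
    ms = MarkerSet.from_strings(kmers, spec)
    ms.n_males = int(meta.get("n_males", 0))
    ms.n_females = int(meta.get("n_females", 0))
    ms.m_threshold = int(meta.get("m_threshold", 0))
    db = meta.get("depth_band")
    ms.depth_band = tuple(db) if db else None
    return ms
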