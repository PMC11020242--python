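"""Canonical k-mer extraction, exact per-individual counting, presence calls and table I/O.

k-mers are represented internally by *keys*: for k <= 31 a 2-bit packed
``uint64`` (A=0, C=1, G=2, T=3, most significant bits first), for larger k a
fixed-width byte string.  In both representations the numeric/lexicographic
order of keys equals the lexicographic order of the k-mer strings, so sorted
key arrays double as lexicographically sorted marker lists and set algebra
reduces to ``numpy`` merge operations.

The canonical form of a k-mer is the lexicographically smaller of the k-mer
and its reverse complement, matching the convention of standard k-mer
counters (KMC, jellyfish) so their dump files interoperate with ours.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

# ASCII -> 2-bit base code; anything not in ACGTacgt maps to the invalid
# marker 255 and poisons every window that covers it.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)

#: base code used to separate concatenated reads; invalid on purpose
SENTINEL = np.uint8(255)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string as a uint8 array of 2-bit base codes (255 = invalid)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_str(codes: np.ndarray) -> str:
    if np.any(codes > 3):
        raise ValueError("cannot decode: array contains invalid base codes")
    return _CHAR[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class KmerSpec:
    """k-mer length contract.

    ``k`` must be odd so that no k-mer is its own reverse complement and the
    canonical form is unambiguous.  The supported range is 3-63 (3 only to
    keep toy examples tractable; 21 and 51 are the working defaults).
    """

    k: int = 21

    def __post_init__(self) -> None:
        if not (3 <= self.k <= 63):
            raise ValueError(f"k must be in [3, 63], got {self.k}")
        if self.k % 2 == 0:
            raise ValueError(f"k must be odd, got {self.k}")

    @property
    def packed(self) -> bool:
        """True when k-mers fit a 2-bit packed uint64."""
        return self.k <= 31


def canonical_kmer(seq: str) -> str:
    """Canonical (strand-independent) form of a single k-length k-mer.

    Returns the lexicographically smaller of ``seq`` and its reverse
    complement, uppercased.  Raises ``ValueError`` on non-ACGT characters so
    the caller can decide to skip the window.
    """
    s = seq.upper()
    if any(c not in "ACGT" for c in s):
        raise ValueError(f"non-ACGT character in k-mer {seq!r}")
    rc = reverse_complement(s)
    return s if s <= rc else rc


# ---------------------------------------------------------------------------
# vectorised window extraction
# ---------------------------------------------------------------------------

def _window_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over the len-k+1 windows: True iff all k bases are ACGT."""
    invalid = (codes > 3).astype(np.int32)
    csum = np.concatenate(([0], np.cumsum(invalid)))
    return (csum[k:] - csum[:-k]) == 0


def _pack_windows_u64(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement packed codes for every window (k <= 31)."""
    n = len(codes) - k + 1
    b = (codes & 3).astype(np.uint64)  # invalid bases masked; validity handled separately
    two = np.uint64(2)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        np.left_shift(fwd, two, out=fwd)
        np.bitwise_or(fwd, b[j : j + n], out=fwd)
    return fwd, revcomp_keys_u64(fwd, k)


_numba_kernel = None
_numba_failed = False


def _get_numba_kernel():
    """Rolling-hash canonical packer, JIT-compiled on first use.

    Maintains the forward key and the reverse-complement key of the current
    window simultaneously (one base enters the forward key at the low end
    and its complement enters the reverse key at the high end), so the whole
    scan is a single O(n) pass.
    """
    global _numba_kernel, _numba_failed
    if _numba_kernel is None and not _numba_failed:
        try:
            import numba

            @numba.njit(cache=True)
            def kernel(b3: np.ndarray, k: int) -> np.ndarray:  # pragma: no cover - jitted
                n = b3.shape[0] - k + 1
                out = np.empty(n, np.uint64)
                mask = (np.uint64(1) << np.uint64(2 * k)) - np.uint64(1)
                top = np.uint64(2 * (k - 1))
                two = np.uint64(2)
                three = np.uint64(3)
                fwd = np.uint64(0)
                rc = np.uint64(0)
                for i in range(k - 1):
                    c = np.uint64(b3[i])
                    fwd = ((fwd << two) | c) & mask
                    rc = (rc >> two) | ((three ^ c) << top)
                for i in range(n):
                    c = np.uint64(b3[i + k - 1])
                    fwd = ((fwd << two) | c) & mask
                    rc = (rc >> two) | ((three ^ c) << top)
                    out[i] = fwd if fwd < rc else rc
                return out

            _numba_kernel = kernel
        except Exception:  # pragma: no cover - numba unavailable
            _numba_failed = True
    return _numba_kernel


_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def revcomp_keys_u64(keys: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement 2-bit packed k-mer keys.

    Complements every 2-bit base and reverses the 32 base slots of the word
    in O(log) swap passes, then shifts the payload back to the low bits.
    """
    y = ~keys
    y = ((y & _M2) << np.uint64(2)) | ((y >> np.uint64(2)) & _M2)
    y = ((y & _M4) << np.uint64(4)) | ((y >> np.uint64(4)) & _M4)
    y = y.byteswap()  # reverses the 8 byte slots, completing the 32-slot reversal
    return y >> np.uint64(64 - 2 * k)


def window_keys(codes: np.ndarray, spec: KmerSpec, return_mask: bool = False, lazy_mask: bool = False):
    """Canonical keys for every window of a code array.

    With ``return_mask=False`` only valid windows are returned (order
    preserved).  With ``return_mask=True`` returns ``(keys, valid)`` of length
    ``len(codes)-k+1`` where invalid windows carry garbage keys and must be
    masked by the caller — this variant keeps positional alignment for
    density scans.  ``lazy_mask=True`` additionally allows ``valid`` to be
    ``None`` when the caller prefers to re-derive validity from the sparse
    non-ACGT positions itself.
    """
    k = spec.k
    n = len(codes) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64 if spec.packed else f"S{k}")
        return (empty, np.empty(0, dtype=bool)) if return_mask else empty
    if spec.packed:
        kernel = _get_numba_kernel()
        if kernel is not None:
            keys = kernel(codes & 3, k)
        else:
            fwd, rev = _pack_windows_u64(codes, k)
            keys = np.minimum(fwd, rev)
        if return_mask and lazy_mask:
            return keys, None
        valid = _window_valid(codes, k)
    else:
        valid = _window_valid(codes, k)
        idx = np.flatnonzero(valid) if not return_mask else np.arange(n)
        win = (codes & 3)[idx[:, None] + np.arange(k)]
        fwd = _CHAR[win].view(f"S{k}").ravel()
        rev = _CHAR[3 - win[:, ::-1]].view(f"S{k}").ravel()
        keys_sub = np.where(fwd < rev, fwd, rev)
        if not return_mask:
            return keys_sub
        keys = keys_sub
        return keys, valid
    if return_mask:
        return keys, valid
    return keys[valid]


def keys_to_strings(keys: np.ndarray, spec: KmerSpec) -> list[str]:
    """Decode an array of keys back to uppercase k-mer strings."""
    if len(keys) == 0:
        return []
    if spec.packed:
        k = spec.k
        chars = np.empty((len(keys), k), dtype=np.uint8)
        for j in range(k):
            chars[:, j] = _CHAR[(keys >> np.uint64(2 * (k - 1 - j))) & np.uint64(3)]
        return [s.decode() for s in chars.view(f"S{k}").ravel()]
    return [s.decode() for s in keys]


def strings_to_keys(kmers: list[str] | np.ndarray, spec: KmerSpec) -> np.ndarray:
    """Canonical keys for many k-mer strings at once (vectorised).

    All inputs must be k-length ACGT strings (case-insensitive); raises
    ``ValueError`` naming the index of the first offender otherwise.
    """
    k = spec.k
    n = len(kmers)
    if n == 0:
        return _empty_keys(spec)
    if isinstance(kmers, np.ndarray):
        kmers = kmers.tolist()
    lens = np.fromiter(map(len, kmers), dtype=np.int64, count=n)
    if np.any(lens != k):
        bad = int(np.argmax(lens != k))
        raise ValueError(f"k-mer #{bad} has length {lens[bad]} != k={k}")
    joined = "".join(kmers)
    codes = _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)].reshape(n, k)
    if np.any(codes > 3):
        bad = int(np.argmax((codes > 3).any(axis=1)))
        raise ValueError(f"k-mer #{bad} contains non-ACGT characters")
    if spec.packed:
        fwd = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            np.left_shift(fwd, np.uint64(2), out=fwd)
            np.bitwise_or(fwd, codes[:, j].astype(np.uint64), out=fwd)
        return np.minimum(fwd, revcomp_keys_u64(fwd, k))
    fwd_s = _CHAR[codes].view(f"S{k}").ravel()
    rev_s = _CHAR[3 - codes[:, ::-1]].copy().view(f"S{k}").ravel()
    return np.where(fwd_s < rev_s, fwd_s, rev_s)


def string_to_key(kmer: str, spec: KmerSpec):
    """Key of the canonical form of one k-mer string."""
    can = canonical_kmer(kmer)
    if spec.packed:
        key = np.uint64(0)
        for c in can:
            key = (key << np.uint64(2)) | np.uint64("ACGT".index(c))
        return key
    return can.encode("ascii")


# ---------------------------------------------------------------------------
# count tables and presence sets
# ---------------------------------------------------------------------------

@dataclass
class KmerCountTable:
    """Exact canonical k-mer multiplicities for one individual's reads.

    ``keys`` is sorted ascending (equals lexicographic k-mer order) and
    ``counts`` is aligned with it; all counts are >= 1.
    """

    spec: KmerSpec
    keys: np.ndarray
    counts: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        if len(self.keys) != len(self.counts):
            raise ValueError("keys and counts must align")

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer) > 0

    def get(self, kmer: str) -> int:
        key = string_to_key(kmer, self.spec)
        i = np.searchsorted(self.keys, key)
        if i < len(self.keys) and self.keys[i] == key:
            return int(self.counts[i])
        return 0

    def items(self) -> Iterator[tuple[str, int]]:
        for s, c in zip(keys_to_strings(self.keys, self.spec), self.counts):
            yield s, int(c)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_dict(cls, d: dict[str, int], spec: KmerSpec, source_label: str = "") -> "KmerCountTable":
        if not d:
            return cls(spec, _empty_keys(spec), np.empty(0, dtype=np.int64), source_label)
        keys = strings_to_keys(list(d), spec)
        counts = np.array([d[s] for s in d], dtype=np.int64)
        order = np.argsort(keys, kind="stable")
        keys, counts = keys[order], counts[order]
        # merge duplicates that canonicalise to the same key
        uk, inv = np.unique(keys, return_inverse=True)
        uc = np.zeros(len(uk), dtype=np.int64)
        np.add.at(uc, inv, counts)
        return cls(spec, uk, uc, source_label)


@dataclass
class PresenceSet:
    """The k-mers an individual is called to *have*: count >= min_count.

    A k-mer seen only once is attributed to sequencing error and not called
    present, hence the default ``min_count=2``.
    """

    spec: KmerSpec
    keys: np.ndarray
    min_count: int = 2

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, kmer: str) -> bool:
        key = string_to_key(kmer, self.spec)
        i = np.searchsorted(self.keys, key)
        return bool(i < len(self.keys) and self.keys[i] == key)

    def to_strings(self) -> list[str]:
        return keys_to_strings(self.keys, self.spec)


def _empty_keys(spec: KmerSpec) -> np.ndarray:
    return np.empty(0, dtype=np.uint64 if spec.packed else f"S{spec.k}")


def pack_reads(reads: Iterable[str | np.ndarray]) -> np.ndarray:
    """Concatenate reads (strings or code arrays) with sentinel separators."""
    parts: list[np.ndarray] = []
    sep = np.array([SENTINEL], dtype=np.uint8)
    for r in reads:
        parts.append(seq_to_codes(r) if isinstance(r, (str, bytes)) else r)
        parts.append(sep)
    if not parts:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(parts)


def count_kmers(
    reads: Iterable[str | np.ndarray] | np.ndarray,
    spec: KmerSpec,
    source_label: str = "",
    chunk_bases: int = 16_000_000,
) -> KmerCountTable:
    """Count canonical k-mers over a stream of reads.

    Every length-k window consisting solely of ACGT contributes one count to
    its canonical k-mer; windows containing any other symbol are skipped.
    ``reads`` may be an iterable of strings / uint8 code arrays, or a single
    packed code array with sentinel separators.  Counting is exact.
    """
    if isinstance(reads, np.ndarray):
        packed_iter: Iterable[np.ndarray] = [reads]
    else:
        packed_iter = _packed_chunks(reads, spec.k, chunk_bases)

    pieces: list[np.ndarray] = []
    for packed in packed_iter:
        if len(packed) >= spec.k:
            pieces.append(window_keys(packed, spec))
    if not pieces:
        warnings.warn("no countable k-mer windows in input", stacklevel=2)
        return KmerCountTable(spec, _empty_keys(spec), np.empty(0, dtype=np.int64), source_label)
    allkeys = pieces[0] if len(pieces) == 1 else np.concatenate(pieces)
    if len(allkeys) == 0:
        warnings.warn("no countable k-mer windows in input", stacklevel=2)
        return KmerCountTable(spec, _empty_keys(spec), np.empty(0, dtype=np.int64), source_label)
    keys, counts = np.unique(allkeys, return_counts=True)
    return KmerCountTable(spec, keys, counts.astype(np.int64), source_label)


def _packed_chunks(reads: Iterable[str | np.ndarray], k: int, chunk_bases: int) -> Iterator[np.ndarray]:
    """Pack reads into sentinel-separated chunks of roughly chunk_bases bases."""
    buf: list[np.ndarray] = []
    size = 0
    sep = np.array([SENTINEL], dtype=np.uint8)
    for r in reads:
        codes = seq_to_codes(r) if isinstance(r, (str, bytes)) else r
        buf.append(codes)
        buf.append(sep)
        size += len(codes) + 1
        if size >= chunk_bases:
            yield np.concatenate(buf)
            buf, size = [], 0
    if buf:
        yield np.concatenate(buf)


def presence_set(table: KmerCountTable, min_count: int = 2) -> PresenceSet:
    """k-mers of a count table with multiplicity >= min_count."""
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    return PresenceSet(table.spec, table.keys[table.counts >= min_count], min_count)


# ---------------------------------------------------------------------------
# table I/O (KMC-dump compatible TSV)
# ---------------------------------------------------------------------------

def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_table(table: KmerCountTable, path) -> None:
    """Write a count table as two-column TSV (k-mer TAB count), sorted
    lexicographically; gzip-compressed when the path ends in ``.gz``."""
    strings = keys_to_strings(table.keys, table.spec)
    with _open_text(path, "w") as fh:
        fh.writelines(f"{s}\t{c}\n" for s, c in zip(strings, table.counts))


def read_table(path, spec: KmerSpec | None = None, source_label: str | None = None) -> KmerCountTable:
    """Parse a KMC-dump style TSV back into a count table.

    Malformed lines (wrong column count, non-ACGT k-mer, inconsistent length,
    non-positive or non-integer count) raise ``ValueError`` naming the line.
    """
    with _open_text(path, "r") as fh:
        raw = fh.read()
    lines = raw.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    kmers: list[str] = []
    counts_s: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 TAB-separated columns")
        kmers.append(cols[0].upper())
        counts_s.append(cols[1])
    if spec is None:
        if not kmers:
            raise ValueError(f"{path}: empty table and no KmerSpec given")
        spec = KmerSpec(len(kmers[0]))
    label = source_label if source_label is not None else str(path)
    if not kmers:
        return KmerCountTable(spec, _empty_keys(spec), np.empty(0, dtype=np.int64), label)
    try:
        keys = strings_to_keys(kmers, spec)
    except ValueError as e:
        # recover the line number from the reported k-mer index
        head, _, detail = str(e).partition(" #")
        idx = int(detail.split(" ")[0])
        rest = detail.split(" ", 1)[1]
        raise ValueError(f"{path}: line {idx + 1}: k-mer {rest}") from None
    arr = pd.to_numeric(pd.Series(counts_s), errors="coerce")
    if arr.isna().any():
        bad = int(arr.isna().idxmax())
        raise ValueError(f"{path}: line {bad + 1}: count {counts_s[bad]!r} is not an integer")
    arr = arr.to_numpy()
    if np.any(arr != np.floor(arr)):
        bad = int(np.argmax(arr != np.floor(arr)))
        raise ValueError(f"{path}: line {bad + 1}: count {counts_s[bad]!r} is not an integer")
    counts = arr.astype(np.int64)
    if counts.min() < 1:
        bad = int(np.argmax(counts < 1))
        raise ValueError(f"{path}: line {bad + 1}: count must be >= 1")
    order = np.argsort(keys, kind="stable")
    return KmerCountTable(spec, keys[order], counts[order], label)
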