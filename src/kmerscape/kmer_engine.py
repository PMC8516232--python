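"""Canonical k-mer extraction, counting and set algebra.

A k-mer and its reverse complement are counted as one *canonical* k-mer, the
lexicographically smaller of the pair, which makes counting strand
independent.  Only odd k are accepted so that no k-mer is its own reverse
complement and the canonical sequence space has size exactly ``4^k / 2``.

Counting is exact and in memory.  For k <= 31 each window is packed into a
64-bit integer (two bits per base) and the whole genome is processed with
vectorised numpy; for 31 < k <= 51 a plain string fallback is used, which is
fine at the small scales where such long k-mers are of interest here.
Windows containing ``N`` contribute neither to the counts nor to the total
window count ``N_T``.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Mapping

import numpy as np

from .sequence_io import GenomeRecord, reverse_complement

__all__ = [
    "KmerSet",
    "extract_canonical_kmers",
    "union",
    "intersection_cardinality",
    "save_kmerset",
    "load_kmerset",
    "canonical",
]

K_MIN, K_MAX = 3, 51
_NUMPY_K_MAX = 31  # 2*31 = 62 bits fit a uint64

_BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_FORMAT_MAGIC = "#kmerscape-kset"
_FORMAT_VERSION = 1


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(
            f"k must be odd (got {k}): the canonical space 4^k/2 assumes no "
            "reverse-complement palindromes"
        )
    if not (K_MIN <= k <= K_MAX):
        raise ValueError(f"k must be in [{K_MIN}, {K_MAX}], got {k}")


def canonical(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _decode(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def _encode(kmer: str) -> int:
    code = 0
    for c in kmer:
        code = (code << 2) | int(_CODE[ord(c)])
    return code


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Canonical 2-bit packed codes of all valid (N-free) windows of ``seq``."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = len(codes) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    c = codes.astype(np.uint64)
    comp = np.where(codes < 4, 3 - codes, 0).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j : j + m]
        rev |= comp[j : j + m] << np.uint64(2 * j)
    # windows containing an N are invalid
    is_n = (codes == 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cum[k:] - cum[:-k]) == 0
    return np.minimum(fwd, rev)[valid]


def _windows_string(seq: str, k: int) -> list[str]:
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        out.append(canonical(w))
    return out


class KmerSet:
    """The set of distinct canonical k-mers of a sequence collection.

    Attributes
    ----------
    k : int
        Odd k-mer length.
    N_D : int
        Number of distinct canonical k-mers.
    N_T : int
        Total number of counted (valid) k-mer windows.  For N-free
        sequences of lengths ``L_i`` this equals ``sum(L_i - k + 1)``.
    """

    __slots__ = ("k", "_keys", "_counts", "_n_total")

    def __init__(self, k: int, keys: np.ndarray, counts: np.ndarray, n_total: int):
        _check_k(k)
        self.k = k
        self._keys = keys
        self._counts = counts.astype(np.int64)
        self._n_total = int(n_total)

    # ------------------------------------------------------------------ #
    @property
    def N_D(self) -> int:
        return int(self._keys.size)

    @property
    def N_T(self) -> int:
        return self._n_total

    @property
    def space_size(self) -> float:
        """S = 4^k / 2, the size of the canonical k-mer space."""
        return 4.0**self.k / 2.0

    def __len__(self) -> int:
        return self.N_D

    def __contains__(self, kmer: str) -> bool:
        key = self._to_key(canonical(kmer.upper()))
        i = np.searchsorted(self._keys, key)
        return bool(i < self._keys.size and self._keys[i] == key)

    def _to_key(self, canon: str):
        if self._keys.dtype == np.uint64:
            return np.uint64(_encode(canon))
        return canon.encode("ascii")

    def _key_to_str(self, key) -> str:
        if self._keys.dtype == np.uint64:
            return _decode(int(key), self.k)
        return key.decode("ascii")

    @property
    def counts(self) -> dict[str, int]:
        """Canonical k-mer -> frequency, decoded to strings.

        Intended for inspection and small sets; the internal representation
        stays packed.
        """
        return {
            self._key_to_str(key): int(cnt)
            for key, cnt in zip(self._keys, self._counts)
        }

    def count(self, kmer: str) -> int:
        key = self._to_key(canonical(kmer.upper()))
        i = np.searchsorted(self._keys, key)
        if i < self._keys.size and self._keys[i] == key:
            return int(self._counts[i])
        return 0

    # ------------------------------------------------------------------ #
    def union(self, other: "KmerSet") -> "KmerSet":
        return union(self, other)

    def intersection_cardinality(self, other: "KmerSet") -> int:
        return intersection_cardinality(self, other)

    def union_cardinality(self, other: "KmerSet") -> int:
        _check_same_k(self, other)
        return int(np.union1d(self._keys, other._keys).size)

    def __repr__(self) -> str:  # pragma: no cover
        return f"KmerSet(k={self.k}, N_D={self.N_D}, N_T={self.N_T})"


def _check_same_k(a: KmerSet, b: KmerSet) -> None:
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")


def _from_window_keys(k: int, window_keys: np.ndarray) -> KmerSet:
    n_total = int(window_keys.size)
    if n_total == 0:
        dtype = np.uint64 if k <= _NUMPY_K_MAX else f"S{k}"
        return KmerSet(k, np.empty(0, dtype=dtype), np.empty(0, dtype=np.int64), 0)
    keys, counts = np.unique(window_keys, return_counts=True)
    return KmerSet(k, keys, counts, n_total)


def extract_canonical_kmers(record: GenomeRecord | str | Iterable[str], k: int) -> KmerSet:
    """Count the canonical k-mers of a genome (or raw sequence(s)).

    The sliding window moves left to right over every sequence
    independently; windows containing ``N`` are skipped entirely.
    """
    _check_k(k)
    if isinstance(record, GenomeRecord):
        seqs = record.sequences
    elif isinstance(record, str):
        seqs = [record]
    else:
        seqs = list(record)
    seqs = [s.upper() for s in seqs]
    if all(k > len(s) for s in seqs):
        warnings.warn(
            f"k={k} exceeds every sequence length; empty k-mer set (N_T = 0)",
            stacklevel=2,
        )
    if k <= _NUMPY_K_MAX:
        parts = [_window_codes(s, k) for s in seqs]
        window_keys = np.concatenate(parts) if parts else np.empty(0, np.uint64)
    else:
        strs: list[str] = []
        for s in seqs:
            strs.extend(_windows_string(s, k))
        window_keys = np.array(strs, dtype=f"S{k}") if strs else np.empty(0, f"S{k}")
    return _from_window_keys(k, window_keys)


def union(a: KmerSet, b: KmerSet) -> KmerSet:
    """Set union; counts of shared k-mers are summed, N_T values add."""
    _check_same_k(a, b)
    if a.N_D == 0:
        return KmerSet(b.k, b._keys.copy(), b._counts.copy(), a.N_T + b.N_T)
    if b.N_D == 0:
        return KmerSet(a.k, a._keys.copy(), a._counts.copy(), a.N_T + b.N_T)
    merged = np.concatenate([a._keys, b._keys])
    weights = np.concatenate([a._counts, b._counts])
    keys, inverse = np.unique(merged, return_inverse=True)
    counts = np.bincount(inverse, weights=weights.astype(np.float64)).astype(np.int64)
    return KmerSet(a.k, keys, counts, a.N_T + b.N_T)


def intersection_cardinality(a: KmerSet, b: KmerSet) -> int:
    """|A ∩ B| obtained as |A| + |B| − |A ∪ B|."""
    _check_same_k(a, b)
    return a.N_D + b.N_D - a.union_cardinality(b)


# ---------------------------------------------------------------------- #
# on-disk format: a small versioned TSV of (kmer, count), sorted
# ---------------------------------------------------------------------- #
def save_kmerset(kset: KmerSet, path: str | os.PathLike) -> None:
    """Write a k-mer set as a versioned TSV (internal, lossless format)."""
    with open(path, "w") as fh:
        fh.write(f"{_FORMAT_MAGIC}\tversion={_FORMAT_VERSION}\tk={kset.k}\tn_total={kset.N_T}\n")
        for key, cnt in zip(kset._keys, kset._counts):
            fh.write(f"{kset._key_to_str(key)}\t{int(cnt)}\n")


def load_kmerset(path: str | os.PathLike) -> KmerSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if not fields or fields[0] != _FORMAT_MAGIC:
            raise ValueError(f"{path!r} is not a kmerscape k-mer set file")
        meta: Mapping[str, str] = dict(f.split("=", 1) for f in fields[1:])
        if int(meta.get("version", -1)) != _FORMAT_VERSION:
            raise ValueError(f"unsupported k-mer set format version in {path!r}")
        k = int(meta["k"])
        _check_k(k)
        n_total = int(meta["n_total"])
        kmers: list[str] = []
        counts: list[int] = []
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path!r}:{line_no}: malformed line")
            kmer, cnt = parts
            if len(kmer) != k or any(c not in _BASES for c in kmer):
                raise ValueError(
                    f"{path!r}:{line_no}: key {kmer!r} inconsistent with k={k}"
                )
            kmers.append(kmer)
            counts.append(int(cnt))
    if sum(counts) != n_total:
        raise ValueError(
            f"{path!r}: counts do not add up to declared n_total; truncated file?"
        )
    if k <= _NUMPY_K_MAX:
        keys = np.array([_encode(s) for s in kmers], dtype=np.uint64)
    else:
        keys = np.array(kmers, dtype=f"S{k}")
    order = np.argsort(keys)
    return KmerSet(k, keys[order], np.array(counts, dtype=np.int64)[order], n_total)
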