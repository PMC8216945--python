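"""Canonical k-mer machinery shared by the YGS-style classifier and read screens.

A k-mer and its reverse complement are collapsed onto the lexicographically
smaller 2-bit encoding (the *canonical* form), so strandedness of reads and
scaffolds never matters.  With the default k = 31 a k-mer packs into a single
unsigned 64-bit integer, which keeps whole-genome k-mer sets as flat sorted
numpy arrays instead of Python sets.

Windows containing any non-ACGT character (N, IUPAC ambiguity codes, ...) are
skipped entirely: an ambiguous base carries no single-copy information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

MAX_K = 31

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
del _i, _b


def canonical_kmers(seq: str, k: int = 31) -> np.ndarray:
    """All canonical k-mers of ``seq`` as a uint64 array (positional order).

    K-mer windows overlapping a non-ACGT base are dropped.  Sequences shorter
    than ``k`` yield an empty array.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = codes == 255
    clean = np.where(bad, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        w = clean[j : j + n]
        fwd = (fwd << np.uint64(2)) | w
        rev |= (np.uint64(3) - w) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        keep = (cs[k:] - cs[:-k]) == 0
        canon = canon[keep]
    return canon


def kmer_to_string(kmer: int, k: int) -> str:
    """Decode a 2-bit packed k-mer back to its ACGT string (debugging aid)."""
    bases = "ACGT"
    out = []
    v = int(kmer)
    for _ in range(k):
        out.append(bases[v & 3])
        v >>= 2
    return "".join(reversed(out))


@dataclass(frozen=True)
class KmerDictionary:
    """A set of canonical k-mers with O(log n) membership via binary search.

    ``kmers`` is a sorted, de-duplicated uint64 array.  ``min_count`` records
    the occurrence threshold the dictionary was built with (k-mers seen fewer
    times in the source reads were discarded as likely sequencing errors).
    """

    k: int
    kmers: np.ndarray = field(repr=False)
    min_count: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.kmers, dtype=np.uint64)
        object.__setattr__(self, "kmers", arr)

    def __len__(self) -> int:
        return int(self.kmers.size)

    def contains(self, query: np.ndarray) -> np.ndarray:
        """Boolean membership mask for an array of packed k-mers."""
        query = np.asarray(query, dtype=np.uint64)
        if self.kmers.size == 0:
            return np.zeros(query.size, dtype=bool)
        idx = np.searchsorted(self.kmers, query)
        idx[idx == self.kmers.size] = self.kmers.size - 1
        return self.kmers[idx] == query

    def match_fraction(self, query: np.ndarray) -> float:
        """Fraction of ``query`` k-mers present in the dictionary."""
        query = np.asarray(query, dtype=np.uint64)
        if query.size == 0:
            raise ValueError("empty k-mer query has no match fraction")
        return float(self.contains(query).mean())


def count_kmers(arrays: Iterable[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (unique_kmer, multiplicity) over any number of k-mer arrays."""
    chunks = [np.asarray(a, dtype=np.uint64) for a in arrays]
    if not chunks:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    pool = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    if pool.size == 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    uniq, counts = np.unique(pool, return_counts=True)
    return uniq, counts


def dictionary_from_sequences(
    seqs: Iterable[str], k: int = 31, min_count: int = 1
) -> KmerDictionary:
    """Build a :class:`KmerDictionary` from raw sequences (reads, scaffolds)."""
    uniq, counts = count_kmers(canonical_kmers(s, k) for s in seqs)
    return KmerDictionary(k=k, kmers=uniq[counts >= min_count], min_count=min_count)
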