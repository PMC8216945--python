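"""Sample sex inference from the mapping rate against male-specific seed regions.

The classifier exploits the simplest property of the Y chromosome: reads from
a female sample cannot originate from male-specific sequence.  Regions of a
Y-candidate scaffold that are covered in every known male and empty in every
known female are truncated into a *seed set*; the fraction of an unknown
sample's reads that map to the seed set then separates the sexes by orders of
magnitude (males around a few hundredths of a percent of all reads, females
at 0.00%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .kmers import KmerDictionary, dictionary_from_sequences, canonical_kmers
from .simdata import SimRead

__all__ = [
    "SeedRegionSet",
    "SexThresholds",
    "SexCall",
    "derive_seed_regions",
    "mapping_rate",
    "call_sex",
    "threshold_separation_test",
    "seed_kmer_index",
    "count_mapped_reads",
    "sex_from_reads",
]


@dataclass(frozen=True)
class SeedRegionSet:
    """Male-specific intervals, 0-based half-open, non-overlapping per scaffold."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        by_scaffold: dict[str, list[tuple[int, int]]] = {}
        for sid, start, end in self.intervals:
            if not 0 <= start < end:
                raise ValueError(f"bad interval {(sid, start, end)}")
            by_scaffold.setdefault(sid, []).append((start, end))
        for sid, ivs in by_scaffold.items():
            ivs.sort()
            for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping seed intervals on {sid}")

    @property
    def total_len(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, start, end in self.intervals:
                fh.write(f"{sid}\t{start}\t{end}\n")


@dataclass(frozen=True)
class SexThresholds:
    """Mapping-rate cutoffs in percent; male is a strict inequality."""

    male_min: float = 0.04
    female_max: float = 0.00

    def __post_init__(self) -> None:
        if not self.female_max < self.male_min:
            raise ValueError("female_max must be < male_min")


@dataclass(frozen=True)
class SexCall:
    sample_id: str
    mapped_reads: int
    total_reads: int
    call: str  # male / female / ambiguous

    @property
    def mapping_rate(self) -> float:
        return mapping_rate(self.mapped_reads, self.total_reads)


def derive_seed_regions(
    scaffold_id: str,
    male_depths: Sequence[np.ndarray],
    female_depths: Sequence[np.ndarray],
    min_male_depth: float = 3.0,
    max_female_depth: float = 0.0,
    min_run_len: int = 500,
) -> SeedRegionSet:
    """Maximal male-covered, female-empty runs of a Y-candidate scaffold.

    A position qualifies when *every* known male has depth >= ``min_male_depth``
    and *every* known female has depth <= ``max_female_depth``; qualifying runs
    shorter than ``min_run_len`` are discarded.  Depth arrays must cover every
    position of the scaffold (the depth-tool "-aa" convention).
    """
    if not male_depths or not female_depths:
        raise ValueError("need at least one male and one female depth array")
    lengths = {len(a) for a in list(male_depths) + list(female_depths)}
    if len(lengths) != 1:
        raise ValueError("depth arrays must share the scaffold's coordinates")
    males = np.vstack([np.asarray(a, dtype=float) for a in male_depths])
    females = np.vstack([np.asarray(a, dtype=float) for a in female_depths])
    ok = (males >= min_male_depth).all(axis=0) & (females <= max_female_depth).all(axis=0)

    intervals: list[tuple[str, int, int]] = []
    padded = np.concatenate(([False], ok, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_run_len:
            intervals.append((scaffold_id, int(start), int(end)))
    if not intervals:
        warnings.warn(
            f"no male-specific run of >= {min_run_len} bp on {scaffold_id}",
            stacklevel=2,
        )
    return SeedRegionSet(tuple(intervals))


def mapping_rate(mapped_reads: int, total_reads: int) -> float:
    """Percentage of a sample's reads that map to the seed set."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if not 0 <= mapped_reads <= total_reads:
        raise ValueError("mapped_reads must be in [0, total_reads]")
    return 100.0 * mapped_reads / total_reads


def call_sex(rate: float, thresholds: SexThresholds = SexThresholds()) -> str:
    """male above ``male_min`` (strict), female at or below ``female_max``."""
    if rate < 0 or rate > 100:
        raise ValueError("mapping rate must be a percentage in [0, 100]")
    if rate > thresholds.male_min:
        return "male"
    if rate <= thresholds.female_max:
        return "female"
    return "ambiguous"


def threshold_separation_test(
    rates_male: Sequence[float], rates_female: Sequence[float]
) -> float:
    """Welch two-sample t-test p-value on male vs female mapping rates.

    Degenerate case: both groups constant with equal means carries no evidence
    of separation and returns p = 1.
    """
    a = np.asarray(rates_male, dtype=float)
    b = np.asarray(rates_female, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


# ---------------------------------------------------------------------------
# lightweight k-mer read screen (stands in for an aligner on simulated data)
# ---------------------------------------------------------------------------


def seed_kmer_index(
    seed_sequences: Iterable[str], k: int = 31
) -> KmerDictionary:
    """Exact k-mer index over the seed regions, for screening reads."""
    return dictionary_from_sequences(seed_sequences, k=k, min_count=1)


def count_mapped_reads(
    reads: Iterable[SimRead], index: KmerDictionary, min_hits: int = 1
) -> tuple[int, int]:
    """(mapped, total): a read maps when >= ``min_hits`` of its k-mers hit the index."""
    mapped = total = 0
    for r in reads:
        total += 1
        km = canonical_kmers(r.sequence, index.k)
        if km.size and int(index.contains(km).sum()) >= min_hits:
            mapped += 1
    if total == 0:
        raise ValueError("no reads supplied")
    return mapped, total


def sex_from_reads(
    sample_id: str,
    reads: Iterable[SimRead],
    index: KmerDictionary,
    thresholds: SexThresholds = SexThresholds(),
    min_hits: int = 1,
) -> SexCall:
    mapped, total = count_mapped_reads(reads, index, min_hits=min_hits)
    return SexCall(
        sample_id=sample_id,
        mapped_reads=mapped,
        total_reads=total,
        call=call_sex(mapping_rate(mapped, total), thresholds),
    )
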