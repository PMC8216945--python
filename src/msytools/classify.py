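"""Y-scaffold classification: depth ratio, single-copy k-mer profiling, homology.

Three independent lines of evidence assign unplaced scaffolds to the Y
chromosome:

* **AD ratio** — normalized female/male mean read depth.  A Y scaffold draws
  no female reads (AD ~ 0), an autosome equal depth (AD ~ 1), an X scaffold
  twice the female depth (AD ~ 2).  X-transposed Y segments leak female
  depth, which is why the Y window is deliberately relaxed to AD < 0.4.
* **YGS profile** — the fraction of a scaffold's single-copy 31-mers found in
  male vs female read dictionaries.  Y calls require > 90% male and < 10%
  female matching; SNP-level divergence (not copy number) is its weakness.
* **Homology voting** — summed aligned bases against an annotated reference,
  calling Y when the Y-target total dominates and covers enough of the
  scaffold.

The consensus table records per-method membership plus the intersection
(high confidence) and union (high sensitivity) sets, and an N10..N90 ladder
summarizes any scaffold length distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kmers import KmerDictionary, canonical_kmers, count_kmers, dictionary_from_sequences
from .simdata import DepthTable

__all__ = [
    "ADConfig",
    "ad_ratio",
    "ad_table",
    "classify_ad",
    "build_kmer_dictionary",
    "single_copy_kmers",
    "YgsProfile",
    "ygs_profile",
    "classify_ygs",
    "HomologyHit",
    "classify_homology",
    "consensus",
    "n_ladder",
]


# ---------------------------------------------------------------------------
# AD ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ADConfig:
    """Classification windows for the normalized female/male depth ratio."""

    y_max: float = 0.4
    auto_lo: float = 0.6
    auto_hi: float = 1.4
    x_lo: float = 1.6
    x_hi: float = 2.4
    strict_y_max: float = 0.3  # positive-control check, not a classification window
    min_scaffold_len: int = 1_000

    def __post_init__(self) -> None:
        if not self.y_max < self.auto_lo < self.auto_hi < self.x_lo < self.x_hi:
            raise ValueError("windows must satisfy y_max < auto_lo < auto_hi < x_lo < x_hi")


def ad_ratio(
    mean_depth_female: float,
    mean_depth_male: float,
    total_reads_female: int,
    total_reads_male: int,
) -> float:
    """Normalized depth ratio; NaN (undefined) when the male depth is zero."""
    if total_reads_female <= 0 or total_reads_male <= 0:
        raise ValueError("total read counts must be > 0")
    if mean_depth_female < 0 or mean_depth_male < 0:
        raise ValueError("depths must be >= 0")
    if mean_depth_male == 0:
        return float("nan")
    norm = total_reads_female / total_reads_male
    return mean_depth_female / (mean_depth_male * norm)


def ad_table(female: DepthTable, male: DepthTable) -> pd.DataFrame:
    """Per-scaffold AD ratios from two single-sex depth tables.

    Returns columns scaffold_id, length, ad (NaN where undefined).
    """
    f = female.table.set_index("scaffold_id")
    m = male.table.set_index("scaffold_id")
    common = f.index.intersection(m.index)
    norm = female.total_reads / male.total_reads
    with np.errstate(divide="ignore", invalid="ignore"):
        ad = f.loc[common, "mean_depth"].to_numpy() / (
            m.loc[common, "mean_depth"].to_numpy() * norm
        )
    ad = np.where(m.loc[common, "mean_depth"].to_numpy() == 0, np.nan, ad)
    return pd.DataFrame(
        {
            "scaffold_id": common,
            "length": f.loc[common, "length"].to_numpy(),
            "ad": ad,
        }
    ).reset_index(drop=True)


def classify_ad(ad: float, cfg: ADConfig = ADConfig(), length: int | None = None) -> str:
    """Window classification; undefined AD or a too-short scaffold is unassigned."""
    if length is not None and length < cfg.min_scaffold_len:
        return "unassigned"
    if ad is None or np.isnan(ad):
        return "unassigned"
    if ad < cfg.y_max:
        return "Y"
    if cfg.auto_lo < ad < cfg.auto_hi:
        return "A"
    if cfg.x_lo <= ad < cfg.x_hi:
        return "X"
    return "unassigned"


# ---------------------------------------------------------------------------
# YGS-style k-mer profiling
# ---------------------------------------------------------------------------


def build_kmer_dictionary(
    read_seqs: Iterable[str], k: int = 31, min_count: int = 2
) -> KmerDictionary:
    """Canonical k-mer dictionary from reads; ``min_count`` suppresses error k-mers."""
    if not (k % 2 == 1 and k >= 11):
        raise ValueError("k must be odd and >= 11")
    return dictionary_from_sequences(read_seqs, k=k, min_count=min_count)


def single_copy_kmers(
    scaffolds: Mapping[str, str], k: int = 31, scope: str = "pool"
) -> dict[str, np.ndarray]:
    """Per-scaffold single-copy (non-repetitive) canonical k-mer arrays.

    ``scope="pool"`` (default): a k-mer is single-copy when it occurs exactly
    once across the entire scaffold pool, so repeats shared between scaffolds
    are excluded everywhere.  ``scope="per-scaffold"`` relaxes this to
    uniqueness within each scaffold.
    """
    if scope not in {"pool", "per-scaffold"}:
        raise ValueError("scope must be 'pool' or 'per-scaffold'")
    per_scaffold = {sid: canonical_kmers(seq, k) for sid, seq in scaffolds.items()}
    if scope == "per-scaffold":
        out = {}
        for sid, km in per_scaffold.items():
            uniq, counts = np.unique(km, return_counts=True)
            out[sid] = uniq[counts == 1]
        return out
    uniq, counts = count_kmers(per_scaffold.values())
    singles = uniq[counts == 1]
    out = {}
    for sid, km in per_scaffold.items():
        out[sid] = np.intersect1d(km, singles, assume_unique=False)
    return out


@dataclass(frozen=True)
class YgsProfile:
    """Match percentages of one scaffold's single-copy k-mers in sexed dictionaries."""

    scaffold_id: str
    n_single_copy_kmers: int
    pct_matched_female: float
    pct_matched_male: float

    @property
    def defined(self) -> bool:
        return self.n_single_copy_kmers > 0

    @property
    def pct_unmatched_female(self) -> float:
        return 100.0 - self.pct_matched_female


def ygs_profile(
    scaffold_id: str,
    scaffold_kmers: np.ndarray,
    female_dict: KmerDictionary,
    male_dict: KmerDictionary,
) -> YgsProfile:
    km = np.asarray(scaffold_kmers, dtype=np.uint64)
    if km.size == 0:
        return YgsProfile(scaffold_id, 0, float("nan"), float("nan"))
    return YgsProfile(
        scaffold_id,
        int(km.size),
        100.0 * female_dict.match_fraction(km),
        100.0 * male_dict.match_fraction(km),
    )


def classify_ygs(
    profile: YgsProfile,
    male_min: float = 90.0,
    female_max: float = 10.0,
    female_rule: str = "matched",
) -> str:
    """Y iff male match > ``male_min`` and the female criterion holds.

    ``female_rule="matched"`` (text rule, default): female match < female_max.
    ``female_rule="unmatched"``: female *unmatched* >= 100 - female_max, which
    is equivalent here but exposed separately because the two phrasings differ
    once boundary values are involved.
    """
    if not profile.defined:
        return "undefined"
    if female_rule == "matched":
        female_ok = profile.pct_matched_female < female_max
    elif female_rule == "unmatched":
        female_ok = profile.pct_unmatched_female >= 100.0 - female_max
    else:
        raise ValueError("female_rule must be 'matched' or 'unmatched'")
    return "Y" if (profile.pct_matched_male > male_min and female_ok) else "not-Y"


# ---------------------------------------------------------------------------
# homology voting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologyHit:
    scaffold_id: str
    target_chrom: str
    aligned_bases: int
    identity: float

    def __post_init__(self) -> None:
        if self.aligned_bases < 0:
            raise ValueError("aligned_bases must be >= 0")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


def classify_homology(
    hits: Sequence[HomologyHit],
    scaffold_len: int,
    y_target: str = "Y",
    min_identity: float = 0.8,
    min_cov_fraction: float = 0.5,
) -> str:
    """Y when the Y-target aligned total is the strict maximum and covers enough.

    Ties never call Y (conservative).  No hits passing ``min_identity`` is a
    no-call, distinct from an informative not-Y.
    """
    if scaffold_len <= 0:
        raise ValueError("scaffold_len must be > 0")
    totals: dict[str, int] = {}
    for h in hits:
        if h.aligned_bases > scaffold_len:
            raise ValueError(f"hit of {h.aligned_bases} bp exceeds scaffold length")
        if h.identity >= min_identity:
            totals[h.target_chrom] = totals.get(h.target_chrom, 0) + h.aligned_bases
    if not totals:
        return "no-call"
    y_total = totals.get(y_target, 0)
    best_other = max((v for t, v in totals.items() if t != y_target), default=0)
    if y_total > best_other and y_total >= min_cov_fraction * scaffold_len:
        return "Y"
    return "not-Y"


# ---------------------------------------------------------------------------
# consensus + assembly statistics
# ---------------------------------------------------------------------------


def consensus(
    ad_calls: Mapping[str, str],
    ygs_calls: Mapping[str, str],
    hom_calls: Mapping[str, str],
) -> pd.DataFrame:
    """Per-scaffold method flags plus intersection/union membership.

    A method "votes" for a scaffold when its call is exactly "Y"; undefined,
    unassigned and no-call verdicts are non-votes.  The scaffold universe is
    the union of the three call maps.
    """
    universe = sorted(set(ad_calls) | set(ygs_calls) | set(hom_calls))
    rows = []
    for sid in universe:
        ad = ad_calls.get(sid) == "Y"
        ygs = ygs_calls.get(sid) == "Y"
        hom = hom_calls.get(sid) == "Y"
        rows.append(
            {
                "scaffold_id": sid,
                "ad": ad,
                "ygs": ygs,
                "homology": hom,
                "in_intersection": ad and ygs and hom,
                "in_union": ad or ygs or hom,
            }
        )
    return pd.DataFrame(
        rows, columns=["scaffold_id", "ad", "ygs", "homology", "in_intersection", "in_union"]
    )


def n_ladder(lengths: Sequence[int]) -> pd.DataFrame:
    """N10..N90 / L10..L90 ladder of a scaffold length distribution.

    Nx is the length of the scaffold at which the cumulative sorted-descending
    length first reaches x% of the total; Lx counts the scaffolds used to get
    there.  The result carries ``total`` and ``count`` in ``DataFrame.attrs``.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty length list")
    if (arr <= 0).any():
        raise ValueError("all lengths must be > 0")
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    total = int(cum[-1])
    rows = []
    for x in range(10, 100, 10):
        idx = int(np.searchsorted(cum, x / 100.0 * total))
        rows.append({"stat": f"N{x}", "length": int(desc[idx]), "count": idx + 1})
    out = pd.DataFrame(rows).set_index("stat")
    out.attrs["total"] = total
    out.attrs["count"] = int(arr.size)
    return out
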