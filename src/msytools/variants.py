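"""Y-SNP quality cascade, SNP concatenation, and mutation-rate derivation.

The cascade mirrors standard haploid Y curation: GATK-style hard filters on
site annotations, removal of any site also seen in female samples (female
"Y" calls betray misassembled or pseudoautosomal regions), then biallelic /
minor-allele-frequency / call-rate site filters.  Surviving SNPs can be
concatenated into a per-sample alignment for tree or skyline inference, with
the per-site mutation rate rescaled so that each retained column absorbs the
mutational opportunity of the sequence it summarizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "FilterSpec",
    "Site",
    "MalformedAnnotationError",
    "read_vcf",
    "read_exclusion_list",
    "hard_filter",
    "exclude_female_sites",
    "site_filters",
    "FilterReport",
    "filter_cascade",
    "concat_snps",
    "write_alignment_fasta",
    "RateSpec",
    "y_rate_per_year",
    "rescale_rate_for_concat",
]

HARD_FILTER_FIELDS = ("QD", "MQRankSum", "FS", "ReadPosRankSum", "MQ", "SOR")


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds of the hard-filter expression plus site-level criteria.

    Hard-filter inequalities are strict (a record *fails* on QD < 2.0, ...,
    SOR > 3.0, exactly as the bcftools expression reads); MAF and call-rate
    cutoffs are inclusive.
    """

    qd_min: float = 2.0
    mqranksum_min: float = -12.5
    fs_max: float = 60.0
    readpos_min: float = -8.0
    mq_min: float = 40.0
    sor_max: float = 3.0
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in (
            "qd_min",
            "mqranksum_min",
            "fs_max",
            "readpos_min",
            "mq_min",
            "sor_max",
            "maf_min",
            "call_rate_min",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


class MalformedAnnotationError(ValueError):
    """A site annotation could not be interpreted as a number."""


@dataclass(frozen=True)
class Site:
    """One VCF record reduced to what the cascade needs."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    info: Mapping[str, object]
    genotypes: tuple[tuple[int | None, ...], ...]  # allele indices per sample

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def read_vcf(path: str | Path) -> list[Site]:
    """Load a VCF into :class:`Site` records (order preserved)."""
    sites: list[Site] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            gts = tuple(
                tuple(rec.samples[s]["GT"]) if rec.samples[s]["GT"] is not None else (None,)
                for s in rec.samples
            )
            sites.append(
                Site(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    info=dict(rec.info),
                    genotypes=gts,
                )
            )
    return sites


def read_exclusion_list(path: str | Path) -> set[tuple[str, int]]:
    """Female-observed sites as a set of (scaffold, 1-based position)."""
    out: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos = line.split("\t")[:2]
            out.add((chrom, int(pos)))
    return out


def _numeric(value: object, fieldname: str) -> float:
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise MalformedAnnotationError(f"{fieldname}={value!r} is not numeric") from exc


def hard_filter(site: Site, spec: FilterSpec = FilterSpec()) -> tuple[bool, list[str]]:
    """(passed, violated fields).  Absent annotations never trigger a failure."""
    checks = (
        ("QD", lambda v: v < spec.qd_min),
        ("MQRankSum", lambda v: v < spec.mqranksum_min),
        ("FS", lambda v: v > spec.fs_max),
        ("ReadPosRankSum", lambda v: v < spec.readpos_min),
        ("MQ", lambda v: v < spec.mq_min),
        ("SOR", lambda v: v > spec.sor_max),
    )
    reasons = []
    for name, bad in checks:
        if name in site.info and site.info[name] is not None:
            if bad(_numeric(site.info[name], name)):
                reasons.append(name)
    return (not reasons, reasons)


def exclude_female_sites(
    sites: Sequence[Site], female_sites: Iterable[tuple[str, int]]
) -> tuple[list[Site], int]:
    """Drop every record whose (scaffold, pos) appears in the female site list."""
    excl = set(female_sites)
    kept = [s for s in sites if s.key not in excl]
    return kept, len(sites) - len(kept)


def _observed_allele_counts(site: Site) -> tuple[dict[int, int], int, int]:
    """(allele -> count over observed haplotypes, n observed samples, n samples)."""
    counts: dict[int, int] = {}
    n_obs_samples = 0
    for gt in site.genotypes:
        observed = [a for a in gt if a is not None]
        if observed:
            n_obs_samples += 1
            for a in observed:
                counts[a] = counts.get(a, 0) + 1
    return counts, n_obs_samples, len(site.genotypes)


def site_filters(
    sites: Sequence[Site], spec: FilterSpec = FilterSpec()
) -> tuple[list[Site], dict[str, int]]:
    """Biallelic / MAF / call-rate filters on observed genotypes.

    A site survives when exactly two alleles are observed among non-missing
    calls, the minor allele frequency over observed haplotypes is
    >= ``maf_min`` (inclusive), and the fraction of samples with a call is
    >= ``call_rate_min`` (inclusive).
    """
    kept: list[Site] = []
    lost = {"multiallelic": 0, "maf": 0, "call_rate": 0}
    for s in sites:
        counts, n_obs, n_samples = _observed_allele_counts(s)
        if n_obs / n_samples < spec.call_rate_min:
            lost["call_rate"] += 1
            continue
        if spec.biallelic_only and len(counts) != 2:
            lost["multiallelic"] += 1
            continue
        total_hap = sum(counts.values())
        if min(counts.values()) / total_hap < spec.maf_min:
            lost["maf"] += 1
            continue
        kept.append(s)
    return kept, lost


@dataclass
class FilterReport:
    survivors: list[Site]
    n_input: int
    n_hard_failed: int
    n_malformed: int
    n_female_excluded: int
    site_losses: dict[str, int]
    hard_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)


def filter_cascade(
    sites: Sequence[Site],
    female_sites: Iterable[tuple[str, int]] = (),
    spec: FilterSpec = FilterSpec(),
) -> FilterReport:
    """Hard filters, then female-site exclusion, then site-level filters.

    The three stages act on disjoint criteria, so their order does not change
    the surviving set; this composition is the one used for Y SNPs.
    """
    n_input = len(sites)
    hard_ok: list[Site] = []
    n_malformed = 0
    reason_counts: dict[str, int] = {}
    for s in sites:
        try:
            ok, reasons = hard_filter(s, spec)
        except MalformedAnnotationError:
            n_malformed += 1
            continue
        if ok:
            hard_ok.append(s)
        else:
            for r in reasons:
                reason_counts[r] = reason_counts.get(r, 0) + 1
    after_female, n_excluded = exclude_female_sites(hard_ok, female_sites)
    survivors, site_losses = site_filters(after_female, spec)
    return FilterReport(
        survivors=survivors,
        n_input=n_input,
        n_hard_failed=n_input - n_malformed - len(hard_ok),
        n_malformed=n_malformed,
        n_female_excluded=n_excluded,
        site_losses=site_losses,
        hard_reasons=reason_counts,
    )


# ---------------------------------------------------------------------------
# SNP concatenation
# ---------------------------------------------------------------------------


def concat_snps(
    sites: Sequence[Site], sample_order: Sequence[str]
) -> dict[str, str]:
    """Concatenate haploid SNP columns into one pseudo-sequence per sample.

    Columns follow (scaffold, position) order; missing calls become ``N``.
    Per-sequence character multisets are invariant under scaffold reordering,
    mirroring the observation that scaffold order and orientation do not
    change concatenated-SNP inferences.
    """
    ordered = sorted(sites, key=lambda s: s.key)
    seen: set[tuple[str, int]] = set()
    for s in ordered:
        if s.key in seen:
            raise ValueError(f"duplicated site {s.key}")
        seen.add(s.key)
    columns: list[list[str]] = []
    for s in ordered:
        alleles = (s.ref,) + s.alts
        col = []
        for gt in s.genotypes:
            if len(gt) != 1:
                raise ValueError("concat_snps requires haploid genotypes")
            a = gt[0]
            if a is None:
                col.append("N")
            else:
                base = alleles[a]
                if len(base) != 1:
                    raise ValueError(f"site {s.key} is not a SNP")
                col.append(base)
        columns.append(col)
    n_samples = len(sample_order)
    if columns and any(len(c) != n_samples for c in columns):
        raise ValueError("sample_order length does not match genotype columns")
    return {
        name: "".join(col[i] for col in columns) for i, name in enumerate(sample_order)
    }


def write_alignment_fasta(alignment: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# mutation-rate derivation and rescaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSpec:
    """Inputs of the Y mutation-rate derivation.

    ``mu_auto_per_gen`` is the genome-average per-generation rate,
    ``alpha`` the male-to-female mutation rate ratio, ``gen_time`` the
    generation time in years; ``seq_len`` and ``n_snp`` describe the sequence
    a concatenated-SNP alignment summarizes.
    """

    mu_auto_per_gen: float = 1.3e-8
    alpha: float = 2.0
    gen_time: float = 2.0
    seq_len: int | None = None
    n_snp: int | None = None

    def __post_init__(self) -> None:
        if self.mu_auto_per_gen <= 0:
            raise ValueError("mu_auto_per_gen must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.gen_time <= 0:
            raise ValueError("gen_time must be > 0")
        for name in ("seq_len", "n_snp"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")


def y_rate_per_year(spec: RateSpec) -> float:
    """Male-lineage substitution rate per bp per year.

    The Y passes only through males, so its per-generation rate is the
    autosomal average scaled by 2 alpha / (1 + alpha) (an autosome spends
    half its history in each sex); dividing by the generation time gives the
    per-year clock rate.
    """
    per_gen = spec.mu_auto_per_gen * 2.0 * spec.alpha / (1.0 + spec.alpha)
    return per_gen / spec.gen_time


def rescale_rate_for_concat(rate_seq_per_year: float, seq_len: int, n_snp: int) -> float:
    """Per-column rate for a concatenated-SNP alignment.

    Each retained SNP column stands for ``seq_len / n_snp`` monitored bases,
    so the per-column rate is the per-bp rate times that factor; a skyline or
    tree run on the concatenated alignment then sees the same expected number
    of mutations as the full sequence.
    """
    if seq_len <= 0 or n_snp <= 0:
        raise ValueError("seq_len and n_snp must be > 0")
    return rate_seq_per_year * seq_len / n_snp
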