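"""Synthetic genomes, sexed depth/read data, RH panels and VCFs with ground truth.

The generators emulate the study conditions every downstream stage is built
for, without requiring any external sequencing data:

* a scaffold pool of autosomal / X / Y origin, where exactly one Y scaffold
  may carry an X-derived ("X-transposed") segment of configurable fraction
  and per-base identity — the feature that makes Y identification hard;
* sex-dependent copy number (female 2 autosome / 2 X / 0 Y; male 2/1/1),
  expressed either as per-scaffold mean depths (fast) or as sampled short
  reads (for full end-to-end runs);
* radiation-hybrid retention vectors under Poisson breakage with independent
  fragment retention, call flips and ambiguous masking;
* haploid (or diploid) VCFs with a known number of records violating each
  hard-filter and site-level criterion, so survivor counts are exact
  bookkeeping rather than estimates.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSpec",
    "HomologyBlock",
    "LabeledScaffold",
    "make_genome",
    "copy_number",
    "DepthTable",
    "simulate_depths",
    "SimRead",
    "sample_reads",
    "write_fastq",
    "write_fasta",
    "RHPanelSpec",
    "RHPanel",
    "simulate_rh_panel",
    "VcfSimSpec",
    "VcfSimResult",
    "simulate_vcf",
    "HARD_FILTER_FIELDS",
    "SITE_FILTER_FIELDS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for a labeled scaffold pool.

    ``xy_homology_fraction`` of exactly one Y scaffold is copied from an X
    scaffold and degraded to ``xy_identity`` per-base identity, mimicking
    X-transposed regions whose high X similarity attracts female reads.
    """

    n_auto_scaffolds: int = 8
    n_x_scaffolds: int = 4
    n_y_scaffolds: int = 4
    scaffold_len_range: tuple[int, int] = (5_000, 10_000)
    xy_homology_fraction: float = 0.0
    xy_identity: float = 0.99
    gc: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_auto_scaffolds, self.n_x_scaffolds, self.n_y_scaffolds) < 0:
            raise ValueError("scaffold counts must be >= 0")
        lo, hi = self.scaffold_len_range
        if not 1 <= lo <= hi:
            raise ValueError("scaffold_len_range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.xy_homology_fraction <= 1.0:
            raise ValueError("xy_homology_fraction must be in [0, 1]")
        if not 0.0 <= self.xy_identity <= 1.0:
            raise ValueError("xy_identity must be in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.xy_homology_fraction > 0 and (
            self.n_x_scaffolds == 0 or self.n_y_scaffolds == 0
        ):
            raise ValueError(
                "xy_homology_fraction > 0 requires at least one X and one Y scaffold"
            )


@dataclass(frozen=True)
class HomologyBlock:
    """Half-open interval of a Y scaffold copied from ``donor_id`` (an X scaffold)."""

    start: int
    end: int
    identity: float
    donor_id: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LabeledScaffold:
    id: str
    sequence: str
    true_origin: str  # one of {"A", "X", "Y"}
    homology: HomologyBlock | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("scaffold sequence must be non-empty")
        if self.true_origin not in {"A", "X", "Y"}:
            raise ValueError(f"unknown origin {self.true_origin!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return rng.choice(_BASES, size=length, p=p)


def make_genome(spec: GenomeSpec) -> list[LabeledScaffold]:
    """Generate the scaffold pool described by ``spec`` (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.scaffold_len_range
    layout: list[tuple[str, str]] = []  # (id, origin)
    arrays: dict[str, np.ndarray] = {}
    for origin, n in (
        ("A", spec.n_auto_scaffolds),
        ("X", spec.n_x_scaffolds),
        ("Y", spec.n_y_scaffolds),
    ):
        for i in range(n):
            sid = f"{origin}_scaf_{i + 1:03d}"
            length = int(rng.integers(lo, hi + 1))
            arrays[sid] = _random_sequence(rng, length, spec.gc)
            layout.append((sid, origin))

    homology: dict[str, HomologyBlock] = {}
    if spec.xy_homology_fraction > 0:
        y_id = f"Y_scaf_{1:03d}"
        y_arr = arrays[y_id]
        block_len = int(round(spec.xy_homology_fraction * y_arr.size))
        if block_len > 0:
            donor_id = max(
                (sid for sid, origin in layout if origin == "X"),
                key=lambda sid: arrays[sid].size,
            )
            donor = arrays[donor_id]
            if block_len > donor.size:
                raise ValueError(
                    "homology block longer than the longest X scaffold "
                    f"({block_len} > {donor.size} bp)"
                )
            start = (y_arr.size - block_len) // 2
            block = donor[:block_len].copy()
            mutate = rng.random(block_len) >= spec.xy_identity
            if mutate.any():
                # substitute to a uniformly chosen *different* base
                shift = rng.integers(1, 4, size=int(mutate.sum())).astype(np.uint8)
                idx = np.flatnonzero(mutate)
                code = _CODE_OF_BASE[block[idx]]
                block[idx] = _BASES[(code + shift) % 4]
            y_arr[start : start + block_len] = block
            homology[y_id] = HomologyBlock(start, start + block_len, spec.xy_identity, donor_id)

    return [
        LabeledScaffold(
            sid,
            arrays[sid].tobytes().decode("ascii"),
            origin,
            homology.get(sid),
        )
        for sid, origin in layout
    ]


_CODE_OF_BASE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF_BASE[_b] = _i
del _i, _b


def copy_number(origin: str, sex: str) -> int:
    """Chromosome copy number of a scaffold origin in a female/male genome."""
    if sex not in {"male", "female"}:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if origin == "A":
        return 2
    if origin == "X":
        return 2 if sex == "female" else 1
    if origin == "Y":
        return 0 if sex == "female" else 1
    raise ValueError(f"unknown origin {origin!r}")


def write_fasta(scaffolds: Iterable[LabeledScaffold], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description=f"origin={s.true_origin}")
        for s in scaffolds
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# depth emulation
# ---------------------------------------------------------------------------

NOMINAL_READ_LEN = 150  # used only to convert coverage targets into read counts


@dataclass
class DepthTable:
    """Per-scaffold mean depth of one sample plus its total read count.

    ``total_reads`` plays the role of the sample's sequencing effort, the
    normalizer of the female/male depth-ratio statistic.
    """

    sex: str
    table: pd.DataFrame  # columns: scaffold_id, length, mean_depth
    total_reads: int

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["total_mapped_reads"] = self.total_reads
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sex: str = "unknown") -> "DepthTable":
        df = pd.read_csv(path, sep="\t")
        total = int(df["total_mapped_reads"].iloc[0])
        return cls(sex=sex, table=df[["scaffold_id", "length", "mean_depth"]], total_reads=total)


def _expected_depth_profile(
    scaffold: LabeledScaffold, sex: str, target_depth: float
) -> tuple[float, np.ndarray | None]:
    """(uniform expected depth, or per-position expectation for leaky scaffolds)."""
    base = target_depth * copy_number(scaffold.true_origin, sex) / 2.0
    blk = scaffold.homology
    if sex == "female" and scaffold.true_origin == "Y" and blk is not None and len(blk) > 0:
        # Female X reads split between the donor X and its Y homolog; the block
        # receives the single-copy-equivalent female depth scaled by identity.
        e = np.zeros(len(scaffold))
        e[blk.start : blk.end] = blk.identity * target_depth / 2.0
        return base, e
    return base, None


def simulate_depths(
    scaffolds: Sequence[LabeledScaffold],
    sex: str,
    target_depth: float,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DepthTable:
    """Emulate per-scaffold mean mapped depth for one sexed sample.

    Expected depth is ``target_depth x copy/2`` (autosome 2 copies both sexes,
    X 2/1, Y 0/1).  ``noise_cv`` is the coefficient of variation of a
    per-position multiplicative lognormal noise; scaffold means average it
    down by ~sqrt(length).  The X-homologous block of a Y scaffold leaks
    female depth proportionally to its identity.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma2 = math.log1p(noise_cv**2)
    sigma = math.sqrt(sigma2)

    rows = []
    for s in scaffolds:
        L = len(s)
        base, profile = _expected_depth_profile(s, sex, target_depth)
        if noise_cv == 0:
            mean = base if profile is None else float(profile.mean())
        else:
            noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=L)
            e = profile if profile is not None else base
            mean = float(np.mean(e * noise))
        rows.append((s.id, L, mean))
    df = pd.DataFrame(rows, columns=["scaffold_id", "length", "mean_depth"])
    total_reads = int(round(target_depth * df["length"].sum() / NOMINAL_READ_LEN))
    return DepthTable(sex=sex, table=df, total_reads=total_reads)


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimRead:
    """A simulated read; the id encodes its true source scaffold and position."""

    id: str
    sequence: str

    @property
    def source_scaffold(self) -> str:
        return self.id.rsplit("|", 2)[0]

    @property
    def source_pos(self) -> int:
        return int(self.id.rsplit("|", 2)[1])


def sample_reads(
    scaffolds: Sequence[LabeledScaffold],
    sex: str,
    depth: float,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SimRead]:
    """Uniform single-end reads at ``depth`` x coverage per chromosome copy.

    Fragments are drawn proportionally to scaffold length x copy number, so
    the sample's whole genome (sum of length x copy) is covered ``depth``
    times in expectation; per-base substitution errors at ``error_rate``.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    weighted = [(s, len(s) * copy_number(s.true_origin, sex)) for s in scaffolds]
    active = [(s, w) for s, w in weighted if w > 0]
    if not active:
        return []
    short = [s.id for s, _ in active if len(s) < read_len]
    if short:
        raise ValueError(f"read_len {read_len} exceeds scaffold length of {short}")
    rng = np.random.default_rng(seed)
    weights = np.array([w for _, w in active], dtype=float)
    genome_size = weights.sum()
    n_reads = int(round(depth * genome_size / read_len))
    counts = rng.multinomial(n_reads, weights / genome_size)

    reads: list[SimRead] = []
    for (s, _), cnt in zip(active, counts):
        if cnt == 0:
            continue
        arr = np.frombuffer(s.sequence.encode("ascii"), dtype=np.uint8)
        starts = rng.integers(0, len(s) - read_len + 1, size=cnt)
        windows = arr[starts[:, None] + np.arange(read_len)]
        if error_rate > 0:
            errs = rng.random(windows.shape) < error_rate
            if errs.any():
                shift = rng.integers(1, 4, size=int(errs.sum())).astype(np.uint8)
                code = _CODE_OF_BASE[windows[errs]]
                windows[errs] = _BASES[(code + shift) % 4]
        for i, (pos, row) in enumerate(zip(starts, windows)):
            reads.append(
                SimRead(f"{s.id}|{int(pos)}|{i}", row.tobytes().decode("ascii"))
            )
    return reads


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_coverage(
    reads: Iterable[SimRead], scaffold_lengths: Mapping[str, int], read_len: int
) -> dict[str, np.ndarray]:
    """Per-position coverage arrays reconstructed from read ids (no alignment)."""
    cov = {sid: np.zeros(L, dtype=np.int32) for sid, L in scaffold_lengths.items()}
    for r in reads:
        sid = r.source_scaffold
        if sid in cov:
            p = r.source_pos
            cov[sid][p : p + read_len] += 1
    return cov


# ---------------------------------------------------------------------------
# radiation-hybrid panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RHPanelSpec:
    """Geometry and noise of a radiation-hybrid panel.

    ``groups`` holds the physical marker positions of each linkage group (a
    single-element group is an intentionally unlinked marker).  Breaks fall as
    a Poisson process, so the breakage probability of an interval of length d
    is ``theta = 1 - exp(-break_rate * d)``; every resulting fragment is
    retained independently with probability ``retention_prob``.
    """

    groups: tuple[tuple[float, ...], ...]
    n_hybrids: int = 93
    retention_prob: float = 0.3
    break_rate: float = 1.0
    error_rate: float = 0.0
    ambiguous_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one marker group required")
        for g in self.groups:
            if len(g) == 0:
                raise ValueError("empty marker group")
            if any(b <= a for a, b in zip(g, g[1:])):
                raise ValueError("marker positions must be strictly increasing")
        if not 0.0 < self.retention_prob < 1.0:
            raise ValueError("retention_prob must be in (0, 1)")
        if self.break_rate < 0:
            raise ValueError("break_rate must be >= 0")
        for name in ("error_rate", "ambiguous_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_hybrids < 1:
            raise ValueError("n_hybrids must be >= 1")


@dataclass
class RHPanel:
    """Simulated panel: noisy call vectors plus the ground truth behind them."""

    spec: RHPanelSpec
    marker_ids: list[str]
    calls: dict[str, str]  # marker_id -> string over {H, A, ?} of length n_hybrids
    true_order: list[list[str]]  # per group, physical marker order
    true_theta: list[list[float]]  # per group, breakage prob per adjacent interval

    def vectors(self):
        from .rhmap import RHVector  # local import to avoid a cycle

        return [RHVector(mid, self.calls[mid]) for mid in self.marker_ids]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for mid in self.marker_ids:
                fh.write(f"{mid}\t{self.calls[mid]}\n")


def simulate_rh_panel(spec: RHPanelSpec) -> RHPanel:
    """Simulate retention vectors under random breakage with observation noise."""
    rng = np.random.default_rng(spec.seed)
    marker_ids: list[str] = []
    true_order: list[list[str]] = []
    true_theta: list[list[float]] = []
    for gi, positions in enumerate(spec.groups):
        ids = [f"g{gi + 1}m{j + 1:02d}" for j in range(len(positions))]
        marker_ids.extend(ids)
        true_order.append(ids)
        true_theta.append(
            [
                1.0 - math.exp(-spec.break_rate * (b - a))
                for a, b in zip(positions, positions[1:])
            ]
        )

    raw: dict[str, list[str]] = {mid: [] for mid in marker_ids}
    for _h in range(spec.n_hybrids):
        for gi, positions in enumerate(spec.groups):
            m = len(positions)
            theta = np.array(true_theta[gi])
            breaks = rng.random(m - 1) < theta if m > 1 else np.empty(0, bool)
            frag = np.concatenate(([0], np.cumsum(breaks)))
            retained = rng.random(int(frag[-1]) + 1) < spec.retention_prob
            present = retained[frag]
            if spec.error_rate > 0:
                flips = rng.random(m) < spec.error_rate
                present = present ^ flips
            mask = rng.random(m) < spec.ambiguous_rate if spec.ambiguous_rate > 0 else None
            for j in range(m):
                call = "?" if (mask is not None and mask[j]) else ("H" if present[j] else "A")
                raw[true_order[gi][j]].append(call)
    calls = {mid: "".join(v) for mid, v in raw.items()}
    return RHPanel(spec, marker_ids, calls, true_order, true_theta)


# ---------------------------------------------------------------------------
# VCF simulation
# ---------------------------------------------------------------------------

HARD_FILTER_FIELDS = ("QD", "MQRankSum", "FS", "ReadPosRankSum", "MQ", "SOR")
SITE_FILTER_FIELDS = ("maf", "call_rate", "multiallelic")

# clean-record annotation ranges: comfortably inside the pass region, and the
# violation ranges comfortably outside, so %g float rendering cannot move a
# record across a threshold between writing and re-reading.
_CLEAN_RANGES = {
    "QD": (5.0, 35.0),
    "MQRankSum": (-5.0, 5.0),
    "FS": (0.0, 30.0),
    "ReadPosRankSum": (-5.0, 5.0),
    "MQ": (45.0, 60.0),
    "SOR": (0.3, 2.5),
}
_VIOLATION_RANGES = {
    "QD": (0.0, 1.7),
    "MQRankSum": (-25.0, -12.8),
    "FS": (60.5, 120.0),
    "ReadPosRankSum": (-20.0, -8.3),
    "MQ": (5.0, 39.5),
    "SOR": (3.3, 8.0),
}


@dataclass(frozen=True)
class VcfSimSpec:
    """Recipe for a VCF with a known number of failures per filter criterion.

    ``n_violations_per_filter`` maps a field name (one of
    ``HARD_FILTER_FIELDS`` or ``SITE_FILTER_FIELDS``) to the number of
    records seeded to fail exactly that criterion; seeded sites are disjoint
    from each other and from the ``n_female_leak_sites`` placed on the
    female-observed exclusion list, so the expected survivor count is exact.
    """

    n_sites: int = 50
    n_samples: int = 24
    ploidy: int = 1
    maf_beta: tuple[float, float] = (0.8, 0.8)
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    missing_rate: float = 0.02
    n_violations_per_filter: Mapping[str, int] = field(default_factory=dict)
    n_female_leak_sites: int = 0
    contig: str = "Y_scaffold_1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 0 or self.n_samples < 1:
            raise ValueError("n_sites >= 0 and n_samples >= 1 required")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        bad = set(self.n_violations_per_filter) - set(HARD_FILTER_FIELDS) - set(
            SITE_FILTER_FIELDS
        )
        if bad:
            raise ValueError(f"unknown filter fields: {sorted(bad)}")
        if any(v < 0 for v in self.n_violations_per_filter.values()):
            raise ValueError("violation counts must be >= 0")
        n_seeded = sum(self.n_violations_per_filter.values()) + self.n_female_leak_sites
        if n_seeded > self.n_sites:
            raise ValueError("more seeded sites than n_sites")
        n_hap = self.n_samples * self.ploidy
        if self.n_violations_per_filter.get("maf", 0) > 0 and 1.0 / n_hap >= self.maf_min:
            raise ValueError(
                "a seeded MAF violation needs n_samples*ploidy > 1/maf_min "
                f"({n_hap} haplotypes cannot express 0 < MAF < {self.maf_min})"
            )


@dataclass
class VcfSimResult:
    vcf_path: Path
    exclusion_path: Path
    expected_survivors: int
    truth: pd.DataFrame  # columns: chrom, pos, category ('clean'/'female_leak'/field)


def _clean_genotypes(
    rng: np.random.Generator, spec: VcfSimSpec, *, n_missing: int | None = None
) -> tuple[list[tuple[int | None, ...]], int]:
    """Genotypes guaranteed biallelic, MAF >= maf_min, call rate >= call_rate_min."""
    n, p = spec.n_samples, spec.ploidy
    max_missing = int(math.floor((1.0 - spec.call_rate_min) * n))
    if n_missing is None:
        n_missing = min(int(rng.binomial(n, spec.missing_rate)), max_missing)
    n_obs_hap = (n - n_missing) * p
    a_lo = max(1, int(math.ceil(spec.maf_min * n_obs_hap)))
    a_hi = n_obs_hap - a_lo
    if a_lo > a_hi:
        raise ValueError("too few samples to express a clean biallelic site")
    maf = rng.beta(*spec.maf_beta) * (0.5 - spec.maf_min) + spec.maf_min
    a = int(np.clip(round(maf * n_obs_hap), a_lo, a_hi))
    hap = np.zeros(n_obs_hap, dtype=int)
    hap[rng.choice(n_obs_hap, size=a, replace=False)] = 1
    missing_samples = set(rng.choice(n, size=n_missing, replace=False).tolist())
    gts: list[tuple[int | None, ...]] = []
    k = 0
    for si in range(n):
        if si in missing_samples:
            gts.append((None,) * p)
        else:
            gts.append(tuple(int(x) for x in hap[k : k + p]))
            k += p
    return gts, n_missing


def simulate_vcf(spec: VcfSimSpec, out_dir: str | Path) -> VcfSimResult:
    """Write a VCF + female-exclusion list with construction-time survivor count."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    positions = np.sort(
        rng.choice(np.arange(1, max(spec.n_sites * 100, 1000)), size=spec.n_sites, replace=False)
    )
    categories = np.array(["clean"] * spec.n_sites, dtype=object)
    seeded: list[str] = []
    for fieldname, cnt in spec.n_violations_per_filter.items():
        seeded.extend([fieldname] * cnt)
    seeded.extend(["female_leak"] * spec.n_female_leak_sites)
    if seeded:
        idx = rng.choice(spec.n_sites, size=len(seeded), replace=False)
        categories[idx] = seeded

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={spec.contig},length={int(positions[-1]) + 1000 if spec.n_sites else 1000}>")
    for f in HARD_FILTER_FIELDS:
        header.add_line(f'##INFO=<ID={f},Number=1,Type=Float,Description="{f}">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for si in range(spec.n_samples):
        header.add_sample(f"S{si + 1:03d}")

    vcf_path = out_dir / "sim.vcf"
    excl_path = out_dir / "female_sites.tsv"
    exclusion: list[int] = []
    n_lost = 0
    bases = "ACGT"

    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for pos, cat in zip(positions, categories):
            ref, alt = rng.choice(4, size=2, replace=False)
            alleles = [bases[ref], bases[alt]]
            info = {f: round(float(rng.uniform(*_CLEAN_RANGES[f])), 4) for f in HARD_FILTER_FIELDS}
            if cat in HARD_FILTER_FIELDS:
                info[cat] = round(float(rng.uniform(*_VIOLATION_RANGES[cat])), 4)
                gts, _ = _clean_genotypes(rng, spec)
                n_lost += 1
            elif cat == "maf":
                n_hap = spec.n_samples * spec.ploidy
                hap = np.zeros(n_hap, dtype=int)
                hap[rng.choice(n_hap, size=1, replace=False)] = 1  # singleton: MAF = 1/n_hap
                gts = [
                    tuple(int(x) for x in hap[si * spec.ploidy : (si + 1) * spec.ploidy])
                    for si in range(spec.n_samples)
                ]
                n_lost += 1
            elif cat == "call_rate":
                n_missing = int(math.floor((1.0 - spec.call_rate_min) * spec.n_samples)) + 1
                if n_missing >= spec.n_samples:
                    raise ValueError("cannot seed a call-rate violation: panel too small")
                gts, _ = _clean_genotypes(rng, spec, n_missing=n_missing)
                n_lost += 1
            elif cat == "multiallelic":
                alt2 = [b for b in range(4) if b not in (ref, alt)][0]
                alleles.append(bases[alt2])
                gts, _ = _clean_genotypes(rng, spec)
                # promote one alt call to the second alt so three alleles are observed
                for si, g in enumerate(gts):
                    if any(x == 1 for x in g if x is not None):
                        gts[si] = tuple(2 if x == 1 else x for x in g)
                        break
                n_lost += 1
            else:  # clean or female_leak
                gts, _ = _clean_genotypes(rng, spec)
                if cat == "female_leak":
                    exclusion.append(int(pos))
                    n_lost += 1
            rec = vf.new_record(contig=spec.contig, start=int(pos) - 1, alleles=tuple(alleles))
            for f, v in info.items():
                rec.info[f] = v
            for si in range(spec.n_samples):
                rec.samples[si]["GT"] = gts[si]
            vf.write(rec)

    with open(excl_path, "w") as fh:
        for pos in exclusion:
            fh.write(f"{spec.contig}\t{pos}\n")

    truth = pd.DataFrame(
        {"chrom": spec.contig, "pos": positions.astype(int), "category": categories}
    )
    return VcfSimResult(
        vcf_path=vcf_path,
        exclusion_path=excl_path,
        expected_survivors=spec.n_sites - n_lost,
        truth=truth,
    )
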