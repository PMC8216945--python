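"""Reference simulation scenarios exercising the whole toolkit.

Each scenario wires the synthetic generators to the classifiers at the study
conditions the package is designed around, and returns the measured
quantities (accuracies, recovered group structure, survivor counts) so that
tests and reproduction scripts evaluate one shared, seeded configuration.
Problem sizes are desk-scale: hundreds of scaffolds for depth-based
classification, a ~100 kb genome for read-level k-mer profiling, a 93-hybrid
panel for RH mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import classify, rhmap, simdata

__all__ = [
    "ad_recovery",
    "ygs_recovery",
    "random_twopoint_tables",
    "rh_panel_geometry",
    "small_group_ordering",
    "vcf_replay_batch",
]


def _spawn(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, deterministic in ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# AD-ratio recovery (depth emulation, 200 scaffolds per origin)
# ---------------------------------------------------------------------------


def ad_recovery(
    seed: int,
    n_per_origin: int = 200,
    depth: float = 30.0,
    noise_cv: float = 0.1,
    homology_fraction: float = 0.5,
    homology_identity: float = 0.99,
) -> dict:
    """Classify a 3 x ``n_per_origin`` scaffold pool from simulated depths.

    Exactly one Y scaffold carries an X-derived block; its AD ratio should
    land between the Y window and the autosomal window (~fraction x identity),
    which is the motivation for the relaxed Y cutoff.
    """
    s_genome, s_f, s_m = _spawn(seed, 3)
    genome = simdata.make_genome(
        simdata.GenomeSpec(
            n_auto_scaffolds=n_per_origin,
            n_x_scaffolds=n_per_origin,
            n_y_scaffolds=n_per_origin,
            scaffold_len_range=(2_000, 4_000),
            xy_homology_fraction=homology_fraction,
            xy_identity=homology_identity,
            seed=s_genome,
        )
    )
    female = simdata.simulate_depths(genome, "female", depth, noise_cv, seed=s_f)
    male = simdata.simulate_depths(genome, "male", depth, noise_cv, seed=s_m)
    cfg = classify.ADConfig()
    table = classify.ad_table(female, male).set_index("scaffold_id")
    origin = {s.id: s.true_origin for s in genome}
    homolog_id = next(s.id for s in genome if s.homology is not None)

    calls = {
        sid: classify.classify_ad(row.ad, cfg, length=int(row.length))
        for sid, row in table.iterrows()
    }
    n_a = sum(1 for sid, o in origin.items() if o == "A")
    n_x = sum(1 for sid, o in origin.items() if o == "X")
    acc_a = sum(1 for sid, o in origin.items() if o == "A" and calls[sid] == "A") / n_a
    acc_x = sum(1 for sid, o in origin.items() if o == "X" and calls[sid] == "X") / n_x
    plain_y = [sid for sid, o in origin.items() if o == "Y" and sid != homolog_id]
    recall_y = sum(1 for sid in plain_y if calls[sid] == "Y") / len(plain_y)
    return {
        "n_scaffolds": len(genome),
        "accuracy_autosome": acc_a,
        "accuracy_x": acc_x,
        "recall_y_plain": recall_y,
        "homolog_ad": float(table.loc[homolog_id, "ad"]),
        "homolog_call": calls[homolog_id],
        "calls": calls,
        "ad_table": table,
    }


# ---------------------------------------------------------------------------
# YGS recovery end-to-end from reads
# ---------------------------------------------------------------------------


def ygs_recovery(
    seed: int,
    depth: float = 10.0,
    error_rate: float = 0.01,
    read_len: int = 150,
    min_count: int = 2,
) -> dict:
    """Read-level k-mer classification of a small scaffold pool.

    Reads of one male and one female sample are sampled at ``depth`` x per
    chromosome copy with ``error_rate`` substitutions, turned into canonical
    31-mer dictionaries, and compared against each scaffold's single-copy
    k-mers.  Includes the AD and homology votes needed for a consensus table.
    """
    s_genome, s_fr, s_mr, s_fd, s_md = _spawn(seed, 5)
    genome = simdata.make_genome(
        simdata.GenomeSpec(
            n_auto_scaffolds=6,
            n_x_scaffolds=5,
            n_y_scaffolds=5,
            scaffold_len_range=(8_000, 12_000),
            xy_homology_fraction=0.5,
            xy_identity=0.99,
            seed=s_genome,
        )
    )
    homolog_id = next(s.id for s in genome if s.homology is not None)
    origin = {s.id: s.true_origin for s in genome}

    reads_f = simdata.sample_reads(genome, "female", depth, read_len, error_rate, seed=s_fr)
    reads_m = simdata.sample_reads(genome, "male", depth, read_len, error_rate, seed=s_mr)
    dict_f = classify.build_kmer_dictionary((r.sequence for r in reads_f), min_count=min_count)
    dict_m = classify.build_kmer_dictionary((r.sequence for r in reads_m), min_count=min_count)
    singles = classify.single_copy_kmers({s.id: s.sequence for s in genome})
    profiles = {
        sid: classify.ygs_profile(sid, km, dict_f, dict_m) for sid, km in singles.items()
    }
    ygs_calls = {sid: classify.classify_ygs(p) for sid, p in profiles.items()}

    female = simdata.simulate_depths(genome, "female", 30.0, 0.1, seed=s_fd)
    male = simdata.simulate_depths(genome, "male", 30.0, 0.1, seed=s_md)
    cfg = classify.ADConfig()
    adt = classify.ad_table(female, male).set_index("scaffold_id")
    ad_calls = {
        sid: classify.classify_ad(row.ad, cfg, length=int(row.length))
        for sid, row in adt.iterrows()
    }

    # homology votes: every scaffold aligns to its true chromosome over 80% of
    # its length; the X-transposed Y block additionally aligns to X.
    hom_calls = {}
    for s in genome:
        target = {"A": "chr1", "X": "X", "Y": "Y"}[s.true_origin]
        hits = [classify.HomologyHit(s.id, target, int(0.8 * len(s)), 0.9)]
        if s.homology is not None:
            hits.append(
                classify.HomologyHit(
                    s.id, "X", int(0.99 * len(s.homology)), s.homology.identity
                )
            )
        hom_calls[s.id] = classify.classify_homology(hits, len(s))

    table = classify.consensus(ad_calls, ygs_calls, hom_calls)
    return {
        "genome": genome,
        "origin": origin,
        "homolog_id": homolog_id,
        "profiles": profiles,
        "ygs_calls": ygs_calls,
        "ad_calls": ad_calls,
        "hom_calls": hom_calls,
        "consensus": table,
        "n_reads_female": len(reads_f),
        "n_reads_male": len(reads_m),
    }


# ---------------------------------------------------------------------------
# two-point tables
# ---------------------------------------------------------------------------


def random_twopoint_tables(
    seed: int, n_tables: int = 100, n_hybrids: int = 93
) -> list[tuple[int, int, int, int]]:
    """Random 2x2 co-retention tables from the breakage-retention model."""
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n_tables:
        theta = float(rng.uniform(0.02, 0.98))
        r = float(rng.uniform(0.15, 0.85))
        d = theta * r * (1 - r)
        p = [r - d, d, d, (1 - r) - d]
        nhh, nha, nah, naa = rng.multinomial(n_hybrids, p)
        if nhh + nha + nah + naa == 0:
            continue
        tables.append((int(nhh), int(nha), int(nah), int(naa)))
    return tables


# ---------------------------------------------------------------------------
# RH panel geometry (29 markers, 93 hybrids)
# ---------------------------------------------------------------------------


def rh_panel_spec_29(seed: int, error_rate: float = 0.0, ambiguous_rate: float = 0.0
                     ) -> simdata.RHPanelSpec:
    """A 93-hybrid panel: two linkage groups (14 + 13 markers) + 2 singletons.

    Adjacent intervals are spaced so the per-interval breakage probability is
    0.05 (break_rate x spacing = -ln 0.95).  At 93 hybrids and retention 0.3
    the expected adjacent LOD is then ~21 with standard deviation ~2.7
    (4 sigma above the grouping threshold of 10, and neighbouring-but-one
    pairs at ~18 provide backup edges), while between-group and singleton
    pairs carry no linkage signal at all.
    """
    spacing = -math.log(0.95)  # theta = 0.05 at break_rate 1
    g1 = tuple(i * spacing for i in range(14))
    g2 = tuple(i * spacing for i in range(13))
    singles = ((0.0,), (0.0,))
    return simdata.RHPanelSpec(
        groups=(g1, g2) + singles,
        n_hybrids=93,
        retention_prob=0.3,
        break_rate=1.0,
        error_rate=error_rate,
        ambiguous_rate=ambiguous_rate,
        seed=seed,
    )


def rh_panel_geometry(seed: int, lod_threshold: float = 10.0) -> dict:
    """Simulate the 29-marker panel and recover its linkage-group structure."""
    panel = simdata.simulate_rh_panel(rh_panel_spec_29(seed))
    vectors = panel.vectors()
    pairwise = rhmap.pairwise_table(vectors)
    groups = rhmap.linkage_groups(vectors, lod_threshold=lod_threshold, pairwise=pairwise)
    singleton_ids = {panel.true_order[2][0], panel.true_order[3][0]}
    return {
        "panel": panel,
        "pairwise": pairwise,
        "groups": groups,
        "group_sizes": sorted((len(g) for g in groups), reverse=True),
        "true_groups": [set(panel.true_order[0]), set(panel.true_order[1])],
        "singleton_ids": singleton_ids,
    }


def small_group_ordering(
    seed: int, sizes: Sequence[int] = (5, 6, 7, 8, 8), theta_adjacent: float = 0.15
) -> list[dict]:
    """Noise-free small panels: heuristic vs exhaustive ordering vs truth."""
    spacing = -math.log(1.0 - theta_adjacent)
    out = []
    for child, size in zip(_spawn(seed, len(sizes)), sizes):
        spec = simdata.RHPanelSpec(
            groups=(tuple(i * spacing for i in range(size)),),
            n_hybrids=93,
            retention_prob=0.3,
            break_rate=1.0,
            seed=child,
        )
        panel = simdata.simulate_rh_panel(spec)
        vectors = panel.vectors()
        pairwise = rhmap.pairwise_table(vectors)
        markers = panel.true_order[0]
        heur = rhmap.order_markers(markers, pairwise, strategy="heuristic", seed=child)
        exact = rhmap.order_markers(markers, pairwise, strategy="exhaustive")
        truth = tuple(markers)
        out.append(
            {
                "size": size,
                "heuristic": heur,
                "exhaustive": exact,
                "truth": truth,
                "heuristic_matches_truth": heur.order in (truth, truth[::-1]),
            }
        )
    return out


# ---------------------------------------------------------------------------
# VCF filter replay
# ---------------------------------------------------------------------------


@dataclass
class VcfReplayCase:
    spec: simdata.VcfSimSpec
    result: simdata.VcfSimResult
    package_survivors: int


def _random_vcf_spec(rng: np.random.Generator, seed: int) -> simdata.VcfSimSpec:
    n_sites = int(rng.integers(10, 41))
    fields = list(simdata.HARD_FILTER_FIELDS) + list(simdata.SITE_FILTER_FIELDS)
    violations = {}
    budget = n_sites - 4
    for f in fields:
        k = int(rng.integers(0, 3))
        k = min(k, budget)
        if k > 0:
            violations[f] = k
            budget -= k
    n_leak = min(int(rng.integers(0, 3)), budget)
    return simdata.VcfSimSpec(
        n_sites=n_sites,
        n_samples=24,
        ploidy=1,
        missing_rate=0.02,
        n_violations_per_filter=violations,
        n_female_leak_sites=n_leak,
        seed=seed,
    )


def vcf_replay_batch(seed: int, n_specs: int, out_dir: str | Path) -> list[VcfReplayCase]:
    """Simulate ``n_specs`` random VCFs and run the package cascade on each."""
    from . import variants

    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    cases = []
    for i, child in enumerate(_spawn(seed + 1, n_specs)):
        spec = _random_vcf_spec(rng, child)
        result = simdata.simulate_vcf(spec, out_dir / f"case_{i:04d}")
        sites = variants.read_vcf(result.vcf_path)
        female = variants.read_exclusion_list(result.exclusion_path)
        report = variants.filter_cascade(sites, female)
        cases.append(VcfReplayCase(spec, result, report.n_survivors))
    return cases
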