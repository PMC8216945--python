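# Methods

This note documents the models behind each module, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical conventions (boundaries, tie-breaks, degenerate inputs) that a
user of the toolkit should know about.

## Sex inference from seed-region mapping rates

A male-specific **seed region set** is derived by comparing per-position
depth of known males and known females over a Y-candidate scaffold: a
position qualifies when every male sample has depth ≥ `min_male_depth`
(default 3) and every female sample has depth ≤ `max_female_depth` (default
0), and qualifying runs shorter than `min_run_len` (default 500 bp) are
discarded. The exact truncation rule behind published seed sets is not
standardized; maximal male-covered/female-empty runs are the simplest rule
that reproduces the behaviour of a fully male-specific scaffold yielding one
seed interval covering its whole length. Depth inputs must cover every
position (the `samtools depth -aa` convention), otherwise run boundaries are
meaningless.

An unknown sample is then sexed by the percentage of its reads mapping to
the seed set: **male** above 0.04% (strict inequality — "greater than"),
**female** at or below 0.00%, **ambiguous** in between (such samples should
be excluded rather than guessed). Both cutoffs are configurable; a small
positive `female_max` accommodates noisy mappers. The separation of the two
known-sex groups is quantified with a Welch (unequal-variance) two-sample
t-test; Welch is used because there is no reason to assume equal mapping-rate
variance in males and females. Degenerate input (both groups constant and
equal) returns p = 1 by contract. For simulated reads the package ships an
exact 31-mer containment screen (`sexing.seed_kmer_index` /
`count_mapped_reads`) as a deliberately simple stand-in for an aligner: a
read "maps" when at least `min_hits` of its canonical k-mers occur in the
seed index. It has no mismatch tolerance beyond what k-mer redundancy
provides, which is adequate at ≤ a few percent sequencing error.

## AD-ratio classification

For each scaffold, `AD = depth_f / (depth_m x norm)` with
`norm = total_reads_f / total_reads_m`. Depth averages include zero-coverage
positions. Classification windows: Y below 0.4, autosome strictly inside
(0.6, 1.4), X in [1.6, 2.4) — the lower X bound is treated as inclusive.
Everything else, including scaffolds shorter than `min_scaffold_len`
(default 1,000 bp, where mean depth is unstable) and scaffolds with zero
male depth, is *unassigned*: an undefined ratio is evidence of missing data,
never of Y linkage. A stricter `AD < 0.3` window is kept in the
configuration for positive-control checks only.

The relaxed 0.4 cutoff exists because of X-transposed Y segments: a block
copied from the X at identity q attracts female X reads, and the scaffold's
expected AD rises to roughly `fraction x q` (see the leakage model below).
At fraction 0.5 the scaffold already leaves the Y window — which is exactly
why the toolkit never relies on a single classifier.

## YGS-style k-mer classification

K-mers are canonical (a k-mer and its reverse complement collapse onto the
lexicographically smaller 2-bit encoding), k = 31 by default, packed into
uint64 and handled as flat sorted numpy arrays; windows containing non-ACGT
characters are skipped. A scaffold's informative set is its **single-copy**
k-mers: those occurring exactly once across the whole query scaffold pool
(configurable to per-scaffold uniqueness via `scope="per-scaffold"`). The
pool-level definition removes shared repeats everywhere; its side effect is
that a region duplicated *within the pool* (e.g. an X-transposed block when
the donor X scaffold is also queried) contributes no k-mers at all. When the
donor lives on the assembled reference instead, the block's k-mers stay
single-copy in the pool and are matched by female reads — the situation in
which the k-mer classifier genuinely weakens and the AD ratio must carry the
call (demonstrated in the test suite both ways).

Male and female read dictionaries keep canonical k-mers seen at least
`min_count` times (default 2, suppressing sequencing-error k-mers; at 1%
per-base error only ~73% of 31-mer observations are error-free, so error
k-mers outnumber real singletons at high depth). A scaffold is called Y when
its single-copy k-mers match the male dictionary at > 90% **and** the female
dictionary at < 10%. The figure-axis phrasing of the female criterion
("≥ 90% unmatched") is exposed as `female_rule="unmatched"`; the text rule
is the default. Scaffolds with no single-copy k-mers are undefined and
excluded from the call.

## Homology voting and consensus

Tabular best-hit alignments (scaffold, target chromosome, aligned bases,
identity) are summed per target over hits passing `min_identity` (default
0.8); a scaffold is called Y when the Y-target total is the **strict**
maximum and covers at least `min_cov_fraction` (default 0.5) of the
scaffold. Ties never call Y; no passing hits is a no-call, distinct from an
informative not-Y. The original similarity-search parameters are not
restated in the source method descriptions, so both thresholds are explicit
configuration with conservative defaults. The consensus table records, per
scaffold, which of the three methods voted Y, plus intersection (all three;
high confidence) and union (any; high sensitivity) membership. The N10–N90
ladder reports, for each decile x, the scaffold length at which the
cumulative sorted-descending length first reaches x% of the total, and how
many scaffolds that takes.

## Radiation-hybrid mapping

**Model.** Each hybrid retains donor fragments independently with
probability r; breaks between two markers occur with probability θ. Under
equal retention the pair probabilities are `P(H,H) = (1-θ)r + θr²`,
`P(H,A) = P(A,H) = θr(1-r)`, `P(A,A) = (1-θ)(1-r) + θ(1-r)²`. Ambiguous
('?') calls are dropped pairwise; r is estimated jointly per pair, not
globally.

**Estimation.** Writing d = θr(1-r), the model maps (θ, r) one-to-one onto
the trinomial (P(H,H), P(disc), P(A,A)) = (r-d, 2d, (1-r)-d), so the MLE is
closed-form: r̂ is the marginal retention frequency (2n_HH + n_disc)/2n and
θ̂ = [n_disc/2n] / (r̂(1-r̂)), clipped to [0, 1]. A clip to θ̂ = 1 lands
exactly on the unlinked submodel, so exact-independence tables report
LOD = 0 with no numerical tolerance games; n_disc = 0 gives θ̂ = 0 (perfect
co-segregation). LOD is log10 of the likelihood ratio against θ = 1 and is
clamped at 0 (the linked model nests the unlinked one). Distance is
`100 x (-ln(1-θ̂))` centiRays, additive under Poisson breakage; θ̂ = 1 pairs
get a 500 cR ceiling for ordering input but never create linkage edges. A
constant marker pair (r̂ at 0 or 1) carries no linkage information and is
reported unlinked.

**Grouping and ordering.** Linkage groups are single-linkage connected
components of the LOD ≥ threshold graph (default 10); singletons are
reported unlinked. Ordering minimizes the sum of adjacent distances — an
open-path TSP. Groups of up to 8 markers are solved exhaustively (mirror
orders skipped) and marked optimal; larger groups use multi-start
nearest-neighbour (every marker as a start, or 16 seeded starts) polished by
best-improvement 2-opt and Or-opt (segment lengths 1–3) until no move
improves. The heuristic is deterministic given its seed and can never return
worse than the best plain nearest-neighbour start. An order and its reverse
are equivalent; the returned orientation puts the lexicographically smaller
endpoint first.

**Error flagging.** With a fixed order, the map likelihood is chained along
adjacent intervals: per hybrid, log10 P(first call) plus log10 of each
conditional P(next | current) under the pair model, using per-interval θ̂
from adjacent two-point fits and the panel-wide retention frequency for r.
'?' calls are skipped, with the effective breakage probability across a gap
equal to 1 - Π(1-θ_i). A call is flagged when flipping it alone raises the
chained log10-likelihood by at least the threshold (default 3). In a map
with ~20 cR intervals a genuine isolated fragment loss gains only ~2 units
(unflagged), while in a tight map (~2 cR) an isolated discordance gains > 4
(flagged) — the threshold separates map density regimes exactly as intended.
The alternative reading of error flagging — count isolated double-break
singletons — is available as `mode="singleton"`.

## Variant cascade and mutation rates

Hard filters fail a record when any of QD < 2.0, MQRankSum < -12.5,
FS > 60.0, ReadPosRankSum < -8.0, MQ < 40.0, SOR > 3.0 holds — strict
inequalities, exactly as the filter expression reads, so records sitting
precisely at a threshold pass. Absent annotations never trigger their
condition (rank-sum statistics are routinely missing for sites without
heterozygous evidence); non-numeric annotations reject the record and are
counted separately. Female-observed site exclusion removes exact
(scaffold, position) matches — on a properly male-specific Y no female
sample can yield a call, so any female "Y" call betrays misassembled or
pseudoautosomal sequence; the operation is idempotent. Site filters keep
records with exactly two observed alleles, minor allele frequency ≥ 0.05
among observed haplotypes (inclusive), and call rate ≥ 90% of samples
(inclusive); a missing call is any genotype without an allele. The three
stages act on disjoint criteria, so their composition order does not change
the surviving set (verified by permuting stages on simulated VCFs).

Surviving haploid SNPs are concatenated into one pseudo-sequence per sample,
columns in (scaffold, position) order, missing calls as N. Scaffold order
and orientation only permute columns, so per-sequence character multisets
and pairwise Hamming distances are invariant — the property that justifies
running skyline/tree inference on concatenated SNPs regardless of how the
draft scaffolds were arranged.

The Y passes only through males, so its per-generation rate is the
genome-average rate scaled by 2α/(1+α), where α is the male-to-female
mutation rate ratio (an autosome spends half its history in each sex);
dividing by the generation time gives the per-year clock. Defaults
(1.3e-8/bp/generation, α = 2, 2 years) give 8.67e-9/bp/year. For a
concatenated alignment of n_SNP columns summarizing L monitored bases, each
column absorbs L/n_SNP bases of mutational opportunity:
`rate_concat = rate x L / n_SNP`. L is an explicit argument — it is the
length of sequence the SNPs were ascertained from, not something the
alignment itself records.

## Synthetic data: what it emulates, and what it does not

**Genomes.** Uniform-composition random scaffolds (GC configurable) labeled
A/X/Y; exactly one Y scaffold optionally carries a block copied from the
longest X scaffold, degraded to a per-base identity (mutated positions get a
uniformly random different base). This emulates X-transposed regions — the
one Y feature that actively confuses both depth and k-mer classifiers.

**Depths.** Expected scaffold depth is `target_depth x copy/2` (autosome 2
copies in both sexes, X 2/1, Y 0/1). `noise_cv` is the coefficient of
variation of *per-position* multiplicative lognormal noise (unit mean);
since the reported statistic is the scaffold mean, its CV shrinks to
~`noise_cv/sqrt(L)`. This models position-scale sampling and mappability
jitter around an unbiased mean; it deliberately does **not** model
scaffold-level mappability bias, GC bias or repeat pile-ups, which in real
data produce heavy AD-ratio tails — so perfect window recovery on simulated
depths shows the windows are consistent with the copy-number law, not that
real unplaced scaffolds are this clean. The X-homologous Y block receives
female depth `identity x target_depth/2` — the single-copy-equivalent female
X depth, modeling female X reads splitting between the donor X and the Y
homolog. The corresponding small depth loss on the donor X itself is
ignored (it would be at most a few percent on one scaffold and adds
bookkeeping without changing any classifier's behaviour). Reported total
read counts are `target_depth x Σ length / 150` for both sexes, playing the
role of sequencing effort in the AD normalizer.

**Reads.** Single-end reads of fixed length; `depth` is coverage per
chromosome copy, so total bases ≈ depth x Σ(length x copy) of the sample's
actual genome — a male Y scaffold at depth 10 is covered 10x and an
autosome 20x, matching how coverage accumulates on a haploid chromosome
when a male genome is sampled to a given per-copy depth. Fragments are
uniform within scaffolds, weighted by length x copy across them; errors are
uniform substitutions. No indels, no quality profiles, no platform bias, no
duplicates. Read ids encode the true source and position, which the test
suite uses to rebuild exact coverage without an aligner.

**RH panels.** Per hybrid and group, breaks fall independently between
adjacent markers with probability `1 - exp(-break_rate x distance)`
(Poisson process), fragments are retained independently with probability r,
calls are flipped at `error_rate` and masked '?' at `ambiguous_rate`
(missing at random — the real mechanism behind ambiguous assays is not
modeled). Retention is equal across fragments and hybrids; real panels show
centromere-proximal retention gradients the model omits.

**VCFs.** Sites are seeded as clean or as violating exactly one criterion
(one of the six hard-filter fields, MAF, call rate, or multiallelic), with
violation sites mutually disjoint and disjoint from female-leak sites, so
the expected survivor count is exact arithmetic. Clean sites draw MAF from
a Beta rescaled into [0.05, 0.5] and cap missingness at the call-rate
boundary. INFO floats are rounded to 4 decimals and kept ≥ 0.25 away from
every threshold so that text round-tripping cannot move a record across a
filter. A seeded MAF violation needs more than 1/maf_min haplotypes (a
smaller panel cannot express 0 < MAF < 0.05); `VcfSimSpec` validates this.

## Reference scenario sizes

The shipped scenarios (`msytools.scenarios`, used by the test suite and the
reproduction script) run at desk scale, chosen so each statistical check has
comfortable power: 200 scaffolds per origin of 2–4 kb at 30x for AD-window
recovery; a 16-scaffold, ~160 kb genome with 10x, 1%-error, 150 bp reads for
read-level k-mer classification (at 10x per copy, a Y k-mer is observed
error-free ≥ 2 times with probability ~0.98, putting the 90% male-match
cutoff ~5 sigma below the expected per-scaffold match rate); a 93-hybrid
panel of 14 + 13 linked markers spaced at ~5.1 cR plus two singletons (the
expected adjacent LOD of ~21 ± 2.7 keeps all within-group links above the
LOD-10 threshold, and between-group pairs carry no signal); and 1,000
random VCF specs of 10–40 sites x 24 haploid samples for filter bookkeeping.

## Known limitations

- The AD and YGS classifiers consume simulated depths/reads; the mapping
  and k-mer-counting behaviour of real aligners (multi-mapping heuristics,
  soft-clipping, quality trimming) is outside the model.
- The chained multipoint likelihood used for error flagging is a Markov
  approximation along the order — exact for the breakage-retention model
  when retention is equal, but not a full multipoint maximum-likelihood map.
- Diploid RH models, retention gradients and typing-batch effects are not
  implemented.
- `concat_snps` is haploid-only by design; diploid input raises rather than
  silently collapsing heterozygotes.
- The homology classifier trusts its input hit table; it does not run or
  validate an aligner.
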