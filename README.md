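# msytools

Toolkit for identifying, validating and exploiting Y-linked scaffolds in a
draft mammalian genome assembly, built around the strategy used to assemble
livestock Y chromosomes from existing short-read, radiation-hybrid and
resequencing data. Everything runs on synthetic data with known ground truth,
so each stage of the pipeline can be exercised and benchmarked without
terabyte-scale downloads.

## Who it is for

Genome assembly and population-genetics practitioners who have a pile of
unplaced scaffolds, sexed (or unsexed) short-read samples, an RH panel, and a
haploid variant call set — and need to answer, in order:

1. **Which samples are male?** Reads from females cannot map to male-specific
   sequence. Mapping rates against a male-specific *seed region* set separate
   the sexes by orders of magnitude (`sexing`).
2. **Which scaffolds are Y-linked?** Three independent classifiers with a
   consensus (`classify`):
   - **AD ratio** — normalized female/male mean depth:
     `AD = depth_f / (depth_m x norm)`, `norm = reads_f / reads_m`.
     Y ≈ 0, autosome ≈ 1, X ≈ 2; windows `AD < 0.4` (Y), `0.6 < AD < 1.4`
     (autosome), `1.6 <= AD < 2.4` (X). The Y window is deliberately relaxed
     because X-transposed Y segments (~99% identical to X) leak female depth.
   - **YGS profile** — the fraction of a scaffold's *single-copy* canonical
     31-mers found in male vs female whole-genome read dictionaries; Y calls
     require > 90% male and < 10% female matching.
   - **Homology voting** against an annotated related reference.
3. **In what order do the Y scaffolds sit?** Radiation-hybrid two-point
   analysis under the haploid equal-retention model
   `P(H,H) = (1-θ)r + θr²`, `P(H,A) = θr(1-r)`, LOD-threshold linkage
   grouping, and marker ordering as an open-path travelling-salesman problem
   with distances `100 x (-ln(1-θ̂))` centiRays (`rhmap`), plus
   likelihood-gain flagging of probable laboratory errors.
4. **Which Y SNPs are trustworthy, and at what clock rate do they tick?**
   GATK-style hard filters (`QD < 2.0 || MQRankSum < -12.5 || FS > 60.0 ||
   ReadPosRankSum < -8.0 || MQ < 40.0 || SOR > 3.0`), exclusion of any site
   also called in female samples, biallelic/MAF/call-rate site filters, SNP
   concatenation into a per-sample alignment, and male-lineage mutation-rate
   derivation `μ_Y = μ_auto x 2α/(1+α) / g` with per-column rescaling
   `μ_concat = μ_Y x L / n_SNP` (`variants`).

A first-class synthetic-data module (`simdata`) generates the genomes, sexed
depth tables and reads, RH panels and VCFs — with the ground truth needed to
verify every stage.

## Worked example

```python
from msytools import simdata, classify, variants

spec = simdata.GenomeSpec(
    n_auto_scaffolds=3, n_x_scaffolds=2, n_y_scaffolds=3,
    scaffold_len_range=(3000, 5000),
    xy_homology_fraction=0.5, xy_identity=0.99, seed=42,
)
genome = simdata.make_genome(spec)
female = simdata.simulate_depths(genome, "female", target_depth=30, noise_cv=0.1, seed=1)
male = simdata.simulate_depths(genome, "male", target_depth=30, noise_cv=0.1, seed=2)
table = classify.ad_table(female, male)
table["call"] = [classify.classify_ad(ad, length=int(L))
                 for ad, L in zip(table["ad"], table["length"])]
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
```

```
scaffold_id  length    ad       call
 A_scaf_001    3178 1.003          A
 A_scaf_002    4548 0.994          A
 A_scaf_003    3745 0.997          A
 X_scaf_001    3532 1.992          X
 X_scaf_002    4742 2.001          X
 Y_scaf_001    3343 0.495 unassigned
 Y_scaf_002    4177 0.000          Y
 Y_scaf_003    3813 0.000          Y
```

Autosomes sit at AD ≈ 1, X scaffolds at ≈ 2, and plain Y scaffolds at ≈ 0 —
all inside their windows. `Y_scaf_001` carries an X-derived block spanning
half its length at 99% identity, so female X reads leak onto it and push its
AD to ≈ fraction x identity = 0.495: too high for the Y window, which is why
the consensus also consults the k-mer and homology classifiers (and why the
Y cutoff is 0.4 rather than a stricter 0.3, which only positive controls are
held to).

The mutation-rate derivation:

```python
rate = variants.y_rate_per_year(variants.RateSpec())   # defaults: 1.3e-8, alpha 2, 2 y
print(f"{rate:.3g}")                                   # 8.67e-09 per bp per year
variants.rescale_rate_for_concat(rate, 5_690_000, 6_914)  # 7.13e-06 per SNP column
```

A Y chromosome passes only through males, so with a male-to-female mutation
rate ratio α = 2 it ticks at 2α/(1+α) = 4/3 of the genome average; dividing
by the 2-year generation time gives 8.67e-9 substitutions/bp/year. When 6,914
SNP columns stand in for a 5.69 Mb alignment, each column absorbs the
mutational opportunity of ~823 bp, giving 7.13e-6 per column per year.

The same functionality is exposed on the command line:

```bash
msy sim genome --spec genome.yaml --seed 5 --out sim/
msy sim depths --spec genome.yaml --sex female --depth 30 --out sim/
msy classify ad --female sim/depth_female.tsv --male sim/depth_male.tsv
msy rhmap group --panel panel.tsv --lod-threshold 10
msy snps filter --vcf calls.vcf --exclude female_sites.tsv --out survivors.tsv
msy snps rates --seq-len 5690000 --n-snp 6914
```

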