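# clonehet

Heterozygosity-based clonal lineage analysis for vegetatively
propagating plant genomes.

## The problem

Clonal plants — bamboos are the canonical case — can spread for
centuries without sexual reproduction. Somatic mutations then accumulate
in **heterozygous** state: each new mutation sits on one chromosome copy
and is inherited by every shoot descended from the cell lineage in which
it arose. Standard phylogenetics (which uses homozygous characters and
substitution models) has little power here, but the heterozygous calls
themselves carry the pedigree: *the exact set of samples sharing a
heterozygous locus is the clade of the branch on which the mutation
arose*.

`clonehet` turns that observation into a tested pipeline:

* **filters** — two auditable genotype-quality ladders: a WGS
  high-quality-SNP ladder (per-sample `[DP>4 ∧ GQ/RGQ>0] ∨ [DP=0]`
  gates, DP < 100, reference-read control exclusion, all-REF exclusion,
  MQ = 60 SNPs only) and a GRAS-Di amplicon ladder (hard annotation
  filters, newly-generated-HET extraction, GQ/QUAL and grove-structure
  filters);
* **intersections** — exact UpSet-style partition of loci by the sample
  set carrying a genotype class; pruning of monomorphic and singleton
  loci; conditioning on a focal sample; detection of outlier-peak
  combinations via a degree-stratified robust z-score
  (z = (count − median)/(1.4826·MAD), zeros included for unobserved
  combinations);
* **pedigree** — greedy extraction of the maximal nested chain
  S₁ ⊃ S₂ ⊃ … ⊃ S_k of elevated sets containing the focal sample (the
  divergence order), plus the conventional baselines: Ward.D2
  clustering with bootstrap support and PCA on the 0/0.5/1 encoding;
* **inheritance** — closed-form selfing segregation
  (p_HET = (1/2)^g; ratio 1:2:1 after one selfing, 3:2:3 after two),
  classification of homozygous-alternative loci (loss-of-heterozygosity
  signatures), and somatic mutation-rate estimation
  μ̂ = m/(L·T) with an exact Poisson 95 % interval;
* **simulate** — a forward simulator of the whole generative story:
  diverged-haplotype founder selfed g₀ times, clonal propagation along a
  dated tree with heterozygous gains (infinite sites) and HET→ALT
  conversion, selfed seedlings with recombination, and a noisy
  observation layer (negative-binomial depth, depth-dependent miscalls,
  amplicon dropout and PCR error in GRAS-Di mode).

Inputs are multi-sample diploid VCFs (`GT:DP:GQ`/`RGQ`; INFO `MQ`, `QD`,
`FS`, `MQRankSum`, `ReadPosRankSum`) or genotype-class TSV matrices.

## Worked example

Simulate eight clones propagating along a caterpillar pedigree (50-year
branches, elevated somatic rate so each branch carries ~25 mutations),
then run the full WGS analysis with sample `S8` as focal:

```bash
$ cat sim.json
{"genome_length": 200000, "somatic_rate": 2.5e-6, "depth_mean": 60.0, "seed": 7}

$ clonehet simulate --config sim.json --mode wgs --out simout
wrote 943 records for 8 clones to simout

$ clonehet analyze --vcf simout/observed.vcf --mode wgs --focal S8 --out analysis
filter stage sample_dp_gq_gate: 943 -> 942
filter stage sample_dp_lt_100: 942 -> 942
filter stage ref_control: 942 -> 942
filter stage all_ref: 942 -> 699
filter stage mq60_snp: 699 -> 699
missing policy drop: 699 -> 699 loci
pruned 354 monomorphic + 202 singleton; 143 kept
focal-HET conditioning on S8: 143 loci
6 elevated combinations (min_degree=2, z_cut=3.5)
divergence chain length 6
```

The funnel reads: 943 emitted sites → 699 after the ladder (the 243
removed are sites homozygous-reference in every sample) → 143
informative loci after pruning loci that are monomorphic among samples
(founder heterozygosity shared by all clones) or private to one sample
→ all 143 are heterozygous in S8. The text UpSet rendering
(`analysis/upset_HET.txt`):

```
# class HET: 143 loci, showing 6/6 combinations
  S S S S S S S S
  1 2 3 4 5 6 7 8
  . # # # # # # #        23 ======================
  . . # # # # # #        32 ==============================
  . . . # # # # #        24 ======================
  . . . . # # # #        24 ======================
  . . . . . # # #        19 ==================
  . . . . . . # #        21 ====================
```

Every elevated combination is a nested superset of `{S7,S8}`, so the
divergence chain (`analysis/divergence_chain.json`) recovers the true
order: S1 diverged first, then S2, …, with S7 the focal sample's sister
— exactly the simulated caterpillar.

The closed-form inheritance helpers print:

```bash
$ clonehet segregate --g 2
g=2  REF:HET:ALT = 3:2:3
probabilities REF=0.375 HET=0.25 ALT=0.375

$ clonehet rate -m 9 -L 6e6 -T 300
rate = 5e-09 /bp/yr (point 5.000e-09; 95% CI 2.29e-09 - 9.49e-09)
```

i.e. a heterozygous locus segregates 3:2:3 after two selfings, and nine
somatic mutations over a 6 Mbp surveyed region and 300 years correspond
to 5 × 10⁻⁹ mutations per base per year.

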