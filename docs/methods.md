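# Methods

## The problem

In long-lived clonal plants such as Moso bamboo (*Phyllostachys edulis*),
decades pass between flowering events and stands spread vegetatively.
Classical phylogenetic methods assume homozygous, sexually recombining
markers and perform poorly here: almost all polymorphism within a clone
is carried in heterozygous state, because somatic mutations arise on one
chromosome copy and are then propagated mitotically. `clonehet`
implements an analysis built directly on that observation: a somatic
mutation is heterozygous in exactly the descendants of the shoot on
which it arose, so the exact set of samples sharing a heterozygous call
at a locus is itself the phylogenetic signal.

## Genotype classes and filter ladders

Diploid calls are reduced to five classes relative to the reference:
REF (0/0), HET (0/x), ALT (x/x), OTHER (e.g. 1/2), MISSING (no call or
DP = 0).

Two quality ladders are implemented as ordered, auditable stages, each
reporting in/out counts and per-reason tallies.

**WGS high-quality-SNP ladder** — (1) every sample satisfies
[DP > 4 and RGQ > 0] or [DP > 4 and GQ > 0] or [DP = 0]; (2) every sample
has DP < 100; (3) loci flagged by re-sequencing of the reference
individual (called ALT or OTHER there) are removed, since the variant may
be a reference-assembly error; (4) loci where every sample is exactly REF
are removed (a MISSING call does not count as REF); (5) only SNPs with
site MQ exactly 60 — the maximum RMS mapping quality — are retained;
InDels and records without MQ are dropped and tallied separately.
Stages 1 and 2 are per-sample gates and commute; the order is fixed for
reproducible stage counts. Any absent annotation fails the gate that
needs it — conservative, and tallied so the loss is visible.

**GRAS-Di ladder** (genotyping by random amplicon sequencing) —
(1) loci with any sample at DP < 10 or missing GQ are removed;
(2) GATK-style hard filters: SNPs fail on QD < 2.0, FS > 60.0, MQ < 40.0,
MQRankSum < −12.5 or ReadPosRankSum < −8.0; InDels on QD < 2.0,
FS > 200.0 or ReadPosRankSum < −20.0; (3) "newly generated HET"
extraction keeps loci where at least one sample is HET and all others are
REF; (4) a genotype-quality condition: by default a locus is *kept* when
every HET sample has [20 ≤ GQ < 90 and QUAL ≥ 160] or [GQ ≥ 90]. The
protocol this ladder follows is phrased as a removal of such loci, which
would discard precisely the best-supported candidates; we read it as a
quality selection, and expose `filter2_literal=True` for the verbatim
reading; (5) loci whose HET samples form exactly one, two or three
complete groves are removed — a mutation uniformly present in whole
groves predates the grove planting and carries no information about
*new* within-grove variation. `grove_rule="count-only"` drops instead on
raw HET counts of 4, 8 or 12 (grove size four).

## Exact set-intersection analysis

`combination_counts` partitions the loci carrying a class by the *exact*
set of samples carrying it (the UpSet partition): each locus contributes
to exactly one sample combination, so counts sum to the number of
class-carrying loci. Rows are ordered degree-descending, then
count-descending, then lexicographically — byte-stable output.

Before counting, two cleaning steps mirror standard practice:
`prune_uninformative` removes loci monomorphic among samples (no signal)
and singleton loci (one sample HET with the rest REF, or one sample ALT
with the rest uniform — indistinguishable from private noise);
`condition_on_focal` keeps loci heterozygous in the focal sample, so
every combination speaks about the focal lineage.

**Missing data.** Loci containing any MISSING call are excluded from the
intersection analysis by default (`missing="drop"`); `missing="as-ref"`
recodes them as REF for the permissive alternative. The default avoids
inventing membership for samples that were simply not observed.

**Outlier-peak detection.** Within each degree d the locus counts of all
same-degree combinations are compared with a robust z-score,
z = (count − median) / (1.4826 · MAD). When the combination space
C(n, d) is at most 10⁶, unobserved combinations enter as zeros;
otherwise only observed combinations are used, and each flagged set
records which convention applied. Sparse degrees routinely have median
and MAD both zero; the scale then falls back to 1.4826 times the mean
absolute deviation from the median, keeping the statistic finite and
deterministic (if all counts are equal nothing is flagged). The default
threshold z ≥ 3.5 is the conventional robust-outlier cut; the full
same-degree distribution is always reported so the call can be audited.
A degree with fewer than three combinations is skipped with a warning.

## Divergence chain

Among elevated sets containing the focal sample, the maximal chain under
strict set inclusion is extracted greedily from the largest degree, ties
broken by higher count then lexicographic order. Sets that do not nest
are reported as residuals, never dropped: non-nesting elevated sets are a
warning that the data do not fit a single divergence order. The
interpretation contract: for consecutive chain sets S_i ⊃ S_{i+1}, the
samples in S_i \ S_{i+1} diverged from the focal lineage before the
interior of S_{i+1}.

## Baselines

* `encode_numeric`: REF → 0, HET → 0.5, ALT → 1.
* `bootstrap_cluster`: Ward linkage on Euclidean distances (the Ward.D2
  convention — squared distances inside the criterion; SciPy's `ward`
  on the observation matrix implements exactly this). Support values
  are ordinary bootstrap proportions over locus resamples with
  replacement — not multiscale-bootstrap approximately-unbiased
  p-values; they are known to be conservative for small clades.
* `pca_scores`: column-centred SVD; the largest-magnitude loading of
  each component is made positive, so signs are reproducible.
* `select_representatives`: per region, the sample closest (Euclidean,
  PC1–3) to the componentwise median of its region.

A seeded regression test pins the qualitative contrast that motivates
the chain method: when the focal sample carries a large private mutation
load, its distances to every other sample inflate and Ward clustering
separates it from its true sister, while the chain — which prunes
private singletons and uses only shared counts — recovers the order.

## Inheritance arithmetic

* `selfing_distribution(g)`: a heterozygous locus stays heterozygous
  with probability (1/2)^g after g selfings; the rest splits evenly
  between the homozygous classes. Ratios in smallest integers:
  1:2:1 (g = 1), 3:2:3 (g = 2). Verified against exact brute-force
  enumeration of gamete combinations for g ≤ 6.
* `classify_alt_loci`: ALT-containing loci partitioned by co-occurring
  classes (ALT only / ALT+HET / ALT+REF / all three), with a separate
  count of loci having exactly one ALT sample and all others HET — the
  signature of a single loss-of-heterozygosity conversion in a clone.
* `estimate_mutation_rate(m, L, T)`: point rate m/(L·T) per base per
  year, with an exact (Garwood) Poisson 95% interval on the count
  propagated to the rate. The interval is an extension beyond the usual
  point-estimate presentation and is labelled as such in output.
* `convert_per_generation_rate`: divides a per-generation rate by the
  generation time in years (e.g. 8.51 × 10⁻⁸ per generation over 67
  years → 1.3 × 10⁻⁹ per base per year).

## The forward simulator

The simulator generates data with exactly the structure the analysis
assumes, plus controllable violations.

**Founder.** Two parental haplotypes differ at ~Binomial(L, d) sites
(default d = 0.003, the observed magnitude of variant density in Moso
bamboo); an F1 is selfed g0 times (default 2, matching the inference
that the widespread clone is an F2/F3 of a cross between diverged
*Phyllostachys* haplotypes). Meiosis draws Poisson(`map_length`)
crossovers per scaffold with uniform positions and no interference —
the simplest model producing the observed block mosaic of heterozygous
and homozygous runs. After g0 selfings a fraction (1/2)^g0 of divergent
sites remains heterozygous.

**Clonal propagation.** On a branch of t years, heterozygous gains
arrive as Poisson(μ·L·t) (default μ = 5 × 10⁻⁹ /bp/yr, the magnitude
estimated for Moso bamboo) under the infinite-sites convention: a drawn
position colliding with any segregating or previously mutated site is
redrawn and the redraw counted. This guarantees the clade-sharing
property the analysis relies on — the exact leaf set carrying a somatic
mutation is the clade of its branch. Each existing HET site converts to
ALT with probability 1 − exp(−ρ·t), a memoryless per-year model of
loss of heterozygosity via homologous-recombination repair. The default
ρ = 7 × 10⁻⁸ per heterozygous locus per year makes conversions roughly
1% of gains under the default founder, echoing the observed rarity of
ALT calls within the clone; conversions are applied at the start of a
branch, before that branch's gains.

**Seedlings.** g selfings of the founder with the same meiosis model;
founder-HET loci segregate with `selfing_distribution(g)` across
seedlings (loci are linked within a seedling, so the seedling count is
the effective sample size for frequency checks).

**Observation layer.** Read depth is negative-binomial with mean
`depth_mean` and dispersion k (variance m + m²/k), truncated at
`depth_cap` = 99 — the DP < 100 analysis gate targets repeat/CNV
pileups, which the simulator does not model. DP = 0 yields MISSING. A
true heterozygote with depth dp is miscalled homozygous with probability
2·(1/2)^dp (all reads sampling one allele). In GRAS-Di mode only an
amplicon panel covering `amplicon_fraction` of the genome (default
0.005, the scale of a ~6 Mbp panel on a gigabase genome) is observable;
each allele of a heterozygote independently fails to amplify with
probability `dropout_prob` (one failure → confident wrong homozygote;
two → missing), and panel sites that are REF in all samples acquire
per-sample false HET calls with probability `pcr_error_prob`. **The
dropout and PCR-error defaults (0.1 and 10⁻⁶) are placeholders**: no
empirical rates for GRAS-Di are established, and any study of artifact
sensitivity should scan these parameters rather than trust the
defaults. Error-free sites are emitted with MQ = 60, QD 20–35, FS 0–3,
rank sums in (−2, 2), QUAL 200–2000, GQ 90–99 at variant calls and
RGQ 30–99 at reference calls (GQ in GRAS-Di mode, whose genotyped VCFs
carry GQ everywhere) — all inside the filter-ladder pass bands. A
fraction `artifact_fail_frac` (default 0.9) of PCR-artifact sites is
instead emitted with MQ in (20, 40) and QD < 2 so the hard filters can
catch them. Annotation distributions are a modelling choice: real
callers specify thresholds, not distributions, so only the pass/fail
geometry is meaningful.

Identical config (including seed) gives bit-identical output; the VCF
writer formats floats explicitly for that reason. Coordinates are
0-based half-open internally and 1-based in VCF output.

**What the simulator does not emulate.** Read-level errors, indel
realization, mapping ambiguity, reference-assembly haplotype mosaicism,
linked selection and demography are all absent. Passing tests therefore
show that the analysis is correct *under its own assumptions* and robust
to the modelled artifact classes — not that those are the only artifact
classes in real amplicon data.

## Problem sizes and numerical choices

Validation runs use genomes of 20 kb–1 Mb, 8-leaf clone trees and
100–200 replicates — large enough that every stochastic check has ≥ 20
expected events per branch or ≥ 2,000 observations, while the whole
suite runs in well under a minute. Tolerances on stochastic checks are
3 standard errors with the effective sample size chosen to respect
correlation structure (replicates, seedlings or blocks — never raw
locus-pairs). Chain inference, table ordering and tie-breaks are fully
deterministic; all randomness flows from a single integer seed through
named `numpy` generator streams (founder 0, propagation 1, seedlings 2,
observation 3).

## Known limitations

* The elevated-set test is a robust outlier rule, not a calibrated
  hypothesis test; it presumes that most same-degree combinations are
  noise.
* Bootstrap support is an ordinary proportion; no multiscale correction.
* The GRAS-Di artifact parameters are placeholders (above).
* `prune_uninformative` evaluates singletons against non-missing calls
  only; with heavy missingness the singleton rule becomes permissive.
* The divergence chain assumes a single introduction/divergence order;
  reticulate histories surface only as residual non-nested sets.
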