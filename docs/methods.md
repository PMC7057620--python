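# Methods

This note documents the models behind `herdcnv`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and encodings

All genomic intervals are 1-based and closed (the rawcnv convention): a
segment from SNP *i* to SNP *j* has length `end − start + 1`; BED export
converts to 0-based half-open. Genotypes are B-allele dosages (0/1/2, −1
missing). CNV marker alleles are N (normal, one copy per haplotype), D
(deletion, zero copies) and P (duplication, two copies); the diploid copy
number is the sum of the two haplotype contributions, so the tri-allelic
genotype map is exactly (D,D)→0, (N,D)→1, (N,N)→2, (N,P)→3, (P,P)→4. Mixed
(D,P) pairs are not produced by the default simulator configuration; the
encoding has no category for them.

## Synthetic population

**Pedigree.** Discrete generations; each generation forms `n_founders // 2`
sire×dam pairs sampled from the previous generation with
`offspring_per_mating` offspring each. Birth order is total and
generation-consistent, which is all the oldest-80% reference split needs.
The demo uses 60 founders × 4 generations × 2 offspring (300 animals); the
linkage-extremes analyses use 30 founders × 5 generations × 3 offspring,
i.e. larger half-sib families, the structure under which reference panels
actually carry repeated copies of each local haplotype in cattle.

**SNP map.** Uniform random positions per chromosome (demo: 3 × 5,000 SNPs
on 100 Mb chromosomes). The GC fraction of the ±500 kb window around each
SNP is emulated as an AR(1) series (autocorrelation 0.995 per SNP step)
squashed into [0.30, 0.60]; only its smoothness and its correlation with
LRR matter to the GC-wave adjustment, so no real genome track is used.

**Haplotypes.** Founder haplotypes are independent Bernoulli draws from
per-SNP B-allele frequencies sampled from a configurable MAF spectrum
(default uniform 0.05–0.5, the ascertainment-biased spectrum typical of
commercial panels). Meiosis places Poisson crossovers at
`recomb_rate_per_mb` (default 0.01/Mb, ~1 crossover per 100 Mb chromosome).
A parallel array tracks the founder-haplotype origin of every site, giving
an exact local identity-by-descent lineage.

**CNV loci.** Intervals are drawn from a configurable length law (the demo
plants fixed 15-SNP loci; a lognormal in bp is available) and must span ≥3
HD SNPs. Linkage with the flanking haplotype is controlled per locus:

- `perfect` — the CNV allele is carried by exactly one founder-haplotype
  lineage at the locus midpoint, so the local flanking haplotype identifies
  carriers deterministically (the regime in which imputation can work);
- `independent` — carrier haplotypes are chosen uniformly at random,
  independent of the flanking alleles (the no-information regime);
- `("tagged", r)` — carrier status equals the lineage indicator with
  probability `r`, otherwise it is redrawn at the lineage frequency, giving
  carrier–lineage correlation ≈ `r` (pass `r = √0.5` for r² ≈ 0.5).

Realized carrier fractions are constrained to a configurable range.
Defaults in the recovery analyses use 8–15%: loci that clear a ≥30-carrier
selection threshold in a ~1,000-animal breed sit at a few percent
frequency, and the behaviour of any imputer at the independent extreme
depends strongly on this (see "Known limitations").

**Signals.** LRR at a SNP with copy number `cn` is
`state_lrr_means[cn] + gc_wave_coef · (gc − mean gc) + N(0, state_lrr_sds[cn])`
with the conventional state means (−3.5, −0.66, 0, 0.40, 0.68) and
standard deviations (1.3, 0.28, 0.21, 0.21, 0.26); all configurable, since
no array-specific values are being reproduced. BAF concentrates at `b/cn`
for `b` B-allele copies with Gaussian noise (default sd 0.04) truncated to
[0,1], and is uniform where both copies are deleted (no probe
hybridization). Genotype calls come from the two underlying SNP alleles.

**Defects and QC.** Missingness is Bernoulli per genotype cell. Mendelian
defects plant opposing-homozygote conflicts at a fraction of SNPs in a
fraction of parent–progeny pairs (default 5%, above the filter threshold so
planted SNPs are removable). The QC filter drops SNPs with call rate < 95%
or opposing-homozygote inconsistency in > 2% of parent–progeny pairs,
fractioned over pairs where both members are genotyped.

## CNV caller

States are copy numbers 0–4, state 2 normal. Emissions: a Gaussian in LRR
per state; a BAF mixture over the `b/cn` cluster means with binomial
weights at the SNP's population B-allele frequency, half-normal boundary
clusters at 0 and 1 (avoiding degenerate point masses), a 1% uniform
outlier component, and a uniform BAF law for state 0. Transitions: the
probability of leaving the current state over an inter-SNP gap `d` is
`p_event · (1 − exp(−d / L))` — a one-parameter geometric length prior with
scale `L` (`expected_cnv_length_bp`, default 100 kb; the Bayes-factor
caller personality uses 500 kb). Leaving a CNV state returns to normal with
probability 0.95. Defaults (`p_event = 1e-4`) were chosen for clear
separation: planted 15-SNP CNVs at default noise are recovered at ≥ 0.8
reciprocal overlap for well over 90% of carrier instances while CNV-free
animals produce ≤ 2 calls per 10,000 SNPs (both recomputed by
`scripts/acceptance.py`).

Decoding is exact Viterbi, vectorized across animals; ties in the backtrace
resolve toward the normal state (conservative calling), and the test suite
checks the decoded score against brute-force enumeration of all 5^L paths.
Maximal runs of a constant non-normal state with ≥ 3 SNPs become calls;
shorter runs are discarded, not merged. The GC wave is removed per animal
by simple least-squares regression of LRR on the GC track (level
preserved); the artifact being removed is a correlation, so plain
regression suffices and no quantile/wave machinery is used. The Bayes factor attached
by the `quanti_like` personality is the log10 likelihood ratio of the
called state against the normal state summed over the segment's SNPs — an
additive, monotone segment-support score, not a full objective-Bayes
treatment.

## Concordance

Each HD call is compared with the same animal's MD calls on the same
chromosome: `direct` requires identical start and end coordinates (the
strictest reading of "same genomic position"), `partial` any intersection,
`none` otherwise; the best-overlapping MD call wins with ties to the
leftmost. Copy-number state is deliberately ignored — the comparison is of
genomic position. Summaries report per-category counts, linear-interpolation
quartiles of length (kb, closed-interval convention) and SNP count, the
population frequency of each exact call region, one-way ANOVA across
categories, and two fractions: HD calls with no MD counterpart, and HD
calls whose region holds < 3 MD SNPs — regions in which an MD call is
impossible by the ≥3-SNP rule. The MD panel is a seeded systematic
thinning keeping exactly `floor(fraction · n)` SNPs (default fraction
45,677 / 713,162), or an explicit SNP-id list emulating a commercial
manifest.

## Imputation experiment

Consensus CNVs pair calls from the two caller personalities on the same
animal and chromosome when both endpoint SNP indices differ by ≤ 1 and the
copy numbers agree (greedy by position, each call used once, merged
interval = union). Consensus CNVs group into population loci by region;
grouping is exact by default, with a configurable bp tolerance — the demo
pipeline uses 50 kb (~2–3 inter-SNP gaps at its density) because caller
boundary jitter otherwise splits one planted locus into several groups.
Loci carried by ≥ 30 animals within a breed are selected, per breed.

Each selected CNV becomes a variant at `floor((start+end)/2)`. The flank
window takes the k nearest SNPs strictly left and right of the midpoint
(k ∈ {10, 25, 50, 100, 250, 500} supported; SNPs inside the CNV are
eligible by design; a chromosome end truncates a side with a log note; the
demo uses k ∈ {10, 25, 50}, matched to its 5,000-SNP chromosomes). The
oldest 80% of the breed by birth order is the reference population, the
rest validation, the same split for every mode and k.

The imputer is a diploid Li–Stephens-style haplotype-copying model over the
reference haplotypes, evaluated on the flank window with the marker as one
extra, unobserved column. Transitions factorize per haplotype
(`T = (1−ρ)I + (ρ/H)J`, switch rate ρ = 0.01 per window SNP); genotype
emissions allow an error rate of 0.002; both are standard small-panel
values and configurable. The forward–backward posterior over ordered
haplotype pairs is aggregated into N/D/P allele-pair classes at the marker
and the posterior-mode unordered pair is returned; copy number follows from
the encoding map. A second preset (`window`) scores haplotype pairs by
squared dosage error over the window and takes a softmax-weighted vote —
a sliding-window-matching stand-in in the same contract. Both are
deterministic given their inputs. Reference panels are deterministically
thinned to 200 haplotypes by even subsampling for tractability. Reference
marker alleles are phased onto haplotypes using the simulator's true phase
when consistent with the called genotype, otherwise the non-normal allele
goes on the first haplotype (orientation only matters for heterozygotes);
with real data, trio-resolvable cases would be used and ambiguous reference
animals dropped. Opposing-homozygote marker conflicts in sire–progeny pairs
are counted and logged, never auto-corrected.

## Evaluation

Per-CNV, per-called-state accuracy is `n_correct / n_called` over
validation animals (the "times called in validation" denominator); the
alternative denominator — all validation animals of the breed — is
available as `denominator="all_validation"`, since the two readings differ
and both are legitimate. The adjusted Rand index (Hubert–Arabie,
pair-counting form) is computed per breed over all validation-animal ×
selected-locus pairs, pooling states; the degenerate single-cluster case
returns 0 with a log note. ANOVA families (flank count, called state,
breed) each use Tukey HSD internally with no cross-family correction.
Pearson correlations (accuracy vs population frequency and vs length)
carry Fisher r-to-z 95% intervals, `tanh(atanh(r) ± 1.96/√(n−3))`, and are
called different from zero only when the interval excludes zero. The
Bayes-factor comparison is a two-level one-way ANOVA (correctly vs
incorrectly imputed CNV instances) per breed and pooled, with the direction
of the mean difference. Tables use linear-interpolation quantiles
(stated in the report footer); the high-accuracy listing applies the 85%
threshold to non-normal called states.

## Reproducibility

Every stage draws its generator from the root seed plus the stage name
hashed into a `SeedSequence` substream, so adding a stage never perturbs
earlier stages' randomness. Outputs are written with fixed float
formatting; the run manifest records SHA-256 checksums of every artifact,
and re-running an identical config reproduces identical checksums (tested
byte-for-byte).

## Problem sizes

The demo and test configurations are desk-scale by design: 3 × 5,000 SNPs,
300 animals, 12 loci for the calling/concordance analyses; 1 × 1,500 SNPs,
~255 animals, 3 loci for the linkage-extremes analyses; k up to 50. The
machinery accepts field-scale inputs (700k-SNP maps, thousands of animals,
k to 500), but nothing at that scale is claimed or reproduced here:
published empirical results at that scale derive from proprietary
genotypes that are not available.

## Known limitations

- The caller is a clean-room 5-state HMM in the conventional parameter
  space, not a numerical re-implementation of any published tool; no claim
  of call-level identity with PennCNV/QuantiSNP is made.
- At the independent-LD extreme, any posterior-mode imputer's pooled
  accuracy sits near the majority-class frequency only when the marker is
  rare; at high carrier frequency the gap to the majority baseline grows
  like f(1−f). The package therefore evaluates the LD gradient on
  deletion-state accuracy, which carries the signal unconfounded by the
  majority class, and runs the extreme-LD analyses at realistic (rare)
  frequencies.
- The simulator's BAF/LRR noise model is Gaussian per state with a linear
  GC wave; real arrays show heavier tails, batch waves and probe-specific
  biases, so passing tests bound behaviour under the stated model only.
- Breeds are simulated as fully independent populations; admixture and
  cross-breed reference panels are out of scope, as are X/Y chromosomes,
  mosaic states and trio-aware calling.
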