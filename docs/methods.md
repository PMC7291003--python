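# Methods

## Data model

Genotypes are diploid biallelic autosomal SNP calls held as an allele-dosage
matrix (samples × markers) over {0, 1, 2, missing}, counting copies of the
minor allele by default. Orientation never matters for any statistic
implemented here (r², homozygosity, MAF are all invariant to swapping
0 ↔ 2 at a marker); the minor-allele convention just makes files
deterministic. Coordinates are 1-based inclusive; only BED export converts
to 0-based half-open. Markers are sorted by (chromosome, bp) at load and all
downstream code assumes that order.

## Quality control

Five filters, each reporting its removals so any ordering is auditable:
marker call rate ≥ 0.95, sample call rate ≥ 0.95, MAF ≥ 0.05, Hardy–Weinberg
exact-test p ≥ 1e-4, and PI_HAT < 0.5. The default order is the listing
above; the order is configurable because published pipelines differ in
whether HWE precedes MAF.

The HWE test enumerates the conditional distribution of the heterozygote
count given the allele counts and sums probabilities ≤ that of the observed
table (a chi-square variant with 1 df is available). Monomorphic markers
return p = 1: they cannot deviate.

Relatedness uses method-of-moments IBD: observed IBS0/1/2 counts over
jointly non-missing markers are equated to their expectations under IBD
state 0/1/2 given plug-in sample allele frequencies; P(IBD=k) are clipped to
[0,1] and renormalized. No small-sample bias correction is applied — at the
thousands of markers this package targets the correction is negligible
against the decision threshold (0.5). Pruning is greedy from the
highest-PI_HAT pair down, dropping the lower-call-rate member (ties: the
later sample in file order), which makes the pruned set reproducible.

## ROH calling

A window of `window_snps` (50) consecutive SNPs passes if it has at most
`max_het_per_window` (1) heterozygous and `max_missing_per_window` (1)
missing calls. A SNP is in-run when the fraction of covering windows that
pass is ≥ `window_hit_fraction` (0.05). Only windows fully inside a
chromosome are slid; SNPs near the ends are covered by fewer windows and the
fraction uses the actual covering count, so short chromosomes (fewer SNPs
than one window) degrade gracefully to a single truncated window rather than
erroring. Maximal in-run stretches are split wherever two consecutive SNPs
are > `max_gap_kb` (1000) apart, then filtered on `min_snps` (10) and
`min_length_kb` (1000). Segment length is end − start + 1 bp; the +1 is
immaterial at Mb scale but fixed for determinism.

Two consequences of the window design are intentional and documented rather
than "fixed": a final segment may contain an isolated heterozygote if every
window spanning it still passes, and no SNP-density criterion is applied
beyond the gap rule (a density option exists, default off). With
`window_snps = 1` and `window_hit_fraction = 1` the caller reduces exactly
to a brute-force maximal-run scan, which is how it is verified (200 random
instances in the test suite).

Size classes: short [1, 5) Mb, intermediate [5, 10) Mb, long ≥ 10 Mb.

## LD and effective population size

r² is the squared Pearson correlation of unphased dosages (composite LD)
over the samples non-missing at both markers, for all same-chromosome pairs
within 10 Mb; pairs with fewer than 4 complete observations or a
zero-variance marker are skipped and counted. The implementation computes
all pairwise complete-case moments with matrix products, so no per-pair
Python loop is involved.

Sved's relation Ne = (1/4c)(1/E(r²) − 1) converts bin-mean r² to Ne, and
t = 1/(2c) labels the generation depth each bin reflects. Distance bins are
formed, by default, in *physical* units — 100, 200, 500, 1000, 2000,
5000 kb, each ±5% — with c = bin length (Mb) × chromosome cM/Mb / 100; the
generation labels use the nominal genetic targets (0.1 cM → 500
generations). This convention is what reproduces published per-chromosome
tables built on chromosome-level cM/Mb conversion; a genuinely-genetic
binning mode (`units="genetic"`) is selectable because table headers and
method texts in this literature are ambiguous between the two. The
genome-wide row is the unweighted mean of per-chromosome Ne values (not a
pooled-pairs estimate), and the genome-wide cM/Mb is the unweighted mean of
the chromosome rates; both choices are verified against the bundled
reference table, whose 108 Ne cells reproduce to ±0.1. No sample-size
correction is subtracted from E(r²) by default (the reference arithmetic
uses none); a 1/n correction flag exists.

## Inbreeding coefficients

* **F_PED**: recursive kinship f(a,b) = ½[f(sire_a, b) + f(dam_a, b)] with
  f(a,a) = ½(1 + F_a); founders (including unknown parents) are unrelated
  and non-inbred. F_PED of an individual is the kinship of its parents.
  Verified against single-locus gene-dropping on random looped pedigrees.
* **F_HOM** = (O − E)/(L − E) per sample, with E the sum over the sample's
  genotyped markers of 1 − 2pq·n/(n−1) (unbiased expected homozygosity;
  the uncorrected variant is available), p the panel frequency, n the
  non-missing allele count at the marker.
* **F_ROH** = ΣL_ROH / L_auto, with L_auto defaulting to 2,478,445 kb (the
  pig autosomal assembly length) and configurable; class-restricted values
  partition the total exactly because every segment has exactly one class.

Spearman comparisons use average ranks with a two-sided t-approximation
p-value (exact permutation available for n ≤ 10). Comparisons across
coefficient sets use the sample intersection and report n.

## ROH islands

Pooling is exact breakpoint decomposition: all segment endpoints on a
chromosome cut the pooled ROH into atomic intervals, each supported by the
set of samples whose ROH covers it entirely; adjacent intervals with equal
support merge back. This makes "fraction of individuals containing the
region" well-defined and exactly conserves per-bp counts (Σ region length ×
support = Σ segment lengths), which the tests assert on random cohorts.
Islands are the regions whose coverage ranks in the top `top_fraction`
(default 1%): k = ⌈fraction × N⌉ regions are kept plus all ties at the
cutoff coverage, and touching islands are merged. The empirical percentile
is rank/N (not (rank+1)/(N+1)); the choice is configurable. The
homozygosity track reports, per fixed 100-kb window, the fraction of samples
whose ROH covers ≥ half the window (any-overlap and full-coverage rules are
selectable, since published figures rarely state theirs).

## Synthetic data

The gene-dropping generator assigns every founder gamete a unique label and
transmits label mosaics through the pedigree with Haldane recombination
(Poisson crossover count with mean = chromosome length in Morgans, uniform
breakpoints, no interference, no sex differences). Autozygous truth is
computed on the *continuous* label mosaics — tract ends are exact
recombination breakpoints, not marker positions — so marker density affects
only what the ROH caller can see, never the truth itself. Genotypes are read
off by assigning each founder haplotype Bernoulli(p) alleles with
p ~ Uniform(0.05, 0.5) per marker (founders in linkage equilibrium: LD in
descendants arises only from pedigree structure, which keeps LD-based tests
interpretable). Genotyping error (symmetric flip) and missingness default to
0 so truth comparisons are exact unless noise is requested.

The Wright–Fisher simulator holds a constant diploid population of size
Ne_true under random mating (parents drawn with replacement), with the same
recombination model, and finally generates `sample_n` offspring from the
last parental generation — so a 200-animal genotyping cohort can be sampled
from a population of 50, as in a cross-sectional breeding survey.

The default genome emulates the target chip: 18 autosomes of 137,691,389 bp
(total 2,478,445 kb), 2,793 markers each (~50k), 1.1057 cM/Mb everywhere.
Tests and analysis drivers use `scaled_config()` — fewer chromosomes at the
same marker density (e.g., 6 × 100 Mb with ~830–2,030 markers each) — chosen
as the smallest genomes on which tract-level recovery statistics are stable.

What the generator does *not* emulate: real chips' uneven marker spacing and
ascertainment bias, population-level LD in founders, crossover interference,
sex chromosomes, and genotype-calling artifacts correlated along the genome.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to array artifacts.

## Recovery experiments and their sizes

* Full-sib-mating truth: 500 independent single-offspring families; the mean
  true autozygous fraction must sit within 3 SE of 0.25.
* F_ROH vs truth: 200 offspring (50 families × 4, mixed designs with
  F ∈ {0, 1/16, 1/8, 1/4}), ~5,000 markers; Spearman ρ > 0.8 (observed
  ≈ 0.99). The same cohort shows ρ(F_ROH long, F_HOM) > ρ(F_ROH short,
  F_HOM), the expected signature of recent inbreeding in long ROH.
* Ne recovery: true Ne = 50, 200 generations (= 4·Ne, the equilibrium
  guideline), 200 sampled diploids, 4 chromosomes × 400 markers, 10
  replicate simulations. The 5-cM-bin mean r² is pooled over replicates
  (pair-count weighted) before applying Sved's formula; per-replicate Ne is
  convex in E(r²), so averaging per-replicate estimates would be biased
  upward (≈ +28% at these sizes) while the pooled estimate lands within a
  few percent of truth. The acceptance band is ±40%.

## Numerical choices and degenerate inputs

* HWE uses log-gamma arithmetic with a 1+1e-12 slack when accumulating
  probabilities "≤ observed", avoiding float-order artifacts; all p-values
  for tables with n ≤ 50 match exact rational enumeration.
* Empty QC output at any step raises rather than silently propagating an
  empty matrix; all-missing markers are counted as their own removal class.
* estimate_ne rejects E(r²) ∉ (0,1] and c ≤ 0; empty distance bins are
  reported with n_pairs = 0 and excluded from genome-wide means.
* Duplicate marker positions keep the first occurrence with a warning;
  duplicate marker ids are an error.
* pool_overlaps on an empty segment set returns an empty region table;
  islands on all-tied coverages return everything, flagged degenerate.
* All simulators are deterministic given (config, seed); derived seeds stay
  below 2³¹.

## Known limitations

* PI_HAT omits the finite-sample IBS correction, so estimates on very few
  markers (hundreds) are noisier than PLINK's; the pruning threshold path is
  unaffected at chip scale.
* The ROH caller is the classical sliding-window heuristic, not an HMM;
  window parameters interact with marker density, and the defaults assume
  ~50k-chip density.
* Ne estimates inherit all the assumptions of Sved's closed form (constant
  Ne per bin, no mutation, no admixture) and are known to be sensitive for
  t below ~7 generations; the trajectory therefore stops at t = 10.
* F_PED treats every unknown parent as a unique non-inbred founder; with
  shallow pedigrees this underestimates inbreeding relative to genomic
  measures, which is precisely the discrepancy the coefficient comparison
  is designed to expose.
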