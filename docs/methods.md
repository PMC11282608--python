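# Methods

`hetscan` detects heterozygous-enriched regions (HERs, also called runs of
heterozygosity) in diploid biallelic SNP data, aggregates them into
population-level HER islands, and validates the islands with diversity
statistics.  This note records the model, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## The run model

For one individual and one chromosome, genotypes are an ordered sequence of
dosage codes (0 hom-ref, 1 het, 2 hom-alt, −1 missing) at strictly
increasing physical positions.  A HER is a maximal stretch of SNPs that

1. starts and ends on a heterozygous SNP (non-het flanks are trimmed);
2. contains at most `max_hom` homozygous SNPs anywhere inside (total, not
   consecutive) and at most `max_miss` missing calls;
3. has no two physically consecutive SNPs farther apart than `max_gap`
   (a positional constraint, applied regardless of genotype);
4. after trimming, spans at least `min_snp` SNPs and at least `min_length`
   bp, with length defined as `end − start` (the convention that reproduces
   the published island lengths this package checks against).

The scan is *consecutive* (window-free) and greedy: starting from the first
unconsumed heterozygous SNP, the run is extended until the next extension
would exceed a tolerance or cross a gap, closed at the last heterozygous SNP
reached, and scanning resumes after it.  `min_snp`/`min_length` are
post-filters; they never change the segmentation.  The greedy rule is
deterministic and pinned by an exhaustive maximal-window enumerator in the
test-suite on all small instances tried.  One consequence worth knowing:
with a nonzero homozygote tolerance the left-to-right closure is
directional — reversing a chromosome can regroup the same heterozygous SNPs
into different runs (e.g. `H·hom·H·hom·H` with `max_hom = 1`).  Mirror
symmetry holds exactly only for tolerance-free runs, and is asserted only
there.

The scanner jumps from tolerance violation to tolerance violation using
sorted index arrays, so its cost scales with the number of runs rather than
the number of SNPs; a 648-scenario grid on 200 individuals × 20,000 markers
runs in about a minute on one core because scenarios sharing
(`max_gap`, `max_hom`, `max_miss`) reuse one genome scan.

Missing genotypes (including half-missing VCF calls such as `./0`) never
count as homozygous, may appear inside a run up to `max_miss` (default 1),
and count toward the SNP span.

## Parameter presets

* `FULL_GRID` — 648 scenarios: `min_snp` {5, 10, 15, 20, 25, 30} ×
  `max_gap` {500 Kb, 1 Mb, 2 Mb} × `min_length` {10, 25, 50, 100, 500,
  1000 Kb} × `max_hom` {0…5}.
* `ADDITIONAL_SCENARIOS` — nine scenarios named `5_0`…`5_2`, `10_0`…`10_5`
  (`min_snp`_`max_hom`), all at `max_gap` 500 Kb and `min_length` 10 Kb.
  These are the scenarios intersected when calling islands.
* `BREED_COMPARISON_PARAMS` — `min_snp` 10, `max_gap` 500 Kb, `min_length`
  10 Kb, `max_hom` 2, used for cross-population island comparison.

## Islands

The per-SNP incidence track of a scenario is the fraction of individuals
with at least one run covering the SNP.  A SNP is *supported* when its
incidence is at least the threshold (default 10%, inclusive) in **every**
scenario; consecutive supported SNPs at most `merge_gap` apart (default
500 Kb, matching the preset `max_gap` — the merge rule was an open design
choice) form one island whose boundaries are the first and last supported
SNP.  A lone supported SNP is discarded: an island is an interval and needs
`end > start`.  Island length statistics use `end − start` with the sample
(n−1) standard deviation.

Within-island LD is the squared Pearson correlation of genotype dosages
(0/1/2) over individuals with both sites called, averaged over the strict
upper triangle of defined pairs.  Dosage correlation, rather than
EM-estimated haplotype frequencies, is the appropriate choice for unphased
genotypes; pairs with fewer than two complete observations or zero variance
are undefined and excluded.

Cross-population comparison judges shared-ness from the reference side: a
reference island is shared when it intersects any island of the other set
by at least 1 bp, and the percentage in common divides by the reference
island count.

## Diversity statistics

* Observed heterozygosity: het calls / called individuals per site.
  Expected heterozygosity: 2p(1−p) with p the alternate-allele frequency
  among called alleles.
* Per-site nucleotide diversity: π = 2j(k−j)/(k(k−1)) for j alternate among
  k called alleles — the probability that two alleles drawn without
  replacement differ; equivalently π = 2p̂(1−p̂)·k/(k−1).
* Tajima's D in non-overlapping windows anchored at position 1 (default
  10 kb; the window size is a free parameter):
  D = (π − S/a₁) / √(e₁S + e₂S(S−1)), with S the count of sites polymorphic
  among called alleles, π the window sum of per-site π, and the standard
  constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ computed from
  n = 2 × (maximum called individuals at any site in the window).  Windows
  with S = 0, or fewer than four usable sequences, report D as NaN rather
  than a value.
* Rank correlations are Spearman's ρ with average ranks for ties over
  paired non-missing entries; a constant vector makes ρ undefined (NaN with
  a warning).

## Quality control

Sites are removed when the call rate (fraction of non-missing genotypes,
the PLINK convention) is below 0.95, when they duplicate an earlier
chrom+pos (first record kept), when they are non-autosomal, or when the
position is missing/non-positive.  Each removed site is attributed to one
reason, with precedence unknown-position → non-autosomal → duplicate →
call-rate, so the report counts reconcile exactly.  The filter is
idempotent.

## The synthetic population

`default_study_config(seed)` defines the reference simulation used by the
test-suite and the acceptance script: 200 individuals, two 5-Mb
chromosomes at one marker per 500 bp (a sequence-like density at desk
scale), and five planted islands of 40–60 Kb in which half the individuals
("carriers") are heterozygous with probability 0.95 per site.  Background
genotypes are Hardy–Weinberg draws at alternate-allele frequencies sampled
uniformly from the minor-allele band [0.05, 0.5] with a random allele
flip; genotyping error (0.001 per call, a symmetric flip to a uniformly
chosen other state) and missingness (0.01) are applied last.  Positions
are a sorted uniform draw without replacement.  Everything is reproducible
from one integer seed.

What this emulates: excess observed heterozygosity concentrated in known
intervals across a known fraction of individuals, panel-vs-sequence marker
density (via `thin_to_panel`), genotyping error breaking runs, and
missingness.  What it does not emulate: linkage and recombination maps
(sites are independent given their frequencies, so background LD is near
zero), a realistic site-frequency spectrum (the uniform frequency band
produces positive Tajima's D genome-wide; planted islands are higher
still), multi-allelic sites, and any explicit model of how heterozygous
stretches are inherited.  Passing tests therefore demonstrate that the
detector, the island caller and the statistics behave as specified on data
with known truth — not that the biological interpretation of any real
dataset is settled.

## Problem sizes and numerical choices

The test-suite and the acceptance script run the full 648-scenario grid,
the nine-scenario island call and windowed Tajima's D on the 200 × 20,000
reference simulation, and check the scanner against an exhaustive
enumerator on thousands of random 20-SNP chromosomes; these sizes keep a
complete run in a few minutes on one core while leaving every code path
exercised.  Oracle comparisons use 1e-9 absolute tolerance (the
computations are closed-form); interval bins are left-closed right-open;
ties in Spearman use average ranks; length bins below 10 Kb go to an
explicit below-range bucket.

## Known limitations

* No sliding-window (fixed-width) detection mode, and no run-of-
  homozygosity mode, although the scanner generalises directly.
* No PLINK binary (bed/bim/fam) input; VCF only.
* LD is dosage-based only; an EM haplotype-frequency estimator is a
  possible extension.
* Island calling assumes all scenario tracks share one site set.
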