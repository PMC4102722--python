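# Methods

## The problem and the study design

A monozygotic twin pair discordant for a disease is a natural experiment: the
co-twins share their germline genome, so a genotype difference between them is
either a postzygotic (somatic) event or an artifact. `mosatwin` implements the
comparison workflow for the two designs such studies use:

* **four-sample design** — blood and affected-tissue biopsy from both twins;
  three pairwise comparisons are run (affected biopsy vs affected blood,
  affected blood vs healthy blood, affected biopsy vs healthy biopsy), and the
  two samples not in a comparison serve as held-out evidence for arbitration;
* **two-sample design** — blood from both twins; one comparison, no held-out
  samples, no twin-differential CNV cascade.

Because the interesting signal is rare and the error modes are well
characterised, the package ships a first-class synthetic-data generator with
planted truth rather than relying on real data: every detector and filter is
validated by recovery experiments against that truth.

## Genotype model

Reads with mapping quality below `min_mq` (default 10) are discarded. For a
diploid genotype g = {a₁, a₂}, each remaining read of base b and quality Q
contributes ½P(b|a₁) + ½P(b|a₂), with P(b|a) = 1−e for a match and e/3
otherwise, e = 10^(−Q/10). Log-likelihoods are summed over at most
`max_depth` = 500 reads (beyond this the posterior is saturated; the cap
bounds numerics) and reported phred-scaled over the ten diploid genotypes with
the minimum pinned to exactly 0. Call quality is the phred gap to the
second-best genotype. Sites with fewer than 8 usable reads are flagged
low-confidence; zero usable reads is a *no-call*, deliberately distinct from a
hom-ref call. The genotype prior is flat — a heterozygosity-weighted prior
(θ, default 10⁻³) exists behind `prior="het"` but is off so that results carry
no hidden constants.

## The genotype-difference (somatic) score

With flat-prior posteriors P(g|A), P(g|B) computed independently per sample,

    P(same) = Σ_g P(g|A) · P(g|B),   score = min(255, round(−10 log₁₀ P(same))).

Posterior independence across samples (no shared-genotype prior coupling) is a
deliberate choice: it is the simplest reading of a "Bayesian comparison of
genotype likelihoods" and makes the score a pure function of the two pileups.
The score is rounded to the nearest integer *before* the 255 cap; when
P(same) underflows to 0 in double precision the score is 255 by definition.
Score 100 corresponds to a difference probability of 1 − 10⁻¹⁰; the default
pass threshold is score > 100.

## Fisher detectors

`fisher_allele_test` computes the classic two-sided Fisher's exact p-value on
the 2×2 (ref, alt) × (sample A, sample B) table: with margins fixed, table k
has probability C(n_A, k)·C(n_B, c_ref − k)/C(n, c_ref), and the p-value sums
every table whose probability does not exceed the observed one. The sum is
done on integer numerators over the common denominator, so ties are resolved
exactly rather than through floating-point epsilons; the result is converted
to float once at the end. The pass rule is p < 0.01 *and* zero variant-allele
reads in the reference sample (the second clause is what keeps shared
germline heterozygotes out of the candidate list).

The filtered variant drops observations with base quality < 20 or mapping
quality < 20 and zeroes an allele whose supporting reads span fewer than 3
distinct alignment start points — stacked duplicate-like evidence is the
signature of PCR and misalignment artifacts. These filter values are
conservative defaults (the filter *kinds* are standard; no canonical values
exist) and are configurable in `DetectorThresholds`.

No multiple-testing correction is applied: the design is a raw p < 0.01
screen followed by arbitration, and the pipeline report states the number of
tests performed so users can post-correct if they prefer.

## Query-position selection and arbitration

In the four-sample design, candidate sites are restricted to variants (a) not
called in all four samples, (b) not called in both biopsies, (c) not called in
both bloods, and (d) with population frequency ≤ 0.20 or unknown — a common
variant visible across the pair is germline, not somatic.

Arbitration assigns each passing candidate one verdict and never promotes:

1. **artifact** — the detector statistic no longer passes when recomputed on
   realigned pileups. This automates the manual-realignment review of
   indel-adjacent false positives: reads spanning an unmodelled insertion
   deposit spurious mismatches at nearby positions, and realignment collapses
   them.
2. **low-coverage** — the reference sample has < 8 usable reads, so the
   variant's absence there is uninformative.
3. **artifact** (cross-sample veto) — the variant allele appears at ≥ 5%
   frequency in a held-out sample of the reference twin. A difference between
   the affected twin's blood and the healthy twin's blood cannot be somatic if
   the healthy twin's biopsy carries the allele. The veto deliberately never
   consults the *affected* twin's other tissue, which may legitimately carry a
   twin-discordant event.
4. **confirmed-candidate** — everything else.

## CNV calling and the differential cascade

Window depth is the summed per-base coverage in a 100 bp window, simulated as
Poisson(mean depth × window size × copy ratio). Samples are scaled to unit
median (removing library-size effects) and divided by the mean of the scaled
background panel per window ("average ratio against the background controls";
a median-centred variant sits behind `background_center="median"`). Windows
with ratio < 0.62 are loss calls and > 1.38 gain calls — the one-copy
expectations being 0.5 and 1.5 — and maximal same-direction runs, extended
over uncalled gaps while support stays ≥ 80%, become regions kept at ≥ 20
windows, ≥ 80% support and a mean ratio beyond the threshold.

The cascade: stage 1 pairs affected-twin regions with ≥ 90% reciprocal
overlap and merges each pair as its *intersection* (conservative bounds;
union would inflate candidates). Stage 2 removes candidates with any ≥ 1 bp
overlap with a healthy-twin region, regardless of direction (a
direction-sensitive mode exists behind a flag). Stage 3 removes loss
candidates whose mean mappability uniqueness is below 0.5 — depth drops in
non-unique sequence are alignment artifacts, not deletions. An audit records
counts surviving each stage. LOH support for a loss requires ≥ 5 informative
sites and a carrier heterozygote fraction below half the other sample's;
fewer sites yield the explicit verdict "insufficient".

## Risk model

The carriership score is S = Σ_j c_j ln(OR_j) with c_j ∈ {0, 1, 2} risk-allele
copies. Natural log is the default (per-carrier counting and other log bases
sit behind flags; the reported surface is the *percentile*, so the base choice
cannot silently mislead). Missing loci are skipped, never imputed, and
`n_loci_used` is always reported. Percentiles are midrank,
100·(below + ties/2)/n, against a control distribution stamped with a hash of
its locus subset; comparing a score against a distribution built from a
different subset raises, since a 133-locus score is incommensurable with a
44-locus one. Under Hardy–Weinberg equilibrium the control mean and variance
have closed forms Σ 2f_j ln OR_j and Σ (ln OR_j)² 2f_j(1−f_j), which the
tests check against simulation.

## What the generator emulates — and what it does not

Emulated: shared germline variation (binomial SNV count at 0.1%/bp diversity;
het:hom 2:1, a typical resequencing figure), substitution spectra (transition
probability titv/(titv+1), 2.1 genome-wide and 2.8 inside CDS), Poisson depth
at 40× (the 36–48× band of genome sequencing, configurable per sample, to 72×
for exomes), constant Q30 base errors flipping to a uniform wrong base, a
bimodal mapping-quality mix (2% of reads at MQ 5), somatic events at
configurable VAF in configurable sample subsets (default 0.5, clonal; the
mosaic-VAF option reflects dilution when pooled biopsies carry an event in
only some cells), the indel-misalignment pileup signature (encoded directly in
pileup space — the artifact is fully characterised by its pileup signature, so
no aligner is needed in the loop), CNVs as windowed depth perturbations with a
58-sample background panel, and a 1,920-control HWE cohort.

Not emulated: read-level FASTQ/SAM structure, platform error profiles
(colorspace, cycle effects), GC/bait coverage bias, tumour-like subclonal
phylogenies, and learned base-quality profiles. Passing recovery tests
therefore demonstrates the *statistical machinery* is correct under the stated
noise model, not that real-data artifact rates are matched; on real data the
arbitration and filtering stages carry proportionally more weight.

Pileups are generated only at requested positions (truth sites plus any extra
sites of interest), since every downstream statistic is per-site; this keeps
megabase-scale recovery runs in seconds. Every stage draws from its own RNG
stream keyed by (stage label, master seed), so adding a stage never perturbs
earlier output and a fixed seed is byte-stable.

## Numerical and design notes

* Likelihoods are computed in log10 space and renormalised; the brute-force
  linear-space enumeration agrees to 10⁻¹⁰ relative on ≤ 20-read pileups.
* Fisher p-values are exact rationals until the final float conversion.
* Top-k ranking ties break by (contig, position) lexicographically; the
  cross-method Venn counts use (contig, pos, test sample, reference sample)
  as call identity. Ranking can be pooled or per comparison.
* The alt allele at a site is the most frequent non-reference base across the
  two compared pileups, ties broken lexicographically.
* Reports serialise floats at 6 decimals and sort keys, so identical
  configurations yield byte-identical reports.
* The depth-ratio caller with the region filters above replaces genome-scale
  z-score callers; the cascade itself is caller-agnostic and accepts external
  region lists in BED form, so two-caller designs remain representable.
* "Window" is the unit of region support throughout (the bait-level support
  filter of exome callers maps onto 100 bp windows here).

## Problem sizes used by the test suite

Recovery experiments run on a 1 Mb genome at 40× (≈ 1,000 germline SNVs, 20
planted somatic events at VAF 0.5) over 10 seeds, plus 10 event-free seeds;
CNV recovery plants two 25-window one-copy events among 1,500 windows over 10
seeds; spectrum recovery draws ~100,000 SNVs; the risk checks use 133 loci,
1,920 controls and 10 subject seeds. These sizes give comfortable
Monte-Carlo margins for every asserted tolerance while keeping the suite
fast.

## Known limitations

* Indel genotyping is out of scope; indels appear only as artifact generators.
* Multi-allelic sites are rejected, not decomposed.
* The somatic score's behaviour exactly at the 255 boundary depends on the
  round-then-cap rule documented above.
* The synthetic risk-locus table is a stand-in with realistic effect sizes,
  not a published locus set; scores are only ever interpreted relative to a
  cohort scored on the same loci.
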