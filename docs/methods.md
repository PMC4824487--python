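# Methods

This note documents the models, conventions, and numerical choices behind
`as3c`, and what the synthetic-data tests do and do not demonstrate.

## The allelic-imbalance model

At a heterozygous site, every sequenced tag (read pair, counted once per
DNA fragment) is assumed to support one of the two alleles independently,
so the allele-supporting count among *n* tags is Binomial(*n*, π). Balance —
equal chromatin-interaction frequency, binding occupancy, or expression of
the two alleles — corresponds to π = 0.5.

* Per experiment, deviation from 0.5 is tested with the **exact two-sided
  binomial test**. Two-sidedness uses the minimum-likelihood convention:
  the p-value sums P(X = j) over all j with P(X = j) ≤ P(X = k)·(1 + 10⁻⁷).
  The 10⁻⁷ relative tolerance absorbs floating-point ties; the convention
  matches the widely used exact-test implementations (it agrees with
  `scipy.stats.binomtest`, which the test suite checks).
* Across experiments, the **likelihood-ratio test** uses the pooled MLE
  π₁ = Σnᵢₐ/Σnᵢ and statistic 2Σᵢ[nᵢₐ ln(π₁/π₀) + (nᵢ−nᵢₐ) ln((1−π₁)/(1−π₀))]
  against χ² with 1 df. 0·ln 0 ≡ 0 when π₁ hits 0 or 1; the statistic is
  clamped at 0 against rounding. For a single experiment this equals twice
  the binomial log-likelihood gap between the MLE and the null (verified as
  an oracle identity in the tests).
* A proportion converts to an **implied fold change** as the odds p/(1−p):
  64.0% expression on one haplotype means a 1.78-fold difference between
  haplotypes; 66.5% means ≈2-fold.
* Expression-level comparisons use t-tests on log2 scale: paired (cDNA vs
  genomic-DNA allele ratios per sample), one-sample (log2 fold change vs 0),
  and Welch's two-sample. **Zero-variance inputs** are handled by contract
  rather than returning NaN: zero mean gives t = 0, p = 1; nonzero mean
  gives an infinite statistic with p = 0; both set a `degenerate` flag and
  warn. Allele-count ratios never receive a silent pseudocount — a zero
  count raises unless the caller opts into the Haldane +0.5 correction.

No multiple-testing correction is applied anywhere; the statistics are
per-site, per-assay quantities.

## Fragment maps and the artificial chromosome

The cut of a recognition site R (length r) is placed at
`occurrence_start + cut_offset` (HindIII A^AGCTT: offset 1), so digestion
fragments carry the split site across their shared boundary and
concatenating two cohesive ends is a string identity reconstituting R —
exactly the ligation chemistry of 3C. Overlapping occurrences are resolved
left-to-right with the search resuming at each cut; N never matches.
Coordinates are 0-based half-open internally, 1-based only at VCF
boundaries.

The 3C PCR product ("artificial chromosome") joins fragment A (forward) to
fragment B either forward (`A + B`) or flipped. The flipped join accounts
for the single-strand overhang: the product is
`A + R[c:r−c] + revcomp(B)[max(0, 2c−r):]` for cut offset c, which
regenerates R exactly once at `junction_start = len(A) − c` for any
palindromic site. Sites lifted into the flipped fragment get mirrored
coordinates and complemented alleles; the liftover is cross-checked in the
tests by locating the reverse-complemented 11-mer context in the product.
The orientation of the distal fragment is a user parameter — real 3C
products can capture either orientation and the assay itself does not fix
it.

## Tag counting

The counting unit is the fragment (tag), never the read: when both mates
cover a site they contribute one count if concordant and a discordant-pair
count otherwise. Records failing MAPQ, bases failing baseQ, and deletions
spanning the site make a mate's call "failed"; a pair whose every covering
mate failed is counted as filtered. Bases that are neither allele go to a
separate "other" bucket and are never imputed. The five categories are
disjoint and sum to the pairs covering the site — an invariant the tests
assert on randomized data. Defaults MAPQ > 30 and baseQ > 20 apply to both
interaction and expression counting (a single threshold precedent,
configurable). Duplicate-marked, secondary, and supplementary records are
skipped.

Haplotype counting over k ≥ 1 phased sites lets a tag vote for a haplotype
only if every cleanly-called covered site shows that haplotype's allele;
clean calls pointing to different haplotypes are "recombinant-like"
(template switching, contamination, or phasing error). Tags whose only
evidence is non-allelic or mate-discordant are folded into the filtered
count, which keeps the four returned categories disjoint.

## Mapping-bias simulation

Allele-specific counting can be biased toward the reference allele because
alternative-allele reads carry one extra mismatch against the reference.
The simulation measures this for a given locus: enumerate all read
placements covering the SNP site(s) for both haplotypes (reference alleles
co-occur on one haplotype, alternative alleles on the other — the
perfect-LD convention for sites 76 bp apart scanned with 100 bp reads),
inject per-base substitution errors (Bernoulli rate; uniform choice among
the three other bases; constant base quality 41), remap, and record the
proportion of retained allele-informative reads supporting the reference
allele, over many replicates.

Design choices:

* **Built-in mapper instead of an external aligner.** Reads are placed at
  the Hamming-distance-minimal ungapped offset over both strands and kept
  only when the best placement beats the second best by a uniqueness margin
  (default 1 mismatch). This replaces an aligner-specific MAPQ cutoff with a
  deterministic, brute-force-checkable rule; the tests verify exact
  equivalence with an exhaustive all-offsets scorer. An adapter accepts
  external SAM/BAM for users who prefer a real aligner.
* **Shortcut with exact fallback.** A read differing from its origin window
  by d mismatches is provably unique-best at its origin whenever the
  second-best self-distance of that window exceeds 2d + margin; only reads
  failing this bound get the full scan. The replayed-replicate test shows
  the shortcut path is bit-identical to exhaustive remapping.
* **Per-replicate RNG streams** are spawned from the master seed by
  replicate index, so results do not depend on execution order, and error
  draws use the coupling "error iff u < rate", making runs at different
  error rates from one seed share error positions (paired comparisons).
* **Default locus**: a seeded synthetic non-repetitive 10 kb sequence at
  50% GC with the SNP at the midpoint. Any FASTA can be supplied instead.
  On a non-repetitive locus the unique-best margin rule loses essentially
  no reads at realistic error rates, so the measured bias is ≈0 and the
  simulation certifies *upper bounds* on bias rather than reproducing the
  bias profile of a heuristic seed-and-extend aligner near repeats. Because
  the expected bias is flat at 0.5 here, monotonicity of the mean in error
  rate/read length is asserted weakly (within Monte-Carlo standard error,
  ties allowed), not strictly.
* The **sensitivity (reference-swap) analysis** substitutes the alternative
  allele into the reference, remaps the same reads against both references
  identically, and reports the absolute difference of the allele
  proportions. By construction it is symmetric for the built-in mapper on
  symmetric read sets; on real libraries it bounds residual locus-specific
  bias.

Problem sizes: the acceptance script runs the full 10,000 replicates per
grid cell (seconds per cell with the vectorized shortcut); the test suite
uses 100–1,000 replicates per cell, at which the Monte-Carlo standard error
of the mean (≤ ~2×10⁻⁴ at the tight cells) is several times smaller than
the asserted ceilings.

## qPCR and TaqMan quantification

TaqMan allelic discrimination is calibrated by OLS of log2(VIC/FAM
intensity) on log2 odds of the known mix proportions (50:50 through 90:10);
the fit is pooled over replicate mixes rather than averaging three separate
curves. Inversion maps an observed intensity ratio back to an allelic
proportion; the round trip is exact on noise-free data (tested to 1e-10
relative). The VIC dye is assigned to an allele by configuration, never by
assumption. qPCR efficiency is fixed at 2 — one cycle, one doubling — so
ChIP enrichment is 2^−(Ct_IP−Ct_input) normalized by the negative-control
region (invariant to any global Ct shift), and expression is
2^−(Ct_gene−Ct_ACTB) with treated/vehicle folds paired by replicate index by
default (an unpaired geometric-mean fallback exists, because replicate
pairing in such designs is often unrecorded).

## Prioritization

r² and D′ come from phased haplotype frequencies only; no EM fallback from
unphased genotypes is offered, matching a pipeline where phasing is done
upstream. Strong LD is r² > 0.8; perfect proxies (r² = 1.0) are flagged as
statistically indistinguishable from the tag SNP. DHS annotation reports
peak membership (BED half-open) and signal relative to the peak-calling
threshold; sites outside all peaks default to 0 unless a background track
value is supplied. PWM scanning compares each allele's 61-nt centered
window by the best log2 odds versus background over all placements
overlapping the SNP on both strands; matrices are pseudocounted (0.01 per
cell) and the background defaults to uniform 0.25 — reports should state
this, since scoring against a genome-composition background shifts all
scores. Indels are carried in LD listings but excluded from PWM scanning.

## Synthetic data: what it emulates, what it does not

The generators emulate: tagmentation-style libraries as uniform fragment
sampling over the product (so junction-spanning pairs arise naturally),
haplotype sampling as a Bernoulli draw per fragment, uniform substitution
errors at constant Q41, and phased VCFs with the planted LD structure.
Read names carry the true haplotype (`|hap=...`) for oracle joins; `blind`
strips them.

They do not emulate: coverage non-uniformity (GC, tagmentation insertion
bias, the low-coverage homopolymer stretches seen in real promoter
fragments), instrument-specific error and quality profiles, PCR
duplication, chimeric artifacts, or RNA structure effects on RT-PCR.
Passing the parameter-recovery tests therefore shows the counting and
testing machinery is correct and unbiased under the stated sampling model —
not that real libraries are free of library-specific artifacts; the
mapping-bias and sensitivity analyses are the tools provided for probing
part of that gap on real data.

## Known limitations

* The built-in mapper is ungapped and single-end within the bias
  simulation; indel errors and gapped alignment are out of scope.
* Counting supports SNVs only; indel alleles are rejected at the counters.
* The LRT assumes independent tags; overdispersion (e.g. PCR duplicates
  surviving filters) would inflate significance. No beta-binomial
  alternative is provided.
* No p-value combination across antibodies/assays and no multiple-testing
  correction are implemented.
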