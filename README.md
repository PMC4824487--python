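# as3c — allele-specific 3C-seq toolkit

`as3c` is a toolkit for detecting **allelic imbalance** in chromatin
interaction, factor binding, and gene expression at a heterozygous risk
locus. It targets the analysis style used in allele-specific 3C sequencing
(AS3C-seq): a chromosome-conformation-capture (3C) PCR product spanning a
ligation junction is deep-sequenced in a cell line heterozygous for the SNP
of interest, and the read tags supporting each allele (or phased haplotype)
are compared against the balanced 50:50 expectation. The package is aimed at
regulatory-genomics analysts characterizing candidate causal variants behind
GWAS signals.

## What it does

* **Restriction-fragment maps and 3C products** (`as3c.fragmentmap`) —
  in-silico digestion with 6-bp cutters (HindIII, EcoRI), reconstitution of
  the ligation-junction recognition site, construction of the *artificial
  chromosome* (the exact expected sequence of the 3C PCR product, used as
  the alignment reference), and liftover of variant sites onto it.
* **Haplotype-aware tag counting** (`as3c.allelecount`) — one count per
  read *pair* at each heterozygous site with MAPQ > 30 / baseQ > 20 filters,
  haplotype voting across linked sites, and junction-spanning pair counts.
* **Imbalance statistics** (`as3c.imbalance_stats`) — the exact two-sided
  binomial test per experiment and, pooling experiments *i* with totals
  *n<sub>i</sub>* and allele counts *n<sub>iA</sub>*, the likelihood-ratio
  test

  LRT = 2 Σ<sub>i</sub> [ n<sub>iA</sub> ln(π₁/π₀) + (n<sub>i</sub> −
  n<sub>iA</sub>) ln((1−π₁)/(1−π₀)) ],  π₁ = Σn<sub>iA</sub> / Σn<sub>i</sub>,  π₀ = 0.5,

  referred to χ²₁. A proportion *p* converts to the implied allelic fold
  change *p*/(1−*p*). Paired, one-sample, and Welch t-tests cover the
  expression-level comparisons.
* **Mapping-bias controls** (`as3c.mapbias`) — a simulation that enumerates
  every read placement over the SNP for both haplotypes, injects Bernoulli
  base errors, remaps with a built-in exhaustive unique-best ungapped
  mapper, and measures the reference-allele proportion per replicate; plus
  the reference-swap sensitivity analysis (alternative allele substituted
  into the reference, identical remapping, difference reported).
* **qPCR / TaqMan quantification** (`as3c.quantcal`) — standard-curve
  calibration of VIC/FAM allelic ratios, IP-vs-input binding tests,
  2^−(Ct_IP−Ct_input) ChIP enrichment with negative-control normalization,
  and ACTB-normalized expression fold changes.
* **Variant prioritization** (`as3c.prioritize`) — phased-haplotype r²/D′,
  LD-partner selection (r² > 0.8), DNase-hypersensitivity overlap with
  signal-relative-to-threshold, and allele-differential PWM scanning on
  61-nt windows.
* **Synthetic data** (`as3c.synthdata`) — seeded generators for every input
  (locus FASTA, phased VCF, 3C/ASE read sets, TaqMan tables) with recorded
  ground truth.

## Worked example

Build a synthetic locus, form the 3C product between its outer HindIII
fragments, simulate a library with a known 66.5% protective-haplotype
interaction frequency, align with the built-in mapper, count, and test:

```python
import tempfile
from as3c import fragmentmap as fm, synthdata as sd, allelecount as ac, imbalance_stats as ist
from as3c.align import align_pairs_to_sam

spec = sd.SyntheticLocusSpec(
    length=2000, enzyme=fm.HINDIII, enzyme_site_positions=(600, 1300),
    snps=(sd.SnpSpec(300, id="rsEnh"), sd.SnpSpec(1700, id="rsPromo")), seed=11)
locus = sd.make_synthetic_locus(spec)
frags = fm.digest(locus.sequence, fm.HINDIII)
fa, fc = frags[0], frags[2]
product = fm.build_artificial_chromosome(
    fa, locus.sequence[fa.start:fa.end], fc, locus.sequence[fc.start:fc.end],
    fm.HINDIII, name="product")

pairs, truth = sd.simulate_3c_readset(product, locus.sites, 0.665, 5000, seed=42)
sam = tempfile.mktemp(suffix=".sam")
align_pairs_to_sam(pairs, product.name, product.sequence, sam)
counts = ac.count_haplotype_tags(sam, fm.product_sites(locus.sites, product))
n = counts["n_protective"] + counts["n_risk"]
res = ist.lrt_combined(ist.ExperimentCounts([(n, counts["n_protective"])]))
print(f"LRT = {res.statistic:.1f}, P = {res.p_value:.3g}, fold = {ist.odds_fold(res.estimate):.2f}")
```

Output:

```
digested locus into 3 HindIII fragments: [(0, 601), (601, 1301), (1301, 2000)]
product: 1300 bp, junction at 600
haplotype tags: 1641 protective / 759 risk (68.4% protective)
junction-spanning pairs: 1413
LRT = 331.9, P = 3.79e-74, fold = 2.16
```

The 68.4% estimate sits within sampling error of the planted 66.5% (the
binomial standard error at 2,400 informative tags is about 1%), the LRT
rejects the balanced null decisively, and the implied fold change says the
protective haplotype forms roughly twice the chromatin contacts of the risk
haplotype. The 1,413 junction-spanning pairs are direct sequence evidence of
the ligation event.

A CLI mirrors the library (`as3c digest`, `as3c build-product`, `as3c
count`, `as3c test`, `as3c simulate-bias`, `as3c ld`, `as3c dhs`, `as3c
motif`, `as3c chip`, `as3c expr`, `as3c calibrate`, `as3c synth locus`); run
`as3c --help` for details.

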