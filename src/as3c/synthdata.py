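"""Seeded synthetic-data generators with recorded ground truth.

Every input the other modules consume can be produced here — a synthetic
locus with planted restriction sites and phased SNPs, 3C-product read sets
at a chosen haplotype proportion, allele-specific-expression read sets, and
TaqMan calibration tables — so the whole pipeline is testable end to end
with known truth and no external data. All generators are pure functions of
their specification plus a seed (byte-identical reruns).

Conventions the generators emulate (and their limits) are discussed in the
package methods note: fragment positions are uniform over the product,
errors are uniform substitutions, base qualities are constant Q41, and read
names encode the true haplotype (``|hap=...``) for oracle joins unless
``blind`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragmentmap import ArtificialChromosome, RestrictionEnzyme, liftover_sites
from .sequtil import revcomp, validate_dna, write_fasta
from .variants import PROTECTIVE, RISK, BiallelicSite, write_phased_vcf

_BASES = "ACGT"


@dataclass(frozen=True)
class SnpSpec:
    """One SNP to plant: 0-based position, optional fixed alleles.

    ``protective_allele`` names which allele tags the protective haplotype
    ("alt" by default, matching a risk-tagging reference allele).
    """

    pos0: int
    id: str | None = None
    ref: str | None = None
    alt: str | None = None
    protective_allele: str = "alt"


@dataclass(frozen=True)
class SyntheticLocusSpec:
    length: int
    gc_fraction: float = 0.5
    enzyme: RestrictionEnzyme | None = None
    enzyme_site_positions: tuple[int, ...] = ()
    snps: tuple[SnpSpec, ...] = ()
    seed: int = 0
    contig: str = "synlocus"

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError("locus length must be >= 10")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.enzyme_site_positions and self.enzyme is None:
            raise ValueError("enzyme_site_positions given without an enzyme")
        occupied: set[int] = set()
        if self.enzyme is not None:
            w = len(self.enzyme.recognition)
            for p in self.enzyme_site_positions:
                if not 0 <= p <= self.length - w:
                    raise ValueError(f"enzyme site at {p} outside locus")
                span = set(range(p, p + w))
                if span & occupied:
                    raise ValueError("planted enzyme sites overlap")
                occupied |= span
        for s in self.snps:
            if not 0 <= s.pos0 < self.length:
                raise ValueError(f"SNP at {s.pos0} outside locus")
            if s.pos0 in occupied:
                raise ValueError(f"SNP at {s.pos0} overlaps a planted enzyme site")
            occupied.add(s.pos0)


@dataclass
class SyntheticLocus:
    """A generated locus: sequence plus phased sites and the generating spec."""

    sequence: str
    sites: list[BiallelicSite]
    spec: SyntheticLocusSpec

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(path, {self.spec.contig: self.sequence})

    def write_vcf(self, path: str | Path, sample: str = "SYN") -> None:
        gts = []
        for s in self.sites:
            # haplotype 0 carries the risk allele, haplotype 1 the protective one
            prot_is_alt = s.haplotype_label[s.alt] == PROTECTIVE
            gts.append("0|1" if prot_is_alt else "1|0")
        write_phased_vcf(path, self.sites, sample=sample, genotypes=gts)


def _occurrences(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i >= 0:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def make_synthetic_locus(spec: SyntheticLocusSpec, max_retries: int = 50) -> SyntheticLocus:
    """Generate a locus whose planted features appear exactly where specified.

    Unintended occurrences of the recognition motif (on the reference and on
    the alternative-allele haplotype) are removed by deterministic point
    mutations; if a clean sequence cannot be reached within the retry budget
    the spec is considered infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    planted = set(spec.enzyme_site_positions)
    snp_pos = {s.pos0 for s in spec.snps}
    enz = spec.enzyme
    protected: set[int] = set(snp_pos)
    if enz is not None:
        for p in planted:
            protected |= set(range(p, p + len(enz.recognition)))

    for _ in range(max_retries):
        seq = list(rng.choice(list(_BASES), size=spec.length, p=probs))
        if enz is not None:
            for p in planted:
                seq[p : p + len(enz.recognition)] = list(enz.recognition)
        for s in spec.snps:
            if s.ref is not None:
                seq[s.pos0] = s.ref.upper()
        # resolve SNP alleles
        sites: list[BiallelicSite] = []
        for k, s in enumerate(spec.snps):
            ref = seq[s.pos0]
            alt = s.alt.upper() if s.alt is not None else str(rng.choice([b for b in _BASES if b != ref]))
            if alt == ref:
                raise ValueError(f"SNP at {s.pos0}: alt equals ref allele {ref}")
            if s.protective_allele not in ("ref", "alt"):
                raise ValueError("protective_allele must be 'ref' or 'alt'")
            prot = alt if s.protective_allele == "alt" else ref
            risk = ref if prot == alt else alt
            sites.append(
                BiallelicSite(
                    s.id or f"snp{k}",
                    spec.contig,
                    s.pos0 + 1,
                    ref,
                    alt,
                    {prot: PROTECTIVE, risk: RISK},
                )
            )
        if enz is None:
            return SyntheticLocus("".join(seq), sites, spec)
        # scrub unintended motif occurrences on the reference and alt haplotype
        motif = enz.recognition
        clean = False
        for _ in range(200):
            ref_seq = "".join(seq)
            alt_seq = list(ref_seq)
            for site in sites:
                alt_seq[site.pos0] = site.alt
            alt_seq = "".join(alt_seq)
            stray = [p for p in _occurrences(ref_seq, motif) if p not in planted]
            stray += [p for p in _occurrences(alt_seq, motif) if p not in planted]
            if not stray:
                clean = True
                break
            for p in set(stray):
                targets = [i for i in range(p, p + len(motif)) if i not in protected]
                if not targets:
                    raise ValueError("cannot scrub a motif occurrence overlapping protected bases")
                i = targets[len(targets) // 2]
                seq[i] = str(rng.choice([b for b in _BASES if b != seq[i]]))
        if clean:
            final = "".join(seq)
            assert _occurrences(final, motif) == sorted(planted)
            return SyntheticLocus(final, sites, spec)
    raise ValueError("could not generate a locus satisfying the spec (too many exclusions)")


@dataclass
class ReadSetTruth:
    """Ground truth for a simulated paired-end read set."""

    haplotypes: list[str]  # per-pair haplotype name
    true_proportion: float
    seed: int

    @property
    def n_pairs(self) -> int:
        return len(self.haplotypes)

    def count(self, haplotype: str) -> int:
        return sum(1 for h in self.haplotypes if h == haplotype)


def _inject_str_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _simulate_pairs(
    hap_seqs: dict[str, str],
    proportion_first: float,
    first_hap: str,
    n_pairs: int,
    read_length: int,
    insert_mean: float,
    insert_sd: float,
    error_rate: float,
    rng: np.random.Generator,
    name_prefix: str,
    blind: bool,
) -> tuple[list[tuple[str, str, str]], list[str]]:
    haps = sorted(hap_seqs)
    other = next(h for h in haps if h != first_hap)
    length = len(next(iter(hap_seqs.values())))
    if any(len(s) != length for s in hap_seqs.values()):
        raise ValueError("haplotype sequences must have equal length")
    if read_length > length:
        raise ValueError("read length exceeds template length")
    if insert_mean > length:
        raise ValueError(f"insert_mean {insert_mean} exceeds template length {length}")
    pairs, chosen = [], []
    u = rng.random(n_pairs)
    inserts = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, n_pairs)).astype(int), read_length, length
    )
    starts = rng.integers(0, length - inserts + 1)
    for i in range(n_pairs):
        hap = first_hap if u[i] < proportion_first else other
        chosen.append(hap)
        frag = hap_seqs[hap][starts[i] : starts[i] + inserts[i]]
        r1 = _inject_str_errors(frag[:read_length], error_rate, rng)
        r2 = _inject_str_errors(revcomp(frag[-read_length:]), error_rate, rng)
        name = f"{name_prefix}{i:06d}"
        if not blind:
            name += f"|hap={hap}"
        pairs.append((name, r1, r2))
    return pairs, chosen


def simulate_3c_readset(
    product: ArtificialChromosome,
    sites: list[BiallelicSite],
    true_protective_proportion: float,
    n_pairs: int,
    *,
    read_length: int = 150,
    insert_mean: float = 350.0,
    insert_sd: float = 80.0,
    error_rate: float = 0.0,
    seed: int = 0,
    blind: bool = False,
) -> tuple[list[tuple[str, str, str]], ReadSetTruth]:
    """Paired-end reads from a 3C PCR product, emulating tagmentation libraries.

    Each pair is drawn from the protective-haplotype product with the stated
    probability (risk otherwise); fragment positions are uniform over the
    product, so some pairs straddle the ligation junction. ``sites`` are the
    phased heterozygous sites on the product's source fragments; their lifted
    positions and (strand-adjusted) alleles define the two haplotype
    sequences.
    """
    if not 0.0 < true_protective_proportion < 1.0:
        raise ValueError("true_protective_proportion must be in (0, 1)")
    lifted = liftover_sites(sites, product)
    hap_seq = {PROTECTIVE: list(product.sequence), RISK: list(product.sequence)}
    for site in sites:
        lf = lifted[site.id]
        # lifted ref/alt track the genomic ref/alt (complemented together if flipped)
        hap_of_ref = site.haplotype_label[site.ref]
        hap_of_alt = site.haplotype_label[site.alt]
        hap_seq[hap_of_ref][lf.position] = lf.ref
        hap_seq[hap_of_alt][lf.position] = lf.alt
    hap_seqs = {h: "".join(chars) for h, chars in hap_seq.items()}
    rng = np.random.default_rng(seed)
    pairs, chosen = _simulate_pairs(
        hap_seqs,
        true_protective_proportion,
        PROTECTIVE,
        n_pairs,
        read_length,
        insert_mean,
        insert_sd,
        error_rate,
        rng,
        "c3_",
        blind,
    )
    return pairs, ReadSetTruth(chosen, true_protective_proportion, seed)


def simulate_ase_readset(
    amplicons: dict[str, tuple[str, BiallelicSite]],
    rna_proportions: dict[str, float],
    *,
    dna_proportion: float = 0.5,
    n_pairs: int = 20000,
    read_length: int = 150,
    insert_mean: float = 300.0,
    insert_sd: float = 60.0,
    error_rate: float = 0.0,
    seed: int = 0,
    blind: bool = False,
) -> dict[str, dict[str, tuple[list[tuple[str, str, str]], ReadSetTruth]]]:
    """RNA and genomic-DNA amplicon read sets per gene.

    ``amplicons`` maps gene -> (amplicon sequence, transcribed SNP with its
    position on the amplicon). RNA pairs are drawn at the gene's
    protective-haplotype proportion, DNA pairs at ``dna_proportion`` (0.5 for
    a heterozygous genome).
    """
    out = {}
    master = np.random.SeedSequence(seed)
    children = master.spawn(2 * len(amplicons))
    for k, (gene, (seq, site)) in enumerate(sorted(amplicons.items())):
        seq = validate_dna(seq, name=f"{gene} amplicon")
        if not 0 <= site.pos0 < len(seq):
            raise ValueError(f"{gene}: SNP {site.id} absent from amplicon")
        if seq[site.pos0] != site.ref:
            raise ValueError(
                f"{gene}: amplicon base {seq[site.pos0]!r} at SNP {site.id} does not match ref {site.ref!r}"
            )
        if site.haplotype_label is None:
            raise ValueError(f"{gene}: SNP {site.id} needs haplotype labels")
        if gene not in rna_proportions:
            raise ValueError(f"no RNA proportion for gene {gene!r}")
        hap_seqs = {}
        for allele in (site.ref, site.alt):
            chars = list(seq)
            chars[site.pos0] = allele
            hap_seqs[site.haplotype_label[allele]] = "".join(chars)
        gene_out = {}
        for j, (label, prop) in enumerate((("rna", rna_proportions[gene]), ("dna", dna_proportion))):
            rng = np.random.default_rng(children[2 * k + j])
            pairs, chosen = _simulate_pairs(
                hap_seqs, prop, PROTECTIVE, n_pairs, read_length,
                min(insert_mean, len(seq)), insert_sd, error_rate, rng,
                f"{gene}_{label}_", blind,
            )
            gene_out[label] = (pairs, ReadSetTruth(chosen, prop, seed))
        out[gene] = gene_out
    return out


def simulate_taqman_table(
    true_proportions: dict[str, float],
    *,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
):
    """Calibration and assay TaqMan tables with a known standard curve.

    Calibration rows are the five canonical G:T mixes (50:50, 60:40, 70:30,
    80:20, 90:10), ``replicates`` times each; assay rows are generated for
    each named sample in ``true_proportions``. Observed log2 VIC/FAM equals
    ``intercept + slope * log2(p/(1-p))`` plus Gaussian noise.
    """
    import pandas as pd

    for name, p in true_proportions.items():
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name}: proportion must be in (0, 1)")
    rng = np.random.default_rng(seed)

    def observe(p: float) -> float:
        log2r = intercept + slope * np.log2(p / (1 - p)) + rng.normal(0.0, noise_sd)
        return float(2.0**log2r)

    cal_rows = [
        {"proportion_g": p, "replicate": r, "vic_fam": observe(p)}
        for p in (0.5, 0.6, 0.7, 0.8, 0.9)
        for r in range(1, replicates + 1)
    ]
    assay_rows = [
        {"assay": name, "replicate": r, "vic_fam": observe(p)}
        for name, p in sorted(true_proportions.items())
        for r in range(1, replicates + 1)
    ]
    return pd.DataFrame(cal_rows), pd.DataFrame(assay_rows)


def write_fastq_pairs(
    pairs: list[tuple[str, str, str]],
    path1: str | Path,
    path2: str | Path,
    base_quality: int = 41,
) -> None:
    """Write mate FASTQ files (plain text, constant quality)."""
    q = chr(base_quality + 33)
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, r1, r2 in pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{q * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{q * len(r2)}\n")
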