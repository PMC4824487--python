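"""Biallelic variant sites, haplotype labels, and phased-VCF I/O.

A :class:`BiallelicSite` is one heterozygous variant with its two alleles,
optionally annotated with which named haplotype (e.g. ``"risk"`` /
``"protective"``) each allele tags. Positions are 1-based as in VCF; the
``pos0`` property gives the 0-based coordinate used internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

PROTECTIVE = "protective"
RISK = "risk"


@dataclass(frozen=True)
class BiallelicSite:
    """One biallelic variant with optional allele -> haplotype labels.

    For SNV-only analyses ``ref`` and ``alt`` are single bases; indels may be
    carried (for LD listings) but are rejected by base-level counters.
    """

    id: str
    contig: str
    pos: int  # 1-based, as printed in VCF
    ref: str
    alt: str
    haplotype_label: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site {self.id}: pos must be 1-based positive, got {self.pos}")
        ref, alt = self.ref.upper(), self.alt.upper()
        if ref == alt:
            raise ValueError(f"site {self.id}: ref and alt alleles are identical ({ref})")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if self.haplotype_label is not None:
            labels = {a.upper(): h for a, h in self.haplotype_label.items()}
            if set(labels) != {ref, alt}:
                raise ValueError(
                    f"site {self.id}: haplotype_label keys {sorted(labels)} must be exactly the two alleles"
                )
            if labels[ref] == labels[alt]:
                raise ValueError(f"site {self.id}: both alleles assigned to haplotype {labels[ref]!r}")
            object.__setattr__(self, "haplotype_label", labels)

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def haplotype_of(self, allele: str) -> str | None:
        if self.haplotype_label is None:
            return None
        return self.haplotype_label.get(allele.upper())


def load_sites_vcf(
    path: str | Path,
    *,
    sample: str | None = None,
    protective_phase: int | None = None,
) -> list[BiallelicSite]:
    """Load biallelic sites from a VCF.

    When ``sample`` and ``protective_phase`` (0 or 1) are given, the phased
    genotype of that sample assigns haplotype labels: the allele on the stated
    phase strand is labelled "protective", the other "risk". Only heterozygous,
    phased genotypes receive labels.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_idx = None
    if sample is not None:
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} not in VCF samples {vcf.samples}")
        sample_idx = vcf.samples.index(sample)
        if protective_phase not in (0, 1):
            raise ValueError("protective_phase must be 0 or 1 when a sample is given")
    sites = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        labels = None
        if sample_idx is not None:
            a0, a1, phased = rec.genotypes[sample_idx][:3]
            if phased and {a0, a1} == {0, 1}:
                alleles = [rec.REF.upper(), rec.ALT[0].upper()]
                prot = alleles[(a0, a1)[protective_phase]]
                risk = alleles[(a0, a1)[1 - protective_phase]]
                labels = {prot: PROTECTIVE, risk: RISK}
        sites.append(BiallelicSite(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0], labels))
    return sites


def write_phased_vcf(
    path: str | Path,
    sites: list[BiallelicSite],
    *,
    sample: str = "SYN",
    genotypes: list[str] | None = None,
) -> None:
    """Write a minimal phased single-sample VCF (plain text).

    ``genotypes`` defaults to ``0|1`` at every site (reference alleles on
    haplotype 0, alternative alleles on haplotype 1 — i.e. perfect LD).
    """
    if genotypes is None:
        genotypes = ["0|1"] * len(sites)
    if len(genotypes) != len(sites):
        raise ValueError("genotypes length must match sites")
    contigs = {}
    for s in sites:
        contigs[s.contig] = max(contigs.get(s.contig, 0), s.pos + 1000)
    lines = ["##fileformat=VCFv4.2"]
    for c, ln in contigs.items():
        lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    order = sorted(range(len(sites)), key=lambda i: (sites[i].contig, sites[i].pos))
    for i in order:
        s = sites[i]
        lines.append(f"{s.contig}\t{s.pos}\t{s.id}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{genotypes[i]}")
    Path(path).write_text("\n".join(lines) + "\n")
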