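"""In-silico restriction digestion and 3C ligation-product construction.

A 3C (chromosome conformation capture) experiment digests crosslinked
chromatin with a 6-bp-cutter (HindIII, EcoRI), religates fragment ends, and
amplifies a chimeric product spanning the ligation junction. Because the
enzyme leaves cohesive ends, ligation of any two ends regenerates the full
recognition sequence at the join. The amplified product — two restriction
fragments joined at one reconstituted site — serves as the "artificial
chromosome" alignment reference for allele-specific read counting.

Cut convention: the cut is placed at ``occurrence_start + cut_offset`` on the
top strand (HindIII A^AGCTT has ``cut_offset=1``). Fragments therefore carry
the split recognition site across their boundary, so concatenating adjacent
cohesive ends is a string identity that reconstitutes the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .sequtil import revcomp, validate_dna
from .variants import BiallelicSite


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as a recognition string plus top-strand cut offset.

    ``cut_offset`` is the number of recognition-site bases retained on the
    left fragment (HindIII = 1 for A^AGCTT, EcoRI = 1 for G^AATTC).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = validate_dna(self.recognition, allow_n=False, name=f"{self.name} recognition")
        object.__setattr__(self, "recognition", rec)
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(f"{self.name}: cut_offset {self.cut_offset} outside [0, {len(rec)}]")


HINDIII = RestrictionEnzyme("HindIII", "AAGCTT", 1)
ECORI = RestrictionEnzyme("EcoRI", "GAATTC", 1)

ENZYMES = {e.name: e for e in (HINDIII, ECORI)}


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment in 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.index}: start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


@dataclass
class LiftedSite:
    """A variant lifted onto ligation-product coordinates (0-based)."""

    id: str
    position: int
    ref: str
    alt: str


@dataclass
class ArtificialChromosome:
    """Exact expected sequence of a 3C PCR product (two fragments, one junction)."""

    name: str
    sequence: str
    junction_start: int
    recognition: str
    site_positions: dict[str, int] = field(default_factory=dict)
    source_fragments: tuple[tuple[Fragment, bool], tuple[Fragment, bool]] | None = None

    def __post_init__(self) -> None:
        r = len(self.recognition)
        if self.sequence[self.junction_start : self.junction_start + r] != self.recognition:
            raise ValueError(
                f"product {self.name}: recognition site {self.recognition} not found at junction_start "
                f"{self.junction_start}"
            )
        for vid, pos in self.site_positions.items():
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"product {self.name}: site {vid} position {pos} outside sequence")


def digest(sequence: str, enzyme: RestrictionEnzyme, contig: str = "locus") -> list[Fragment]:
    """Digest a sequence, returning fragments that tile [0, len) without gaps.

    Occurrences of the recognition site are resolved left-to-right; after each
    cut the search resumes at the cut position, so overlapping occurrences are
    handled deterministically. N bases never match the site.
    """
    seq = validate_dna(sequence, allow_n=True, name="sequence")
    cuts = [0]
    search_from = 0
    rec = enzyme.recognition
    while True:
        hit = seq.find(rec, search_from)
        if hit < 0:
            break
        cut = hit + enzyme.cut_offset
        if 0 < cut < len(seq):
            cuts.append(cut)
        search_from = max(cut, hit + 1)
    cuts.append(len(seq))
    return [
        Fragment(contig, start, end, i)
        for i, (start, end) in enumerate(zip(cuts[:-1], cuts[1:]))
    ]


def fragment_sequences(sequence: str, fragments: list[Fragment]) -> list[str]:
    return [sequence[f.start : f.end] for f in fragments]


def reconstitute_junction(enzyme: RestrictionEnzyme) -> str:
    """Sequence regenerated by ligating two cohesive ends of the same enzyme.

    Ligation of compatible ends restores the full palindromic recognition
    sequence (AAGCTT for HindIII).
    """
    return enzyme.recognition


def build_artificial_chromosome(
    frag_a: Fragment,
    seq_a: str,
    frag_b: Fragment,
    seq_b: str,
    enzyme: RestrictionEnzyme,
    *,
    frag_b_reverse: bool = False,
    name: str = "product",
) -> ArtificialChromosome:
    """Join two restriction fragments into the expected 3C ligation product.

    ``frag_a`` must end at a cut site; ``frag_b`` must start (forward) or end
    (reversed) at a cut site of the same enzyme, so that the cohesive ends
    reconstitute the recognition site exactly once at the join. The reversed
    case models a fragment captured in the flipped orientation: its
    contribution is the reverse complement with the single-strand overhang
    accounted for, ``R[c:r-c] + revcomp(B)[max(0, 2c-r):]`` for recognition
    ``R`` of length ``r`` cut at offset ``c``.
    """
    seq_a = validate_dna(seq_a, name="fragment A sequence")
    seq_b = validate_dna(seq_b, name="fragment B sequence")
    if len(seq_a) != len(frag_a) or len(seq_b) != len(frag_b):
        raise ValueError("fragment sequences must match fragment interval lengths")
    rec, c = enzyme.recognition, enzyme.cut_offset
    r = len(rec)
    if c and not seq_a.endswith(rec[:c]):
        raise ValueError(f"fragment A does not end at a {enzyme.name} cut (expected suffix {rec[:c]})")
    if frag_b_reverse:
        if c and not seq_b.endswith(rec[:c]):
            raise ValueError(
                f"reversed fragment B does not end at a {enzyme.name} cut (expected suffix {rec[:c]})"
            )
        fill = rec[c : r - c] if r - 2 * c > 0 else ""
        tail = revcomp(seq_b)[max(0, 2 * c - r) :]
        sequence = seq_a + fill + tail
    else:
        if not seq_b.startswith(rec[c:]):
            raise ValueError(
                f"fragment B does not start at a {enzyme.name} cut (expected prefix {rec[c:]})"
            )
        sequence = seq_a + seq_b
    junction_start = len(seq_a) - c
    if sequence[junction_start : junction_start + r] != rec:
        raise ValueError(
            f"fragment ends do not reconstruct the {enzyme.name} site at the junction"
        )
    return ArtificialChromosome(
        name=name,
        sequence=sequence,
        junction_start=junction_start,
        recognition=rec,
        source_fragments=((frag_a, False), (frag_b, frag_b_reverse)),
    )


def liftover_sites(
    sites: list[BiallelicSite],
    product: ArtificialChromosome,
) -> dict[str, LiftedSite]:
    """Map variant sites from source-contig coordinates onto the product.

    Sites inside the reversed fragment get mirrored coordinates and
    complemented alleles. The product's ``site_positions`` are updated in
    place. Raises for any site outside both source fragments.
    """
    if product.source_fragments is None:
        raise ValueError("product has no source fragment records; cannot lift sites")
    (frag_a, _), (frag_b, b_rev) = product.source_fragments
    rec = product.recognition
    r = len(rec)
    c = len(frag_a) - product.junction_start  # cut_offset recovered from geometry
    fill_len = max(0, r - 2 * c) if b_rev else 0
    trim = max(0, 2 * c - r)
    lifted: dict[str, LiftedSite] = {}
    for site in sites:
        if not site.is_snv:
            raise ValueError(f"site {site.id}: only SNVs can be lifted onto a product")
        p = site.pos0
        if frag_a.contains(p):
            pos = p - frag_a.start
            lifted[site.id] = LiftedSite(site.id, pos, site.ref, site.alt)
        elif frag_b.contains(p):
            j = p - frag_b.start
            if not b_rev:
                pos = len(frag_a) + j
                lifted[site.id] = LiftedSite(site.id, pos, site.ref, site.alt)
            else:
                j_rc = len(frag_b) - 1 - j
                if j_rc < trim:
                    raise ValueError(f"site {site.id} falls inside the junction overlap; cannot lift")
                pos = len(frag_a) + fill_len + (j_rc - trim)
                lifted[site.id] = LiftedSite(site.id, pos, revcomp(site.ref), revcomp(site.alt))
        else:
            raise ValueError(f"site {site.id} (pos {site.pos}) lies in neither source fragment")
        product.site_positions[site.id] = lifted[site.id].position
    return lifted


def product_sites(
    sites: list[BiallelicSite],
    product: ArtificialChromosome,
) -> list[BiallelicSite]:
    """Re-express genomic sites as sites on the product contig.

    Positions are lifted (and alleles complemented for the reversed fragment)
    so the result can be fed straight to the counting functions on
    artificial-chromosome alignments; haplotype labels follow their alleles.
    """
    lifted = liftover_sites(sites, product)
    out = []
    for s in sites:
        lf = lifted[s.id]
        labels = None
        if s.haplotype_label is not None:
            labels = {lf.ref: s.haplotype_label[s.ref], lf.alt: s.haplotype_label[s.alt]}
        out.append(BiallelicSite(s.id, product.name, lf.position + 1, lf.ref, lf.alt, labels))
    return out


def write_fragments_bed(path: str | Path, fragments: list[Fragment]) -> None:
    """Write a fragment map as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\tfrag_{f.index}\n")
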