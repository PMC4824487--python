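"""Shared fixtures: a small synthetic locus, its 3C product, and a SAM writer."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from as3c import fragmentmap as fm
from as3c import synthdata as sd

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def locus():
    """2 kb locus with two HindIII sites and two phased SNPs (one per outer fragment)."""
    spec = sd.SyntheticLocusSpec(
        length=2000,
        enzyme=fm.HINDIII,
        enzyme_site_positions=(600, 1300),
        snps=(sd.SnpSpec(300, id="rsSNP"), sd.SnpSpec(1700, id="rsPromo")),
        seed=11,
    )
    return sd.make_synthetic_locus(spec)


@pytest.fixture(scope="session")
def product(locus):
    """Ligation product joining the first and last fragments (forward orientation)."""
    frags = fm.digest(locus.sequence, fm.HINDIII)
    fa, fc = frags[0], frags[2]
    seq = locus.sequence
    return fm.build_artificial_chromosome(
        fa, seq[fa.start : fa.end], fc, seq[fc.start : fc.end], fm.HINDIII, name="product"
    )


@pytest.fixture(scope="session")
def psites(locus, product):
    return fm.product_sites(locus.sites, product)


def write_sam(path: Path, contig: str, length: int, records: list[tuple]) -> Path:
    """Write a SAM from (qname, flag, pos1, mapq, cigar, seq, qual) tuples."""
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{contig}\tLN:{length}"]
    for qname, flag, pos1, mapq, cigar, seq, qual in records:
        lines.append(
            f"{qname}\t{flag}\t{contig}\t{pos1}\t{mapq}\t{cigar}\t=\t{pos1}\t0\t{seq}\t{qual}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
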