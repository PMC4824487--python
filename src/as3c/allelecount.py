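"""Allele- and haplotype-aware counting of read-pair tags at heterozygous sites.

The counting unit is the sequenced DNA fragment — the paired-end read "tag":
one fragment contributes at most one count per site no matter how many of
its mates cover the site. Records are filtered on mapping quality (default
MAPQ > 30) and base calls on base quality (default > 20); duplicate-marked,
secondary and supplementary records are ignored.

Per-pair resolution at a site:

* only one mate covers the site -> that mate's base decides;
* both mates cover it and agree -> one count; disagree -> discordant pair;
* every covering mate fails a quality filter (or reads a deletion) -> the
  pair is counted as filtered.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from .fragmentmap import ArtificialChromosome
from .variants import BiallelicSite

_FAIL = "fail"


@dataclass(frozen=True)
class CountFilters:
    """Quality thresholds applied before a base call is trusted."""

    min_mapq: int = 30
    min_baseq: int = 20
    require_proper_pair: bool = False

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.min_baseq < 0:
            raise ValueError("quality thresholds must be >= 0")


def _open(alignments) -> tuple[pysam.AlignmentFile, bool]:
    if isinstance(alignments, (str, Path)):
        return pysam.AlignmentFile(str(alignments)), True
    return alignments, False


def _check_sites(af: pysam.AlignmentFile, sites: list[BiallelicSite]) -> None:
    lengths = dict(zip(af.references, af.lengths))
    for s in sites:
        if s.contig not in lengths:
            raise ValueError(f"site {s.id}: contig {s.contig!r} not in alignment header")
        if s.pos > lengths[s.contig]:
            raise ValueError(f"site {s.id}: position {s.pos} beyond contig length {lengths[s.contig]}")


def _usable(rec: pysam.AlignedSegment, filters: CountFilters) -> bool:
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
        return False
    if filters.require_proper_pair and rec.is_paired and not rec.is_proper_pair:
        return False
    return True


def _mate_call(rec: pysam.AlignedSegment, site: BiallelicSite, filters: CountFilters) -> str | None:
    """One mate's call at a site: ref/alt/other/fail, or None if not covering."""
    if rec.reference_name != site.contig:
        return None
    if not rec.reference_start <= site.pos0 < rec.reference_end:
        return None
    if rec.mapping_quality < filters.min_mapq:
        return _FAIL
    qpos = None
    for q, r in rec.get_aligned_pairs():
        if r == site.pos0:
            qpos = q
            break
    if qpos is None:
        return _FAIL  # deletion spanning the site: no base to call
    base = rec.query_sequence[qpos].upper()
    qual = rec.query_qualities[qpos] if rec.query_qualities is not None else filters.min_baseq + 1
    if qual < filters.min_baseq:
        return _FAIL
    if base == site.ref:
        return "ref"
    if base == site.alt:
        return "alt"
    return "other"


def _collect_pair_calls(
    alignments, sites: list[BiallelicSite], filters: CountFilters
) -> dict[str, dict[str, list[str]]]:
    """Stream records once; returns qname -> site id -> list of mate calls."""
    af, owned = _open(alignments)
    try:
        _check_sites(af, sites)
        calls: dict[str, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
        for rec in af:
            if not _usable(rec, filters):
                continue
            for site in sites:
                c = _mate_call(rec, site, filters)
                if c is not None:
                    calls[rec.query_name][site.id].append(c)
        return calls
    finally:
        if owned:
            af.close()


def _resolve(mate_calls: list[str]) -> str:
    """Collapse a pair's mate calls at one site into a single category."""
    informative = [c for c in mate_calls if c != _FAIL]
    if not informative:
        return "filtered"
    if len(set(informative)) > 1:
        return "discordant"
    return informative[0]


def count_allelic_tags(
    alignments,
    sites: list[BiallelicSite],
    filters: CountFilters = CountFilters(),
    sample: str = "sample",
) -> pd.DataFrame:
    """Per-site tag counts: n_ref, n_alt, n_other, n_discordant_pair, n_filtered.

    The five categories are disjoint and sum to the number of pairs with at
    least one mate covering the site.
    """
    calls = _collect_pair_calls(alignments, sites, filters)
    counts = {s.id: dict(n_ref=0, n_alt=0, n_other=0, n_discordant_pair=0, n_filtered=0) for s in sites}
    key = {"ref": "n_ref", "alt": "n_alt", "other": "n_other", "discordant": "n_discordant_pair", "filtered": "n_filtered"}
    for per_site in calls.values():
        for sid, mate_calls in per_site.items():
            counts[sid][key[_resolve(mate_calls)]] += 1
    rows = [{"sample": sample, "site": s.id, **counts[s.id]} for s in sites]
    return pd.DataFrame(rows)


def count_haplotype_tags(
    alignments,
    phased_sites: list[BiallelicSite],
    filters: CountFilters = CountFilters(),
) -> dict[str, int]:
    """Haplotype-resolved tag counts over one or more phased sites.

    Every site must carry ``haplotype_label`` and all sites must share a
    contig and the same pair of haplotype names. A tag votes for a haplotype
    only when every cleanly-called site it covers shows that haplotype's
    allele; clean calls pointing to different haplotypes make the tag
    recombinant-like. Tags whose only calls are quality-failed, non-allelic
    ("other") bases, or mate-discordant are counted as filtered (the returned
    categories have no separate slot for those).

    Returns a dict with the two haplotype names plus ``n_recombinant_like``
    and ``n_filtered``.
    """
    if not phased_sites:
        raise ValueError("at least one phased site required")
    contigs = {s.contig for s in phased_sites}
    if len(contigs) > 1:
        raise ValueError(f"phased sites span multiple contigs: {sorted(contigs)}")
    hap_names: set[str] = set()
    for s in phased_sites:
        if s.haplotype_label is None:
            raise ValueError(f"site {s.id} lacks haplotype labels")
        hap_names.update(s.haplotype_label.values())
    if len(hap_names) != 2:
        raise ValueError(f"expected exactly 2 haplotype names across sites, got {sorted(hap_names)}")
    by_id = {s.id: s for s in phased_sites}

    calls = _collect_pair_calls(alignments, phased_sites, filters)
    out = {f"n_{h}": 0 for h in sorted(hap_names)}
    out["n_recombinant_like"] = 0
    out["n_filtered"] = 0
    for per_site in calls.values():
        votes: list[str] = []
        dirty = False
        any_cover = False
        for sid, mate_calls in per_site.items():
            any_cover = True
            res = _resolve(mate_calls)
            if res in ("ref", "alt"):
                site = by_id[sid]
                allele = site.ref if res == "ref" else site.alt
                votes.append(site.haplotype_label[allele])
            elif res in ("other", "discordant"):
                dirty = True
            # filtered mate-calls contribute nothing
        if not any_cover:
            continue
        if votes and len(set(votes)) == 1 and not dirty:
            out[f"n_{votes[0]}"] += 1
        elif len(set(votes)) > 1:
            out["n_recombinant_like"] += 1
        else:
            out["n_filtered"] += 1
    return out


def junction_spanning_pairs(
    alignments,
    product: ArtificialChromosome,
    min_overhang: int = 0,
) -> int:
    """Count pairs with a mate spanning the reconstituted ligation junction.

    A mate qualifies when its aligned span covers the recognition-site
    interval extended by ``min_overhang`` bases on each side. Reads crossing
    the junction are direct sequence evidence of the chromatin contact.
    """
    lo = product.junction_start - min_overhang
    hi = product.junction_start + len(product.recognition) + min_overhang
    if lo < 0 or hi > len(product.sequence):
        raise ValueError("junction interval (with overhang) extends outside the product")
    af, owned = _open(alignments)
    try:
        spanning: set[str] = set()
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            if rec.reference_name != product.name:
                continue
            if rec.reference_start <= lo and rec.reference_end >= hi:
                spanning.add(rec.query_name)
        return len(spanning)
    finally:
        if owned:
            af.close()
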