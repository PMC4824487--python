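"""Allele/haplotype tag counting over SAM alignments."""

import random

import pysam
import pytest

from as3c import allelecount as ac
from as3c import fragmentmap as fm
from as3c import synthdata as sd
from as3c.align import align_pairs_to_sam
from as3c.variants import PROTECTIVE, RISK, BiallelicSite

from conftest import write_sam

Q40 = "I" * 20  # 20 bases at Q40
LOWQ = "#" * 20  # Q2


@pytest.fixture()
def simple_site():
    return BiallelicSite("rs1", "chr1", 10, "A", "G", {"A": RISK, "G": PROTECTIVE})


def mate(qname, pos1, seq, flag=99, mapq=60, qual=None, cigar=None):
    return (qname, flag, pos1, mapq, cigar or f"{len(seq)}M", seq, qual or "I" * len(seq))


class TestCountAllelicTags:
    def test_pure_reference_pairs(self, tmp_path, simple_site):
        records = [mate(f"p{i}", 1, "C" * 9 + "A" + "C" * 10) for i in range(10)]
        sam = write_sam(tmp_path / "a.sam", "chr1", 100, records)
        table = ac.count_allelic_tags(sam, [simple_site])
        row = table.iloc[0]
        assert row.n_ref == 10 and row.n_alt == 0
        assert row.n_other == row.n_discordant_pair == row.n_filtered == 0

    def test_discordant_mates_counted_once_as_discordant(self, tmp_path, simple_site):
        records = [
            mate("p0", 1, "C" * 9 + "A" + "C" * 10, flag=99),
            mate("p0", 1, "C" * 9 + "G" + "C" * 10, flag=147),
        ]
        sam = write_sam(tmp_path / "a.sam", "chr1", 100, records)
        row = ac.count_allelic_tags(sam, [simple_site]).iloc[0]
        assert row.n_discordant_pair == 1
        assert row.n_ref == row.n_alt == 0

    def test_concordant_overlapping_mates_counted_once(self, tmp_path, simple_site):
        records = [
            mate("p0", 1, "C" * 9 + "G" + "C" * 10, flag=99),
            mate("p0", 1, "C" * 9 + "G" + "C" * 10, flag=147),
        ]
        sam = write_sam(tmp_path / "a.sam", "chr1", 100, records)
        row = ac.count_allelic_tags(sam, [simple_site]).iloc[0]
        assert row.n_alt == 1 and row.n_discordant_pair == 0

    def test_quality_filters_and_other_bases(self, tmp_path, simple_site):
        records = [
            mate("lowmapq", 1, "C" * 9 + "A" + "C" * 10, mapq=10),
            mate("lowbaseq", 1, "C" * 9 + "A" + "C" * 10, qual="I" * 9 + "#" + "I" * 10),
            mate("other", 1, "C" * 9 + "T" + "C" * 10),
            mate("deletion", 1, "C" * 18, cigar="9M2D9M"),
        ]
        sam = write_sam(tmp_path / "a.sam", "chr1", 100, records)
        row = ac.count_allelic_tags(sam, [simple_site]).iloc[0]
        assert row.n_filtered == 3  # low MAPQ, low baseQ, deletion over the site
        assert row.n_other == 1
        assert row.n_ref == 0

    def test_duplicates_and_secondary_skipped(self, tmp_path, simple_site):
        records = [
            ("dup", 99 | 0x400, 1, 60, "20M", "C" * 9 + "A" + "C" * 10, "I" * 20),
            ("sec", 99 | 0x100, 1, 60, "20M", "C" * 9 + "A" + "C" * 10, "I" * 20),
        ]
        sam = write_sam(tmp_path / "a.sam", "chr1", 100, records)
        row = ac.count_allelic_tags(sam, [simple_site]).iloc[0]
        assert row[["n_ref", "n_alt", "n_other", "n_discordant_pair", "n_filtered"]].sum() == 0

    def test_counts_invariant_to_record_order(self, tmp_path, simple_site):
        base = [mate(f"p{i}", 1, "C" * 9 + ("A" if i % 3 else "G") + "C" * 10) for i in range(12)]
        shuffled = base[:]
        random.Random(0).shuffle(shuffled)
        t1 = ac.count_allelic_tags(write_sam(tmp_path / "a.sam", "chr1", 100, base), [simple_site])
        t2 = ac.count_allelic_tags(write_sam(tmp_path / "b.sam", "chr1", 100, shuffled), [simple_site])
        assert t1.equals(t2)

    def test_unknown_contig_and_bad_position_error(self, tmp_path, simple_site):
        sam = write_sam(tmp_path / "a.sam", "chr1", 100, [mate("p", 1, "C" * 20)])
        with pytest.raises(ValueError, match="contig"):
            ac.count_allelic_tags(sam, [BiallelicSite("x", "chrZ", 5, "A", "G")])
        with pytest.raises(ValueError, match="beyond"):
            ac.count_allelic_tags(sam, [BiallelicSite("x", "chr1", 500, "A", "G")])

    def test_category_sum_equals_covering_pairs_on_synthetic_set(self, tmp_path, locus, product, psites):
        pairs, _ = sd.simulate_3c_readset(product, locus.sites, 0.6, 600, error_rate=0.01, seed=3)
        sam = tmp_path / "x.sam"
        align_pairs_to_sam(pairs, product.name, product.sequence, sam)
        table = ac.count_allelic_tags(sam, psites)
        for site in psites:
            covering = set()
            with pysam.AlignmentFile(str(sam)) as af:
                for rec in af:
                    if rec.reference_start <= site.pos0 < rec.reference_end:
                        covering.add(rec.query_name)
            row = table[table.site == site.id].iloc[0]
            total = row.n_ref + row.n_alt + row.n_other + row.n_discordant_pair + row.n_filtered
            assert total == len(covering)

    def test_generation_truth_recovered_without_errors(self, tmp_path, locus, product, psites):
        """Zero-error counts must match per-pair truth exactly (names encode haplotype)."""
        pairs, _ = sd.simulate_3c_readset(product, locus.sites, 2 / 3, 800, error_rate=0.0, seed=9)
        sam = tmp_path / "x.sam"
        align_pairs_to_sam(pairs, product.name, product.sequence, sam)
        table = ac.count_allelic_tags(sam, psites)
        for site in psites:
            alt_hap = site.haplotype_label[site.alt]
            covering = {}
            with pysam.AlignmentFile(str(sam)) as af:
                for rec in af:
                    if rec.reference_start <= site.pos0 < rec.reference_end:
                        covering[rec.query_name] = rec.query_name.split("|hap=")[1]
            row = table[table.site == site.id].iloc[0]
            assert row.n_alt == sum(1 for h in covering.values() if h == alt_hap)
            assert row.n_ref == sum(1 for h in covering.values() if h != alt_hap)
            assert row.n_other == row.n_discordant_pair == 0


class TestCountHaplotypeTags:
    def test_single_site_proportions(self, tmp_path, simple_site):
        records = [mate(f"g{i}", 1, "C" * 9 + "G" + "C" * 10) for i in range(75)]
        records += [mate(f"t{i}", 1, "C" * 9 + "A" + "C" * 10) for i in range(25)]
        sam = write_sam(tmp_path / "a.sam", "chr1", 100, records)
        counts = ac.count_haplotype_tags(sam, [simple_site])
        assert counts["n_protective"] == 75 and counts["n_risk"] == 25
        assert counts["n_recombinant_like"] == 0

    def test_cross_haplotype_read_is_recombinant_like(self, tmp_path):
        s1 = BiallelicSite("s1", "chr1", 5, "A", "G", {"A": RISK, "G": PROTECTIVE})
        s2 = BiallelicSite("s2", "chr1", 15, "C", "T", {"C": RISK, "T": PROTECTIVE})
        # read shows protective allele at s1 but risk allele at s2
        seq = "CCCC" + "G" + "CCCCCCCCC" + "C" + "CCCCC"
        sam = write_sam(tmp_path / "a.sam", "chr1", 100, [mate("p", 1, seq)])
        counts = ac.count_haplotype_tags(sam, [s1, s2])
        assert counts["n_recombinant_like"] == 1
        assert counts["n_protective"] == counts["n_risk"] == 0

    def test_inconsistent_labels_rejected(self):
        with pytest.raises(ValueError):
            BiallelicSite("bad", "chr1", 5, "A", "G", {"A": RISK, "G": RISK})

    def test_haplotype_counts_equal_generation_truth(self, tmp_path, locus, product, psites):
        pairs, truth = sd.simulate_3c_readset(product, locus.sites, 0.665, 1500, error_rate=0.0, seed=21)
        sam = tmp_path / "x.sam"
        align_pairs_to_sam(pairs, product.name, product.sequence, sam)
        counts = ac.count_haplotype_tags(sam, psites)
        # brute-force oracle from read names over site-covering pairs
        expected = {"protective": 0, "risk": 0}
        positions = [s.pos0 for s in psites]
        with pysam.AlignmentFile(str(sam)) as af:
            seen = {}
            for rec in af:
                if any(rec.reference_start <= p < rec.reference_end for p in positions):
                    seen[rec.query_name] = rec.query_name.split("|hap=")[1]
        for h in seen.values():
            expected[h] += 1
        assert counts["n_protective"] == expected["protective"]
        assert counts["n_risk"] == expected["risk"]
        assert counts["n_recombinant_like"] == 0


class TestJunctionSpanningPairs:
    def test_exact_cover_and_one_bp_short(self, tmp_path, product):
        j, r = product.junction_start, len(product.recognition)
        covering = mate("cover", j - 5 + 1, product.sequence[j - 5 : j + r + 5])
        # ends 1 bp before the junction starts
        short = mate("short", j - 20 + 1, product.sequence[j - 20 : j - 1])
        sam = write_sam(
            tmp_path / "a.sam", product.name, len(product.sequence), [covering, short]
        )
        assert ac.junction_spanning_pairs(sam, product, min_overhang=5) == 1
        assert ac.junction_spanning_pairs(sam, product, min_overhang=0) == 1

    def test_matches_interval_oracle_on_synthetic_set(self, tmp_path, locus, product):
        pairs, _ = sd.simulate_3c_readset(product, locus.sites, 0.5, 500, seed=13)
        sam = tmp_path / "x.sam"
        align_pairs_to_sam(pairs, product.name, product.sequence, sam)
        overhang = 3
        lo = product.junction_start - overhang
        hi = product.junction_start + len(product.recognition) + overhang
        expected = set()
        with pysam.AlignmentFile(str(sam)) as af:
            for rec in af:
                if rec.reference_start <= lo and rec.reference_end >= hi:
                    expected.add(rec.query_name)
        assert ac.junction_spanning_pairs(sam, product, min_overhang=overhang) == len(expected)
        assert len(expected) > 0  # uniform coverage straddles the junction

    def test_junction_outside_contig_errors(self, tmp_path, product):
        sam = write_sam(tmp_path / "a.sam", product.name, len(product.sequence), [])
        with pytest.raises(ValueError):
            ac.junction_spanning_pairs(sam, product, min_overhang=10**6)
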