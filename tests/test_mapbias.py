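"""Mapping-bias simulation: enumeration, error injection, the built-in mapper,
replicated simulation, and the reference-swap sensitivity analysis."""

import numpy as np
import pytest

from as3c import mapbias as mb
from as3c import synthdata as sd
from as3c.sequtil import revcomp
from as3c.variants import BiallelicSite


@pytest.fixture(scope="module")
def small_locus():
    spec = sd.SyntheticLocusSpec(length=800, snps=(sd.SnpSpec(400, id="rsX"),), seed=5)
    return sd.make_synthetic_locus(spec)


@pytest.fixture(scope="module")
def linked_locus():
    """Two SNPs 76 bp apart, alleles linked per haplotype (perfect LD)."""
    spec = sd.SyntheticLocusSpec(
        length=1200, snps=(sd.SnpSpec(500, id="rsA"), sd.SnpSpec(576, id="rsB")), seed=6
    )
    return sd.make_synthetic_locus(spec)


def brute_force_best_two(read: str, reference: str):
    """Exhaustive all-offsets, both-strands Hamming scorer (oracle)."""
    L = len(read)
    scored = []
    for strand, r in (("+", read), ("-", revcomp(read))):
        for o in range(len(reference) - L + 1):
            d = sum(1 for a, b in zip(r, reference[o : o + L]) if a != b)
            scored.append((d, o, strand))
    scored.sort(key=lambda t: t[0])
    return scored[0], scored[1]


class TestEnumerateReads:
    def test_one_site_mid_contig_combinatorial_count(self, small_locus):
        reads = mb.enumerate_reads(small_locus.sequence, small_locus.sites, 50)
        assert len(reads) == 50 * 2
        assert {r.haplotype for r in reads} == {"ref", "alt"}

    def test_site_near_contig_edge_truncates_with_warning(self):
        ref = "ACGT" * 50
        site = BiallelicSite("e", "c", 11, ref[10], "A" if ref[10] != "A" else "C")
        with pytest.warns(UserWarning):
            reads = mb.enumerate_reads(ref, [site], 50)
        assert len(reads) == 11 * 2  # starts 0..10 only

    def test_linked_sites_share_a_haplotype_on_long_reads(self, linked_locus):
        reads = mb.enumerate_reads(linked_locus.sequence, linked_locus.sites, 100)
        s1, s2 = sorted(linked_locus.sites, key=lambda s: s.pos0)
        both = [r for r in reads if r.start <= s1.pos0 and s2.pos0 < r.start + 100]
        assert len(both) == 2 * (100 - 76)
        for r in both:
            b1 = r.sequence[s1.pos0 - r.start]
            b2 = r.sequence[s2.pos0 - r.start]
            if r.haplotype == "ref":
                assert (b1, b2) == (s1.ref, s2.ref)
            else:
                assert (b1, b2) == (s1.alt, s2.alt)

    def test_read_longer_than_contig_errors(self, small_locus):
        with pytest.raises(ValueError):
            mb.enumerate_reads(small_locus.sequence, small_locus.sites, 10_000)


class TestInjectErrors:
    def test_zero_rate_is_identity(self, small_locus):
        reads = mb.enumerate_reads(small_locus.sequence, small_locus.sites, 40)
        assert mb.inject_errors(reads, 0.0, 1) == reads

    def test_fixed_seed_reproducible(self, small_locus):
        reads = mb.enumerate_reads(small_locus.sequence, small_locus.sites, 40)
        a = mb.inject_errors(reads, 0.05, 123)
        b = mb.inject_errors(reads, 0.05, 123)
        assert a == b

    def test_mismatch_count_matches_binomial_expectation(self, small_locus):
        L, e = 60, 0.2
        reads = mb.enumerate_reads(small_locus.sequence, small_locus.sites, L)
        mutated = mb.inject_errors(reads, e, 7)
        diffs = [
            sum(1 for x, y in zip(r.sequence, m.sequence) if x != y)
            for r, m in zip(reads, mutated)
        ]
        n_bases = len(reads) * L
        total = sum(diffs)
        sigma = np.sqrt(n_bases * e * (1 - e))
        assert abs(total - n_bases * e) < 3 * sigma


class TestMapper:
    def test_error_free_reads_map_to_true_origin(self, small_locus):
        reads = mb.enumerate_reads(small_locus.sequence, small_locus.sites, 40)
        placements = mb.map_reads_ungapped(reads, small_locus.sequence)
        n_planted = {"ref": 0, "alt": 1}
        for r, p in zip(reads, placements):
            assert p.unique
            assert (p.position, p.strand) == (r.start, "+")
            assert p.distance == n_planted[r.haplotype]

    def test_repeat_placement_is_ambiguous(self):
        unit = "ACGTTGCAAGGCTTACCGTAGGATCCAATTGG"
        ref = unit + "TTTTCCCCAAAAGGGG" + unit
        placements = mb.map_reads_ungapped([unit[4:28]], ref)
        assert not placements[0].unique

    def test_matches_brute_force_oracle(self, small_locus):
        reads = mb.enumerate_reads(small_locus.sequence, small_locus.sites, 30)
        reads = mb.inject_errors(reads, 0.03, 17)
        placements = mb.map_reads_ungapped(reads, small_locus.sequence, uniqueness_margin=2)
        for r, p in zip(reads, placements):
            (d1, o1, s1), (d2, _, _) = brute_force_best_two(r.sequence, small_locus.sequence)
            assert p.distance == d1
            assert p.unique == (d2 - d1 >= 2)
            if p.unique:
                assert (p.position, p.strand) == (o1, s1)


class TestRunBiasSimulation:
    def test_error_free_every_replicate_exactly_half(self, small_locus):
        cfg = mb.SimulationConfig(read_length=50, error_rate=0.0, replicates=100, seed=2)
        res = mb.run_bias_simulation(cfg, small_locus.sequence, small_locus.sites)
        assert np.all(res.proportions == 0.5)
        assert res.sd == 0.0

    def test_shortcut_equals_exhaustive_remapping(self, small_locus):
        """Replay each replicate's error stream and remap exhaustively (oracle)."""
        cfg = mb.SimulationConfig(read_length=40, error_rate=0.05, replicates=4, seed=31,
                                  uniqueness_margin=2)
        res = mb.run_bias_simulation(cfg, small_locus.sequence, small_locus.sites)
        base = mb.enumerate_reads(small_locus.sequence, small_locus.sites, 40)
        site = small_locus.sites[0]
        children = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
        for rep in range(cfg.replicates):
            gen = np.random.default_rng(children[rep])
            mutated = mb.inject_errors(base, cfg.error_rate, gen)
            placements = mb.map_reads_ungapped(mutated, small_locus.sequence, cfg.uniqueness_margin)
            n_ref = n_alt = 0
            for r, p in zip(mutated, placements):
                if not p.unique:
                    continue
                if not p.position <= site.pos0 < p.position + 40:
                    continue
                if p.strand == "+":
                    b = r.sequence[site.pos0 - p.position]
                else:
                    b = revcomp(r.sequence)[site.pos0 - p.position]
                if b == site.ref:
                    n_ref += 1
                elif b == site.alt:
                    n_alt += 1
            assert res.proportions[rep] == pytest.approx(n_ref / (n_ref + n_alt), abs=1e-12)

    def test_mean_within_error_rate_envelope(self, small_locus):
        cfg = mb.SimulationConfig(read_length=50, error_rate=0.01, replicates=200, seed=8)
        res = mb.run_bias_simulation(cfg, small_locus.sequence, small_locus.sites)
        assert abs(res.mean - 0.5) < cfg.error_rate

    def test_bias_nondecreasing_in_error_rate_with_coupled_seeds(self, small_locus):
        """Coupled error draws; weak monotonicity asserted within Monte-Carlo error."""
        means, ses = [], []
        for e in (0.001, 0.005, 0.01):
            cfg = mb.SimulationConfig(read_length=50, error_rate=e, replicates=300, seed=44)
            res = mb.run_bias_simulation(cfg, small_locus.sequence, small_locus.sites)
            means.append(res.mean)
            ses.append(res.sd / np.sqrt(res.proportions.size))
        for lo, hi, se_lo, se_hi in zip(means, means[1:], ses, ses[1:]):
            assert hi >= lo - 3 * np.hypot(se_lo, se_hi)

    def test_duplicated_site_context_yields_missing_replicates(self):
        unit = "ACGTTGCAAGGCTTACCGTAGGATCCAATTGGCCTTAAGGCGCGCATAT"
        ref = unit + unit  # every window around the site has a perfect second copy
        site = BiallelicSite("dup", "c", 10, unit[9], "A" if unit[9] != "A" else "C")
        cfg = mb.SimulationConfig(read_length=20, error_rate=0.0, replicates=2, seed=1)
        with pytest.warns(UserWarning):
            res = mb.run_bias_simulation(cfg, ref, [site])
        assert res.n_missing == 2
        assert res.n_ambiguous > 0


class TestSensitivitySwap:
    def test_symmetric_error_free_reads_give_zero_delta(self, small_locus):
        reads = mb.enumerate_reads(small_locus.sequence, small_locus.sites, 40)
        res = mb.sensitivity_swap_analysis(reads, small_locus.sequence, small_locus.sites[0])
        assert res.proportion_original == pytest.approx(0.5)
        assert res.delta == pytest.approx(0.0)

    def test_imbalanced_noisy_readset_has_small_delta(self, small_locus):
        site = small_locus.sites[0]
        base = mb.enumerate_reads(small_locus.sequence, [site], 60)
        # 2:1 alt:ref imbalance by replicating alt-haplotype reads
        reads = [r for r in base] + [r for r in base if r.haplotype == "alt"]
        reads = reads * 10
        reads = mb.inject_errors(reads, 0.005, 99)
        res = mb.sensitivity_swap_analysis(reads, small_locus.sequence, site)
        assert res.proportion_original == pytest.approx(1 / 3, abs=0.02)
        assert res.delta < 0.005

    def test_non_snv_rejected(self, small_locus):
        indel = BiallelicSite("ind", "c", 5, "A", "AT")
        with pytest.raises(ValueError):
            mb.sensitivity_swap_analysis(["ACGT"], small_locus.sequence, indel)

    def test_sam_input_accepted(self, tmp_path, small_locus):
        from conftest import write_sam

        site = small_locus.sites[0]
        seq = small_locus.sequence[site.pos0 - 20 : site.pos0 + 20]
        alt = seq[:20] + site.alt + seq[21:]
        sam = write_sam(
            tmp_path / "r.sam", "c", len(small_locus.sequence),
            [("a", 0, site.pos0 - 19, 60, "40M", seq, "I" * 40),
             ("b", 0, site.pos0 - 19, 60, "40M", alt, "I" * 40)],
        )
        res = mb.sensitivity_swap_analysis(sam, small_locus.sequence, site)
        assert res.proportion_original == pytest.approx(0.5)
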