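"""Reference-mapping-bias simulation and reference-swap sensitivity analysis.

Allele-specific read counting is vulnerable to mapping bias: reads carrying
the alternative allele differ from the reference by one extra mismatch and
can be preferentially lost or mismapped, inflating the apparent
reference-allele proportion at heterozygous sites. The simulation here
quantifies that bias for a given locus:

1. enumerate every read placement overlapping the SNP site(s), one read per
   start position per haplotype (reference alleles co-occur on one haplotype,
   alternative alleles on the other, matching perfect LD between linked
   sites);
2. inject independent per-base substitution errors (Bernoulli rate, uniform
   choice among the three other bases, all bases at quality 41);
3. remap with a built-in exhaustive ungapped mapper that keeps a read only if
   its best Hamming-distance placement over all offsets and both strands
   beats the second best by a uniqueness margin (the stand-in for an
   aligner-specific MAPQ cutoff, chosen so the procedure is deterministic and
   checkable against a brute-force scorer);
4. record the proportion of retained allele-informative reads supporting the
   reference allele, per replicate.

The companion sensitivity analysis swaps the reference base at the SNP for
the alternative allele, remaps identically against both references, and
reports the change in the measured allele proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequtil import encode, revcomp_codes, validate_dna
from .variants import BiallelicSite

_BIG = np.float32(1e9)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


@dataclass(frozen=True)
class SimRead:
    """A simulated single-end read with its ground truth."""

    sequence: str
    start: int  # true 0-based origin on the source contig
    haplotype: str  # "ref" or "alt"


@dataclass
class Placement:
    """Best ungapped placement of one read."""

    position: int
    strand: str  # "+" or "-"
    distance: int
    unique: bool  # best beats second best by >= uniqueness_margin


@dataclass
class SimulationConfig:
    """Parameters of one mapping-bias simulation grid cell."""

    read_length: int
    error_rate: float
    replicates: int = 10000
    base_quality: int = 41
    uniqueness_margin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.uniqueness_margin < 1:
            raise ValueError("uniqueness_margin must be >= 1")


@dataclass
class SimulationResult:
    """Per-replicate reference-allele proportions plus mapping loss counters."""

    proportions: np.ndarray  # NaN for replicates with zero retained informative reads
    n_reads_per_replicate: int
    n_ambiguous: int = 0
    n_fallback: int = 0

    def _valid(self) -> np.ndarray:
        return self.proportions[~np.isnan(self.proportions)]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.proportions).sum())

    @property
    def mean(self) -> float:
        return float(self._valid().mean())

    @property
    def sd(self) -> float:
        v = self._valid()
        return float(v.std(ddof=1)) if v.size > 1 else 0.0

    @property
    def min(self) -> float:
        return float(self._valid().min())

    @property
    def max(self) -> float:
        return float(self._valid().max())


def enumerate_reads(
    reference: str, sites: list[BiallelicSite], read_length: int
) -> list[SimRead]:
    """All reads of length ``read_length`` overlapping at least one site, per haplotype.

    One read per valid start position and haplotype. The "ref" haplotype
    carries reference alleles at every covered site; the "alt" haplotype
    carries alternative alleles jointly (perfect-LD convention for linked
    sites). Starts that would run off the contig are dropped with a warning.
    """
    ref = validate_dna(reference, name="reference")
    L = read_length
    if L < 1:
        raise ValueError("read length must be >= 1")
    if L > len(ref):
        raise ValueError(f"read length {L} exceeds contig length {len(ref)}")
    site_pos: dict[int, BiallelicSite] = {}
    for s in sites:
        if not s.is_snv:
            raise ValueError(f"site {s.id}: simulation handles SNVs only")
        if not 0 <= s.pos0 < len(ref):
            raise ValueError(f"site {s.id} position {s.pos} outside reference")
        site_pos[s.pos0] = s
    starts: set[int] = set()
    truncated = False
    for p in site_pos:
        for st in range(p - L + 1, p + 1):
            if 0 <= st <= len(ref) - L:
                starts.add(st)
            else:
                truncated = True
    if truncated:
        warnings.warn("some read starts fall outside the contig; fewer reads enumerated", stacklevel=2)
    reads: list[SimRead] = []
    for st in sorted(starts):
        window = ref[st : st + L]
        reads.append(SimRead(window, st, "ref"))
        alt_chars = list(window)
        for p, s in site_pos.items():
            if st <= p < st + L:
                alt_chars[p - st] = s.alt
        reads.append(SimRead("".join(alt_chars), st, "alt"))
    return reads


def inject_errors(
    reads: list[SimRead], error_rate: float, rng: int | np.random.Generator
) -> list[SimRead]:
    """Substitute each base independently with probability ``error_rate``.

    A hit base is replaced by one of the three other bases uniformly. The
    random draws are made for every base regardless of the rate (error iff
    u < rate), so runs at different rates from the same seed share error
    positions — a coupling that makes rate comparisons paired.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if not reads:
        return []
    mat = np.vstack([encode(r.sequence) for r in reads])
    mat = _inject_errors_matrix(mat, error_rate, gen)
    bases = np.frombuffer(b"ACGTN", dtype=np.uint8)
    out = []
    for row, r in zip(mat, reads):
        out.append(SimRead(bases[row].tobytes().decode(), r.start, r.haplotype))
    return out


def _inject_errors_matrix(mat: np.ndarray, error_rate: float, gen: np.random.Generator) -> np.ndarray:
    u = gen.random(mat.shape)
    shift = gen.integers(1, 4, size=mat.shape, dtype=np.uint8)
    hit = u < error_rate
    if hit.any():
        mat = mat.copy()
        mat[hit] = (mat[hit] + shift[hit]) % 4  # N bases are never generated by the synthesizer
    return mat


class _ExhaustiveIndex:
    """All-offsets, both-strands Hamming scorer for fixed-length reads.

    Distances are computed as ``L - matches`` where matches come from a
    one-hot matrix product between read codes and sliding reference windows;
    N never matches anything.
    """

    def __init__(self, refcodes: np.ndarray, read_length: int):
        if refcodes.size < read_length:
            raise ValueError("reference shorter than read length")
        self.L = read_length
        self.ref_length = refcodes.size
        self.n_offsets = refcodes.size - read_length + 1
        fwd = np.lib.stride_tricks.sliding_window_view(refcodes, read_length)
        rc = np.lib.stride_tricks.sliding_window_view(revcomp_codes(refcodes), read_length)
        allw = np.vstack([fwd, rc])
        self._onehot = np.concatenate(
            [(allw == b) for b in range(4)], axis=1
        ).astype(np.float32)

    def distances(self, read_mat: np.ndarray) -> np.ndarray:
        """(n_reads, 2*n_offsets) Hamming distances; columns = fwd offsets then rc offsets."""
        R = np.concatenate([(read_mat == b) for b in range(4)], axis=1).astype(np.float32)
        return self.L - R @ self._onehot.T

    def decode_column(self, col: int) -> tuple[int, str]:
        if col < self.n_offsets:
            return col, "+"
        return self.ref_length - self.L - (col - self.n_offsets), "-"

    def best_two(
        self, read_mat: np.ndarray, chunk: int = 512
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per read: best distance, second-best distance, position, strand code (0 '+', 1 '-')."""
        n = read_mat.shape[0]
        d1 = np.empty(n, dtype=np.int64)
        d2 = np.empty(n, dtype=np.int64)
        pos = np.empty(n, dtype=np.int64)
        strand = np.empty(n, dtype=np.int8)
        for lo in range(0, n, chunk):
            sl = slice(lo, min(lo + chunk, n))
            d = self.distances(read_mat[sl])
            rows = np.arange(d.shape[0])
            i1 = d.argmin(axis=1)
            best = d[rows, i1]
            d[rows, i1] = _BIG
            second = d.min(axis=1)
            d1[sl] = np.rint(best).astype(np.int64)
            d2[sl] = np.rint(second).astype(np.int64)
            for j, col in enumerate(i1):
                p, s = self.decode_column(int(col))
                pos[lo + j] = p
                strand[lo + j] = 0 if s == "+" else 1
        return d1, d2, pos, strand


def map_reads_ungapped(
    reads: list[SimRead] | list[str],
    reference: str,
    uniqueness_margin: int = 1,
) -> list[Placement]:
    """Place each read at its Hamming-minimal ungapped offset over both strands.

    A placement is flagged ``unique`` only when the best distance beats the
    second best by at least ``uniqueness_margin``; non-unique reads should be
    discarded by callers (the proxy for a MAPQ cutoff).
    """
    seqs = [r.sequence if isinstance(r, SimRead) else r for r in reads]
    refcodes = encode(validate_dna(reference, name="reference"))
    placements: list[Placement | None] = [None] * len(seqs)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for L, idxs in by_len.items():
        index = _ExhaustiveIndex(refcodes, L)
        mat = np.vstack([encode(seqs[i]) for i in idxs])
        d1, d2, pos, strand = index.best_two(mat)
        for j, i in enumerate(idxs):
            placements[i] = Placement(
                int(pos[j]),
                "+" if strand[j] == 0 else "-",
                int(d1[j]),
                bool(d2[j] - d1[j] >= uniqueness_margin),
            )
    return placements  # type: ignore[return-value]


def _read_base_at(read_row: np.ndarray, placement_pos: int, strand: int, ref_pos: int, L: int) -> int:
    """Base code the placed read reports at reference position ``ref_pos``."""
    if strand == 0:
        return int(read_row[ref_pos - placement_pos])
    return int(_COMP[read_row[placement_pos + L - 1 - ref_pos]])


def run_bias_simulation(
    config: SimulationConfig,
    reference: str,
    sites: list[BiallelicSite],
) -> SimulationResult:
    """Replicated enumerate -> inject -> remap -> count pipeline.

    Each replicate draws a fresh RNG stream spawned from the master seed by
    replicate index, so results are independent of execution order. A read
    votes for the reference haplotype only if every covered site shows the
    reference allele (and symmetrically for the alternative haplotype); other
    bases and haplotype-discordant combinations are uninformative.

    The remapping shortcut: a read differing from its origin window by
    ``d`` mismatches cannot be beaten (within the uniqueness margin) by any
    other placement whose reference-vs-origin-window distance floor exceeds
    ``2*d + margin``; such reads are placed at their origin without a full
    scan. Reads failing the shortcut get the exact exhaustive scan. This is
    mathematically identical to mapping every read exhaustively.
    """
    ref = validate_dna(reference, name="reference")
    refcodes = encode(ref)
    L = config.read_length
    base_reads = enumerate_reads(ref, sites, L)
    if not base_reads:
        raise ValueError("no reads enumerated; check sites and read length")
    n_reads = len(base_reads)
    mat0 = np.vstack([encode(r.sequence) for r in base_reads])
    starts = np.array([r.start for r in base_reads])
    refslices = np.vstack([refcodes[r.start : r.start + L] for r in base_reads])

    site_list = sorted((s for s in sites), key=lambda s: s.pos0)
    site_positions = [s.pos0 for s in site_list]
    ref_codes_at = {s.pos0: int(encode(s.ref)[0]) for s in site_list}
    alt_codes_at = {s.pos0: int(encode(s.alt)[0]) for s in site_list}
    # group reads by the set of sites they cover so per-replicate voting is
    # a handful of vectorised comparisons instead of a per-read loop
    group_rows: dict[tuple[int, ...], list[int]] = {}
    for i, r in enumerate(base_reads):
        key = tuple(p for p in site_positions if r.start <= p < r.start + L)
        group_rows.setdefault(key, []).append(i)
    groups = []
    for key, rows_list in group_rows.items():
        rows = np.array(rows_list, dtype=np.int64)
        colmat = np.vstack([[p - starts[i] for p in key] for i in rows_list]).astype(np.int64)
        ref_t = np.array([ref_codes_at[p] for p in key])
        alt_t = np.array([alt_codes_at[p] for p in key])
        groups.append((rows, colmat, ref_t, alt_t))

    index = _ExhaustiveIndex(refcodes, L)
    # uniqueness floor per read start: second-best distance of the pure
    # reference window (best is 0 at the origin itself)
    uniq_starts = np.unique(starts)
    pure = np.vstack([refcodes[s : s + L] for s in uniq_starts])
    _, floor_vals, _, _ = index.best_two(pure)
    floor_by_start = dict(zip(uniq_starts.tolist(), floor_vals.tolist()))
    floors = np.array([floor_by_start[s] for s in starts.tolist()])

    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    proportions = np.full(config.replicates, np.nan)
    n_ambiguous = 0
    n_fallback = 0
    margin = config.uniqueness_margin
    zero_warned = False
    for rep in range(config.replicates):
        gen = np.random.default_rng(children[rep])
        mat = _inject_errors_matrix(mat0, config.error_rate, gen)
        d_origin = (mat != refslices).sum(axis=1)
        ok = floors >= 2 * d_origin + margin
        n_ref_votes = 0
        n_alt_votes = 0
        for rows, colmat, ref_t, alt_t in groups:
            sub = mat[rows[:, None], colmat]
            keep = ok[rows]
            n_ref_votes += int(((sub == ref_t).all(axis=1) & keep).sum())
            n_alt_votes += int(((sub == alt_t).all(axis=1) & keep).sum())
        for i in np.nonzero(~ok)[0]:
            n_fallback += 1
            d1, d2, pos, strand = index.best_two(mat[i : i + 1])
            if d2[0] - d1[0] < margin:
                n_ambiguous += 1
                continue
            p0, s0 = int(pos[0]), int(strand[0])
            calls, refs_t, alts_t = [], [], []
            for p in site_positions:
                if p0 <= p < p0 + L:
                    calls.append(_read_base_at(mat[i], p0, s0, p, L))
                    refs_t.append(ref_codes_at[p])
                    alts_t.append(alt_codes_at[p])
            if calls and calls == refs_t:
                n_ref_votes += 1
            elif calls and calls == alts_t:
                n_alt_votes += 1
        informative = n_ref_votes + n_alt_votes
        if informative == 0:
            if not zero_warned:
                warnings.warn("replicate with zero retained informative reads recorded as missing", stacklevel=2)
                zero_warned = True
            continue
        proportions[rep] = n_ref_votes / informative
    return SimulationResult(proportions, n_reads, n_ambiguous, n_fallback)


@dataclass
class SwapResult:
    proportion_original: float
    proportion_swapped: float

    @property
    def delta(self) -> float:
        return abs(self.proportion_original - self.proportion_swapped)


def sensitivity_swap_analysis(
    reads,
    reference: str,
    site: BiallelicSite,
    uniqueness_margin: int = 1,
) -> SwapResult:
    """Reference-swap sensitivity analysis for one SNV.

    Maps the same reads against the original reference and against a
    "changed" reference carrying the alternative allele at the SNP, counting
    the proportion of unique placements that report the (original) reference
    allele each time. A site robust to mapping bias shows a small difference.

    ``reads`` may be a list of sequences / :class:`SimRead`, or a SAM/BAM
    path whose primary records supply the read sequences.
    """
    if not site.is_snv:
        raise ValueError(f"site {site.id}: sensitivity swap requires a biallelic SNV")
    seqs = _extract_sequences(reads)
    ref = validate_dna(reference, name="reference")
    if not 0 <= site.pos0 < len(ref):
        raise ValueError(f"site {site.id} outside reference")
    swapped = ref[: site.pos0] + site.alt + ref[site.pos0 + 1 :]

    def proportion(refseq: str) -> float:
        placements = map_reads_ungapped(seqs, refseq, uniqueness_margin)
        n_ref = n_alt = 0
        ref_code = int(encode(site.ref)[0])
        alt_code = int(encode(site.alt)[0])
        for s, pl in zip(seqs, placements):
            if pl is None or not pl.unique:
                continue
            L = len(s)
            if not pl.position <= site.pos0 < pl.position + L:
                continue
            base = _read_base_at(encode(s), pl.position, 0 if pl.strand == "+" else 1, site.pos0, L)
            if base == ref_code:
                n_ref += 1
            elif base == alt_code:
                n_alt += 1
        if n_ref + n_alt == 0:
            raise ValueError("no allele-informative unique placements at the site")
        return n_ref / (n_ref + n_alt)

    return SwapResult(proportion(ref), proportion(swapped))


def _extract_sequences(reads) -> list[str]:
    if isinstance(reads, (str, Path)):
        import pysam

        seqs = []
        with pysam.AlignmentFile(str(reads), check_sq=False) as af:
            for rec in af:
                if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                    continue
                seqs.append(rec.query_sequence)
        return seqs
    return [r.sequence if isinstance(r, SimRead) else str(r) for r in reads]
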