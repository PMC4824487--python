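"""Candidate causal-variant prioritization.

GWAS hits are usually surrogates: the causal variant is some member of the
LD block. Prioritization here combines three signals, mirroring standard
post-GWAS practice:

* linkage disequilibrium — phased-haplotype r² with the tag SNP (strong LD
  defined as r² > 0.8; perfect proxies, r² = 1.0, are statistically
  indistinguishable from the tag);
* open chromatin — overlap with DNase I hypersensitive sites, quantified as
  the DNase-seq signal relative to the peak-calling threshold (relative
  signal > 1 means a significant DHS);
* allele-differential motif fit — best log-odds PWM score of each allele's
  61-nt window; a nonzero delta means the variant changes a predicted
  transcription-factor binding site.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequtil import revcomp, validate_dna
from .variants import BiallelicSite


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes: rows are the 2N haplotypes, columns phased sites (0=ref, 1=alt)."""

    data: np.ndarray
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.data.shape[1] != len(self.site_ids):
            raise ValueError("site_ids length must match number of columns")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("haplotype matrix entries must be 0 or 1 (no missing data)")

    def column(self, site: str) -> np.ndarray:
        try:
            return self.data[:, self.site_ids.index(site)]
        except ValueError:
            raise KeyError(f"site {site!r} not in haplotype matrix") from None

    @classmethod
    def from_vcf(cls, path: str | Path) -> "HaplotypeMatrix":
        """Build from a phased VCF (biallelic records only; all GTs must be phased)."""
        from cyvcf2 import VCF

        ids, cols = [], []
        for rec in VCF(str(path)):
            if len(rec.ALT) != 1:
                continue
            col = []
            for gt in rec.genotypes:
                a0, a1, phased = gt[:3]
                if not phased and a0 != a1:
                    raise ValueError(f"unphased heterozygote at {rec.ID or rec.POS}")
                if a0 < 0 or a1 < 0:
                    raise ValueError(f"missing genotype at {rec.ID or rec.POS}")
                col.extend([a0, a1])
            ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
            cols.append(col)
        return cls(np.array(cols, dtype=np.int8).T, ids)


def ld_r2(haps: HaplotypeMatrix, site_a: str, site_b: str) -> tuple[float, float]:
    """(r², D') between two sites from phased haplotype frequencies."""
    a = haps.column(site_a).astype(float)
    b = haps.column(site_b).astype(float)
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0):
        raise ValueError(f"site {site_a!r} is monomorphic among haplotypes")
    if p_b in (0.0, 1.0):
        raise ValueError(f"site {site_b!r} is monomorphic among haplotypes")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b) if d > 0 else min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    return float(r2), float(d_prime)


def select_ld_partners(
    haps: HaplotypeMatrix, tag_site: str, threshold: float = 0.8
) -> list[tuple[str, float]]:
    """Sites with r² > threshold against the tag, sorted by descending r².

    The tag itself is excluded. Monomorphic sites are skipped (they carry no
    LD information). r² = 1.0 entries are the perfect-proxy set whose
    association signals cannot be distinguished from the tag's.
    """
    partners = []
    for sid in haps.site_ids:
        if sid == tag_site:
            continue
        try:
            r2, _ = ld_r2(haps, tag_site, sid)
        except ValueError:
            continue
        if r2 > threshold:
            partners.append((sid, r2))
    partners.sort(key=lambda x: (-x[1], x[0]))
    return partners


@dataclass
class DhsAnnotation:
    site_id: str
    cell_type: str | None
    in_peak: bool
    relative_signal: float


def annotate_dhs_overlap(
    sites: list[BiallelicSite],
    peaks: pd.DataFrame,
    threshold: float,
    *,
    cell_type: str | None = None,
    background: dict[str, float] | None = None,
) -> list[DhsAnnotation]:
    """Annotate sites with DHS peak overlap and signal relative to threshold.

    ``peaks`` is a BED-like frame with columns (chrom, start, end, signal),
    0-based half-open. ``threshold`` is the peak caller's significance
    threshold; relative signal = signal / threshold. Sites outside every peak
    get the background track value / threshold when ``background`` (site id
    -> raw signal) is supplied, else 0.
    """
    required = {"chrom", "start", "end", "signal"}
    if not required.issubset(peaks.columns):
        raise ValueError(f"peaks must have columns {sorted(required)}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = peaks[peaks["start"] >= peaks["end"]]
    if len(bad):
        raise ValueError(f"malformed peak intervals (start >= end): {bad.index.tolist()}")
    by_chrom: dict[str, tuple[list[int], np.ndarray, np.ndarray]] = {}
    for chrom, grp in peaks.groupby("chrom"):
        g = grp.sort_values("start")
        by_chrom[str(chrom)] = (g["start"].tolist(), g["end"].to_numpy(), g["signal"].to_numpy())
    out = []
    for site in sites:
        hit_signal = None
        if site.contig in by_chrom:
            starts, ends, signals = by_chrom[site.contig]
            # peaks with start <= pos0; scan back over candidates (peaks may nest)
            i = bisect.bisect_right(starts, site.pos0) - 1
            while i >= 0:
                if ends[i] > site.pos0:
                    hit_signal = float(signals[i]) if hit_signal is None else max(hit_signal, float(signals[i]))
                i -= 1
        if hit_signal is not None:
            out.append(DhsAnnotation(site.id, cell_type, True, hit_signal / threshold))
        elif background is not None and site.id in background:
            out.append(DhsAnnotation(site.id, cell_type, False, background[site.id] / threshold))
        else:
            out.append(DhsAnnotation(site.id, cell_type, False, 0.0))
    return out


@dataclass
class Pwm:
    """Position weight matrix of per-position base probabilities (A, C, G, T columns)."""

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: matrix must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: each position's probabilities must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"PWM {self.name}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls, name: str, counts: np.ndarray, pseudocount: float = 0.01, background=None
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        kwargs = {} if background is None else {"background": np.asarray(background, float)}
        return cls(name, probs, **kwargs)

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.name, self.probs[::-1, ::-1].copy(), self.background[::-1].copy())


def load_pwms(path: str | Path, pseudocount: float = 0.01) -> list[Pwm]:
    """Parse PWM text: ``>name`` header lines, then per-position rows of 4 numbers (A C G T).

    Rows are treated as counts and pseudocounted/normalized; rows already
    summing to 1 pass through the same normalization unchanged up to the
    pseudocount.
    """
    pwms = []
    name, rows = None, []

    def flush():
        if name is not None:
            if not rows:
                raise ValueError(f"PWM {name!r} has no matrix rows")
            pwms.append(Pwm.from_counts(name, np.array(rows, dtype=float), pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].strip(), []
            else:
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"PWM row must have 4 columns (A C G T): {line!r}")
                rows.append(vals)
    flush()
    return pwms


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _log_odds(pwm: Pwm) -> np.ndarray:
    return np.log2(pwm.probs / pwm.background)


def _best_score(window: str, pwm: Pwm, center: int) -> tuple[float, int, str]:
    """Max log-odds over placements (both strands) covering the center position."""
    w = pwm.width
    best = (-math.inf, -1, "+")
    for strand, matrix in (("+", _log_odds(pwm)), ("-", _log_odds(pwm.reverse_complement()))):
        for off in range(0, len(window) - w + 1):
            if not off <= center < off + w:
                continue
            score = 0.0
            ok = True
            for j, base in enumerate(window[off : off + w]):
                idx = _BASE_IDX.get(base)
                if idx is None:
                    ok = False
                    break
                score += matrix[j, idx]
            if ok and score > best[0]:
                best = (score, off, strand)
    return best


@dataclass
class MotifScanResult:
    motif: str
    best_score_ref: float
    best_score_alt: float
    best_offset: int
    strand: str

    @property
    def delta(self) -> float:
        return self.best_score_alt - self.best_score_ref


def pwm_allele_scan(
    reference: str,
    site: BiallelicSite,
    pwms: list[Pwm],
    window: int = 61,
) -> list[MotifScanResult]:
    """Score both alleles' windows against each PWM; delta = best_alt - best_ref.

    The window is ``window`` nt (odd) centered on the SNP; placements are
    restricted to those overlapping the SNP position, scanned on both
    strands. ``best_offset``/``strand`` describe the placement of the
    higher-scoring allele.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd so the site is centered")
    if not site.is_snv:
        raise ValueError(f"site {site.id}: PWM scanning handles SNVs only")
    ref = validate_dna(reference, name="reference")
    half = window // 2
    p = site.pos0
    if p - half < 0 or p + half + 1 > len(ref):
        raise ValueError(f"window around site {site.id} extends outside the reference")
    win_ref = ref[p - half : p + half + 1]
    if win_ref[half] != site.ref:
        raise ValueError(
            f"reference base {win_ref[half]!r} at site {site.id} does not match ref allele {site.ref!r}"
        )
    win_alt = win_ref[:half] + site.alt + win_ref[half + 1 :]
    out = []
    for pwm in pwms:
        if pwm.width > window:
            raise ValueError(f"PWM {pwm.name} wider than the scan window")
        s_ref, off_ref, str_ref = _best_score(win_ref, pwm, half)
        s_alt, off_alt, str_alt = _best_score(win_alt, pwm, half)
        off, strand = (off_alt, str_alt) if s_alt >= s_ref else (off_ref, str_ref)
        out.append(MotifScanResult(pwm.name, s_ref, s_alt, off, strand))
    return out


def prioritize_report(
    haps: HaplotypeMatrix,
    tag_site: str,
    sites: list[BiallelicSite],
    peaks: pd.DataFrame,
    threshold: float,
    *,
    ld_threshold: float = 0.8,
    cell_type: str | None = None,
) -> pd.DataFrame:
    """Combined ranking: LD partners annotated with DHS overlap.

    Rows sorted by (perfect LD, in_peak, relative_signal) descending — the
    highest-priority candidate causal variants first.
    """
    partners = dict(select_ld_partners(haps, tag_site, ld_threshold))
    selected = [s for s in sites if s.id in partners]
    annos = {a.site_id: a for a in annotate_dhs_overlap(selected, peaks, threshold, cell_type=cell_type)}
    rows = []
    for s in selected:
        a = annos[s.id]
        rows.append(
            {
                "site": s.id,
                "r2": partners[s.id],
                "perfect_ld": partners[s.id] >= 1.0 - 1e-12,
                "in_peak": a.in_peak,
                "relative_signal": a.relative_signal,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["perfect_ld", "in_peak", "relative_signal", "r2"], ascending=False
        ).reset_index(drop=True)
    return df
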