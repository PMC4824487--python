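"""Paired-end ungapped alignment to an artificial chromosome, with SAM output.

Real AS3C-seq libraries are aligned with an external aligner; this module
exists so the full generate -> align -> count -> test pipeline runs without
one. It places each mate with the exhaustive unique-best ungapped mapper
from :mod:`as3c.mapbias` and writes a plain-text SAM the counting functions
(and any SAM-aware tool) can consume. Pairs with an ambiguous or unmappable
mate are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .mapbias import _ExhaustiveIndex
from .sequtil import encode, revcomp, validate_dna


@dataclass
class AlignmentStats:
    n_pairs: int
    n_written: int
    n_dropped_ambiguous: int


def align_pairs_to_sam(
    pairs: list[tuple[str, str, str]],
    reference_name: str,
    reference_seq: str,
    out_path: str | Path,
    *,
    uniqueness_margin: int = 1,
    base_quality: int = 41,
    mapq: int = 60,
) -> AlignmentStats:
    """Align (name, mate1, mate2) tuples and write a coordinate-less SAM.

    Mates are mapped independently (Hamming-minimal, both strands); a pair is
    written only when both mates place uniquely. Reverse-strand mates are
    stored reference-oriented with the reverse flag set, CIGAR is always a
    full match, and MAPQ is a fixed value standing for "unique within the
    margin".
    """
    ref = validate_dna(reference_seq, name="reference")
    refcodes = encode(ref)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": reference_name, "LN": len(ref)}],
        }
    )
    by_len: dict[int, _ExhaustiveIndex] = {}

    def place(seqs: list[str]):
        out = [None] * len(seqs)
        lens: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            lens.setdefault(len(s), []).append(i)
        for L, idxs in lens.items():
            if L not in by_len:
                by_len[L] = _ExhaustiveIndex(refcodes, L)
            mat = np.vstack([encode(seqs[i]) for i in idxs])
            d1, d2, pos, strand = by_len[L].best_two(mat)
            for j, i in enumerate(idxs):
                if d2[j] - d1[j] >= uniqueness_margin:
                    out[i] = (int(pos[j]), int(strand[j]))
        return out

    all_seqs: list[str] = []
    for _, m1, m2 in pairs:
        all_seqs.append(m1)
        all_seqs.append(m2)
    placements = place(all_seqs)

    n_written = n_dropped = 0
    with pysam.AlignmentFile(str(out_path), "wh", header=header) as sam:
        for k, (name, m1, m2) in enumerate(pairs):
            p1, p2 = placements[2 * k], placements[2 * k + 1]
            if p1 is None or p2 is None:
                n_dropped += 1
                continue
            records = []
            for mate_idx, (seq, (pos, strand)) in enumerate(((m1, p1), (m2, p2))):
                other_pos, other_strand = (p2, p1)[mate_idx][0], (p2, p1)[mate_idx][1]
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.reference_id = 0
                a.reference_start = pos
                a.mapping_quality = mapq
                a.cigarstring = f"{len(seq)}M"
                a.query_sequence = revcomp(seq) if strand == 1 else seq
                a.query_qualities = pysam.qualitystring_to_array(chr(base_quality + 33) * len(seq))
                flag = 0x1 | 0x2 | (0x40 if mate_idx == 0 else 0x80)
                if strand == 1:
                    flag |= 0x10
                if other_strand == 1:
                    flag |= 0x20
                a.flag = flag
                a.next_reference_id = 0
                a.next_reference_start = other_pos
                records.append(a)
            lo = min(r.reference_start for r in records)
            hi = max(r.reference_start + r.query_length for r in records)
            tlen = hi - lo
            for r in records:
                r.template_length = tlen if r.reference_start == lo else -tlen
            for r in records:
                sam.write(r)
            n_written += 1
    return AlignmentStats(len(pairs), n_written, n_dropped)
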