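"""Small DNA-string utilities shared across the toolkit.

Coordinates are 0-based half-open everywhere inside the package; 1-based
coordinates appear only at VCF boundaries (:class:`as3c.variants.BiallelicSite.pos`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Integer codes used by the vectorised mapper: A=0, C=1, G=2, T=3, N=4.
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASES = "ACGTN"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, allow_n: bool = True, name: str = "sequence") -> str:
    """Return ``seq`` uppercased, or raise ``ValueError`` naming the first bad position."""
    if not seq:
        raise ValueError(f"{name} is empty")
    up = seq.upper()
    alphabet = set("ACGTN" if allow_n else "ACGT")
    for i, c in enumerate(up):
        if c not in alphabet:
            raise ValueError(f"{name} contains non-ACGT{'N' if allow_n else ''} character {c!r} at position {i}")
    return up


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0 C=1 G=2 T=3 N=4)."""
    table = np.full(128, 4, dtype=np.uint8)
    for base, code in BASE_CODES.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr]


def decode(codes: np.ndarray) -> str:
    return "".join(CODE_BASES[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (N maps to N)."""
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    return comp[codes][::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered dict of name -> uppercase sequence."""
    from pyfaidx import Fasta

    fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    try:
        return {name: str(rec[:]) for name, rec in fasta.items()}
    finally:
        fasta.close()


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
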