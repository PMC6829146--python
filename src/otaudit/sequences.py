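"""Small DNA-sequence utilities shared across modules.

Coordinates are 0-based half-open everywhere except at VCF boundaries,
where positions are 1-based (the VCF convention).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes mapped to the set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# uint8 lookup: ASCII byte -> base code, 4 for anything ambiguous.
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def validate_concrete(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq or any(b not in "ACGT" for b in seq):
        raise InvalidArgumentError(f"{what} must be non-empty and contain only A/C/G/T: {seq!r}")
    return seq


def validate_iupac(pattern: str, what: str = "pattern") -> str:
    pattern = pattern.upper()
    if not pattern or any(b not in IUPAC for b in pattern):
        raise InvalidArgumentError(f"{what} must contain only IUPAC codes: {pattern!r}")
    return pattern


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise InvalidArgumentError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def write_fasta(genome: dict[str, str], path) -> None:
    """Write chromosomes as FASTA with a uniform 60-column line layout."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an in-memory {name: sequence} mapping."""
    import pyfaidx

    fasta = pyfaidx.Fasta(str(path))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}
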