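"""Small sequence utilities shared across the pipeline.

Everything here operates on plain uppercase DNA strings. Coordinates in
this package are 0-based half-open internally; writers that emit 1-based
inclusive positions say so in their headers.
"""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                           "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

#: IUPAC nucleotide classes; N matches any base.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def iupac_match(mask: str, seq: str) -> bool:
    """True iff every base of ``seq`` falls in the IUPAC class of ``mask``.

    ``N`` in the mask matches anything, including ``N`` in the sequence.
    An ``N`` in the sequence matches only an ``N``/full class in the mask.
    """
    if len(mask) != len(seq):
        raise ValueError(f"iupac_match: unequal lengths {len(mask)} vs {len(seq)}")
    for m, s in zip(mask.upper(), seq.upper()):
        if m == "N":
            continue
        try:
            cls = IUPAC[m]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {m!r} in mask {mask!r}") from None
        if s not in cls:
            return False
    return True


def validate_dna(seq: str, *, alphabet: str = "ACGTN", context: str = "sequence") -> None:
    """Raise with the offending position if ``seq`` strays outside ``alphabet``."""
    allowed = set(alphabet)
    for i, base in enumerate(seq):
        if base not in allowed:
            raise ValueError(f"{context}: invalid character {base!r} at position {i}")
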