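"""Small nucleotide-sequence helpers shared across the pipeline."""

from __future__ import annotations

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.upper().translate(_COMP)[::-1]


def iupac_match(primer_base: str, read_base: str) -> bool:
    """True if the (possibly degenerate) primer base is compatible with the read base."""
    allowed = IUPAC.get(primer_base.upper())
    if allowed is None:
        raise ValueError(f"invalid IUPAC code {primer_base!r}")
    return read_base.upper() in allowed


def primer_mismatches(primer: str, window: str) -> int:
    """Number of primer positions incompatible with an equally long read window.

    A window shorter than the primer counts every missing position as a mismatch.
    """
    n = min(len(primer), len(window))
    mm = sum(1 for p, b in zip(primer[:n], window[:n]) if not iupac_match(p, b))
    return mm + (len(primer) - n)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    return sum(1 for x, y in zip(a, b) if x != y)


def random_seq(rng, length: int) -> str:
    """Uniform random ACGT sequence from a numpy Generator."""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
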