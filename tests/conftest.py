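"""Shared fixtures: tiny reference databases and sequence builders."""

from __future__ import annotations

import io

import numpy as np
import pytest

# codons for 20 distinct amino acids (no stops), used to build sequences with
# exact, known amino-acid distances
AA_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
AA_LETTERS = sorted(AA_CODON)


def nt_from_protein(protein: str) -> str:
    return "".join(AA_CODON[a] for a in protein)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_LETTERS[i] for i in rng.integers(0, len(AA_LETTERS), size=length))


def mutate_protein(rng: np.random.Generator, protein: str, n_changes: int) -> str:
    """Substitute exactly n_changes positions to different amino acids."""
    pos = rng.choice(len(protein), size=n_changes, replace=False)
    out = list(protein)
    for p in pos:
        choices = [a for a in AA_LETTERS if a != out[p]]
        out[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def fasta_text(records: list[tuple[str, str]]) -> io.StringIO:
    return io.StringIO("".join(f">{name}\n{seq}\n" for name, seq in records))


@pytest.fixture
def rng():
    return np.random.default_rng(20230710)


@pytest.fixture
def toy_refdb():
    """A small class I + class II reference database with known content."""
    from elatype.refdb import load_reference_db

    rng = np.random.default_rng(42)
    records = []
    for name in (
        "Eqca-1*001:01",
        "Eqca-4*001:01",
        "Eqca-N*001:01",
        "Eqca-MHCI*gb1:01",
        "Eqca-DRA*001:01",
        "Eqca-DQA1*001:01",
        "Eqca-DQB1*001:01",
        "Eqca-DRB1*001:01",
    ):
        records.append((name, nt_from_protein(random_protein(rng, 40))))
    return load_reference_db(fasta_text(records))
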