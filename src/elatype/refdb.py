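"""Reference allele database: IPD-style FASTA loading, naming fields, translation.

Allele names follow the ``Eqca-<locus>*<group>:<allele>`` convention used for
equine MHC (ELA) sequences, e.g. ``Eqca-1*001:01`` or ``Eqca-MHCI*gb19:01``.
The locus tag maps onto one of five genes (MHCI, DQA, DQB, DRA, DRB): class II
tags name their gene directly (``DQA1``, ``DRB3`` ...), everything else —
numeric tags, ``N``, ``MHCI`` — is a class I heavy-chain sequence.

Amplicons start mid-exon, so there is no start codon to anchor translation.
The reading frame is therefore *registered* per gene when the database is
loaded: the frame in which at least 90% of that gene's reference alleles
translate without an internal stop.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq

GENES = ("MHCI", "DQA", "DQB", "DRA", "DRB")

_NAME_RE = re.compile(r"^Eqca-(?P<locus>[^*\s]+)\*(?P<group>[^:\s]+):(?P<allele>\S+)$")


class ReferenceDBError(ValueError):
    """Malformed reference database input."""


def parse_allele_name(name: str) -> tuple[str, str, str]:
    """Split a full allele name into (locus_tag, group_field, allele_field)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ReferenceDBError(f"cannot parse allele name {name!r}")
    return m.group("locus"), m.group("group"), m.group("allele")


def gene_of_locus(locus_tag: str) -> str:
    """Map a locus tag onto its gene (MHCI, DQA, DQB, DRA or DRB)."""
    for g in ("DQA", "DQB", "DRA", "DRB"):
        if locus_tag.upper().startswith(g):
            return g
    return "MHCI"


def translate_amplicon(nt_seq: str, frame_offset: int) -> str:
    """Translate complete codons of ``nt_seq`` starting at ``frame_offset``.

    The trailing partial codon is dropped; internal stop codons are kept as
    ``*`` so callers can detect untranslatable sequences.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset!r}")
    coding = nt_seq[frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate())


def choose_frame(nt_seqs: Iterable[str], min_clean_frac: float = 0.9) -> int:
    """Pick the reading frame in which most sequences translate stop-free.

    Returns the smallest frame whose stop-free fraction reaches
    ``min_clean_frac``; if none does, the frame maximising that fraction.
    """
    seqs = [s for s in nt_seqs if len(s) >= 3]
    if not seqs:
        return 0
    fracs = []
    for f in (0, 1, 2):
        clean = sum(1 for s in seqs if "*" not in translate_amplicon(s, f))
        fracs.append(clean / len(seqs))
    for f in (0, 1, 2):
        if fracs[f] >= min_clean_frac:
            return f
    return int(max(range(3), key=lambda f: fracs[f]))


@dataclass(frozen=True)
class ReferenceAllele:
    """One named amplicon-region allele sequence."""

    full_name: str
    locus_tag: str
    group_field: str
    allele_field: str
    nt_seq: str
    aa_seq: str
    frame_offset: int
    classification: str = "known_ipd"  # known_ipd | novel_in_group | novel_group | synonymous_variant

    def __post_init__(self):
        if not self.nt_seq or set(self.nt_seq) - set("ACGT"):
            raise ReferenceDBError(
                f"{self.full_name}: nt_seq must be non-empty ACGT, got "
                f"{sorted(set(self.nt_seq) - set('ACGT'))}"
            )

    @property
    def gene(self) -> str:
        return gene_of_locus(self.locus_tag)

    @property
    def group_name(self) -> str:
        """The allelic-group prefix, e.g. ``Eqca-4*001``."""
        return f"Eqca-{self.locus_tag}*{self.group_field}"


def make_reference_allele(
    full_name: str, nt_seq: str, frame_offset: int, classification: str = "known_ipd"
) -> ReferenceAllele:
    locus, group, allele = parse_allele_name(full_name)
    nt_seq = nt_seq.upper()
    aa = translate_amplicon(nt_seq, frame_offset) if len(nt_seq) >= 3 + frame_offset else ""
    return ReferenceAllele(
        full_name=full_name,
        locus_tag=locus,
        group_field=group,
        allele_field=allele,
        nt_seq=nt_seq,
        aa_seq=aa,
        frame_offset=frame_offset,
        classification=classification,
    )


class ReferenceAlleleDB:
    """Named allele sequences, indexed by gene, the comparison target for naming."""

    def __init__(self, gene_frames: dict[str, int] | None = None):
        self._alleles: dict[str, ReferenceAllele] = {}
        self.gene_frames: dict[str, int] = dict(gene_frames or {})

    def __len__(self) -> int:
        return len(self._alleles)

    def __contains__(self, name: str) -> bool:
        return name in self._alleles

    def __getitem__(self, name: str) -> ReferenceAllele:
        return self._alleles[name]

    def __iter__(self):
        return iter(self._alleles.values())

    def frame_for(self, gene: str) -> int:
        return self.gene_frames.get(gene, 0)

    def add(self, allele: ReferenceAllele) -> None:
        if allele.full_name in self._alleles:
            raise ReferenceDBError(f"duplicate allele name {allele.full_name!r}")
        self._alleles[allele.full_name] = allele

    def by_gene(self, gene: str) -> list[ReferenceAllele]:
        return [a for a in self._alleles.values() if a.gene == gene]

    def by_group(self, group_name: str) -> list[ReferenceAllele]:
        return [a for a in self._alleles.values() if a.group_name == group_name]

    def find_nt(self, nt_seq: str, gene: str) -> ReferenceAllele | None:
        """Exact full-length nucleotide match within a gene, or None."""
        nt_seq = nt_seq.upper()
        for a in self.by_gene(gene):
            if a.nt_seq == nt_seq:
                return a
        return None


def load_reference_db(
    fasta_source: str | TextIO,
    gene_frames: dict[str, int] | None = None,
) -> ReferenceAlleleDB:
    """Load an IPD-style reference FASTA into a :class:`ReferenceAlleleDB`.

    Headers must start with a full allele name (``Eqca-<locus>*<group>:<allele>``);
    anything after whitespace is treated as a free-text description. Reading
    frames are registered per gene unless supplied explicitly.
    """
    raw: list[tuple[str, str]] = []
    for rec in SeqIO.parse(fasta_source, "fasta"):
        name = rec.id
        try:
            parse_allele_name(name)
        except ReferenceDBError as exc:
            raise ReferenceDBError(f"malformed FASTA header for record {rec.id!r}: {exc}") from exc
        raw.append((name, str(rec.seq).upper()))
    if not raw:
        warnings.warn("reference FASTA contained no records; empty database", stacklevel=2)
        return ReferenceAlleleDB(gene_frames)

    frames = dict(gene_frames or {})
    if gene_frames is None:
        by_gene: dict[str, list[str]] = {}
        for name, seq in raw:
            by_gene.setdefault(gene_of_locus(parse_allele_name(name)[0]), []).append(seq)
        frames = {g: choose_frame(seqs) for g, seqs in by_gene.items()}

    db = ReferenceAlleleDB(frames)
    for name, seq in raw:
        gene = gene_of_locus(parse_allele_name(name)[0])
        db.add(make_reference_allele(name, seq, frames.get(gene, 0)))
    return db
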