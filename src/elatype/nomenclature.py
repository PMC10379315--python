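"""Assign names to observed amplicon sequences by amino-acid distance.

The classification rule operates per gene: a query translated in its gene's
registered frame is compared with every database entry of the same gene.

* nucleotide-identical to an entry            -> ``known_ipd`` (that entry's name)
* amino-acid identical, nucleotide different  -> ``synonymous_variant``
* 1-4 amino-acid differences from the nearest -> ``novel_in_group``
* >4 differences from every same-gene entry   -> ``novel_group``

Novel alleles and synonymous variants take two-letter suffixes (``AA``,
``AB`` ...) inside the nearest allelic group; novel groups are numbered per
gene and country of first detection (``gb``, ``is``, ``no``), e.g.
``Eqca-MHCI*gb19:01``. Accepted queries join the database so that later
queries are compared against them as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .refdb import (
    ReferenceAlleleDB,
    ReferenceAllele,
    make_reference_allele,
    translate_amplicon,
)

COUNTRY_CODES = ("gb", "is", "no")


class UntranslatableSequenceError(ValueError):
    """Query contains an internal stop codon in the registered frame."""


def aa_distance(a: str, b: str) -> int:
    """Amino-acid difference count between two sequences.

    Equal lengths: Hamming distance. Unequal lengths: positions substituted,
    inserted or deleted in a global alignment scored match +1, mismatch -1,
    gap -2; among score-optimal alignments the one with the fewest changed
    positions is used, which makes the distance deterministic.
    """
    if not a or not b:
        return len(a) + len(b)
    if len(a) == len(b):
        return sum(1 for x, y in zip(a, b) if x != y)
    # Lexicographic DP: maximise score, then minimise (mismatches + gaps).
    n, m = len(a), len(b)
    prev = [(-2 * j, j) for j in range(m + 1)]  # (score, distance)
    for i in range(1, n + 1):
        cur = [(-2 * i, i)] + [(0, 0)] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            ds, dd = prev[j - 1]
            if ai == b[j - 1]:
                diag = (ds + 1, dd)
            else:
                diag = (ds - 1, dd + 1)
            us, ud = prev[j]
            ls, ld = cur[j - 1]
            best = diag
            for cand in ((us - 2, ud + 1), (ls - 2, ld + 1)):
                if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
            cur[j] = best
        prev = cur
    return prev[m][1]


def _nt_identity(a: str, b: str) -> float:
    """Fractional nucleotide identity used only for tie-breaking."""
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b), 1)


def _letter_suffix(index: int) -> str:
    if index >= 26 * 26:
        raise RuntimeError("two-letter suffix space (AA..ZZ) exhausted")
    return chr(65 + index // 26) + chr(65 + index % 26)


class NomenclatureRegistry:
    """Deterministic naming service: letter suffixes per group, group numbers per gene.

    Counters can be initialised from an existing database so that issued names
    never collide with loaded ones.
    """

    def __init__(self, country_code: str):
        if country_code not in COUNTRY_CODES:
            raise ValueError(f"country_code must be one of {COUNTRY_CODES}, got {country_code!r}")
        self.country_code = country_code
        self._group_numbers: dict[tuple[str, str], int] = {}
        self._suffix_indices: dict[str, int] = {}
        self.issued_names: set[str] = set()

    @classmethod
    def from_db(cls, db: ReferenceAlleleDB, country_code: str) -> "NomenclatureRegistry":
        reg = cls(country_code)
        for allele in db:
            # advance letter-suffix counters past loaded two-letter fields
            first = allele.allele_field.split(":")[0]
            if len(first) == 2 and first.isalpha() and first.isupper():
                idx = (ord(first[0]) - 65) * 26 + (ord(first[1]) - 65) + 1
                key = allele.group_name
                reg._suffix_indices[key] = max(reg._suffix_indices.get(key, 0), idx)
            # advance group counters past loaded country-coded groups
            for cc in COUNTRY_CODES:
                g = allele.group_field
                if g.startswith(cc) and g[len(cc):].isdigit():
                    key2 = (allele.gene, cc)
                    reg._group_numbers[key2] = max(
                        reg._group_numbers.get(key2, 0), int(g[len(cc):])
                    )
        return reg

    def next_name(self, gene: str, kind: str, group: str | None = None) -> str:
        """Issue the next name of the requested kind.

        ``kind`` is ``"variant"`` (letter suffix inside ``group``, which must
        be a full group prefix like ``Eqca-4*001``) or ``"group"`` (a new
        country-coded allelic group for ``gene``).
        """
        if kind == "variant":
            if not group:
                raise ValueError("variant naming requires a group")
            idx = self._suffix_indices.get(group, 0)
            name = f"{group}:{_letter_suffix(idx)}"
            self._suffix_indices[group] = idx + 1
        elif kind == "group":
            key = (gene, self.country_code)
            n = self._group_numbers.get(key, 0) + 1
            self._group_numbers[key] = n
            name = f"Eqca-{gene}*{self.country_code}{n}:01"
        else:
            raise ValueError(f"unknown naming kind {kind!r}")
        if name in self.issued_names:
            raise RuntimeError(f"name {name!r} issued twice")
        self.issued_names.add(name)
        return name


@dataclass(frozen=True)
class NomenclatureResult:
    query_id: str
    assigned_name: str
    classification: str  # known_ipd | novel_in_group | novel_group | synonymous_variant
    nearest_reference: str
    aa_distance: int
    nt_identical: bool


def classify_sequence(
    query_nt: str,
    db: ReferenceAlleleDB,
    gene: str,
    registry: NomenclatureRegistry,
    query_id: str = "",
    novel_group_threshold: int = 4,
) -> NomenclatureResult:
    """Classify and name one primer-trimmed amplicon sequence.

    The accepted query is added to ``db`` (unless nucleotide-identical to an
    existing entry), so re-classifying it later returns its own name at
    distance 0.
    """
    query_nt = query_nt.upper()
    frame = db.frame_for(gene)
    aa = translate_amplicon(query_nt, frame)
    if "*" in aa.rstrip("*") or not aa:
        raise UntranslatableSequenceError(
            f"query {query_id or query_nt[:12]}...: internal stop codon in frame {frame}"
        )

    exact = db.find_nt(query_nt, gene)
    if exact is not None:
        return NomenclatureResult(query_id, exact.full_name, "known_ipd", exact.full_name, 0, True)

    candidates = db.by_gene(gene)
    if not candidates:
        name = registry.next_name(gene, "group")
        db.add(make_reference_allele(name, query_nt, frame, "novel_group"))
        return NomenclatureResult(query_id, name, "novel_group", "", novel_group_threshold + 1, False)

    # nearest entry: min distance, ties by nt identity (desc), then group name
    scored = sorted(
        (
            (aa_distance(aa, c.aa_seq), -_nt_identity(query_nt, c.nt_seq), c.group_name, c.full_name)
            for c in candidates
        ),
    )
    dist, _, _, nearest_name = scored[0]
    nearest = db[nearest_name]

    if dist > novel_group_threshold:
        name = registry.next_name(gene, "group")
        classification = "novel_group"
    else:
        name = registry.next_name(gene, "variant", group=nearest.group_name)
        classification = "synonymous_variant" if dist == 0 else "novel_in_group"
    db.add(make_reference_allele(name, query_nt, frame, classification))
    return NomenclatureResult(query_id, name, classification, nearest.full_name, dist, False)


def nomenclature_report(results: list[NomenclatureResult]) -> str:
    """TSV report of classification results."""
    lines = ["query_id\tassigned_name\tclassification\tnearest_reference\taa_distance\tnt_identical"]
    for r in results:
        lines.append(
            f"{r.query_id}\t{r.assigned_name}\t{r.classification}\t"
            f"{r.nearest_reference}\t{r.aa_distance}\t{str(r.nt_identical).lower()}"
        )
    return "\n".join(lines) + "\n"
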