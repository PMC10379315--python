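"""Haplotype inference from recurrent co-segregation of alleles.

A haplotype is a set of alleles co-inherited on one chromosome. With no
pedigree and no physical phasing, haplotypes are inferred from the cohort's
presence matrix: allele sets that recur across animals, either as a whole
animal (putative homozygote) or as the residual left after subtracting an
already-known haplotype from a heterozygote. A pattern seen in at least two
animals is *confirmed*; one seen in a single animal keeps an ``un`` prefix.

Promiscuous ("universal") alleles present on most haplotypes defeat residual
subtraction — an animal's two haplotypes may share them, so presence cannot
attribute them. They are excluded from the subtraction step and re-attached
afterwards to each haplotype all of whose carrier animals also carry them.

Haplotypes are grouped into families of variants (subtypes a, b, c ...) by
single-linkage clustering on the Jaccard similarity of their allelic-group
content, so an allelic substitution within a group still counts as shared.
MHCII haplotypes in which an entire DQA or DQB locus class went undetected
are flagged partial (``p`` in the id).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .refdb import gene_of_locus, parse_allele_name


@dataclass
class GenotypeMatrix:
    """Animal x allele presence and read-fraction support for one MHC class."""

    presence: pd.DataFrame  # bool
    support: pd.DataFrame  # float, same shape

    @property
    def animals(self) -> list[str]:
        return list(self.presence.index)

    @property
    def alleles(self) -> list[str]:
        return list(self.presence.columns)

    def allele_sets(self) -> dict[str, frozenset[str]]:
        return {
            a: frozenset(self.presence.columns[self.presence.loc[a]])
            for a in self.presence.index
        }

    @classmethod
    def from_presence(cls, sets: Mapping[str, Iterable[str]]) -> "GenotypeMatrix":
        animals = sorted(sets)
        alleles = sorted({al for s in sets.values() for al in s})
        presence = pd.DataFrame(False, index=animals, columns=alleles)
        for a, s in sets.items():
            presence.loc[a, list(s)] = True
        return cls(presence, presence.astype(float))


def build_genotype_matrix(
    final_calls: Mapping[str, Mapping[str, float]],
    drop_empty: bool = True,
) -> GenotypeMatrix:
    """Build the matrix from {animal: {allele_name: support}} final calls.

    Presence means called or recovered; support is the maximum read fraction
    across the contributing amplicons. Animals with no alleles are excluded
    (with a warning) rather than kept as empty rows.
    """
    import warnings

    calls = dict(final_calls)
    empty = [a for a, d in calls.items() if not d]
    if empty and drop_empty:
        warnings.warn(f"animals with no alleles excluded from matrix: {sorted(empty)}", stacklevel=2)
        for a in empty:
            del calls[a]
    animals = sorted(calls)
    alleles = sorted({al for d in calls.values() for al in d})
    presence = pd.DataFrame(False, index=animals, columns=alleles)
    support = pd.DataFrame(0.0, index=animals, columns=alleles)
    for a, d in calls.items():
        for al, sup in d.items():
            if sup <= 0:
                raise ValueError(f"present allele {al!r} in {a!r} must have positive support")
            presence.loc[a, al] = True
            support.loc[a, al] = sup
    return GenotypeMatrix(presence, support)


@dataclass(frozen=True)
class Haplotype:
    id: str
    mhc_class: str  # "MHCI" | "MHCII"
    family_number: int
    subtype_letter: str | None
    allele_set: frozenset[str]
    occurrences: int  # haplotype slots across assigned animals; homozygotes count twice
    n_animals: int  # distinct carrier animals
    confirmed: bool
    partial: bool = False


@dataclass(frozen=True)
class AnimalAssignment:
    animal: str
    haplotypes: tuple[frozenset[str], ...]  # 0, 1 or 2 allele sets; homozygote = same set twice
    unassigned_alleles: frozenset[str]
    ambiguous: bool = False


def _sorted_sets(sets: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    return sorted(sets, key=lambda s: (len(s), tuple(sorted(s))))


def _candidate_sets(sets: dict[str, frozenset[str]]) -> list[frozenset[str]]:
    """Seed and grow candidate haplotypes to fixpoint.

    Rule 1: an animal's whole set contained in another animal's set (putative
    homozygote, or two animals with identical sets). Rule 2: two animals'
    shared alleles (their intersection) — the co-segregating block of a
    haplotype they have in common. Rule 3: an animal with exactly one known
    candidate as a *proper* subset contributes the residual as a new
    candidate. Spurious candidates (e.g. fused unions from repeated
    heterozygous diplotypes) survive here but lose at assignment time to
    higher-support, more parsimonious decompositions and are then pruned.
    """
    order = sorted(sets, key=lambda a: (len(sets[a]), a))
    cands: set[frozenset[str]] = set()
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            inter = sets[a] & sets[b]
            if inter:
                cands.add(inter)
    changed = True
    while changed:
        changed = False
        for a in order:
            s = sets[a]
            if not s:
                continue
            if s not in cands and any(s <= sets[b] for b in sets if b != a):
                cands.add(s)
                changed = True
            proper = [h for h in cands if h < s]
            if len(proper) == 1:
                residual = s - proper[0]
                if residual and residual not in cands:
                    cands.add(residual)
                    changed = True
    return _sorted_sets(cands)


def _decompose(
    s: frozenset[str], cands: list[frozenset[str]], support: dict[frozenset[str], int]
) -> tuple[tuple[frozenset[str], frozenset[str]] | None, bool]:
    """Best diplotype decomposition of one animal's allele set.

    Among candidate pairs whose union equals the set, pick maximal combined
    support, then minimal combined allele count (parsimony), then the
    lexicographically smallest pair. Returns (pair or None, ambiguous).
    """
    subs = [h for h in cands if h <= s]
    options = []
    for i, h1 in enumerate(subs):
        for h2 in subs[i:]:
            if h1 | h2 == s:
                options.append((h1, h2))
    if not options:
        return None, False
    def keyfun(pair):
        h1, h2 = pair
        return (
            -(support.get(h1, 0) + support.get(h2, 0)),
            len(h1) + len(h2),
            tuple(sorted(h1)),
            tuple(sorted(h2)),
        )
    options.sort(key=keyfun)
    ambiguous = len(options) > 1 and keyfun(options[0])[:2] == keyfun(options[1])[:2]
    return options[0], ambiguous


def infer_haplotypes(
    matrix: GenotypeMatrix | Mapping[str, frozenset[str]],
    min_support_animals: int = 2,
    exclude: frozenset[str] = frozenset(),
) -> tuple[list[frozenset[str]], dict[str, AnimalAssignment], dict[frozenset[str], int]]:
    """Infer co-segregating allele sets and per-animal diplotypes.

    ``exclude`` removes promiscuous/universal alleles from the subtraction
    algebra (see module docstring); excluded alleles reappear in assignments'
    ``unassigned_alleles`` unless re-attached by the caller.

    Returns (pool of used candidate sets, assignments keyed by animal,
    carrier-animal counts per candidate). Deterministic for a fixed input.
    """
    sets_full = (
        matrix.allele_sets() if isinstance(matrix, GenotypeMatrix) else {k: frozenset(v) for k, v in matrix.items()}
    )
    sets = {a: s - exclude for a, s in sets_full.items()}

    cands = _candidate_sets(sets)
    containment = {h: sum(1 for s in sets.values() if h <= s) for h in cands}

    assignments: dict[str, AnimalAssignment] = {}
    used: dict[frozenset[str], set[str]] = {}
    slots: dict[frozenset[str], int] = {}
    for a in sorted(sets):
        s = sets[a]
        if not s:
            assignments[a] = AnimalAssignment(a, (), frozenset(sets_full[a]))
            continue
        pair, ambiguous = _decompose(s, cands, containment)
        if pair is None:
            assignments[a] = AnimalAssignment(a, (), frozenset(sets_full[a]))
            continue
        h1, h2 = pair
        leftovers = frozenset(sets_full[a] - (h1 | h2))  # excluded alleles, pre-re-attachment
        assignments[a] = AnimalAssignment(a, (h1, h2), leftovers, ambiguous)
        for h in (h1, h2):
            slots[h] = slots.get(h, 0) + 1
            used.setdefault(h, set()).add(a)

    pool = _sorted_sets(used)
    carriers = {h: len(used[h]) for h in pool}
    return pool, assignments, carriers


def classify_universal(
    pool: Iterable[frozenset[str]],
    majority_frac: float = 0.5,
) -> dict[str, str]:
    """Label each allele standard or universal by haplotype-group coverage.

    Alleles sharing locus tag and group field form one allelic group; a group
    is universal iff the union of haplotypes carrying any member covers more
    than ``majority_frac`` of the pool, and all members inherit the label.
    """
    pool = list(pool)
    if not pool:
        return {}
    groups: dict[str, set[int]] = {}
    members: dict[str, list[str]] = {}
    for i, h in enumerate(pool):
        for allele in h:
            g = _group_key(allele)
            groups.setdefault(g, set()).add(i)
            members.setdefault(g, []).append(allele)
    labels: dict[str, str] = {}
    for g, covered in groups.items():
        label = "universal" if len(covered) / len(pool) > majority_frac else "standard"
        for allele in members[g]:
            labels[allele] = label
    return labels


def _group_key(allele_name: str) -> str:
    """Collapse an allele name to its locus+group; raw sequence ids map to themselves."""
    try:
        locus, group, _ = parse_allele_name(allele_name)
        return f"Eqca-{locus}*{group}"
    except Exception:
        return allele_name


def group_variants(
    pool: list[frozenset[str]],
    occurrences: Mapping[frozenset[str], int],
    jaccard_min: float = 0.5,
) -> tuple[dict[frozenset[str], int], dict[frozenset[str], str | None]]:
    """Cluster haplotypes into families and letter their subtypes.

    Similarity is Jaccard over allelic-group content (so allelic
    substitutions within a group still match); single linkage at
    ``jaccard_min`` (inclusive). Families are numbered from 1 by descending
    total occurrences; within a family, subtypes get letters a, b, c ... by
    descending occurrences; singleton families get no letter.
    """
    pool = list(pool)
    n = len(pool)
    keysets = [frozenset(_group_key(a) for a in h) for h in pool]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            inter = len(keysets[i] & keysets[j])
            union = len(keysets[i] | keysets[j])
            if union and inter / union >= jaccard_min:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    ranked = sorted(
        clusters.values(),
        key=lambda idxs: (
            -sum(occurrences.get(pool[i], 0) for i in idxs),
            tuple(sorted(tuple(sorted(pool[i])) for i in idxs)),
        ),
    )
    family: dict[frozenset[str], int] = {}
    letter: dict[frozenset[str], str | None] = {}
    for fam_no, idxs in enumerate(ranked, start=1):
        ordered = sorted(idxs, key=lambda i: (-occurrences.get(pool[i], 0), tuple(sorted(pool[i]))))
        for rank, i in enumerate(ordered):
            family[pool[i]] = fam_no
            letter[pool[i]] = None if len(ordered) == 1 else chr(ord("a") + rank)
    return family, letter


def flag_partial(allele_set: frozenset[str], locus_class_map: Mapping[str, str]) -> bool:
    """MHCII haplotype is partial iff it carries no DQA or no DQB allele."""
    classes = {locus_class_map.get(a, _gene_key(a)) for a in allele_set}
    return not any(c.startswith("DQA") for c in classes) or not any(
        c.startswith("DQB") for c in classes
    )


def _gene_key(allele_name: str) -> str:
    try:
        locus, _, _ = parse_allele_name(allele_name)
        return gene_of_locus(locus)
    except Exception:
        return "?"


def haplotype_id(mhc_class: str, family: int, letter: str | None, confirmed: bool, partial: bool) -> str:
    digit = "1" if mhc_class == "MHCI" else "2"
    return ("" if confirmed else "un") + ("p" if partial else "") + f"HP{digit}.{family}{letter or ''}"


@dataclass
class HaplotypePool:
    """The labelled result of haplotype inference for one MHC class."""

    mhc_class: str
    haplotypes: list[Haplotype]
    assignments: dict[str, AnimalAssignment]
    allele_labels: dict[str, str]  # standard / universal

    def by_id(self) -> dict[str, Haplotype]:
        return {h.id: h for h in self.haplotypes}

    def set_to_id(self) -> dict[frozenset[str], str]:
        return {h.allele_set: h.id for h in self.haplotypes}

    def to_tsv(self) -> str:
        lines = ["id\tclass\tfamily\tsubtype\toccurrences\tn_animals\tconfirmed\tpartial\talleles"]
        for h in self.haplotypes:
            lines.append(
                f"{h.id}\t{h.mhc_class}\t{h.family_number}\t{h.subtype_letter or ''}\t"
                f"{h.occurrences}\t{h.n_animals}\t{str(h.confirmed).lower()}\t"
                f"{str(h.partial).lower()}\t{';'.join(sorted(h.allele_set))}"
            )
        return "\n".join(lines) + "\n"

    def assignments_tsv(self) -> str:
        ids = self.set_to_id()
        lines = ["animal\thap1\thap2\tunassigned"]
        for a in sorted(self.assignments):
            asg = self.assignments[a]
            haps = [ids.get(h, "?") for h in asg.haplotypes]
            haps += [""] * (2 - len(haps))
            lines.append(f"{a}\t{haps[0]}\t{haps[1]}\t{';'.join(sorted(asg.unassigned_alleles))}")
        return "\n".join(lines) + "\n"


def infer_haplotype_pool(
    matrix: GenotypeMatrix | Mapping[str, frozenset[str]],
    mhc_class: str,
    min_support_animals: int = 2,
    majority_frac: float = 0.5,
    jaccard_min: float = 0.5,
    locus_class_map: Mapping[str, str] | None = None,
    max_universal_rounds: int = 4,
    universal_prepass_frac: float = 0.75,
) -> HaplotypePool:
    """Full inference for one MHC class: universal-exclusion loop, inference,
    re-attachment, variant families, ids.

    The exclusion set is seeded with allelic groups carried by more than
    ``universal_prepass_frac`` of the animals — such groups cannot
    discriminate haplotypes and defeat residual subtraction — and then grows
    iteratively: infer, classify allelic groups covering a pool majority as
    universal, re-infer with those excluded, until stable. Because a very
    common haplotype can push its own alleles over the pre-pass fraction in a
    small cohort, inference also runs without the pre-pass, and the run
    leaving the fewest alleles unexplained after re-attachment (ties: fewer
    unassigned animals, then fewer and smaller haplotypes) wins. Each
    excluded allele is re-attached to every haplotype all of whose carrier
    animals also carry it.
    """
    sets_full = (
        matrix.allele_sets() if isinstance(matrix, GenotypeMatrix) else {k: frozenset(v) for k, v in matrix.items()}
    )

    n_animals_total = len(sets_full)
    group_carriers: dict[str, int] = {}
    for s in sets_full.values():
        for g in {_group_key(al) for al in s}:
            group_carriers[g] = group_carriers.get(g, 0) + 1
    prepass: frozenset[str] = frozenset(
        al
        for s in sets_full.values()
        for al in s
        if n_animals_total and group_carriers[_group_key(al)] / n_animals_total > universal_prepass_frac
    )

    def run(seed_exclude: frozenset[str]):
        exclude = seed_exclude
        pool: list[frozenset[str]] = []
        assignments: dict[str, AnimalAssignment] = {}
        carriers: dict[frozenset[str], int] = {}
        for _ in range(max_universal_rounds):
            pool, assignments, carriers = infer_haplotypes(
                sets_full, min_support_animals, exclude
            )
            labels = classify_universal(pool, majority_frac)
            newly = frozenset(a for a, lab in labels.items() if lab == "universal") - exclude
            # include other members of the universal groups seen in animals
            # but absent from the current pool
            group_univ = {_group_key(a) for a in newly}
            extra = frozenset(
                al for s in sets_full.values() for al in s if _group_key(al) in group_univ
            )
            newly = (newly | extra) - exclude
            if not newly:
                break
            exclude = exclude | newly
        return pool, assignments, carriers, exclude

    def reattach(pool, assignments, exclude):
        """Excluded alleles rejoin each haplotype all of whose carriers bear them."""
        carriers_of: dict[frozenset[str], list[str]] = {h: [] for h in pool}
        for a, asg in assignments.items():
            for h in asg.haplotypes:
                carriers_of[h].append(a)
        attach = {}
        for h in pool:
            anims = carriers_of[h]
            attached = frozenset(
                u for u in exclude if anims and all(u in sets_full[a] for a in anims)
            )
            attach[h] = h | attached
        return attach

    candidates = [run(frozenset())]
    if prepass:
        candidates.append(run(prepass))

    def quality(res):
        pool_r, assignments_r, _, exclude_r = res
        attach_r = reattach(pool_r, assignments_r, exclude_r)
        unexplained = 0
        for a, asg in assignments_r.items():
            covered = frozenset().union(*(attach_r[h] for h in asg.haplotypes)) if asg.haplotypes else frozenset()
            unexplained += len(sets_full[a] - covered)
        unassigned = sum(1 for a in assignments_r.values() if not a.haplotypes)
        return (unexplained, unassigned, len(pool_r), sum(len(h) for h in pool_r))

    pool, assignments, carriers, exclude = min(candidates, key=quality)
    attach = reattach(pool, assignments, exclude)

    final_sets = {h: attach[h] for h in pool}
    occurrences: dict[frozenset[str], int] = {}
    n_animals: dict[frozenset[str], int] = {}
    for h in pool:
        occurrences[final_sets[h]] = occurrences.get(final_sets[h], 0) + sum(
            1 for asg in assignments.values() for hh in asg.haplotypes if hh == h
        )
        n_animals[final_sets[h]] = n_animals.get(final_sets[h], 0) + carriers[h]

    final_pool = _sorted_sets(set(final_sets.values()))
    family, letter = group_variants(final_pool, occurrences, jaccard_min)
    labels = classify_universal(final_pool, majority_frac)

    haplos = []
    for h in final_pool:
        confirmed = n_animals[h] >= min_support_animals
        partial = mhc_class == "MHCII" and flag_partial(h, locus_class_map or {})
        haplos.append(
            Haplotype(
                id=haplotype_id(mhc_class, family[h], letter[h], confirmed, partial),
                mhc_class=mhc_class,
                family_number=family[h],
                subtype_letter=letter[h],
                allele_set=h,
                occurrences=occurrences[h],
                n_animals=n_animals[h],
                confirmed=confirmed,
                partial=partial,
            )
        )
    haplos.sort(key=lambda x: (x.family_number, x.subtype_letter or ""))

    final_assignments = {}
    for a, asg in assignments.items():
        new_haps = tuple(attach[h] for h in asg.haplotypes)
        covered = frozenset().union(*new_haps) if new_haps else frozenset()
        final_assignments[a] = replace(
            asg,
            haplotypes=new_haps,
            unassigned_alleles=frozenset(sets_full[a] - covered),
        )
    return HaplotypePool(mhc_class, haplos, final_assignments, labels)
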