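"""Synthetic cohorts and MiSeq-like amplicon reads with known ground truth.

The generator emulates the statistical structure the genotyping pipeline
assumes: a pool of haplotypes per MHC class (class I carrying 6-16 alleles
including universal alleles shared across haplotypes; class II laid out as a
single DRA, two DQA, two DQB and two or three DRB loci), diploid animals
drawn as independent haplotype pairs (homozygotes arise naturally), per-allele
expression weights spanning about three orders of magnitude, amplicon pool
ratios of 30:30:10:10:10:10, primer-site mismatches that drop an allele out
of an amplicon when they exceed the primer tolerance, uniform substitution
sequencing error, and MID-tagged 300 bp read pairs whose overlap follows the
insert length.

All randomness flows from the seed: identical seeds give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .amplicons import (
    DEFAULT_PANEL,
    MHCI_COMPOSITE_LEN,
    MHCI_FOR32_OFFSET,
    POOL_RATIOS,
    AmpliconDef,
)
from .demux import FastqRead, MidScheme
from .seqs import IUPAC, random_seq, revcomp

_MHCII_LOCI = ("DRA", "DQA1", "DQA2", "DQB1", "DQB2", "DRB1", "DRB2", "DRB3")

# Relative expression of the class II loci: DRB1 strongly dominant, DQB1 and
# DQA1 dominant over their second loci, DRB3 marginal.
DEFAULT_MHCII_LOCUS_WEIGHTS = {
    "DRA": 1.0,
    "DQA1": 0.6,
    "DQA2": 0.4,
    "DQB1": 0.7,
    "DQB2": 0.3,
    "DRB1": 0.9,
    "DRB2": 0.08,
    "DRB3": 0.02,
}


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    n_animals: int = 96
    n_mhci_haplotypes: int = 10
    n_mhcii_haplotypes: int = 10
    mhci_hap_freqs: tuple[float, ...] | None = None  # default uniform
    mhcii_hap_freqs: tuple[float, ...] | None = None
    mhci_alleles_range: tuple[int, int] = (6, 16)  # total alleles per class I haplotype
    n_universal_shared: int = 2  # identical allele present on every class I haplotype
    n_universal_variant: int = 2  # allele groups with one variant per haplotype
    drb3_prob: float = 0.6  # probability a class II haplotype carries a DRB3 locus
    expression_decades: float = 3.0  # log10 spread of class I expression weights
    mhcii_locus_weights: tuple[tuple[str, float], ...] = tuple(DEFAULT_MHCII_LOCUS_WEIGHTS.items())
    pool_ratios: tuple[tuple[str, float], ...] = tuple(POOL_RATIOS.items())
    reads_per_animal: int = 20000
    error_rate: float = 0.001  # substitutions per base
    dropout_prob: float = 0.0  # P(2 primer mismatches) per class I allele and amplicon
    tolerated_mismatch_prob: float = 0.05  # P(1 primer mismatch), still amplified
    chimera_rate: float = 0.0  # chimeric reads per amplicon read
    linkage_strength: float = 0.8  # P(MHCII haplotype is the partner of the MHCI one)
    read_len: int = 300
    mid_len: int = 10
    qual_char: str = "D"  # Q35

    def __post_init__(self):
        for rate in (self.error_rate, self.dropout_prob, self.tolerated_mismatch_prob,
                     self.chimera_rate, self.linkage_strength, self.drb3_prob):
            if not 0.0 <= rate <= 1.0:
                raise SimConfigError("rates must lie in [0, 1]")
        for freqs, n in ((self.mhci_hap_freqs, self.n_mhci_haplotypes),
                         (self.mhcii_hap_freqs, self.n_mhcii_haplotypes)):
            if freqs is not None:
                if len(freqs) != n or abs(sum(freqs) - 1.0) > 1e-9:
                    raise SimConfigError("haplotype frequencies must match count and sum to 1")
        lo, hi = self.mhci_alleles_range
        if self.n_universal_shared + self.n_universal_variant >= lo:
            raise SimConfigError(
                "more universal alleles than the smallest class I haplotype can carry"
            )
        if abs(sum(r for _, r in self.pool_ratios) - 1.0) > 1e-9:
            raise SimConfigError("pool ratios must sum to 1")

    def freqs(self, mhc_class: str) -> np.ndarray:
        if mhc_class == "MHCI":
            f, n = self.mhci_hap_freqs, self.n_mhci_haplotypes
        else:
            f, n = self.mhcii_hap_freqs, self.n_mhcii_haplotypes
        return np.asarray(f if f is not None else [1.0 / n] * n)


@dataclass(frozen=True)
class SimAllele:
    id: str
    gene: str  # MHCI | DQA | DQB | DRA | DRB
    locus: str | None  # class II locus label, e.g. DRB1
    seq: str  # composite 410 bp for class I, insert for class II
    expression: float
    primer_mismatches: tuple[tuple[str, int], ...] = ()  # per amplicon name

    def mismatches_for(self, amplicon: str) -> int:
        return dict(self.primer_mismatches).get(amplicon, 0)

    def insert_for(self, amplicon: AmpliconDef) -> str | None:
        if self.gene != amplicon.gene:
            return None
        if self.gene == "MHCI":
            if amplicon.name == "MHCI_For1Rev2.2":
                return self.seq[: amplicon.expected_insert_len]
            return self.seq[MHCI_FOR32_OFFSET:]
        return self.seq


@dataclass(frozen=True)
class SimHaplotype:
    id: str
    mhc_class: str
    allele_ids: frozenset[str]


@dataclass(frozen=True)
class SimAnimal:
    id: str
    mhci: tuple[str, str]
    mhcii: tuple[str, str]
    fwd_mid: str
    rev_mid: str


@dataclass
class SimTruth:
    """Ground truth: animals → haplotypes → alleles → expected read fractions."""

    alleles: dict[str, SimAllele]
    haplotypes: dict[str, SimHaplotype]
    animals: dict[str, SimAnimal]
    panel: tuple[AmpliconDef, ...] = DEFAULT_PANEL

    def haplotype_sets(self, mhc_class: str) -> dict[str, frozenset[str]]:
        return {
            h.id: h.allele_ids for h in self.haplotypes.values() if h.mhc_class == mhc_class
        }

    def animal_haplotypes(self, animal: str, mhc_class: str) -> tuple[str, str]:
        a = self.animals[animal]
        return a.mhci if mhc_class == "MHCI" else a.mhcii

    def genotype_sets(self, mhc_class: str) -> dict[str, frozenset[str]]:
        """Per-animal union of the two haplotypes' alleles (fully observed)."""
        out = {}
        for a in self.animals.values():
            h1, h2 = self.animal_haplotypes(a.id, mhc_class)
            out[a.id] = self.haplotypes[h1].allele_ids | self.haplotypes[h2].allele_ids
        return out

    def allele_copies(self, animal: str, mhc_class: str) -> dict[str, int]:
        h1, h2 = self.animal_haplotypes(animal, mhc_class)
        copies: dict[str, int] = {}
        for h in (h1, h2):
            for al in self.haplotypes[h].allele_ids:
                copies[al] = copies.get(al, 0) + 1
        return copies

    def expected_fractions(self, animal: str, amplicon: AmpliconDef) -> dict[str, float]:
        """Expected read fractions per allele after expression weights, copy
        number and primer dropout; sums to 1 over non-dropped alleles."""
        mhc_class = "MHCI" if amplicon.gene == "MHCI" else "MHCII"
        copies = self.allele_copies(animal, mhc_class)
        weights = {}
        for al_id, n in copies.items():
            al = self.alleles[al_id]
            if al.insert_for(amplicon) is None:
                continue
            if al.mismatches_for(amplicon.name) > amplicon.max_primer_mismatches:
                continue  # allele dropout in this amplicon
            weights[al_id] = n * al.expression
        total = sum(weights.values())
        return {k: v / total for k, v in sorted(weights.items())} if total else {}

    def mid_scheme(self) -> MidScheme:
        return MidScheme({(a.fwd_mid, a.rev_mid): a.id for a in self.animals.values()})


def _draw_expression(rng, decades: float) -> float:
    return float(10.0 ** rng.uniform(-decades, 0.0))


def simulate_cohort(cfg: SimConfig, seed: int) -> SimTruth:
    """Draw haplotypes, alleles, expression weights and diploid animals."""
    rng = np.random.default_rng(seed)
    alleles: dict[str, SimAllele] = {}
    haplotypes: dict[str, SimHaplotype] = {}
    panel = DEFAULT_PANEL
    mhci_amp_names = [d.name for d in panel if d.gene == "MHCI"]

    def new_mhci_allele(aid: str) -> SimAllele:
        mm = []
        for amp in mhci_amp_names:
            r = rng.random()
            if r < cfg.dropout_prob:
                mm.append((amp, 2))
            elif r < cfg.dropout_prob + cfg.tolerated_mismatch_prob:
                mm.append((amp, 1))
        return SimAllele(
            id=aid,
            gene="MHCI",
            locus=None,
            seq=random_seq(rng, MHCI_COMPOSITE_LEN),
            expression=_draw_expression(rng, cfg.expression_decades),
            primer_mismatches=tuple(mm),
        )

    # class I: shared universal alleles, per-haplotype universal variants, standard alleles
    shared_univ = []
    for u in range(cfg.n_universal_shared):
        aid = f"I_univ{u}"
        alleles[aid] = new_mhci_allele(aid)
        shared_univ.append(aid)

    lo, hi = cfg.mhci_alleles_range
    for h in range(cfg.n_mhci_haplotypes):
        members = list(shared_univ)
        for g in range(cfg.n_universal_variant):
            aid = f"I_uvar{g}_h{h}"
            alleles[aid] = new_mhci_allele(aid)
            members.append(aid)
        n_std = int(rng.integers(lo, hi + 1)) - len(members)
        for k in range(n_std):
            aid = f"I_h{h}_s{k}"
            alleles[aid] = new_mhci_allele(aid)
            members.append(aid)
        haplotypes[f"I{h}"] = SimHaplotype(f"I{h}", "MHCI", frozenset(members))

    # class II: fixed locus layout, DRB3 optional per haplotype
    gene_len = {d.gene: d.expected_insert_len for d in panel if d.gene != "MHCI"}
    locus_w = dict(cfg.mhcii_locus_weights)
    for h in range(cfg.n_mhcii_haplotypes):
        members = []
        loci = ["DRA", "DQA1", "DQA2", "DQB1", "DQB2", "DRB1", "DRB2"]
        if rng.random() < cfg.drb3_prob:
            loci.append("DRB3")
        for locus in loci:
            gene = locus.rstrip("123")
            aid = f"II_h{h}_{locus}"
            jitter = float(10.0 ** rng.uniform(-0.3, 0.3))
            alleles[aid] = SimAllele(
                id=aid,
                gene=gene,
                locus=locus,
                seq=random_seq(rng, gene_len[gene]),
                expression=locus_w[locus] * jitter,
            )
            members.append(aid)
        haplotypes[f"II{h}"] = SimHaplotype(f"II{h}", "MHCII", frozenset(members))

    # MID tags: distinct 2*n tags of fixed length
    tags: list[str] = []
    seen = set()
    while len(tags) < 2 * cfg.n_animals:
        t = random_seq(rng, cfg.mid_len)
        if t not in seen:
            seen.add(t)
            tags.append(t)

    fI = cfg.freqs("MHCI")
    fII = cfg.freqs("MHCII")
    animals: dict[str, SimAnimal] = {}
    for i in range(cfg.n_animals):
        hi1, hi2 = rng.choice(cfg.n_mhci_haplotypes, size=2, p=fI)
        hii = []
        for hic in (hi1, hi2):
            if cfg.n_mhcii_haplotypes == cfg.n_mhci_haplotypes and rng.random() < cfg.linkage_strength:
                hii.append(int(hic))  # linked partner haplotype
            else:
                hii.append(int(rng.choice(cfg.n_mhcii_haplotypes, p=fII)))
        aid = f"A{i + 1:03d}"
        animals[aid] = SimAnimal(
            id=aid,
            mhci=(f"I{hi1}", f"I{hi2}"),
            mhcii=(f"II{hii[0]}", f"II{hii[1]}"),
            fwd_mid=tags[2 * i],
            rev_mid=tags[2 * i + 1],
        )
    return SimTruth(alleles, haplotypes, animals, panel)


def simulate_read_counts(
    truth: SimTruth, cfg: SimConfig, seed: int
) -> dict[tuple[str, str], dict[str, int]]:
    """Multinomial read counts per (animal, amplicon, allele), no sequences.

    Reads per animal are split over amplicons at the pool ratios, then over
    alleles at the truth's expected fractions.
    """
    rng = np.random.default_rng(seed)
    ratios = dict(cfg.pool_ratios)
    amps = [d for d in truth.panel if d.name in ratios]
    p_amp = np.asarray([ratios[d.name] for d in amps])
    out: dict[tuple[str, str], dict[str, int]] = {}
    for aid in sorted(truth.animals):
        n_per_amp = rng.multinomial(cfg.reads_per_animal, p_amp)
        for d, n in zip(amps, n_per_amp):
            fracs = truth.expected_fractions(aid, d)
            if not fracs or n == 0:
                out[(aid, d.name)] = {}
                continue
            ids = sorted(fracs)
            counts = rng.multinomial(n, np.asarray([fracs[k] for k in ids]))
            out[(aid, d.name)] = {k: int(c) for k, c in zip(ids, counts) if c > 0}
    return out


def _concrete(primer: str, rng=None) -> str:
    """Replace degenerate positions with their first allowed base."""
    return "".join(sorted(IUPAC[b])[0] for b in primer)


def _mutate_positions(seq: str, positions: Iterable[int], rng) -> str:
    s = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[int(rng.integers(0, 3))]
        if len(choices) != 3:  # non-ACGT base: force A
            s[p] = "A"
    return "".join(s)


def _amplicon_sequence(allele: SimAllele, d: AmpliconDef, rng) -> str:
    insert = allele.insert_for(d)
    fwd = _concrete(d.fwd_primer)
    rev_rc = revcomp(_concrete(d.rev_primer))
    mm = allele.mismatches_for(d.name)
    if mm:
        fwd = _mutate_positions(fwd, range(min(mm, len(fwd))), rng)
    return fwd + insert + rev_rc


def simulate_reads(
    truth: SimTruth, cfg: SimConfig, seed: int
) -> tuple[list[tuple[FastqRead, FastqRead]], MidScheme]:
    """MID-tagged 300 bp read pairs for the whole cohort, plus the MID scheme.

    Mates are opposite-strand windows of the amplicon, so their overlap is
    consistent with the insert length; substitution errors are applied per
    base at the configured rate; qualities are constant (Q35 by default).
    """
    rng = np.random.default_rng(seed)
    counts = simulate_read_counts(truth, cfg, seed + 1 if seed < 2**31 - 1 else seed - 1)
    panel = {d.name: d for d in truth.panel}
    pairs: list[tuple[FastqRead, FastqRead]] = []
    body = cfg.read_len - cfg.mid_len
    for (aid, amp_name), allele_counts in sorted(counts.items()):
        animal = truth.animals[aid]
        d = panel[amp_name]
        amp_seqs = {
            al_id: _amplicon_sequence(truth.alleles[al_id], d, rng)
            for al_id in sorted(allele_counts)
        }
        i = 0
        for al_id in sorted(allele_counts):
            for _ in range(allele_counts[al_id]):
                amp = amp_seqs[al_id]
                if cfg.chimera_rate and rng.random() < cfg.chimera_rate and len(amp_seqs) > 1:
                    other = sorted(amp_seqs)[int(rng.integers(0, len(amp_seqs)))]
                    if other != al_id and len(amp_seqs[other]) == len(amp):
                        k = int(rng.integers(1, len(amp)))
                        amp = amp[:k] + amp_seqs[other][k:]
                fwd_body = amp[:body]
                rev_body = revcomp(amp)[:body]
                if cfg.error_rate:
                    fwd_body = _apply_errors(fwd_body, cfg.error_rate, rng)
                    rev_body = _apply_errors(rev_body, cfg.error_rate, rng)
                fseq = animal.fwd_mid + fwd_body
                rseq = animal.rev_mid + rev_body
                q = cfg.qual_char * len(fseq)
                rid = f"{aid}:{amp_name}:{i}"
                pairs.append(
                    (FastqRead(rid + "/1", fseq, q[: len(fseq)]),
                     FastqRead(rid + "/2", rseq, cfg.qual_char * len(rseq)))
                )
                i += 1
    return pairs, truth.mid_scheme()


def _apply_errors(seq: str, rate: float, rng) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    return _mutate_positions(seq, sorted(int(p) for p in pos), rng)
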