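"""Per-sample allele calling: dereplication, artifact removal, the 0.2%
resolution threshold, and the cohort-wide allele recovery loop.

The caller works on primer-trimmed inserts from one sample and amplicon.
Identical sequences are collapsed; two artifact classes are flagged before
thresholding:

* *shadows* — low-abundance near-copies of a much more abundant sequence
  (PCR/sequencing error clouds);
* *chimeras* — sequences assembled as a prefix of one abundant sequence and
  the suffix of another (template-switching artifacts).

Frequencies are computed over the non-artifact reads of the sample+amplicon.
Entries at or above the resolution threshold (0.2% of reads by default) are
*called*; the recovery loop then re-admits sub-threshold entries whose
sequence exactly matches an allele called in at least one animal of the
cohort — the mechanism that rescues lowly expressed alleles first seen above
threshold only in homozygotes (the "double-dose" effect).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import edlib

CALLED = "called"
SUB_THRESHOLD = "sub_threshold"
RECOVERED = "recovered"
ARTIFACT_SHADOW = "artifact_shadow"
ARTIFACT_CHIMERA = "artifact_chimera"
PROVISIONAL = "provisional"

_ARTIFACTS = (ARTIFACT_SHADOW, ARTIFACT_CHIMERA)


@dataclass(frozen=True)
class CallingConfig:
    freq_threshold: float = 0.002
    shadow_max_mismatch: int = 1
    shadow_ratio: float = 0.1
    chimera_parent_ratio: float = 1.0
    recovery_min_reads: int = 2

    def __post_init__(self):
        if not 0 < self.freq_threshold < 1:
            raise ValueError("freq_threshold must be in (0, 1)")
        if not 0 < self.shadow_ratio <= 1 or not 0 < self.chimera_parent_ratio <= 1:
            raise ValueError("ratios must be in (0, 1]")


@dataclass(frozen=True)
class CallEntry:
    seq: str
    count: int
    frequency: float
    status: str


@dataclass
class SampleCallSet:
    sample_id: str
    amplicon: str
    entries: list[CallEntry] = field(default_factory=list)

    @classmethod
    def from_counts(cls, sample_id: str, amplicon: str, counts: dict[str, int]) -> "SampleCallSet":
        total = sum(counts.values())
        entries = [
            CallEntry(seq, n, n / total if total else 0.0, PROVISIONAL)
            for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if n > 0
        ]
        return cls(sample_id, amplicon, entries)

    def non_artifact(self) -> list[CallEntry]:
        return [e for e in self.entries if e.status not in _ARTIFACTS]

    def with_status(self, *statuses: str) -> list[CallEntry]:
        return [e for e in self.entries if e.status in statuses]

    def present_sequences(self) -> dict[str, CallEntry]:
        """Sequences in the final genotype: called or recovered."""
        return {e.seq: e for e in self.entries if e.status in (CALLED, RECOVERED)}


def dereplicate(sample_id: str, amplicon: str, inserts: Iterable[str]) -> SampleCallSet:
    """Collapse identical insert sequences into counted entries.

    Entries are sorted by descending count then sequence, so the result is
    invariant under permutation of the input reads.
    """
    return SampleCallSet.from_counts(sample_id, amplicon, Counter(s.upper() for s in inserts))


def _within(a: str, b: str, k: int) -> bool:
    if abs(len(a) - len(b)) > k:
        return False
    return edlib.align(a, b, task="distance", k=k)["editDistance"] != -1


def denoise_artifacts(calls: SampleCallSet, cfg: CallingConfig = CallingConfig()) -> SampleCallSet:
    """Flag shadow and chimera entries; recompute frequencies over survivors.

    An entry is a shadow of a non-artifact entry at least 1/shadow_ratio times
    more abundant if it lies within ``shadow_max_mismatch`` edits of it. An
    entry is a chimera if it equals prefix(P1)+suffix(P2) at some breakpoint
    for two distinct non-artifact entries each at least
    ``chimera_parent_ratio`` times its own count.
    """
    entries = sorted(calls.entries, key=lambda e: (-e.count, e.seq))
    status: dict[str, str] = {e.seq: e.status for e in entries}

    for e in entries:
        for parent in entries:
            if parent.seq == e.seq or status[parent.seq] in _ARTIFACTS:
                continue
            if e.count <= cfg.shadow_ratio * parent.count and _within(
                e.seq, parent.seq, cfg.shadow_max_mismatch
            ):
                status[e.seq] = ARTIFACT_SHADOW
                break

    for e in entries:
        if status[e.seq] in _ARTIFACTS:
            continue
        parents = [
            p
            for p in entries
            if p.seq != e.seq
            and status[p.seq] not in _ARTIFACTS
            and p.count >= cfg.chimera_parent_ratio * e.count
        ]
        if _is_chimera(e.seq, [p.seq for p in parents]):
            status[e.seq] = ARTIFACT_CHIMERA

    surviving = sum(e.count for e in entries if status[e.seq] not in _ARTIFACTS)
    out = []
    for e in entries:
        st = status[e.seq]
        freq = e.count / surviving if (surviving and st not in _ARTIFACTS) else e.frequency
        if st in _ARTIFACTS:
            out.append(replace(e, status=st))
        else:
            out.append(CallEntry(e.seq, e.count, freq, st))
    return SampleCallSet(calls.sample_id, calls.amplicon, out)


def _is_chimera(seq: str, parent_seqs: Sequence[str]) -> bool:
    """True if seq = parent1[:k] + parent2[k:] at any internal breakpoint.

    Equivalent to a full breakpoint scan: a pair (P1, P2) admits a breakpoint
    k iff k <= commonprefix(seq, P1) and n - k <= commonsuffix(seq, P2), i.e.
    the two shared stretches cover the sequence.
    """
    n = len(seq)
    if len(parent_seqs) < 2:
        return False

    def common_prefix(p: str) -> int:
        m = min(len(p), n)
        i = 0
        while i < m and p[i] == seq[i]:
            i += 1
        return i

    def common_suffix(p: str) -> int:
        if len(p) != n:  # suffix coordinates only line up for equal lengths
            return 0
        i = 0
        while i < n and p[n - 1 - i] == seq[n - 1 - i]:
            i += 1
        return i

    pre = [common_prefix(p) for p in parent_seqs]
    suf = [common_suffix(p) for p in parent_seqs]
    for i, p1 in enumerate(parent_seqs):
        if pre[i] < 1:
            continue
        for j, p2 in enumerate(parent_seqs):
            if i == j or p1 == p2 or suf[j] < 1:
                continue
            # breakpoint k must satisfy 1 <= k <= n-1, k <= pre[i], n-k <= suf[j]
            if pre[i] + suf[j] >= n and min(pre[i], n - 1) >= max(1, n - suf[j]):
                return True
    return False


def apply_threshold(calls: SampleCallSet, cfg: CallingConfig = CallingConfig()) -> SampleCallSet:
    """Status ``called`` iff frequency >= threshold (boundary inclusive), else
    ``sub_threshold``; artifact flags untouched."""
    out = []
    for e in calls.entries:
        if e.status in _ARTIFACTS:
            out.append(e)
        elif e.frequency >= cfg.freq_threshold:
            out.append(replace(e, status=CALLED))
        else:
            out.append(replace(e, status=SUB_THRESHOLD))
    return SampleCallSet(calls.sample_id, calls.amplicon, out)


def recovery_loop(
    cohort: Iterable[SampleCallSet],
    cfg: CallingConfig = CallingConfig(),
    validated_refs: Iterable[str] = (),
) -> list[SampleCallSet]:
    """Cohort-wide allele recovery to fixpoint.

    The confirmed set is the union of sequences *called* in at least one
    animal (per amplicon), plus any externally validated reference sequences.
    A sub-threshold entry becomes ``recovered`` iff its sequence exactly
    (full length) matches a confirmed allele and it has at least
    ``recovery_min_reads`` reads. Recovered entries do not expand the
    confirmed set, so the loop is order-independent and terminates.
    """
    cohort = list(cohort)
    confirmed: dict[str, set[str]] = {}
    for cs in cohort:
        bucket = confirmed.setdefault(cs.amplicon, set(s.upper() for s in validated_refs))
        for e in cs.entries:
            if e.status == CALLED:
                bucket.add(e.seq)

    changed = True
    out = cohort
    while changed:
        changed = False
        new_out = []
        for cs in out:
            bucket = confirmed.get(cs.amplicon, set())
            entries = []
            for e in cs.entries:
                if (
                    e.status == SUB_THRESHOLD
                    and e.seq in bucket
                    and e.count >= cfg.recovery_min_reads
                ):
                    entries.append(replace(e, status=RECOVERED))
                    changed = True
                else:
                    entries.append(e)
            new_out.append(SampleCallSet(cs.sample_id, cs.amplicon, entries))
        out = new_out
    return out


@dataclass(frozen=True)
class MhciAllele:
    """A class I allele assembled from one or both of the overlapping amplicons."""

    for1_seq: str | None
    for32_seq: str | None
    composite_seq: str | None  # 410 bp when both segments are consistent
    support: float  # max frequency across the contributing amplicons

    @property
    def key(self) -> str:
        """Stable sequence identity for genotype matrices."""
        return self.composite_seq or self.for1_seq or self.for32_seq or ""


def merge_mhci_amplicons(
    calls_for1: SampleCallSet,
    calls_for32: SampleCallSet,
    composite_overlap: int | None = None,
) -> list[MhciAllele]:
    """Combine one animal's two class I call sets into a single allele set.

    An allele is present if called or recovered in *either* amplicon. The two
    amplicons overlap inside the 410 bp composite region, so a For1 segment
    and a For3.2 segment that agree over the shared interval are joined into
    one composite allele; segments with no unique consistent partner are kept
    as partial (single-amplicon) allele records — mirroring alleles only ever
    amplified by one primer pair.
    """
    from .amplicons import MHCI_COMPOSITE_LEN, MHCI_FOR32_OFFSET

    seg1 = calls_for1.present_sequences()
    seg32 = calls_for32.present_sequences()
    off = MHCI_FOR32_OFFSET  # composite coordinate where the For3.2 insert starts

    def compatible(s1: str, s32: str) -> bool:
        shared = len(s1) - off
        return shared > 0 and s1[off:] == s32[:shared]

    pairs: dict[str, list[str]] = {s: [t for t in sorted(seg32) if compatible(s, t)] for s in sorted(seg1)}
    rev_pairs: dict[str, list[str]] = {
        t: [s for s in sorted(seg1) if compatible(s, t)] for t in sorted(seg32)
    }

    out: list[MhciAllele] = []
    used32: set[str] = set()
    for s1 in sorted(seg1):
        partners = pairs[s1]
        if len(partners) == 1 and len(rev_pairs[partners[0]]) == 1:
            s32 = partners[0]
            used32.add(s32)
            composite = s1 + s32[len(s1) - off:]
            out.append(
                MhciAllele(
                    for1_seq=s1,
                    for32_seq=s32,
                    composite_seq=composite,
                    support=max(seg1[s1].frequency, seg32[s32].frequency),
                )
            )
        else:
            out.append(MhciAllele(s1, None, None, seg1[s1].frequency))
    for s32 in sorted(seg32):
        if s32 not in used32:
            out.append(MhciAllele(None, s32, None, seg32[s32].frequency))
    return out


def call_sample(
    sample_id: str,
    amplicon: str,
    inserts: Iterable[str],
    cfg: CallingConfig = CallingConfig(),
) -> SampleCallSet:
    """dereplicate → denoise → threshold for one sample+amplicon."""
    return apply_threshold(denoise_artifacts(dereplicate(sample_id, amplicon, inserts), cfg), cfg)


def cohort_allele_fasta(cohort: Iterable[SampleCallSet]) -> str:
    """FASTA of the distinct called+recovered sequences across the cohort,
    named by amplicon and discovery rank (by cohort-wide read count)."""
    totals: dict[tuple[str, str], int] = {}
    for cs in cohort:
        for seq, e in cs.present_sequences().items():
            key = (cs.amplicon, seq)
            totals[key] = totals.get(key, 0) + e.count
    lines = []
    rank: dict[str, int] = {}
    for (amplicon, seq), n in sorted(totals.items(), key=lambda kv: (kv[0][0], -kv[1], kv[0][1])):
        rank[amplicon] = rank.get(amplicon, 0) + 1
        lines.append(f">{amplicon}_{rank[amplicon]:03d} reads={n}\n{seq}")
    return "\n".join(lines) + ("\n" if lines else "")


def genotype_tsv(cohort: Iterable[SampleCallSet]) -> str:
    """Long-format per-sample genotype table."""
    lines = ["sample\tamplicon\tseq_id\tcount\tfrequency\tstatus"]
    for cs in cohort:
        for i, e in enumerate(cs.entries):
            lines.append(
                f"{cs.sample_id}\t{cs.amplicon}\t{cs.amplicon}_{i:03d}\t"
                f"{e.count}\t{e.frequency:.6f}\t{e.status}"
            )
    return "\n".join(lines) + "\n"
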