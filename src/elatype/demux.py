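"""Demultiplexing, paired-end merging, quality filtering, amplicon assignment.

These are the upstream stages that turn one multiplexed MiSeq run into
per-sample, per-amplicon primer-trimmed insert sequences:

1. route read pairs to samples by their (forward, reverse) MID tag pair
   (exact match; tags removed);
2. merge each pair across its overlap, resolving disagreements toward the
   higher base quality;
3. drop merged reads whose mean Phred quality is not strictly above Q28;
4. assign each merged read to an amplicon by matching the panel primers
   (IUPAC-aware, one mismatch per primer by default) in either orientation,
   and trim the primers off.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

from .amplicons import AmpliconDef
from .seqs import primer_mismatches, revcomp

MAX_SAMPLES_PER_RUN = 192


class SchemeError(ValueError):
    """Invalid MID scheme."""


@dataclass(frozen=True)
class FastqRead:
    id: str
    seq: str
    qual: str  # phred+33

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.id}: sequence and quality lengths differ")

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]

    def mean_quality(self) -> float:
        return sum(self.phred()) / len(self.qual) if self.qual else 0.0


@dataclass(frozen=True)
class MergedRead:
    id: str
    sample_id: str
    seq: str
    qual: str
    overlap_len: int

    def mean_quality(self) -> float:
        return sum(ord(c) - 33 for c in self.qual) / len(self.qual) if self.qual else 0.0


class MidScheme:
    """Association of (forward tag, reverse tag) pairs with sample ids."""

    def __init__(self, entries: dict[tuple[str, str], str]):
        if len(set(entries.values())) != len(entries):
            raise SchemeError("duplicate sample ids in MID scheme")
        if len(entries) > MAX_SAMPLES_PER_RUN:
            raise SchemeError(
                f"MID scheme has {len(entries)} samples; at most {MAX_SAMPLES_PER_RUN} per run"
            )
        lens = {len(t) for pair in entries for t in pair}
        if len(lens) > 1:
            raise SchemeError(f"MID tags must share one length, got lengths {sorted(lens)}")
        self.entries = dict(entries)
        self.tag_len = lens.pop() if lens else 0

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, stream) -> "MidScheme":
        entries: dict[tuple[str, str], str] = {}
        for ln, line in enumerate(stream, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("sample_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SchemeError(f"MID scheme line {ln}: expected 3 columns, got {len(parts)}")
            sample, fwd, rev = parts
            key = (fwd.upper(), rev.upper())
            if key in entries:
                raise SchemeError(f"duplicate tag pair {key} (line {ln})")
            entries[key] = sample
        return cls(entries)

    def to_tsv(self) -> str:
        lines = ["sample_id\tfwd_tag\trev_tag"]
        for (fwd, rev), sample in self.entries.items():
            lines.append(f"{sample}\t{fwd}\t{rev}")
        return "\n".join(lines) + "\n"


def read_fastq(path) -> Iterator[FastqRead]:
    """Stream a (optionally gzipped) FASTQ file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield FastqRead(rec.id, str(rec.seq).upper(), qual)


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def demultiplex(
    read_pairs: Iterable[tuple[FastqRead, FastqRead]],
    scheme: MidScheme,
) -> tuple[dict[str, list[tuple[FastqRead, FastqRead]]], dict[str, int]]:
    """Route read pairs to samples by exact MID pair match, stripping the tags.

    Returns (per-sample pair lists, routing counts); pairs whose tag
    combination is not in the scheme land in counts under ``undetermined``.
    Totals are conserved: sum of all counts equals the number of input pairs.
    """
    n = scheme.tag_len
    out: dict[str, list[tuple[FastqRead, FastqRead]]] = {s: [] for s in scheme.entries.values()}
    counts = {s: 0 for s in scheme.entries.values()}
    counts["undetermined"] = 0
    for fwd, rev in read_pairs:
        sample = scheme.entries.get((fwd.seq[:n], rev.seq[:n]))
        if sample is None:
            counts["undetermined"] += 1
            continue
        out[sample].append(
            (
                FastqRead(fwd.id, fwd.seq[n:], fwd.qual[n:]),
                FastqRead(rev.id, rev.seq[n:], rev.qual[n:]),
            )
        )
        counts[sample] += 1
    return out, counts


def merge_pair(
    fwd: FastqRead,
    rev: FastqRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
    sample_id: str = "",
) -> MergedRead | None:
    """FLASH-style overlap merge of a read pair; None if no admissible overlap.

    Every overlap length from ``min_overlap`` up to the shorter read is
    scored; among overlaps with mismatch fraction <= ``max_mismatch_frac``
    the one with the most matching bases wins (ties toward the longer
    overlap). Disagreeing bases resolve toward the higher quality score,
    ties toward the forward base.
    """
    import numpy as np

    rseq = revcomp(rev.seq)
    rqual = rev.qual[::-1]
    a = np.frombuffer(fwd.seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rseq.encode(), dtype=np.uint8)
    na = len(a)
    best = None  # (matches, overlap, mismatches)
    # scan overlaps from longest down; once the remaining overlap length cannot
    # beat the best match count, stop (matches <= overlap length)
    for o in range(min(na, len(b)), min_overlap - 1, -1):
        if best is not None and best[0] >= o:
            break
        mm = int((a[na - o:] != b[:o]).sum())
        if mm / o > max_mismatch_frac:
            continue
        key = (o - mm, o)
        if best is None or key > (best[0], best[1]):
            best = (o - mm, o, mm)
    if best is None:
        return None
    o = best[1]
    head_s, head_q = fwd.seq[: len(fwd.seq) - o], fwd.qual[: len(fwd.qual) - o]
    tail_s, tail_q = rseq[o:], rqual[o:]
    f_sub, f_qsub = fwd.seq[len(fwd.seq) - o:], fwd.qual[len(fwd.qual) - o:]
    r_sub, r_qsub = rseq[:o], rqual[:o]
    if f_sub == r_sub and f_qsub == r_qsub:
        # common fast path: overlap halves and their qualities agree
        mid_s, mid_q = [f_sub], [f_qsub]
    else:
        mid_s, mid_q = [], []
        for i in range(o):
            fb, fq = f_sub[i], f_qsub[i]
            rb, rq = r_sub[i], r_qsub[i]
            if fb == rb or fq >= rq:
                mid_s.append(fb)
                mid_q.append(max(fq, rq) if fb == rb else fq)
            else:
                mid_s.append(rb)
                mid_q.append(rq)
    return MergedRead(
        id=fwd.id,
        sample_id=sample_id,
        seq=head_s + "".join(mid_s) + tail_s,
        qual=head_q + "".join(mid_q) + tail_q,
        overlap_len=o,
    )


def quality_filter(read: MergedRead, threshold: float = 28.0) -> tuple[bool, str]:
    """(passed, reason): pass iff mean Phred quality is strictly above threshold."""
    if not read.qual:
        return False, "missing_quality"
    if read.mean_quality() > threshold:
        return True, "ok"
    return False, "low_quality"


def assign_amplicon(
    read: MergedRead | str,
    defs: Iterable[AmpliconDef],
) -> tuple[AmpliconDef, str] | tuple[None, str]:
    """Match a merged read against the panel primers and trim them.

    Both orientations of the read are tried against each definition's forward
    primer (5' end) and reverse-complemented reverse primer (3' end), IUPAC
    codes in primers respected. A definition is admissible if each primer
    matches with at most its mismatch tolerance; the lowest total-mismatch
    definition wins. Returns (definition, insert) or (None, reason) with
    reason ``ambiguous`` or ``no_match``; the insert is reported in the
    forward (primer) orientation.
    """
    seq = read if isinstance(read, str) else read.seq
    rc_seq = revcomp(seq)
    hits = []  # (total_mm, name, def, insert)
    for d in defs:
        fwd_sets = _primer_sets(d.fwd_primer)
        rc_rev_sets = _primer_sets(revcomp(d.rev_primer))
        tol = d.max_primer_mismatches
        for oriented in (seq, rc_seq):
            if len(oriented) < len(d.fwd_primer) + len(d.rev_primer):
                continue
            mm_f = _mm_capped(fwd_sets, oriented[: len(d.fwd_primer)], tol)
            if mm_f > tol:
                continue
            mm_r = _mm_capped(rc_rev_sets, oriented[len(oriented) - len(d.rev_primer):], tol)
            if mm_r > tol:
                continue
            insert = oriented[len(d.fwd_primer): len(oriented) - len(d.rev_primer)]
            hits.append((mm_f + mm_r, d.name, d, insert))
            break  # orientation found; do not also record the reverse
    if not hits:
        return None, "no_match"
    hits.sort(key=lambda h: (h[0], h[1]))
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return None, "ambiguous"
    return hits[0][2], hits[0][3]


_PRIMER_SET_CACHE: dict[str, tuple[frozenset, ...]] = {}


def _primer_sets(primer: str) -> tuple[frozenset, ...]:
    sets = _PRIMER_SET_CACHE.get(primer)
    if sets is None:
        from .seqs import IUPAC

        sets = tuple(IUPAC[b] for b in primer)
        _PRIMER_SET_CACHE[primer] = sets
    return sets


def _mm_capped(primer_sets: tuple[frozenset, ...], window: str, cap: int) -> int:
    mm = 0
    for allowed, b in zip(primer_sets, window):
        if b not in allowed:
            mm += 1
            if mm > cap:
                return mm
    return mm


@dataclass
class RunReport:
    """Per-sample routing counts through the upstream stages."""

    input_pairs: dict[str, int] = field(default_factory=dict)
    merge_failures: dict[str, int] = field(default_factory=dict)
    qc_failures: dict[str, int] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)
    assigned: dict[str, int] = field(default_factory=dict)
    undetermined: int = 0

    def conserved(self, sample: str) -> bool:
        return self.input_pairs.get(sample, 0) == (
            self.assigned.get(sample, 0)
            + self.unassigned.get(sample, 0)
            + self.merge_failures.get(sample, 0)
            + self.qc_failures.get(sample, 0)
        )

    def to_tsv(self) -> str:
        lines = ["sample\tinput_pairs\tmerge_failures\tqc_failures\tunassigned\tassigned"]
        for s in sorted(self.input_pairs):
            lines.append(
                f"{s}\t{self.input_pairs[s]}\t{self.merge_failures.get(s, 0)}\t"
                f"{self.qc_failures.get(s, 0)}\t{self.unassigned.get(s, 0)}\t"
                f"{self.assigned.get(s, 0)}"
            )
        lines.append(f"undetermined\t{self.undetermined}\t0\t0\t0\t0")
        return "\n".join(lines) + "\n"


def process_run(
    read_pairs: Iterable[tuple[FastqRead, FastqRead]],
    scheme: MidScheme,
    panel: Iterable[AmpliconDef],
    q_threshold: float = 28.0,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> tuple[dict[tuple[str, str], list[str]], RunReport]:
    """Run demultiplex → merge → QC → amplicon assignment on a whole run.

    Returns ({(sample, amplicon): [insert, ...]}, report).
    """
    panel = tuple(panel)
    per_sample, route_counts = demultiplex(read_pairs, scheme)
    report = RunReport(undetermined=route_counts["undetermined"])
    inserts: dict[tuple[str, str], list[str]] = {}
    for sample, pairs in per_sample.items():
        report.input_pairs[sample] = len(pairs)
        report.merge_failures[sample] = 0
        report.qc_failures[sample] = 0
        report.unassigned[sample] = 0
        report.assigned[sample] = 0
        for fwd, rev in pairs:
            merged = merge_pair(fwd, rev, min_overlap, max_mismatch_frac, sample_id=sample)
            if merged is None:
                report.merge_failures[sample] += 1
                continue
            ok, _ = quality_filter(merged, q_threshold)
            if not ok:
                report.qc_failures[sample] += 1
                continue
            d, insert = assign_amplicon(merged, panel)
            if d is None:
                report.unassigned[sample] += 1
                continue
            report.assigned[sample] += 1
            inserts.setdefault((sample, d.name), []).append(insert)
    return inserts, report
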