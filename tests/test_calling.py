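"""Allele calling: dereplication, artifacts, threshold, recovery, class I merge."""

import numpy as np
import pytest

from elatype.calling import (
    ARTIFACT_CHIMERA,
    ARTIFACT_SHADOW,
    CALLED,
    RECOVERED,
    SUB_THRESHOLD,
    CallingConfig,
    SampleCallSet,
    apply_threshold,
    denoise_artifacts,
    dereplicate,
    merge_mhci_amplicons,
    recovery_loop,
)
from elatype.seqs import random_seq

from _oracles import chimera_oracle


def _callset(counts, sample="S1", amplicon="DQB"):
    return SampleCallSet.from_counts(sample, amplicon, counts)


class TestDereplicate:
    def test_single_sequence(self):
        cs = dereplicate("S1", "DRA", ["ACGT"] * 50)
        assert len(cs.entries) == 1
        assert cs.entries[0].count == 50
        assert cs.entries[0].frequency == 1.0

    def test_two_sequences_tally(self):
        cs = dereplicate("S1", "DRA", ["AAAA"] * 80 + ["CCCC"] * 20)
        assert [(e.seq, e.count, e.frequency) for e in cs.entries] == [
            ("AAAA", 80, 0.8),
            ("CCCC", 20, 0.2),
        ]

    def test_permutation_invariance(self, rng):
        reads = ["AAAA"] * 5 + ["CCCC"] * 3 + ["GGGG"] * 2
        perm = list(reads)
        rng.shuffle(perm)
        assert dereplicate("S", "DRA", reads) == dereplicate("S", "DRA", perm)

    def test_empty_input(self):
        assert dereplicate("S", "DRA", []).entries == []


class TestDenoise:
    def test_shadow_flagged(self, rng):
        a = random_seq(rng, 100)
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        cs = denoise_artifacts(_callset({a: 1000, b: 8}))
        status = {e.seq: e.status for e in cs.entries}
        assert status[b] == ARTIFACT_SHADOW
        assert status[a] not in (ARTIFACT_SHADOW, ARTIFACT_CHIMERA)
        # frequencies recomputed over surviving reads
        assert {e.seq: e.frequency for e in cs.entries}[a] == 1.0

    def test_abundant_near_neighbour_not_shadow(self, rng):
        a = random_seq(rng, 100)
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        cs = denoise_artifacts(_callset({a: 1000, b: 400}))
        assert all(e.status not in (ARTIFACT_SHADOW, ARTIFACT_CHIMERA) for e in cs.entries)

    def test_chimera_flagged_and_matches_breakpoint_oracle(self, rng):
        a, d = random_seq(rng, 360), random_seq(rng, 360)
        c = a[:200] + d[200:]
        assert chimera_oracle(c, [a, d])
        cs = denoise_artifacts(_callset({a: 500, d: 450, c: 30}))
        status = {e.seq: e.status for e in cs.entries}
        assert status[c] == ARTIFACT_CHIMERA
        assert status[a] == status[d] != ARTIFACT_CHIMERA

    def test_chimera_rule_equals_oracle_random(self, rng):
        """Random low-count candidates are flagged iff a breakpoint scan
        finds two abundant parents."""
        for _ in range(30):
            parents = [random_seq(rng, 40) for _ in range(3)]
            if rng.random() < 0.6:
                k = int(rng.integers(1, 40))
                cand = parents[0][:k] + parents[1][k:]
            else:
                cand = random_seq(rng, 40)
            import edlib

            near_parent = any(
                edlib.align(cand, p, task="distance", k=1)["editDistance"] != -1
                for p in parents
            )
            counts = {p: 100 for p in parents}
            if cand not in counts and not near_parent:  # shadow rule fires first
                counts[cand] = 10
                cs = denoise_artifacts(_callset(counts))
                status = {e.seq: e.status for e in cs.entries}
                assert (status[cand] == ARTIFACT_CHIMERA) == chimera_oracle(
                    cand, parents
                )

    def test_single_entry_unchanged(self, rng):
        a = random_seq(rng, 50)
        cs = denoise_artifacts(_callset({a: 10}))
        assert len(cs.entries) == 1 and cs.entries[0].status not in (
            ARTIFACT_SHADOW,
            ARTIFACT_CHIMERA,
        )


class TestThreshold:
    def _with_freq(self, freq, total=20000):
        n = int(round(freq * total))
        filler = total - n
        cs = _callset({"A" * 30: filler, "C" * 30: n})
        return apply_threshold(cs), "C" * 30

    def test_quarter_percent_called(self):
        cs, seq = self._with_freq(0.0025)
        assert {e.seq: e.status for e in cs.entries}[seq] == CALLED

    def test_sub_threshold_excluded(self):
        cs, seq = self._with_freq(0.0015)
        assert {e.seq: e.status for e in cs.entries}[seq] == SUB_THRESHOLD

    def test_boundary_inclusive(self):
        cs, seq = self._with_freq(0.002)
        assert {e.seq: e.status for e in cs.entries}[seq] == CALLED

    def test_monotone_in_threshold(self, rng):
        """Raising the threshold never adds called entries."""
        counts = {random_seq(rng, 30): int(c) for c in rng.integers(1, 2000, size=12)}
        cs = _callset(counts)
        called_sets = []
        for thr in (0.0005, 0.002, 0.01, 0.1):
            out = apply_threshold(denoise_artifacts(cs), CallingConfig(freq_threshold=thr))
            called_sets.append({e.seq for e in out.entries if e.status == CALLED})
        for lo, hi in zip(called_sets, called_sets[1:]):
            assert hi <= lo


class TestRecovery:
    def _cohort(self):
        allele = "A" * 30
        other = "C" * 30
        # sample X: allele at 0.11% (sub-threshold); sample Y: at 5% (called)
        x = apply_threshold(_callset({other: 9989, allele: 11}, sample="X"))
        y = apply_threshold(_callset({other: 950, allele: 50}, sample="Y"))
        return x, y, allele

    def test_subthreshold_recovered_from_cohort(self):
        x, y, allele = self._cohort()
        out = recovery_loop([x, y])
        sx = {e.seq: e.status for e in out[0].entries}
        assert sx[allele] == RECOVERED

    def test_unmatched_singleton_stays_subthreshold(self):
        x = apply_threshold(_callset({"A" * 30: 9997, "G" * 30: 3}, sample="X"))
        out = recovery_loop([x])
        assert {e.seq: e.status for e in out[0].entries}["G" * 30] == SUB_THRESHOLD

    def test_min_reads_required(self):
        allele = "A" * 30
        x = apply_threshold(_callset({"C" * 30: 9999, allele: 1}, sample="X"))
        y = apply_threshold(_callset({"C" * 30: 950, allele: 50}, sample="Y"))
        out = recovery_loop([x, y])
        assert {e.seq: e.status for e in out[0].entries}[allele] == SUB_THRESHOLD

    def test_double_dose_homozygote_route(self):
        """An allele above threshold only in a homozygote (double dose)
        confirms it for recovery in heterozygotes."""
        allele = "A" * 30
        hom = apply_threshold(_callset({"C" * 30: 9960, allele: 40}, sample="hom"))  # 0.40%
        het1 = apply_threshold(_callset({"C" * 30: 9985, allele: 15}, sample="h1"))  # 0.15%
        het2 = apply_threshold(_callset({"C" * 30: 9982, allele: 18}, sample="h2"))  # 0.18%
        out = recovery_loop([het1, het2, hom])
        statuses = {cs.sample_id: {e.seq: e.status for e in cs.entries} for cs in out}
        assert statuses["hom"][allele] == CALLED
        assert statuses["h1"][allele] == RECOVERED
        assert statuses["h2"][allele] == RECOVERED

    def test_order_independence(self):
        x, y, allele = self._cohort()
        out1 = recovery_loop([x, y])
        out2 = recovery_loop([y, x])
        by_sample1 = {cs.sample_id: cs for cs in out1}
        by_sample2 = {cs.sample_id: cs for cs in out2}
        assert by_sample1 == by_sample2

    def test_recovered_entries_do_not_confirm(self):
        """A sequence only ever recovered (never called) cannot itself
        confirm recovery elsewhere; validated references can."""
        allele = "A" * 30
        x = apply_threshold(_callset({"C" * 30: 9989, allele: 11}, sample="X"))
        out = recovery_loop([x])
        assert {e.seq: e.status for e in out[0].entries}[allele] == SUB_THRESHOLD
        out2 = recovery_loop([x], validated_refs=[allele])
        assert {e.seq: e.status for e in out2[0].entries}[allele] == RECOVERED


class TestMergeMhci:
    def _composite(self, rng):
        return random_seq(rng, 410)

    def _callsets(self, rng, comp, in_for1=True, in_for32=True):
        for1 = comp[:378]
        for32 = comp[92:]
        c1 = {random_seq(rng, 378): 900}
        c2 = {random_seq(rng, 318): 900}
        if in_for1:
            c1[for1] = 100
        if in_for32:
            c2[for32] = 100
        cs1 = apply_threshold(_callset(c1, amplicon="MHCI_For1Rev2.2"))
        cs2 = apply_threshold(_callset(c2, amplicon="MHCI_For3.2Rev1"))
        return cs1, cs2

    def test_single_amplicon_allele_present(self, rng):
        comp = self._composite(rng)
        cs1, cs2 = self._callsets(rng, comp, in_for32=False)
        merged = merge_mhci_amplicons(cs1, cs2)
        assert comp[:378] in {a.for1_seq for a in merged}

    def test_both_segments_compose_once(self, rng):
        comp = self._composite(rng)
        cs1, cs2 = self._callsets(rng, comp)
        merged = merge_mhci_amplicons(cs1, cs2)
        composites = [a for a in merged if a.composite_seq == comp]
        assert len(composites) == 1
        assert composites[0].support == 0.1

    def test_short_form_allele_retained(self, rng):
        """An allele seen only in the 318 bp amplicon stays as a short-form
        record."""
        comp = self._composite(rng)
        cs1, cs2 = self._callsets(rng, comp, in_for1=False)
        merged = merge_mhci_amplicons(cs1, cs2)
        short = [a for a in merged if a.for32_seq == comp[92:]]
        assert len(short) == 1
        assert short[0].composite_seq is None and short[0].for1_seq is None
        assert len(short[0].key) == 318

    def test_cohort_fasta_lists_called_and_recovered_once(self, rng):
        from elatype.calling import cohort_allele_fasta

        lo, hi = "A" * 30, "C" * 30
        x = apply_threshold(_callset({hi: 9989, lo: 11}, sample="X"))
        y = apply_threshold(_callset({hi: 900, lo: 100}, sample="Y"))
        out = recovery_loop([x, y])
        fasta = cohort_allele_fasta(out)
        assert fasta.count(">") == 2  # one record per distinct sequence
        assert lo in fasta and hi in fasta

    def test_frequency_sums_over_non_artifacts(self, rng):
        counts = {random_seq(rng, 40): int(c) for c in rng.integers(10, 500, size=6)}
        cs = apply_threshold(denoise_artifacts(_callset(counts)))
        total = sum(e.frequency for e in cs.non_artifact())
        assert total == pytest.approx(1.0, abs=1e-9)
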