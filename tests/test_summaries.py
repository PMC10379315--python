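"""Fixture tables, their statistics, locus shares, linkage weights."""

import io

import numpy as np
import pandas as pd
import pytest

from elatype.calling import SampleCallSet, apply_threshold
from elatype.haplotypes import AnimalAssignment
from elatype.summaries import (
    FixtureError,
    combined_family_stats,
    linkage_table,
    load_haplotype_table,
    locus_read_proportions,
    locus_share_summary,
    parse_haplotype_id,
    serialize_haplotype_table,
    summarize_haplotype_table,
    allele_frequency_table,
)

ALL_TABLES = [
    "mhci_standard_thoroughbred",
    "mhci_universal_thoroughbred",
    "mhcii_thoroughbred",
    "mhci_icenor",
    "mhcii_icenor",
]


class TestHapIds:
    @pytest.mark.parametrize(
        "hap, cls, fam, sub, un, p",
        [
            ("HP1.6a", "MHCI", 6, "a", False, False),
            ("unHP1.11", "MHCI", 11, None, True, False),
            ("pHP2.26", "MHCII", 26, None, False, True),
            ("unpHP2.40", "MHCII", 40, None, True, True),
            ("HP2.23d", "MHCII", 23, "d", False, False),
        ],
    )
    def test_parse(self, hap, cls, fam, sub, un, p):
        h = parse_haplotype_id(hap)
        assert (h.mhc_class, h.family, h.subtype, h.unconfirmed, h.partial) == (
            cls, fam, sub, un, p,
        )

    def test_bad_id_rejected(self):
        with pytest.raises(FixtureError):
            parse_haplotype_id("HP3.1")


class TestFixtures:
    @pytest.mark.parametrize("name", ALL_TABLES)
    def test_roundtrip_lossless(self, name):
        df = load_haplotype_table(name)
        text = serialize_haplotype_table(df)
        again = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
        for col in again.columns:
            if col.startswith(("occ", "n_", "total_")):
                again[col] = again[col].astype(int)
        pd.testing.assert_frame_equal(df, again)

    def test_occurrence_sums_conserve_cohort_sizes(self):
        """Haplotype slots across each table account for two chromosomes per
        genotyped animal, minus the animals left unassigned."""
        t2 = load_haplotype_table("mhci_standard_thoroughbred")
        assert t2["occurrences"].sum() == 2 * 96 - 2  # one Thoroughbred unassigned
        t5 = load_haplotype_table("mhcii_thoroughbred")
        assert t5["occurrences"].sum() == 2 * 96
        t6 = load_haplotype_table("mhci_icenor")
        assert t6["occ_icelandic"].sum() == 2 * 35
        assert t6["occ_norwegian"].sum() == 2 * 37 - 2  # one Norwegian unassigned
        t7 = load_haplotype_table("mhcii_icenor")
        assert t7["occ_icelandic"].sum() == 2 * 35
        assert t7["occ_norwegian"].sum() == 2 * 37

    def test_standard_and_universal_tables_agree(self):
        """The two Thoroughbred MHCI tables list the same haplotypes with
        complementary allele counts."""
        std = load_haplotype_table("mhci_standard_thoroughbred")
        uni = load_haplotype_table("mhci_universal_thoroughbred")
        assert list(std["haplotype"]) == list(uni["haplotype"])
        assert (std["occurrences"] == uni["occurrences"]).all()
        assert (std["n_standard"] + uni["n_universal"] == std["total_expressed"]).all()

    def test_listed_alleles_match_printed_counts(self):
        for name in ("mhci_standard_thoroughbred", "mhci_universal_thoroughbred",
                     "mhci_icenor"):
            s = summarize_haplotype_table(load_haplotype_table(name))
            assert s["validation_flags"] == []

    def test_known_print_inconsistencies_flagged_not_fatal(self):
        s = summarize_haplotype_table(load_haplotype_table("mhcii_icenor"))
        assert len(s["validation_flags"]) == 2
        assert any("pHP2.26" in f for f in s["validation_flags"])

    def test_empty_table(self):
        s = summarize_haplotype_table(pd.DataFrame({"haplotype": []}))
        assert s["n_rows"] == 0 and s["n_families"] == 0


class TestCombinedFamilies:
    def test_cross_cohort_variants(self):
        """Subtypes split across cohorts (e.g. one variant per breed table)
        still count as one multi-variant family."""
        t2 = load_haplotype_table("mhci_standard_thoroughbred")
        t6 = load_haplotype_table("mhci_icenor")
        stats = combined_family_stats([t2, t6])
        # family 7 has subtype a in one cohort and b in the other
        assert stats["families_with_multiple_variants"] >= 3


def _cs(sample, amplicon, counts):
    return apply_threshold(SampleCallSet.from_counts(sample, amplicon, counts))


class TestLocusProportions:
    def test_single_locus_share_one(self):
        cs = _cs("A1", "DRB", {"x": 500})
        df = locus_read_proportions([cs], {"x": "DRB1"})
        assert df.loc[0, "share"] == 1.0

    def test_arithmetic_shares(self):
        cs = _cs("A1", "DRB", {"x": 900, "y": 80, "z": 20})
        df = locus_read_proportions([cs], {"x": "DRB1", "y": "DRB2", "z": "DRB3"})
        shares = dict(zip(df["locus"], df["share"]))
        assert shares == {"DRB1": 0.9, "DRB2": 0.08, "DRB3": 0.02}

    def test_shares_sum_to_one_within_gene(self):
        cs1 = _cs("A1", "DQB", {"a": 700, "b": 300})
        cs2 = _cs("A1", "DRB", {"c": 950, "d": 50})
        df = locus_read_proportions(
            [cs1, cs2], {"a": "DQB1", "b": "DQB2", "c": "DRB1", "d": "DRB2"}
        )
        sums = df.groupby(["animal", "gene"])["share"].sum()
        assert np.allclose(sums, 1.0)

    def test_simulator_expression_hierarchy_recovered(self):
        """Cohort locus-share medians reflect the simulator's locus
        expression weights within sampling error."""
        from elatype.amplicons import panel_by_name
        from elatype.simulate import SimConfig, simulate_cohort, simulate_read_counts

        cfg = SimConfig(n_animals=20, n_mhci_haplotypes=4, n_mhcii_haplotypes=4,
                        reads_per_animal=40000, drb3_prob=0.0)
        truth = simulate_cohort(cfg, 21)
        counts = simulate_read_counts(truth, cfg, 22)
        panel = panel_by_name()
        callsets, locus_map = [], {}
        for (animal, amp), c in counts.items():
            if amp in ("DRB", "DQA", "DQB"):
                seqs = {truth.alleles[k].insert_for(panel[amp]): v for k, v in c.items()}
                callsets.append(_cs(animal, amp, seqs))
                for k in c:
                    locus_map[truth.alleles[k].insert_for(panel[amp])] = truth.alleles[k].locus
        summary = locus_share_summary(locus_read_proportions(callsets, locus_map))
        med = {
            (r.gene, r.locus): r.median for r in summary.itertuples()
        }
        assert med[("DRB", "DRB1")] > 0.8
        assert med[("DQB", "DQB1")] > med[("DQB", "DQB2")]
        assert med[("DQA", "DQA1")] > 0.5


class TestAlleleFrequencyTable:
    def test_rows_and_flags(self):
        cs = _cs("A1", "DQA", {"hi": 9985, "lo": 15})
        from elatype.calling import recovery_loop

        other = _cs("A2", "DQA", {"hi": 900, "lo": 100})
        out = recovery_loop([cs, other])
        df = allele_frequency_table(out)
        lo_rows = df[(df.animal == "A1") & (df.seq == "lo")]
        assert len(lo_rows) == 1
        assert lo_rows.iloc[0]["status"] == "recovered"
        assert lo_rows.iloc[0]["frequency"] < 0.002
        sums = df.groupby(["animal", "amplicon"])["frequency"].sum()
        assert (sums <= 1.0 + 1e-9).all()


class TestLinkage:
    def _assign(self, animal, sets):
        return AnimalAssignment(animal, tuple(sets), frozenset())

    def test_double_homozygote_single_cell(self):
        h1, h2 = frozenset("ab"), frozenset("cd")
        ids1, ids2 = {h1: "HP1.6a"}, {h2: "HP2.1"}
        cells, excluded = linkage_table(
            {"A": self._assign("A", [h1, h1])}, {"A": self._assign("A", [h2, h2])},
            ids1, ids2,
        )
        assert cells == {("HP1.6a", "HP2.1"): 1.0}
        assert excluded == 0

    def test_double_heterozygote_uniform_quarters(self):
        hA, hB = frozenset("ab"), frozenset("cd")
        hX, hY = frozenset("ef"), frozenset("gh")
        ids1 = {hA: "HP1.1", hB: "HP1.2"}
        ids2 = {hX: "HP2.1", hY: "HP2.2"}
        cells, _ = linkage_table(
            {"A": self._assign("A", [hA, hB])}, {"A": self._assign("A", [hX, hY])},
            ids1, ids2,
        )
        assert all(w == pytest.approx(0.25) for w in cells.values())
        assert len(cells) == 4

    def test_weight_conservation_and_exclusion(self):
        h1, h2 = frozenset("ab"), frozenset("cd")
        hX = frozenset("ef")
        ids1 = {h1: "I1", h2: "I2"}
        ids2 = {hX: "II1"}
        a1 = {"A": self._assign("A", [h1, h2]), "B": self._assign("B", [h1, h1]),
              "C": self._assign("C", [h2, h2])}
        a2 = {"A": self._assign("A", [hX, hX]), "B": self._assign("B", [hX, hX])}
        cells, excluded = linkage_table(a1, a2, ids1, ids2)
        assert sum(cells.values()) == pytest.approx(2.0)  # C excluded
        assert excluded == 1

    def test_simulated_deterministic_linkage_concentrates(self):
        """With fully linked classes, weight lands on the truth pairings."""
        from elatype.haplotypes import infer_haplotype_pool
        from elatype.simulate import SimConfig, simulate_cohort

        cfg = SimConfig(n_animals=80, n_mhci_haplotypes=6, n_mhcii_haplotypes=6,
                        dropout_prob=0.0, linkage_strength=1.0)
        truth = simulate_cohort(cfg, 31)
        pools = {
            cls: infer_haplotype_pool(truth.genotype_sets(cls), cls)
            for cls in ("MHCI", "MHCII")
        }
        ids = {cls: pools[cls].set_to_id() for cls in pools}
        cells, excluded = linkage_table(
            pools["MHCI"].assignments, pools["MHCII"].assignments,
            ids["MHCI"], ids["MHCII"],
        )
        assert excluded == 0
        assert sum(cells.values()) == pytest.approx(len(truth.animals))
        # the linked pairing of each truth MHCI haplotype dominates its row
        set_to_id_i = pools["MHCI"].set_to_id()
        set_to_id_ii = pools["MHCII"].set_to_id()
        for k in range(6):
            hi = set_to_id_i[truth.haplotypes[f"I{k}"].allele_ids]
            hii = set_to_id_ii[truth.haplotypes[f"II{k}"].allele_ids]
            row = {p: w for p, w in cells.items() if p[0] == hi}
            assert max(row, key=row.get) == (hi, hii)
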