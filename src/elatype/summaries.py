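"""Cohort-level summaries: haplotype-table statistics, locus read
proportions, allele read-frequency tables, and MHCI-MHCII linkage.

The packaged haplotype tables (under ``elatype/data/tables``) transcribe the
published gene content of the Thoroughbred and Icelandic/Norwegian Fjord
haplotypes; ``summarize_haplotype_table`` computes the descriptive statistics
those tables support (family and variant counts, allele-class distributions,
cross-breed sharing, means and extremes of expressed-gene counts). The same
schema accepts a live :class:`~elatype.haplotypes.HaplotypePool`, so pipeline
output and the published tables are summarised identically.

Cell markers in the fixtures: a leading ``?`` flags an allele whose presence
was assumed or could not be confirmed (promiscuous alleles); a leading ``!``
flags a cell transcribed verbatim from an apparent misprint. ``?`` cells are
excluded when re-counting expressed genes (matching the printed counts);
``!`` cells are excluded from allele-class counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calling import SampleCallSet
from .haplotypes import AnimalAssignment

PACKAGED_TABLES = {
    "mhci_standard_thoroughbred": "mhci_standard_thoroughbred.tsv",
    "mhci_universal_thoroughbred": "mhci_universal_thoroughbred.tsv",
    "mhcii_thoroughbred": "mhcii_thoroughbred.tsv",
    "mhci_icenor": "mhci_icenor.tsv",
    "mhcii_icenor": "mhcii_icenor.tsv",
}

_HAP_ID_RE = re.compile(r"^(?P<un>un)?(?P<p>p)?HP(?P<cls>[12])\.(?P<fam>\d+)(?P<sub>[a-z])?$")


class FixtureError(ValueError):
    """Malformed haplotype-table fixture."""


@dataclass(frozen=True)
class HapId:
    mhc_class: str
    family: int
    subtype: str | None
    unconfirmed: bool
    partial: bool


def parse_haplotype_id(hap_id: str) -> HapId:
    m = _HAP_ID_RE.match(hap_id.strip())
    if m is None:
        raise FixtureError(f"cannot parse haplotype id {hap_id!r}")
    return HapId(
        mhc_class="MHCI" if m.group("cls") == "1" else "MHCII",
        family=int(m.group("fam")),
        subtype=m.group("sub"),
        unconfirmed=bool(m.group("un")),
        partial=bool(m.group("p")),
    )


def load_haplotype_table(name_or_path) -> pd.DataFrame:
    """Load a packaged fixture (by short name) or a TSV path.

    Validates that every haplotype id parses and that ids are unique.
    """
    if isinstance(name_or_path, str) and name_or_path in PACKAGED_TABLES:
        ref = resources.files("elatype").joinpath("data/tables", PACKAGED_TABLES[name_or_path])
        with ref.open("r") as fh:
            df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    else:
        df = pd.read_csv(name_or_path, sep="\t", comment="#", dtype=str)
    if "haplotype" not in df.columns:
        raise FixtureError("fixture must have a 'haplotype' column")
    if df["haplotype"].duplicated().any():
        dupes = df.loc[df["haplotype"].duplicated(), "haplotype"].tolist()
        raise FixtureError(f"duplicate haplotype rows: {dupes}")
    for hap in df["haplotype"]:
        parse_haplotype_id(hap)
    for col in df.columns:
        if col.startswith(("occ", "n_", "total_")):
            df[col] = df[col].astype(int)
    return df


def serialize_haplotype_table(df: pd.DataFrame) -> str:
    """TSV text; load → serialize → load round-trips losslessly."""
    return df.to_csv(sep="\t", index=False, na_rep="")


_ALLELE_CLASS_COLS = {
    "DQA": ("dqa1", "dqa2", "dqa3"),
    "DQB": ("dqb1", "dqb2", "dqb3"),
    "DRA": ("dra",),
    "DRB": ("drb1", "drb2", "drb3"),
}


def _cell_alleles(cell) -> tuple[list[str], str]:
    """Parse one table cell → (allele designations, marker '' | '?' | '!')."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return [], ""
    text = str(cell).strip()
    marker = ""
    if text[0] in "?!":
        marker, text = text[0], text[1:]
    return [t for t in text.split("/") if t], marker


def _occurrence_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("occ")]


def summarize_haplotype_table(df: pd.DataFrame) -> dict:
    """Descriptive statistics of one haplotype table.

    Family statistics use the *representative* row of each family — the first
    listed subtype — for allele-class counts, since variants within a family
    carry equal class counts. Confirmation is judged on summed occurrences
    (>= 2). Returns a plain dict of scalars and small mappings.
    """
    if df.empty:
        return {
            "n_rows": 0,
            "n_families": 0,
            "families_with_multiple_variants": 0,
            "subtype_counts": {},
            "confirmed_families": 0,
            "validation_flags": [],
        }
    occ_cols = _occurrence_cols(df)
    parsed = [parse_haplotype_id(h) for h in df["haplotype"]]
    df = df.assign(_family=[p.family for p in parsed], _sub=[p.subtype for p in parsed])

    out: dict = {"n_rows": int(len(df))}
    fam_groups = df.groupby("_family", sort=True)
    out["n_families"] = int(fam_groups.ngroups)
    subtype_counts = {int(f): int(len(g)) for f, g in fam_groups}
    out["subtype_counts"] = subtype_counts
    out["families_with_multiple_variants"] = sum(1 for v in subtype_counts.values() if v > 1)
    fam_occ = {int(f): int(g[occ_cols].to_numpy().sum()) for f, g in fam_groups}
    out["confirmed_families"] = sum(1 for v in fam_occ.values() if v >= 2)

    for col in ("n_standard", "n_universal", "total_expressed", "n_expressed"):
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            out[f"{col}_mean"] = float(vals.mean())
            out[f"{col}_min"] = int(vals.min())
            out[f"{col}_max"] = int(vals.max())

    if len(occ_cols) >= 2:
        shared = sum(
            1 for f, g in fam_groups if all(g[c].to_numpy().sum() > 0 for c in occ_cols)
        )
        out["families_shared_across_cohorts"] = int(shared)

    flags: list[str] = []
    class_cols = [c for cols in _ALLELE_CLASS_COLS.values() for c in cols if c in df.columns]
    if class_cols:
        reps = fam_groups.head(1)  # representative = first listed subtype row
        dists: dict[str, dict[int, int]] = {}
        for cls, cols in _ALLELE_CLASS_COLS.items():
            cols = [c for c in cols if c in df.columns]
            if not cols:
                continue
            counter: dict[int, int] = {}
            for _, row in reps.iterrows():
                n = 0
                for c in cols:
                    alleles, marker = _cell_alleles(row[c])
                    if alleles and marker != "!":
                        n += 1
                counter[n] = counter.get(n, 0) + 1
            dists[cls] = dict(sorted(counter.items()))
        out["allele_class_distributions"] = dists

        # validation: recount expressed genes per row ('?' cells excluded,
        # '!' cells included, matching the printed convention)
        count_col = "n_expressed" if "n_expressed" in df.columns else None
        if count_col:
            for _, row in df.iterrows():
                n = 0
                for c in class_cols:
                    alleles, marker = _cell_alleles(row[c])
                    if alleles and marker != "?":
                        n += 1
                if n != int(row[count_col]):
                    flags.append(
                        f"{row['haplotype']}: printed {count_col}={int(row[count_col])} "
                        f"but {n} designated cells"
                    )
    elif "alleles" in df.columns:
        count_col = "n_standard" if "n_standard" in df.columns else "n_universal"
        for _, row in df.iterrows():
            alleles = [a for a in str(row["alleles"]).split(";") if a]
            if len(alleles) != int(row[count_col]):
                flags.append(
                    f"{row['haplotype']}: printed {count_col}={int(row[count_col])} "
                    f"but {len(alleles)} listed alleles"
                )
    out["validation_flags"] = flags
    return out


def combined_family_stats(tables: Iterable[pd.DataFrame]) -> dict:
    """Family statistics across cohorts (e.g. Thoroughbred + Ice/Nor tables).

    A family's variants are its distinct subtype letters across all tables
    (a letterless row counts as one variant).
    """
    variants: dict[int, set[str]] = {}
    for df in tables:
        for hap in df["haplotype"]:
            p = parse_haplotype_id(hap)
            variants.setdefault(p.family, set()).add(p.subtype or "")
    return {
        "n_families": len(variants),
        "families_with_multiple_variants": sum(1 for v in variants.values() if len(v) > 1),
    }


def locus_read_proportions(
    calls: Iterable[SampleCallSet],
    locus_map: Mapping[str, str],
) -> pd.DataFrame:
    """Within-gene locus shares of reads, per animal.

    ``locus_map`` maps a called/recovered sequence (or allele name) to a
    locus label like ``DRB1``; the gene is the label's alphabetic prefix.
    Shares are computed over called+recovered reads of each animal and gene
    and sum to 1 within (animal, gene). Animals missing a gene are simply
    absent from that gene's rows. Returns a long DataFrame
    (animal, gene, locus, share).
    """
    rows = []
    totals: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str, str], float] = {}
    for cs in calls:
        for seq, entry in cs.present_sequences().items():
            locus = locus_map.get(seq)
            if locus is None:
                continue
            gene = locus.rstrip("0123456789")
            totals[(cs.sample_id, gene)] = totals.get((cs.sample_id, gene), 0.0) + entry.count
            key = (cs.sample_id, gene, locus)
            counts[key] = counts.get(key, 0.0) + entry.count
    for (animal, gene, locus), c in sorted(counts.items()):
        rows.append((animal, gene, locus, c / totals[(animal, gene)]))
    return pd.DataFrame(rows, columns=["animal", "gene", "locus", "share"])


def locus_share_summary(shares: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of per-animal locus shares, per gene and locus."""
    def q1(x):
        return float(np.percentile(x, 25))

    def q3(x):
        return float(np.percentile(x, 75))

    return (
        shares.groupby(["gene", "locus"])["share"]
        .agg(median="median", q1=q1, q3=q3, n="count")
        .reset_index()
    )


def allele_frequency_table(calls: Iterable[SampleCallSet]) -> pd.DataFrame:
    """Long table of (animal, amplicon, seq, frequency, status) for every
    called or recovered allele — the input for read-frequency dot plots with
    the 0.2% reference line."""
    rows = []
    for cs in calls:
        for e in cs.entries:
            if e.status in ("called", "recovered"):
                rows.append((cs.sample_id, cs.amplicon, e.seq, e.frequency, e.status))
    return pd.DataFrame(rows, columns=["animal", "amplicon", "seq", "frequency", "status"])


def linkage_table(
    assign_mhci: Mapping[str, AnimalAssignment],
    assign_mhcii: Mapping[str, AnimalAssignment],
    ids_mhci: Mapping[frozenset, str],
    ids_mhcii: Mapping[frozenset, str],
) -> tuple[dict[tuple[str, str], float], int]:
    """Cross-class haplotype association weights.

    Each animal assigned in both classes contributes total weight 1, split
    uniformly over the (MHCI, MHCII) pairings consistent with its diplotypes
    (phase across the two regions is unobservable from expression data: one
    pairing for double homozygotes, up to four for double heterozygotes).
    Returns (cell weights, number of animals excluded for being assigned in
    only one class). Total weight equals the number of contributing animals.
    """
    cells: dict[tuple[str, str], float] = {}
    excluded = 0
    animals = sorted(set(assign_mhci) | set(assign_mhcii))
    for a in animals:
        asg1 = assign_mhci.get(a)
        asg2 = assign_mhcii.get(a)
        if asg1 is None or asg2 is None or not asg1.haplotypes or not asg2.haplotypes:
            excluded += 1
            continue
        # uniform over slot pairings: homozygous slots collapse naturally, so a
        # double homozygote puts weight 1 in one cell, a double heterozygote
        # 0.25 in each of four cells
        n_pairings = len(asg1.haplotypes) * len(asg2.haplotypes)
        weights: dict[tuple[str, str], float] = {}
        for h1 in asg1.haplotypes:
            for h2 in asg2.haplotypes:
                key = (ids_mhci[h1], ids_mhcii[h2])
                weights[key] = weights.get(key, 0.0) + 1.0 / n_pairings
        for key, wv in weights.items():
            cells[key] = cells.get(key, 0.0) + wv
    return cells, excluded
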