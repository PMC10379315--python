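"""Amplicon (primer pair) definitions for the six-plex ELA panel.

The panel amplifies the polymorphic exon 2 (class II: DRA, DRB, DQA, DQB — one
primer pair each, primers in the conserved exons 1 and 3) and exons 2-3
(class I — two overlapping pairs, For1/Rev2.2 and For3.2/Rev1, whose combined
insert spans 410 bp). Primers contain IUPAC degeneracies; a small number of
alleles carry single-base mismatches under a primer, which the default
tolerance of one mismatch per primer accommodates. Alleles with more
mismatches drop out of that amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

MHCI_COMPOSITE_LEN = 410  # bp spanned by the union of the two class I amplicons
MHCI_FOR32_OFFSET = MHCI_COMPOSITE_LEN - 318  # For3.2/Rev1 insert start within the composite


@dataclass(frozen=True)
class AmpliconDef:
    name: str
    gene: str  # MHCI | DQA | DQB | DRA | DRB
    fwd_primer: str
    rev_primer: str
    expected_insert_len: int
    max_primer_mismatches: int = 1
    frame_offset: int = 0

    def __post_init__(self):
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError(f"{self.name}: primers must be non-empty")
        if self.expected_insert_len <= 0:
            raise ValueError(f"{self.name}: expected_insert_len must be positive")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"{self.name}: frame_offset must be 0, 1 or 2")


DEFAULT_PANEL: tuple[AmpliconDef, ...] = (
    AmpliconDef("MHCI_For1Rev2.2", "MHCI", "GTYGGCTAYGTGGACGAC", "SCCMTCYAGGTAGKYCCT", 378),
    AmpliconDef("MHCI_For3.2Rev1", "MHCI", "GGGCCGSARTATTGGGA", "CTCCAGGTRTCTGMGGAGC", 318),
    AmpliconDef("DRA", "DRA", "CAGCTGTCCTGATGAGCTTT", "AGCCACGTGACATCGATCAC", 360),
    AmpliconDef("DRB", "DRB", "GAGGCTCCTGGATGGCAGCT", "GTCTTTGCAGGATACACAGT", 341),
    AmpliconDef("DQA", "DQA", "GATCCTAAACAGAGCTCTGA", "AAGACAGATGAGGGTGTTGG", 370),
    AmpliconDef("DQB", "DQB", "GGCCTTTGGACAKYAGCT", "RGATGGGGAGAYGGTCAC", 351),
)

# Library pooling ratios of the six amplicons (class I pairs at 30% each,
# class II at 10% each).
POOL_RATIOS: dict[str, float] = {
    "MHCI_For1Rev2.2": 0.30,
    "MHCI_For3.2Rev1": 0.30,
    "DRA": 0.10,
    "DRB": 0.10,
    "DQA": 0.10,
    "DQB": 0.10,
}


def panel_by_name(panel: tuple[AmpliconDef, ...] = DEFAULT_PANEL) -> dict[str, AmpliconDef]:
    return {d.name: d for d in panel}


def load_panel(stream) -> tuple[AmpliconDef, ...]:
    """Read amplicon definitions from YAML (a list of mappings)."""
    data = yaml.safe_load(stream)
    defs = []
    for entry in data:
        defs.append(
            AmpliconDef(
                name=entry["name"],
                gene=entry["gene"],
                fwd_primer=entry["fwd_primer"].upper(),
                rev_primer=entry["rev_primer"].upper(),
                expected_insert_len=int(entry["expected_insert_len"]),
                max_primer_mismatches=int(entry.get("max_primer_mismatches", 1)),
                frame_offset=int(entry.get("frame_offset", 0)),
            )
        )
    return tuple(defs)


def dump_panel(panel: tuple[AmpliconDef, ...]) -> str:
    return yaml.safe_dump(
        [
            {
                "name": d.name,
                "gene": d.gene,
                "fwd_primer": d.fwd_primer,
                "rev_primer": d.rev_primer,
                "expected_insert_len": d.expected_insert_len,
                "max_primer_mismatches": d.max_primer_mismatches,
                "frame_offset": d.frame_offset,
            }
            for d in panel
        ],
        sort_keys=False,
    )
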