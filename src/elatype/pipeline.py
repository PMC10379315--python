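"""End-to-end orchestration: reads → call sets → genotype matrices → haplotypes.

This ties the stages together the way a genotyping run uses them; each stage
remains independently usable.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .amplicons import DEFAULT_PANEL, AmpliconDef
from .calling import (
    CallingConfig,
    SampleCallSet,
    apply_threshold,
    call_sample,
    denoise_artifacts,
    merge_mhci_amplicons,
    recovery_loop,
)
from .demux import FastqRead, MidScheme, RunReport, process_run
from .haplotypes import HaplotypePool, build_genotype_matrix, infer_haplotype_pool

MHCI_AMPLICONS = ("MHCI_For1Rev2.2", "MHCI_For3.2Rev1")


def genotype_run(
    read_pairs: Iterable[tuple[FastqRead, FastqRead]],
    scheme: MidScheme,
    panel: tuple[AmpliconDef, ...] = DEFAULT_PANEL,
    cfg: CallingConfig = CallingConfig(),
) -> tuple[list[SampleCallSet], RunReport]:
    """Demultiplex, merge, QC, assign, call and cohort-recover a whole run."""
    inserts, report = process_run(read_pairs, scheme, panel)
    callsets = [
        call_sample(sample, amp, seqs, cfg) for (sample, amp), seqs in sorted(inserts.items())
    ]
    return recovery_loop(callsets, cfg), report


def callsets_from_counts(
    counts: Mapping[tuple[str, str], Mapping[str, int]],
    cfg: CallingConfig = CallingConfig(),
) -> list[SampleCallSet]:
    """Call directly from dereplicated counts (e.g. simulator output),
    running the same denoise → threshold → recovery path."""
    callsets = [
        apply_threshold(
            denoise_artifacts(SampleCallSet.from_counts(sample, amp, dict(c)), cfg), cfg
        )
        for (sample, amp), c in sorted(counts.items())
    ]
    return recovery_loop(callsets, cfg)


def mhci_genotypes(callsets: Iterable[SampleCallSet]) -> dict[str, dict[str, float]]:
    """Per-animal class I allele supports after merging the two amplicons."""
    by_animal: dict[str, dict[str, SampleCallSet]] = {}
    for cs in callsets:
        if cs.amplicon in MHCI_AMPLICONS:
            by_animal.setdefault(cs.sample_id, {})[cs.amplicon] = cs
    out: dict[str, dict[str, float]] = {}
    for animal, by_amp in sorted(by_animal.items()):
        empty1 = SampleCallSet(animal, MHCI_AMPLICONS[0])
        empty2 = SampleCallSet(animal, MHCI_AMPLICONS[1])
        merged = merge_mhci_amplicons(
            by_amp.get(MHCI_AMPLICONS[0], empty1), by_amp.get(MHCI_AMPLICONS[1], empty2)
        )
        out[animal] = {a.key: a.support for a in merged}
    return out


def mhcii_genotypes(callsets: Iterable[SampleCallSet]) -> dict[str, dict[str, float]]:
    """Per-animal class II allele supports, keyed by (amplicon, sequence)."""
    out: dict[str, dict[str, float]] = {}
    for cs in callsets:
        if cs.amplicon in MHCI_AMPLICONS:
            continue
        bucket = out.setdefault(cs.sample_id, {})
        for seq, e in cs.present_sequences().items():
            key = f"{cs.amplicon}:{seq}"
            bucket[key] = max(bucket.get(key, 0.0), e.frequency)
    return out


def write_insert_fastas(inserts: Mapping[tuple[str, str], list[str]], outdir) -> None:
    """One FASTA of primer-trimmed inserts per (sample, amplicon)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (sample, amplicon), seqs in sorted(inserts.items()):
        path = outdir / f"{sample}.{amplicon}.fasta"
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">{sample}:{amplicon}:{i}\n{s}\n")


def haplotype_cohort(
    callsets: Iterable[SampleCallSet],
    mhc_class: str,
    min_support_animals: int = 2,
) -> HaplotypePool:
    """Genotype matrix plus haplotype inference for one MHC class."""
    callsets = list(callsets)
    geno = mhci_genotypes(callsets) if mhc_class == "MHCI" else mhcii_genotypes(callsets)
    matrix = build_genotype_matrix(geno)
    return infer_haplotype_pool(matrix, mhc_class, min_support_animals)
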