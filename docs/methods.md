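# Methods

This note records the models, rules and numerical choices behind `elatype`,
what the simulator does and does not emulate, and the design decisions taken
where more than one reasonable convention exists.

## Amplicon panel

Six PCRs cover the polymorphic regions: two overlapping class I amplicons
(For1/Rev2.2, 378 bp insert; For3.2/Rev1, 318 bp) spanning a 410 bp composite
of the exon 2/3 region, and one amplicon per class II gene (DRA 360, DRB 341,
DQA 370, DQB 351 bp) spanning exon 2. Primer sequences carry IUPAC
degeneracies; matching is set-based (K = G/T, Y = C/T, S = C/G, M = A/C,
R = A/G). The default tolerance is one mismatch per primer, because known
alleles carry documented single-base mismatches under several primers; an
allele with more mismatches than the tolerance drops out of that amplicon.
The class I redundancy exists precisely to catch such dropout: an allele is
accepted if seen in *either* class I amplicon, and segments that agree over
the 286 bp shared interval are joined into the 410 bp composite. Segments
with no unique consistent partner stay as partial records (some real alleles
only ever amplify at 318 bp).

Library pooling mixes the amplicons 30:30:10:10:10:10 (class I pairs vs the
four class II pools), so per-animal read depth differs threefold between
classes.

## Upstream processing

* **Demultiplexing** is exact on (forward, reverse) MID tag pairs, at most
  192 samples per run. No tag error correction: tags are short, and a
  mis-routed read costs more than a lost one.
* **Merging** scans every overlap length from the read length down to 10 bp
  and keeps the overlap maximising matching bases subject to a mismatch
  fraction ≤ 0.25, ties to the longer overlap. Disagreeing bases resolve to
  the higher Phred score, ties to the forward base. This reimplements the
  FLASH criterion rather than its exact internal scoring.
* **Quality**: mean Phred of the merged read strictly greater than 28. The
  aggregation (per-read mean) and strictness are configurable; these
  defaults are the package's reading of a bare ">Q28" specification.
* **Amplicon assignment** tries both orientations, requires both primers
  within tolerance, takes the fewest-total-mismatch panel entry, and reports
  ties as `ambiguous` rather than guessing.

## Allele calling

Frequencies are computed over the non-artifact reads of one sample and
amplicon — the denominator choice matters and is stated here because "% of
reads" alone does not fix it. Two artifact filters run before thresholding:

* **Shadows**: an entry within `shadow_max_mismatch` (default 1) edits of an
  entry at least `1/shadow_ratio` (default 10×) more abundant. This is a
  deliberately simple one-step rule, not a full error-model denoiser; it
  assumes the read depth is high enough that the 0.2% threshold sits well
  above error singletons (roughly ≥ 2000 reads per sample and amplicon —
  at a few hundred reads, two-error singletons can cross the threshold).
* **Chimeras**: an entry exactly equal to a prefix of one non-artifact entry
  plus the suffix of another (equal-length, both at least as abundant,
  `chimera_parent_ratio` = 1.0), detected via common-prefix/suffix lengths,
  which is equivalent to scanning every breakpoint.

The resolution threshold is 0.2% of reads, boundary inclusive (an entry at
exactly 0.2% is called); both the value and the boundary convention are
configurable. The **recovery loop** then re-admits sub-threshold entries
whose sequence *exactly* matches (full length) an allele called in at least
one animal, with at least `recovery_min_reads` = 2 reads. Exact identity —
not near-identity — prevents artifact laundering through the confirmed set.
Recovered entries do not themselves confirm further recoveries, so the loop
reaches its fixpoint in one pass and is independent of sample order. The
original pipeline this re-implements does not publish its artifact or
recovery rules; the rules above are this package's own, and all parameters
are exposed in `CallingConfig`.

## Nomenclature

Queries are translated in a per-gene reading frame registered at database
load: the frame in which ≥ 90% of that gene's reference alleles translate
without internal stops (the amplicons start mid-exon, so no start codon is
available). Classification per gene (MHCI, DQA, DQB, DRA, DRB — gene
identity comes from the amplicon, never from sequence similarity):

* nucleotide-identical → the known name;
* amino-acid distance 0 but nucleotide-different → synonymous variant,
  lettered in the matched group;
* 1–4 differences from the nearest same-gene entry → novel member of that
  group, next two-letter suffix (AA, AB, … ZZ; the suffix space is shared
  between synonymous and nonsynonymous variants, with the nucleotide
  sequence kept to distinguish them);
* more than 4 from everything → new allelic group,
  `Eqca-<gene>*<cc><n>:01` with country code gb/is/no and a per-(gene,
  country) counter.

Amino-acid distance is Hamming distance for equal lengths; otherwise the
substituted-plus-indel column count of a global alignment (match +1,
mismatch −1, gap −2), computed by a lexicographic dynamic program that
maximises score and then minimises the distance, making the value
deterministic when several alignments tie on score. Nearest-entry ties break
by nucleotide identity, then lexicographic group name. Accepted queries join
the database, so classification is idempotent and later queries compare
against earlier novelties; naming is a pure function of the processing
order, and a canonical ordering (by sample, then descending read count)
makes whole-cohort naming reproducible. Whether novel groups should be
numbered in detection or frequency order is unrecorded upstream; detection
order is used here. The ≤4-difference rule is applied to the full amplicon
translation (not an exon-2-only window), which is the stricter and simpler
reading.

## Haplotype inference

The genotype matrix holds presence (called or recovered) and support (max
read fraction across contributing amplicons) per animal and named allele.
Inference works on allele sets:

1. **Candidates** are seeded from whole-genotype recurrence (an animal's set
   contained in another's — putative homozygotes and repeated genotypes),
   from pairwise genotype intersections (the co-segregating block two
   animals share), and grown by residuals: an animal with exactly one
   candidate as a proper subset contributes the complement as a new
   candidate, to a fixpoint. The *proper*-subset condition matters: without
   it, two animals sharing a heterozygous diplotype would seed the fused
   union and block the residual forever.
2. **Assignment** picks, per animal, the candidate pair whose union equals
   its set, maximising combined containment support, then minimising total
   allele count (parsimony — this is what discards fused unions), then
   lexicographic order; remaining ties are flagged ambiguous. Animals with
   no consistent pair keep all alleles unassigned. Candidates never used in
   an assignment are pruned.
3. **Confirmation** requires the pattern in at least 2 distinct animals
   (a single homozygote contributes 2 occurrence slots but is still one
   animal, hence unconfirmed); unconfirmed ids carry the `un` prefix.
4. **Universal alleles** (allelic groups present on a majority of
   haplotypes) defeat residual subtraction because an animal's two
   haplotypes may share them. The exclusion set is seeded with allelic
   groups carried by more than 75% of animals, then grown by re-inference
   and pool-level classification (group coverage > 50% of haplotypes) until
   stable; excluded alleles are finally re-attached to every haplotype whose
   carrier animals all bear them. Because a very common haplotype can push
   its own alleles over the pre-pass fraction in a small cohort, inference
   also runs without the pre-pass and the run leaving the fewest alleles
   unexplained after re-attachment (ties: fewer unassigned animals, then
   fewer and smaller haplotypes) is kept. Promiscuous class II alleles (the
   DRB3 situation) follow the same rule.
5. **Families and subtypes**: single-linkage clustering at Jaccard ≥ 0.5
   (inclusive) on allelic-group content, so `*gb13:01 → *gb13:02`
   substitutions still match; families numbered by descending total
   occurrences, subtypes lettered a, b, c … likewise; singleton families
   unlettered. The 0.5 threshold is this package's operationalisation of an
   informal grouping and is configurable.
6. **Partial class II haplotypes** — no DQA or no DQB allele at all — gain a
   `p` marker after any `un` prefix.

The method needs recurrence: in a cohort where some haplotype never appears
as a homozygote, a repeated genotype, or a clean intersection, that
haplotype is not identifiable from presence data, and the corresponding
animals are honestly left unassigned (real cohorts contain such animals).
Determinism is guaranteed throughout by sorted iteration orders.

Cross-class linkage distributes each doubly assigned animal's unit weight
uniformly over the MHCI × MHCII pairings consistent with its diplotypes
(phase between the two regions is unobservable from expression data), so the
table's total weight equals the number of contributing animals.

## Simulator

The generator emulates the statistical structure the pipeline assumes, with
defaults matching the study conditions it models:

| parameter | default | meaning |
| --- | --- | --- |
| `n_animals` | 96 | cohort size |
| `n_mhci_haplotypes` / `n_mhcii_haplotypes` | 10 | pool sizes; animals are iid haplotype pairs (homozygotes arise naturally) |
| `mhci_alleles_range` | (6, 16) | total class I alleles per haplotype |
| `n_universal_shared` / `n_universal_variant` | 2 / 2 | class I alleles identical across all haplotypes, and allele groups with one variant per haplotype |
| class II layout | 1 DRA, 2 DQA, 2 DQB, 2–3 DRB | `drb3_prob` = 0.6 for the third DRB locus |
| `expression_decades` | 3.0 | class I weights log-uniform over 10⁻³…1; class II weights follow a locus hierarchy (DRB1 0.9, DRB2 0.08, DRB3 0.02; DQB1 0.7/DQB2 0.3; DQA1 0.6/DQA2 0.4) with ±0.3-decade jitter |
| `pool_ratios` | 30:30:10:10:10:10 | library mixing of the six amplicons |
| `reads_per_animal` | 20 000 | gives ≈ 2000 reads per class II amplicon, the depth at which the 0.2% threshold is meaningful |
| `error_rate` | 0.001 | uniform substitutions per base |
| `dropout_prob` / `tolerated_mismatch_prob` | 0 / 0.05 | per class I allele and amplicon: two (dropout) or one (tolerated) primer-site mismatches |
| `linkage_strength` | 0.8 | probability the class II haplotype is the partner of the drawn class I haplotype |
| `chimera_rate` | 0 | chimeric reads, available to exercise the chimera filter |

Reads are 300 bp with MID tags prepended, mates are opposite-strand windows
of the amplicon (overlap consistent with insert length), qualities constant
Q35. All randomness flows from the seed; identical seeds give byte-identical
reads. Not emulated: position-dependent Illumina error profiles, indels,
quality decay, PhiX spike-in, and within-locus allele similarity (simulated
alleles are random sequences, so simulated data is *easier* to dereplicate
and harder to chimera-confound than real MHC data — passing tests demonstrate
the pipeline logic, not robustness to near-identical paralogs).

## Problem sizes used in tests and the acceptance script

Benign-regime parameter recovery runs at 100 animals × 10 haplotypes per
class for five seeds on fully observed genotypes (the no-dropout regime);
read-level end-to-end checks run at 12 animals × 3 haplotypes ×
20 000 reads/animal, a size at which haplotype identifiability held for
every seed tested in a 40-seed sweep. The merge/demux conservation check
uses 1000 simulated pairs; oracle equivalences (translation, alignment
distance, overlap choice, chimera breakpoints, minimal haplotype pools) run
on exhaustively enumerable inputs. Published-table statistics come from the
packaged fixtures; the two cells of those tables with apparent print
inconsistencies are stored verbatim, flagged by the validator, and excluded
from every statistic the package reports.

## Known limitations

* Shadow filtering is single-step; at very high error rates or very low
  depth, multi-error reads can survive to the threshold stage.
* Haplotype inference reports one maximum-support decomposition per animal;
  animals consistent with several decompositions are flagged ambiguous
  rather than enumerated.
* Universal-allele re-attachment requires unanimity among carrier animals,
  so a universal allele sub-threshold (and unrecovered) in even one carrier
  detaches from that haplotype.
* Nomenclature compares full amplicon translations; official IPD assignment
  works on curated exon boundaries and may differ for length-variant
  alleles.
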