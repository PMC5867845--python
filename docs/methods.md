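# Methods

## Data model

The pipeline operates on per-position allele counts, not reads: one record
per sample × position holding forward and reverse read counts for A, C, G, T
(optionally a mean quality score per base). Producing such pileups from
alignments is a standard `samtools mpileup`-style step and is out of scope;
only substitutions are modeled — insertions/deletions and length
heteroplasmy (the 302/310 C-stretch, 16189 region) are excluded, and
position 310 is excluded from calling by default because apparent
substitutions there are artifacts of the adjacent homopolymer.

## Variant calling

Frequencies are fractions of the **total** position coverage over all four
bases (the convention that reproduces the printed worked example: 2255 minor
reads over an implied total of 11,214 = 20.11%, not of major+minor =
20.15%). The filter cascade, in order: total coverage ≥ 200 → minor
fraction ≥ 1% (analytical threshold, applied to raw fractions, not rounded
percentages) → minor reads ≥ 40 → strand balance ≤ 2.5 → quality balance
≤ 10 (only when quality columns are present; per-base mean quality is the
only quality summary the count data model can carry) → reported iff minor
fraction ≥ 2% (reporting threshold). Major-allele ties break
lexicographically (A<C<G<T) and are logged. The detection floor at a
position is max(analytical threshold, min reads / coverage); coverage is
"adequate for reporting" when that floor is ≤ the reporting threshold,
i.e. ≥ 2000 reads at defaults.

**Strand balance.** The default statistic is the minor allele's
forward/reverse odds normalised by the major allele's odds (folded to ≥ 1).
Rationale: long-range-PCR amplicon data shows locus-wide strand imbalance
affecting both alleles equally (e.g. a genuine 15% variant at 552:155 under
a major at 3088:856 — raw minor ratio 3.6, normalised ratio 1.01), while
the artifacts the filter exists for are *one-sided* minors under balanced
majors, which remain infinite/large under both readings. The raw max/min of
the minor allele's strand counts is available as
`FilterConfig(balance_mode="minor_only")`. A minor allele observed on a
single strand always fails.

## Quartet classification

For each family and each position where at least one of the four samples
(mother/child × buccal/blood) has a reported call, the slot pattern decides
the label: ≥ 1 reported tissue in each member → **shared** (this covers the
one-tissue-of-each pattern, and the 2+1 pattern, by the literal reading of
the definition); both tissues of one member and neither of the other →
**differentiating**; exactly one slot → **random**; the three labels are
mutually exclusive and exhaust all nonzero patterns. Site identity is the
position alone — minor-variant direction is ignored, so a mother
heteroplasmic toward the variant and a child heteroplasmic back toward the
reference match at the same site.

For differentiating sites, "absence" in the non-carrier requires coverage
adequate for the reporting threshold in both of that member's tissues;
otherwise the site is downgraded to *unclassifiable* and logged (absence
cannot be certified below the detection floor). Random sites are taken at
face value (the single-slot rule), without the adequacy requirement.

A **primary haplotype change** is flagged when the mother's and child's
consensus (major) alleles differ, compared tissue against tissue. Carrier
buccal/blood comparisons report the fold difference (max/min of the two
minor frequencies), which tissue is higher, and the 10% band (both below /
both above / mixed).

## Group statistics

Frequency sets pool minor-variant percentages per label: every reported
slot of a shared site (so up to four observations per site), the carrier's
two slots of a differentiating site, the single slot of a random site.
Non-detections are excluded, never imputed as zero — with the packaged
shared-site table this is the convention that reproduces the printed mean
(54 = 56 slots − 2 non-detections → 15.6%). Group comparisons use the Welch
unequal-variance two-sample t-test with Welch–Satterthwaite degrees of
freedom and two-sided p-values (scipy's implementation; the df is
recomputed explicitly for reporting).

## Error profiling

At each sample × position, every base call constituting ≤ 50% of the reads
is assumed erroneous; per-position rates sum those calls across samples and
divide by summed coverage, and average rates pool all positions. The ≤ 50%
cut is applied per sample *before* aggregation. This is deliberately
conservative: true heteroplasmy below 50% is included and inflates the
estimate (a constructed fixture in the tests demonstrates a 20% site
contributing 20 points). Zero-coverage positions are flagged and excluded
from averages; the placeholder position 3107 is excluded throughout. Rates
print in percent to 4 significant figures. The hotspot report ranks the top
rates per base (default depth 25, extended to 35 for C — following the
practice of extending the C list to include all rates above 2%), attaches
the flanking context and motif flags, and warns about any position/base
rate exceeding the reporting threshold, since calls there need manual
scrutiny even though balance and quality filters usually reject them.

## Flanking contexts and motifs

`adjacent_sequence` returns 3 bases each side of a position (marked `*`),
extended through the entire run when the flank is homopolymeric, wrapping
the circular origin. Motif flags are: a run of ≥ 3 A (or ≥ 3 C) abutting
the site on either side, or the trinucleotide GGT immediately adjacent.
Two rows of the packaged hotspot-context table do not follow the
convention the table itself states (np 2465's printed context crosses a
non-homopolymeric base; np 10287's contradicts the overlapping np 10290
row, whose reading matches the genome); they are documented exclusions in
the context tests.

## Reference scaffold

The packaged reference (`data/rcrs_scaffold_synthetic.fasta`) is a
**synthetic rCRS-coordinate scaffold**, not the NCBI NC_012920.1 record: a
real human mitochondrial genome (NC_001807.4) remapped onto the 16,569-bp
rCRS numbering (three extra C's in the origin-region and 16183-region
C-runs removed, the historical placeholder restored as N at 3107) and
patched to the documented rCRS allele at every anchor locus the packaged
tables print. Verified anchors: all 108 regular hotspot flanking contexts,
all 35 printed variant-site reference bases, and the reference and alternate
amino acids at all 11 protein-coding variant sites under the vertebrate
mitochondrial code (ATA=Met, TGA=Trp, AGA/AGG=stop; light-strand ND6
reverse-complemented). Positions away from anchored loci are real human
mtDNA sequence but are not guaranteed base-identical to the rCRS; every
sequence-dependent test and result in this package exercises anchored loci
only. The gene map is the standard NC_012920.1 annotation; overlapping
features (ATP8/ATP6, ND4L/ND4, tRNA-Ile/Gln, tRNA-Cys/Tyr) resolve to the
first feature in map order, intergenic spacers carry a `non_coding`
category so the map tiles all 16,569 positions, and the control region is
16024–16569 ∪ 1–576 (the convention consistent with every printed site
annotation: all five control-region differentiating sites fall inside it,
all coding-region sites outside).

## Table fixtures

The packaged transcriptions of the two cohort tables are checksummed and
loaded fail-hard. Differentiating-site pileups rebuild the printed
forward:reverse counts exactly; the total coverage is inferred from the
printed major count and percentage (total = major/major%), because the
printed denominators include third/fourth alleles, and the small residual
(≤ a few dozen reads) is split over the two remaining bases. Shared-site
pileups synthesize counts at 10,000× coverage (a round figure safely above
the 2000-read floor; the table prints no counts) reproducing each printed
percentage to two decimals, with non-detected slots emitted flat. Slots
whose minor variant *is* the reference base need a non-reference major: the
partner sample's printed variant is used where available, otherwise the
canonical transition allele — classification depends only on within-family
major-allele identity. Unlisted families are emitted flat at 10,000× at
every fixture position, so non-carrier "absence" is certified at adequate
coverage throughout.

## Simulator

The generator produces the statistical structure the analysis assumes, with
the simplest mechanism at each stage: one binomial segregation through an
effective germline bottleneck (default size 9, the small end of the
published range, chosen because it reproduces the pronounced
mother-child drift that motivates the method; a multi-generation
Wright-Fisher chain would add parameters without changing the assumed
structure), one further binomial segregation per tissue (defaults: blood
500, buccal 150 effective units — buccal smaller so buccal heteroplasmy
runs higher and more variable, as observed across tissue panels), founder
frequencies uniform on [0.02, 0.5] at 2 seeded sites per family, lognormal
coverage with median 24,000 (the study-scale depth) and σ = 0.5, and
per-read substitution error 0.05% (the order of the measured per-base
averages) spread uniformly over the three non-template bases, with optional
hotspot-multiplier and strand-bias knobs. Reads split 50/50 binomially
across strands. Identical configurations (including the seed) produce
byte-identical output.

What the simulator does **not** emulate: PCR duplicates and jackpot
amplification, alignment- and motif-driven coverage troughs, quality-score
structure, indels/length heteroplasmy, and selection against
non-synonymous variants. Tests passing on simulated cohorts therefore
validate the estimators' arithmetic and the classification logic under the
assumed sampling model, not robustness to those real-data artifacts.

## Problem sizes

The packaged-cohort pipeline (39 families × 4 samples × 35 positions) runs
in seconds. Simulation-backed checks use 13 families (52 samples) × 1000
positions for error-rate recovery, 25 families × 2500 positions for
classification recovery, and 10,000 replicates for drift moments — sizes
chosen so the full suite and the acceptance script run in minutes on one
CPU while keeping Monte-Carlo error well inside the asserted tolerances.
Cohort-scale error-rate and coverage figures from the study's raw 156-sample
dataset (billions of base calls) are outside desk scale by construction;
the property-based checks above stand in for them.
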